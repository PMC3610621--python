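"""Elliptic solvers on the cell-centered grid with zero-flux boundaries.

Two problems recur in the model:

* screened diffusion (quasi-steady substrate/VEGF):  ``(c(x) - D lap) u = s``
* variable-mobility pressure Poisson:  ``div(k(x) grad p) = rhs``

Both are solved matrix-free with conjugate gradients, preconditioned by an
exact constant-coefficient solve in DCT space (the cosine basis diagonalises
the zero-flux Laplacian on a regular grid).  The pure-Neumann Poisson problem
is singular: the right-hand side is projected to zero mean (physically, a
uniform water efflux balances net tissue creation) and the solution is gauged
to zero mean.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve exhausts its budget; carries residuals."""

    def __init__(self, message, residuals):
        super().__init__(message)
        self.residuals = list(residuals)


def laplacian_neumann(u: np.ndarray, h: float) -> np.ndarray:
    """Second-order 5/7-point Laplacian with reflecting (zero-flux) boundaries."""
    out = np.zeros_like(u)
    for ax in range(u.ndim):
        lo = [slice(None)] * u.ndim
        hi = [slice(None)] * u.ndim
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        d = np.diff(u, axis=ax)          # u[i+1]-u[i] at interior faces
        out[tuple(hi)] += d              # inflow across the upper face
        out[tuple(lo)] -= d              # outflow across the lower face
    return out / h**2


def _dct_eigenvalues(shape, h):
    """Eigenvalues of the (negated) zero-flux Laplacian in the DCT-II basis."""
    eig = np.zeros(shape)
    for ax, n in enumerate(shape):
        k = np.arange(n)
        lam = (2.0 - 2.0 * np.cos(np.pi * k / n)) / h**2
        sh = [1] * len(shape)
        sh[ax] = n
        eig = eig + lam.reshape(sh)
    return eig


def _pcg(apply_A, b, precond, rtol, maxiter, project=None):
    """Preconditioned CG; ``project`` removes a known nullspace component."""
    x = np.zeros_like(b)
    r = b.copy()
    if project is not None:
        r = project(r)
    b_norm = np.linalg.norm(b) or 1.0
    residuals = [np.linalg.norm(r) / b_norm]
    if residuals[-1] <= rtol:
        return x, residuals
    z = precond(r)
    p = z.copy()
    rz = float(np.vdot(r, z))
    for _ in range(maxiter):
        Ap = apply_A(p)
        alpha = rz / float(np.vdot(p, Ap))
        x += alpha * p
        r -= alpha * Ap
        if project is not None:
            r = project(r)
        res = np.linalg.norm(r) / b_norm
        residuals.append(res)
        if res <= rtol:
            return x, residuals
        z = precond(r)
        rz_new = float(np.vdot(r, z))
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"CG failed to reach rtol={rtol} in {maxiter} iterations "
        f"(final residual {residuals[-1]:.3e})", residuals)


def solve_screened(D: float, c: np.ndarray, s: np.ndarray, h: float,
                   rtol: float = 1e-8, maxiter: int = 2000):
    """Solve ``(c(x) - D lap) u = s`` with zero-flux boundaries.

    ``c >= 0`` pointwise with ``c > 0`` somewhere (otherwise the operator is
    singular); returns ``(u, residuals)``.
    """
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(c < 0):
        raise ValueError("screened-diffusion coefficient c must be >= 0")
    if not np.any(c > 0):
        if np.allclose(s, 0.0):
            return np.zeros_like(s), [0.0]
        raise ValueError("c == 0 everywhere with a nonzero source: no steady state")
    c_bar = float(c.mean())
    eig = D * _dct_eigenvalues(s.shape, h) + c_bar

    def precond(r):
        rh = sfft.dctn(r, type=2, norm="ortho")
        return sfft.idctn(rh / eig, type=2, norm="ortho")

    def apply_A(u):
        return c * u - D * laplacian_neumann(u, h)

    return _pcg(apply_A, s, precond, rtol, maxiter)


def _face_harmonic(k: np.ndarray, ax: int) -> np.ndarray:
    lo = np.take(k, range(k.shape[ax] - 1), axis=ax)
    hi = np.take(k, range(1, k.shape[ax]), axis=ax)
    return 2.0 * lo * hi / (lo + hi)


def div_k_grad(p: np.ndarray, k: np.ndarray, h: float) -> np.ndarray:
    """``div(k grad p)`` with harmonic face mobilities and zero-flux boundaries."""
    out = np.zeros_like(p)
    for ax in range(p.ndim):
        kf = _face_harmonic(k, ax)
        flux = kf * np.diff(p, axis=ax)   # k * dp at interior faces
        lo = [slice(None)] * p.ndim
        hi = [slice(None)] * p.ndim
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        out[tuple(hi)] += flux
        out[tuple(lo)] -= flux
    return out / h**2


def solve_pressure(k: np.ndarray, rhs: np.ndarray, h: float,
                   rtol: float = 1e-8, maxiter: int = 2000):
    """Solve ``div(k grad p) = rhs`` (zero-flux, zero-mean gauge).

    The source is projected to zero mean for solvability; the returned
    pressure has zero mean.  Returns ``(p, residuals)``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("mobility must be strictly positive everywhere")
    rhs = np.asarray(rhs, dtype=float)
    b = -(rhs - rhs.mean())          # SPD form: -div(k grad) p = -rhs

    k_bar = float(k.mean())
    eig = k_bar * _dct_eigenvalues(rhs.shape, h)
    eig_safe = np.where(eig > 0, eig, 1.0)   # constant mode handled by projection

    def project(r):
        return r - r.mean()

    def precond(r):
        rh = sfft.dctn(r, type=2, norm="ortho")
        rh /= eig_safe
        flat = rh.reshape(-1)
        flat[0] = 0.0                 # remove the constant mode
        out = sfft.idctn(rh, type=2, norm="ortho")
        return out - out.mean()

    def apply_A(p):
        return -div_k_grad(p, k, h)

    p, residuals = _pcg(apply_A, b, precond, rtol, maxiter, project=project)
    return p - p.mean(), residuals
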