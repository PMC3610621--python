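"""IHC conversion formulas, fixture generation, and the calibration model."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphsim.calibration import (AcceptanceBands, IHCCalibration,
                                  apoptosis_rate, hypoxic_cell_fraction,
                                  proliferation_rate, read_ihc_csv,
                                  stained_fraction, synth_ihc,
                                  validate_ihc_table,
                                  vascular_support_fraction)


class TestConversionFormulas:
    @pytest.mark.parametrize("f, mean_n, expected", [
        (0.0, 1.0, 0.0),
        (0.5, 1.0, 0.6),     # (0.5/20 h) * 24 h/day
        (0.5, 0.5, 1.2),
        (1.0, 1.0, 1.2),
    ])
    def test_proliferation_rate(self, f, mean_n, expected):
        assert proliferation_rate(f, mean_n) == pytest.approx(expected)

    @pytest.mark.parametrize("f, expected", [
        (0.0, 0.0),
        (0.1, 0.48),         # (0.1/5 h) * 24 h/day
        (1.0, 4.8),
    ])
    def test_apoptosis_rate(self, f, expected):
        assert apoptosis_rate(f) == pytest.approx(expected)

    @pytest.mark.parametrize("f, expected", [
        (0.0, 1.0), (1.0, 0.0), (0.75, 0.125),
    ])
    def test_vascular_support(self, f, expected):
        assert vascular_support_fraction(f) == pytest.approx(expected)

    @pytest.mark.parametrize("f, expected", [
        (0.0, 0.0), (1.0, 1.0), (0.25, 0.125),
    ])
    def test_hypoxic_fraction(self, f, expected):
        assert hypoxic_cell_fraction(f) == pytest.approx(expected)

    def test_zero_mean_substrate_rejected(self):
        with pytest.raises(ValueError, match="mean_n"):
            proliferation_rate(0.5, 0.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apoptosis_rate(1.5)

    def test_monotone_and_bounded_over_fraction_grid(self):
        fs = np.linspace(0, 1, 51)
        lam_A = [apoptosis_rate(f) for f in fs]
        lam_Mn = [proliferation_rate(f, 1.0) for f in fs]
        hyp = [hypoxic_cell_fraction(f) for f in fs]
        sup = [vascular_support_fraction(f) for f in fs]
        assert all(np.diff(lam_A) > 0) and max(lam_A) == pytest.approx(4.8)
        assert all(np.diff(lam_Mn) > 0) and max(lam_Mn) == pytest.approx(1.2)
        assert all(np.diff(hyp) >= 0) and all(np.diff(sup) <= 0)
        assert all(0 <= v <= 1 for v in hyp + sup)


class TestSynthIhc:
    def test_large_counts_concentrate_at_target(self):
        t = synth_ihc({"Ki67": (0.5, 0.5)}, counts=10**6, rng=0)
        assert stained_fraction(t, "Ki67") == pytest.approx(0.5, abs=1e-3)

    def test_zero_fraction_all_unstained(self):
        t = synth_ihc({"HIF1a": (0.0, 0.0)}, counts=500, rng=0)
        assert t["stained"].sum() == 0

    def test_fixed_seed_reproducible(self):
        a, b = synth_ihc("baseline", rng=5), synth_ihc("baseline", rng=5)
        pd.testing.assert_frame_equal(a, b)

    def test_contrast_scaling(self):
        t = synth_ihc("resistant", counts=10**5, rng=0, contrast=0.0)
        core = stained_fraction(t, "CD31", region="core")
        peri = stained_fraction(t, "CD31", region="periphery")
        assert core == pytest.approx(peri, abs=0.01)

    def test_resistant_preset_has_central_ec_enrichment(self):
        t = synth_ihc("resistant", counts=10**5, rng=0)
        core = stained_fraction(t, "CD31", region="core")
        peri = stained_fraction(t, "CD31", region="periphery")
        assert core / peri == pytest.approx(4.0, rel=0.1)

    def test_schema_valid_and_five_sections(self):
        t = validate_ihc_table(synth_ihc("baseline", rng=0))
        assert sorted(t["section"].unique()) == ["S1", "S2", "S3", "S4", "S5"]
        assert set(t["region"].unique()) == {"core", "periphery"}


class TestIhcTableValidation:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            validate_ihc_table(pd.DataFrame({"section": ["S1"]}))

    def test_unknown_marker_rejected(self):
        t = synth_ihc("baseline", rng=0)
        t.loc[0, "marker"] = "CD99"
        with pytest.raises(ValueError, match="marker"):
            validate_ihc_table(t)

    def test_empty_row_counts_rejected(self):
        t = synth_ihc("baseline", rng=0)
        t.loc[0, ["stained", "unstained"]] = 0
        with pytest.raises(ValueError, match="> 0"):
            validate_ihc_table(t)

    def test_csv_round_trip(self, tmp_path):
        t = synth_ihc("baseline", rng=0)
        path = tmp_path / "ihc.csv"
        t.to_csv(path, index=False)
        pd.testing.assert_frame_equal(read_ihc_csv(path), t)


class TestCalibrationModel:
    def test_calibration_is_pure(self):
        t = synth_ihc("baseline", rng=0)
        r1 = IHCCalibration(t).fit(mean_n=0.7)
        r2 = IHCCalibration(t).fit(mean_n=0.7)
        assert r1.lambda_M == r2.lambda_M and r1.lambda_A == r2.lambda_A

    def test_round_trip_reproduces_A_relationship(self):
        """fixture fractions -> rates -> A matches the analytic
        A = 4 <n> f_Casp3 / f_Ki67 up to sampling error."""
        f_K, f_C, mean_n = 0.8, 0.2, 0.6
        t = synth_ihc({"Ki67": (f_K, f_K), "Casp3": (f_C, f_C),
                       "CD31": (0.5, 0.5), "HIF1a": (0.2, 0.2),
                       "HE": (0.9, 0.9)}, counts=10**5, rng=1)
        r = IHCCalibration(t).fit(mean_n=mean_n)
        assert r.A_ratio == pytest.approx(4 * mean_n * f_C / f_K, rel=0.02)

    def test_summary_and_dict_report_rates(self):
        r = IHCCalibration(synth_ihc("baseline", rng=0)).fit()
        assert "lambda_M" in r.summary()
        d = r.to_dict()
        assert d["A_ratio"] == pytest.approx(r.A_ratio)

    def test_apply_installs_rates(self):
        from lymphsim.params import ModelParameters
        r = IHCCalibration(synth_ihc("baseline", rng=0)).fit()
        p = r.apply(ModelParameters())
        assert p.lambda_M == pytest.approx(r.lambda_M)
        assert p.vascular_support == pytest.approx(r.vascular_support)


class TestAcceptanceBands:
    def test_fixture_bands_bracket_fixture_values(self):
        t = synth_ihc("baseline", rng=0)
        bands = AcceptanceBands.from_fixture(t)
        hyp = hypoxic_cell_fraction(stained_fraction(t, "HIF1a"))
        lam_A = apoptosis_rate(stained_fraction(t, "Casp3"))
        assert bands.accepts(hyp, lam_A)

    def test_vacuous_bands_accept_everything(self):
        bands = AcceptanceBands(hypoxic=(0.0, 1.0), apoptosis=(0.0, np.inf))
        assert bands.accepts(0.99, 123.0)

    def test_disjoint_bands_reject_everything(self):
        bands = AcceptanceBands(hypoxic=(2.0, 3.0), apoptosis=(0.0, np.inf))
        assert not bands.accepts(0.5, 1.0)


def test_two_voxel_toy_necrosis_monotonicity():
    """Exhaustive stepping of a two-voxel tissue: one supported voxel, one
    hypoxic. A larger necrosis rate clears the hypoxic voxel's viable
    tissue sooner, so the voxel-measure hypoxic fraction at a fixed time is
    monotone non-increasing in lambda_N."""
    from lymphsim.params import ModelParameters

    def hypoxic_fraction_after(lambda_N_nd, t=2.0, dt=0.001):
        p = ModelParameters(lambda_N_nd=lambda_N_nd)
        rho = np.array([1.0, 1.0])       # [supported, hypoxic]
        n = np.array([1.0, 0.0])
        for _ in range(int(t / dt)):
            growth = p.lambda_M * n * (n > p.n_N) * rho
            death = (p.lambda_A + p.lambda_N * (n < p.n_N)) * rho
            rho = np.clip(rho + dt * (growth - death), 0.0, 1.0)
        viable = rho > 1e-3
        return (viable & (n < p.n_N)).sum() / max(viable.sum(), 1)

    fracs = [hypoxic_fraction_after(lam) for lam in (0.0, 2.0, 6.0, 12.0)]
    assert all(b <= a for a, b in zip(fracs, fracs[1:]))
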