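"""Viability normalization, 4PL IC50 fitting and transwell permeability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpascreen import (
    DoseResponseDataset,
    SimConfig,
    exposure_ratio,
    fit_ic50,
    gen_dose_response,
    normalize_viability,
    permeability,
    summarize_viability,
    teer_normalize,
)
from bpascreen.errors import AssayError


class TestViability:
    def test_signal_equal_vehicle_is_100(self):
        assert normalize_viability([1.0], 1.0)[0] == 100.0

    def test_zero_signal_is_zero(self):
        assert normalize_viability([0.0], 1.0)[0] == 0.0

    def test_triplicate_mean_and_sd(self):
        ds = DoseResponseDataset(
            "x",
            [(1.0, 0, 0.5), (1.0, 1, 0.55), (1.0, 2, 0.45), (2.0, 0, 0.4)],
            vehicle_signal=1.0,
        )
        summary = summarize_viability(ds)
        row = summary[summary["concentration"] == 1.0].iloc[0]
        assert row["mean"] == pytest.approx(50.0)
        assert row["sd"] == pytest.approx(5.0)

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(AssayError):
            normalize_viability([1.0], 0.0)


def noiseless_dataset(ic50=1.0, hill=1.0, top=100.0, bottom=0.0, n=8):
    cfg = SimConfig(noise_sd_pct=0.0, n_concentrations=n)
    return gen_dose_response(
        {"ic50": ic50, "hill": hill, "top": top, "bottom": bottom}, cfg
    )


class TestIc50Fit:
    def test_noiseless_curve_recovered_exactly(self):
        fit = fit_ic50(noiseless_dataset(ic50=1.0))
        assert fit.converged
        assert fit.ic50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)
        assert fit.top == pytest.approx(100.0, abs=1e-3)
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)

    def test_noisy_triplicates_within_15pct(self):
        cfg = SimConfig(seed=20230420, noise_sd_pct=5.0, n_concentrations=8, replicates=3)
        ds = gen_dose_response({"ic50": 2.87}, cfg)  # the HR76-scale value
        fit = fit_ic50(ds)
        assert fit.converged
        assert fit.ic50 == pytest.approx(2.87, rel=0.15)

    def test_monotone_increasing_viability_flagged(self):
        concs = np.geomspace(0.1, 10, 6)
        points = [(float(c), 0, 20.0 + 10.0 * i) for i, c in enumerate(concs)]
        fit = fit_ic50(DoseResponseDataset("up", points))
        assert not fit.converged
        assert fit.diagnostics["monotone_increasing"]

    def test_too_few_concentrations_rejected(self):
        points = [(c, 0, 50.0) for c in (1.0, 2.0, 4.0)]
        with pytest.raises(AssayError, match="concentrations"):
            fit_ic50(DoseResponseDataset("few", points))

    def test_scale_equivariance(self):
        base = noiseless_dataset(ic50=1.5)
        scaled = DoseResponseDataset(
            "scaled", [(c * 7.0, r, s) for c, r, s in base.points]
        )
        f1, f2 = fit_ic50(base), fit_ic50(scaled)
        assert f2.ic50 == pytest.approx(7.0 * f1.ic50, rel=1e-5)

    def test_parameter_recovery_over_simulations(self):
        # 200 triplicate datasets at 5% noise: median |error| < 10% and the
        # fitted residual SD is consistent with the generating noise
        errors, resids = [], []
        for seed in range(200):
            cfg = SimConfig(seed=seed, noise_sd_pct=5.0)
            true_ic50 = 0.5 + 4.5 * (seed / 200.0)
            fit = fit_ic50(gen_dose_response({"ic50": true_ic50}, cfg))
            assert fit.converged
            errors.append(abs(fit.ic50 - true_ic50) / true_ic50)
            resids.append(fit.residual_sd)
        assert float(np.median(errors)) < 0.10
        assert float(np.median(resids)) == pytest.approx(5.0, rel=0.35)


class TestPermeability:
    def test_printed_geometry_arithmetic(self):
        p = permeability(0.5, 2.5, 10800.0, 0.33, 25.0)
        assert p == pytest.approx(1.40e-5, rel=0.01)

    def test_zero_receiver_concentration(self):
        assert permeability(0.5, 0.0, 10800.0, 0.33, 25.0) == 0.0

    def test_doubling_time_halves_p(self):
        p1 = permeability(0.5, 2.5, 10800.0, 0.33, 25.0)
        p2 = permeability(0.5, 2.5, 21600.0, 0.33, 25.0)
        assert p2 == pytest.approx(p1 / 2.0)

    @given(
        c_a=st.floats(0.01, 100),
        t=st.floats(600, 1e5),
        s=st.floats(0.1, 5),
        c_l=st.floats(0.1, 100),
        k=st.floats(1.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_linearity_properties(self, c_a, t, s, c_l, k):
        p = permeability(0.5, c_a, t, s, c_l)
        assert permeability(0.5, k * c_a, t, s, c_l) == pytest.approx(k * p, rel=1e-9)
        assert permeability(0.5, c_a, k * t, s, c_l) == pytest.approx(p / k, rel=1e-9)
        assert permeability(0.5, c_a, t, k * s, c_l) == pytest.approx(p / k, rel=1e-9)
        assert permeability(0.5, c_a, t, s, k * c_l) == pytest.approx(p / k, rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(AssayError):
            permeability(0.5, 2.5, -1.0, 0.33, 25.0)


class TestTeerNormalization:
    def test_reference_teer_unchanged(self):
        assert teer_normalize(1e-5, 150.0, 150.0) == 1e-5

    def test_double_teer_doubles_p(self):
        assert teer_normalize(1e-5, 300.0, 150.0) == pytest.approx(2e-5)

    def test_batch_mean_reference_preserves_mean_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1e-4, 12)
        teer = rng.uniform(100, 200, 12)
        ref = teer.mean()
        # normalizing a constant-P batch to its mean TEER preserves the mean
        const_p = np.full(12, 2e-5)
        normalized = [teer_normalize(pi, ti, ref) for pi, ti in zip(const_p, teer)]
        assert np.mean(normalized) == pytest.approx(2e-5, rel=1e-12)
        del p

    def test_nonpositive_teer_rejected(self):
        with pytest.raises(AssayError):
            teer_normalize(1e-5, 0.0, 150.0)


class TestExposure:
    def test_printed_brain_tumor_values_exceed_3fold(self):
        ratio = exposure_ratio(3.7, 1.17)
        assert ratio == pytest.approx(3.16, abs=0.01)
        assert ratio > 3.0

    def test_unity(self):
        assert exposure_ratio(1.0, 1.0) == 1.0

    def test_subtherapeutic_below_one(self):
        assert exposure_ratio(0.5, 1.0) == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(AssayError):
            exposure_ratio(0.0, 1.0)
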