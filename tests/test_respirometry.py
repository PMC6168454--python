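import logging

import numpy as np
import pandas as pd
import pytest

from polskit.respirometry import (
    ClosedPhase,
    RespirometryTrace,
    estimate_smr,
    extract_closed_phase_slopes,
    fit_two_normal_mixture,
    smr_from_trace,
)
from polskit.simulate import generate_respirometry_trace


def make_phase(slope, retained=True, pid=0):
    return ClosedPhase(pid, slope, 0.99, 4000.0, 600.0, retained)


def synthetic_trace(phases):
    """Build a trace DataFrame from (phase_type, times, o2) triples."""
    rows = []
    for pid, (ptype, t, y) in enumerate(phases):
        for tt, yy in zip(t, y):
            rows.append((tt, yy, pid, ptype))
    return pd.DataFrame(rows, columns=["time_s", "o2_mg_per_l", "phase_id", "phase_type"])


class TestTraceValidation:
    def test_requires_increasing_time(self):
        df = synthetic_trace([("closed", [0.0, 1.0, 1.0], [8, 8, 8])])
        with pytest.raises(ValueError, match="strictly increasing"):
            RespirometryTrace(df, 5e-4, 0.1)

    def test_requires_alternating_phases(self):
        df = pd.concat(
            [
                synthetic_trace([("closed", [0.0, 1.0], [8, 8])]),
                synthetic_trace([("closed", [2.0, 3.0], [8, 8])]).assign(phase_id=1),
            ]
        )
        with pytest.raises(ValueError, match="alternate"):
            RespirometryTrace(df, 5e-4, 0.1)

    def test_requires_positive_mass_and_volume(self):
        df = synthetic_trace([("closed", [0.0, 1.0], [8, 8])])
        with pytest.raises(ValueError, match="positive"):
            RespirometryTrace(df, 0.0, 0.1)


class TestSlopeExtraction:
    def test_exact_line_recovered_and_retained(self):
        t = np.arange(0.0, 600.0, 5.0) + 4000.0
        y = 8.0 - 0.01 * (t - t[0]) / 60.0
        df = synthetic_trace([("closed", t, y)])
        tr = RespirometryTrace(df, 5e-4, 0.1)
        (phase,) = extract_closed_phase_slopes(tr)
        assert phase.slope_mg_per_l_min == pytest.approx(-0.01, abs=1e-12)
        assert phase.r_squared == pytest.approx(1.0)
        assert phase.retained

    def test_curvature_drops_r2_below_threshold(self):
        # quadratic bend sized so that an independently computed OLS R^2
        # falls below 0.95: the phase must not be retained
        t = np.arange(0.0, 600.0, 5.0)
        tm = t[(t >= 120.0) & (t <= t[-1] - 120.0)]
        y_all = 8.0 - 0.01 * t / 60.0 + 4e-3 * (t / 60.0 - 5.0) ** 2
        ym = 8.0 - 0.01 * tm / 60.0 + 4e-3 * (tm / 60.0 - 5.0) ** 2
        # independent R^2 oracle: squared Pearson correlation
        r2_oracle = np.corrcoef(tm, ym)[0, 1] ** 2
        df = synthetic_trace([("closed", t + 4000.0, y_all)])
        tr = RespirometryTrace(df, 5e-4, 0.1)
        (phase,) = extract_closed_phase_slopes(tr)
        assert phase.r_squared == pytest.approx(r2_oracle, abs=1e-10)
        if r2_oracle < 0.95:
            assert not phase.retained
        # the constructed curvature is meant to violate the filter
        assert r2_oracle < 0.95

    def test_first_hour_phase_excluded_regardless_of_fit(self):
        t = np.arange(0.0, 600.0, 5.0) + 30.0 * 60.0  # starts at 30 min
        y = 8.0 - 0.01 * (t - t[0]) / 60.0
        df = synthetic_trace([("closed", t, y)])
        tr = RespirometryTrace(df, 5e-4, 0.1)
        (phase,) = extract_closed_phase_slopes(tr)
        assert phase.r_squared == pytest.approx(1.0)
        assert not phase.retained
        assert "acclimation" in phase.reason

    def test_no_closed_phases_warns_and_returns_empty(self, caplog):
        t = np.arange(0.0, 300.0, 5.0)
        df = synthetic_trace([("open", t, np.full_like(t, 8.0))])
        tr = RespirometryTrace(df, 5e-4, 0.1)
        with caplog.at_level(logging.WARNING):
            out = extract_closed_phase_slopes(tr)
        assert out == []
        assert any("no closed phases" in r.message for r in caplog.records)

    def test_phase_too_short_after_trimming_flagged(self):
        t = np.arange(0.0, 250.0, 5.0) + 4000.0
        y = 8.0 - 0.01 * (t - t[0]) / 60.0
        df = synthetic_trace([("closed", t, y)])
        tr = RespirometryTrace(df, 5e-4, 0.1)
        (phase,) = extract_closed_phase_slopes(tr)
        assert not phase.retained
        assert "short" in phase.reason


class TestMixtureAndSMR:
    def test_unit_conversion_arithmetic(self):
        # slope -0.01 mg/L/min, 1 L chamber, 0.5 g fish -> 1200 mg O2/kg/h
        phases = [make_phase(-0.01, pid=i) for i in range(5)]
        est = estimate_smr(phases, fish_mass_kg=5e-4, chamber_volume_l=1.0)
        assert est.smr_mass_specific == pytest.approx(1200.0)

    def test_identical_slopes_collapse_mixture(self):
        phases = [make_phase(-150.0 / (60.0 * 2000.0), pid=i) for i in range(6)]
        est = estimate_smr(phases, fish_mass_kg=5e-4, chamber_volume_l=1.0)
        assert est.mixture_means[0] == pytest.approx(est.mixture_means[1])
        assert est.smr_mass_specific == pytest.approx(150.0)

    def test_too_few_retained_phases_is_an_error(self):
        phases = [make_phase(-0.01, pid=i) for i in range(3)]
        with pytest.raises(ValueError, match="retained phases"):
            estimate_smr(phases, 5e-4, 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_em_recovers_lower_component_mean(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate(
            [rng.normal(100.0, 5.0, 40), rng.normal(200.0, 5.0, 40)]
        )
        mu, sd, w, ll = fit_two_normal_mixture(x, seed=seed)
        assert mu[0] == pytest.approx(100.0, rel=0.02)
        assert mu[1] == pytest.approx(200.0, rel=0.02)

    def test_em_matches_sklearn_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(100.0, 8.0, 60), rng.normal(180.0, 10.0, 30)])
        mu, sd, w, ll = fit_two_normal_mixture(x, seed=3)
        gm = GaussianMixture(2, n_init=10, random_state=0, tol=1e-8).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        np.testing.assert_allclose(mu, ref, rtol=0.02)

    def test_mixture_brackets_sample_mean(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.concatenate(
                [rng.normal(90.0, 6.0, 30), rng.normal(210.0, 12.0, 20)]
            )
            mu, _, _, _ = fit_two_normal_mixture(x, seed=seed)
            assert mu[0] <= x.mean() <= mu[1]

    def test_smr_tracks_resting_not_overall_mean(self):
        # raising activity probability shifts the overall mean upward but
        # must leave the lower-component (resting) estimate near truth
        truth = 0.05 * 60.0 * 0.1 / 5e-4
        for p_active in (0.2, 0.5):
            trace, _ = generate_respirometry_trace(
                -0.05, -0.15, p_active, noise_sd=0.01, seed=11
            )
            tr = RespirometryTrace(trace, 5e-4, 0.1)
            est, _ = smr_from_trace(tr, seed=11)
            assert est.smr_mass_specific == pytest.approx(truth, rel=0.05)
            rates_mean = np.mean(est.mixture_weights[0] * est.mixture_means[0]
                                 + est.mixture_weights[1] * est.mixture_means[1])
            assert rates_mean > est.smr_mass_specific
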