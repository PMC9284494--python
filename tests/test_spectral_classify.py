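"""Spectral classification: periodograms, autocorrelations, bootstrap
cutoffs and the class-assignment ladder."""

import numpy as np
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from chronomics import (AutocorrVector, SyntheticConfig, assign_class,
                        autocorrelations, bootstrap_null, classify_subject,
                        frame_frequencies, generate_cohort, lomb_scargle,
                        plant_lag_signal)
from chronomics.spectral_classify import CutoffSet
from conftest import make_series


def uneven_grid(rng, n=14, step=7.0, span=40):
    days = np.sort(rng.choice(np.arange(1, span) * step, n - 1, replace=False))
    return np.concatenate([[0.0], days])


class TestLombScargle:
    def test_matches_scipy_on_uneven_grid(self):
        rng = np.random.default_rng(0)
        t = uneven_grid(rng)
        y = rng.normal(size=len(t))
        p = lomb_scargle(t, y, t)
        ref = scipy_lombscargle(t, y - y.mean(), 2 * np.pi * p.frequencies)
        np.testing.assert_allclose(p.powers, ref, atol=1e-10)

    def test_pure_cosine_identified_at_second_harmonic(self):
        t = np.arange(16.0)
        freqs, _ = frame_frequencies(t)
        y = np.cos(2 * np.pi * freqs[1] * t + 0.4)
        p = lomb_scargle(t, y, t)
        assert np.argmax(p.powers) == 1

    def test_cosine_survives_missing_points(self):
        rng = np.random.default_rng(3)
        t_full = np.arange(16.0)
        freqs, _ = frame_frequencies(t_full)
        keep = np.sort(rng.choice(16, 11, replace=False))
        y = np.cos(2 * np.pi * freqs[1] * t_full + 0.4)
        p = lomb_scargle(t_full[keep], y[keep], t_full)
        assert np.argmax(p.powers) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        t = uneven_grid(rng)
        y = rng.normal(size=len(t))
        p1 = lomb_scargle(t, y, t)
        p2 = lomb_scargle(t, y, t)
        np.testing.assert_array_equal(p1.powers, p2.powers)

    def test_constant_series_rejected(self):
        t = np.arange(8.0)
        with pytest.raises(ValueError, match="constant"):
            lomb_scargle(t, np.ones(8), t)


class TestAutocorrelations:
    def test_rho0_is_one(self):
        rng = np.random.default_rng(1)
        t = uneven_grid(rng)
        p = lomb_scargle(t, rng.normal(size=len(t)), t)
        ac = autocorrelations(p)
        assert abs(ac.values[0] - 1.0) < 1e-9
        assert np.all(np.abs(ac.values) <= 1 + 1e-9)

    def test_matches_circular_autocorrelation_on_uniform_grid(self):
        """Harmonic signals on a complete uniform grid: the inverse-transform
        autocorrelation equals the direct circular sample autocorrelation."""
        rng = np.random.default_rng(2)
        n, delta = 12, 7.0
        t = np.arange(n) * delta
        k = np.arange(1, (n - 1) // 2 + 1)
        a, b = rng.normal(size=len(k)), rng.normal(size=len(k))
        y = (a * np.cos(2 * np.pi * np.outer(t, k) / (n * delta))
             + b * np.sin(2 * np.pi * np.outer(t, k) / (n * delta))).sum(axis=1)
        ac = autocorrelations(lomb_scargle(t, y, t))
        yc = y - y.mean()
        direct = np.array([(yc * np.roll(yc, -j)).sum() for j in
                           range(n // 2 + 1)]) / (yc * yc).sum()
        np.testing.assert_allclose(ac.values, direct, atol=1e-6)

    def test_slow_signal_rho1_exceeds_rho5(self):
        t = np.arange(20.0) * 7
        y = plant_lag_signal(t, lag=1, amplitude=3.0, noise_sd=1.0, seed=4)
        ac = autocorrelations(lomb_scargle(t, y - y[0], t))
        assert ac.values[1] > ac.values[5]


def _noise_pool(rng, times, n_series=40):
    return [make_series(omic=f"g{j}", times=tuple(times),
                        values=tuple(rng.normal(size=len(times))))
            for j in range(n_series)]


class TestBootstrapNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        t = np.arange(10.0) * 7
        pool = _noise_pool(rng, t)
        c1 = bootstrap_null(pool, t, B=2000, seed=42)
        c2 = bootstrap_null(pool, t, B=2000, seed=42)
        np.testing.assert_array_equal(c1.rho_cutoffs, c2.rho_cutoffs)
        assert c1.spike_max == c2.spike_max

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(7)
        t = np.arange(10.0) * 7
        pool = _noise_pool(rng, t)
        c95 = bootstrap_null(pool, t, B=4000, q_auto=0.95, seed=1)
        c99 = bootstrap_null(pool, t, B=4000, q_auto=0.99, seed=1)
        assert np.all(c99.rho_cutoffs >= c95.rho_cutoffs)

    def test_lag1_cutoff_matches_direct_null_simulation(self):
        """Bootstrap cutoff vs brute-force i.i.d. Gaussian null for the
        same lag-1 statistic on a complete uniform grid."""
        rng = np.random.default_rng(8)
        t = np.arange(20.0) * 7
        pool = _noise_pool(rng, t, n_series=60)
        cut = bootstrap_null(pool, t, B=10_000, seed=2)

        sims = []
        for _ in range(10_000):
            y = rng.normal(size=20)
            ac = autocorrelations(lomb_scargle(t, y - y[0], t))
            sims.append(ac.values[1])
        direct = np.quantile(sims, 0.95)
        assert abs(cut.rho_cutoffs[0] - direct) < 0.05

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_null([], np.arange(10.0), B=2000, seed=0)

    def test_small_B_rejected(self):
        rng = np.random.default_rng(9)
        t = np.arange(10.0) * 7
        with pytest.raises(ValueError, match="B"):
            bootstrap_null(_noise_pool(rng, t), t, B=10, seed=0)


def _manual_cutoffs(rho_cutoffs, max_cn, min_cn, n):
    return CutoffSet(rho_cutoffs=np.asarray(rho_cutoffs, float),
                     spike_max={n: max_cn}, spike_min={n: min_cn},
                     q_auto=0.95, q_spike=0.95, B=1000, seed=0)


class TestAssignClass:
    def _ac(self, values):
        values = np.asarray(values, float)
        return AutocorrVector(lags=np.arange(len(values)), values=values)

    def test_min_lag_rule(self):
        cut = _manual_cutoffs([0.5, 0.5], 3.1, -3.1, 5)
        label = assign_class(self._ac([1, 0.8, 0.2]), (1.0, -1.0, 5), cut)
        assert (label.kind, label.lag) == ("Lag", 1)

    def test_min_lag_skips_failing_lag(self):
        cut = _manual_cutoffs([0.5, 0.5], 3.1, -3.1, 5)
        label = assign_class(self._ac([1, 0.2, 0.6]), (1.0, -1.0, 5), cut)
        assert (label.kind, label.lag) == ("Lag", 2)

    def test_fallback_ladder(self):
        cut = _manual_cutoffs([0.5, 0.5], 3.1, -3.1, 5)
        up = assign_class(self._ac([1, 0.2, 0.1]), (5.0, -1.0, 5), cut)
        down = assign_class(self._ac([1, 0.2, 0.1]), (1.0, -5.0, 5), cut)
        neither = assign_class(self._ac([1, 0.2, 0.1]), (1.0, -1.0, 5), cut)
        assert up.kind == "SpikeMax"
        assert down.kind == "SpikeMin"
        assert neither.kind == "NoTrend"

    def test_lag_precedence_over_spike(self):
        cut = _manual_cutoffs([0.5, 0.5], 3.1, -3.1, 5)
        label = assign_class(self._ac([1, 0.9, 0.1]), (9.0, -9.0, 5), cut)
        assert label.kind == "Lag"

    def test_equality_passes_lag_but_not_spike(self):
        cut = _manual_cutoffs([0.5], 3.1, -3.1, 5)
        at_cut = assign_class(self._ac([1, 0.5]), (3.1, -3.1, 5), cut)
        assert (at_cut.kind, at_cut.lag) == ("Lag", 1)
        spike_eq = assign_class(self._ac([1, 0.1]), (3.1, -3.1, 5), cut)
        assert spike_eq.kind == "NoTrend"  # spike comparisons are strict

    def test_missing_length_cutoff_errors(self):
        cut = _manual_cutoffs([0.5], 3.1, -3.1, 5)
        with pytest.raises(ValueError, match="length"):
            assign_class(self._ac([1, 0.1]), (1.0, -1.0, 7), cut)


class TestClassifySubject:
    @pytest.fixture(scope="module")
    def classified(self):
        cfg = SyntheticConfig(n_subjects=1,
                              n_omics_per_modality={"transcript": 120},
                              visits_per_subject=(12, 12),
                              frac_lag_responders={1: 0.15},
                              frac_spike_max=0.1, frac_spike_min=0.0,
                              missing_fraction=0.0, seed=31)
        ds, _, truth = generate_cohort(cfg)
        subject = ds.subjects[0]
        signals = ds.subject_signals(subject)
        frame = ds.subject_days(subject)
        cutoffs = bootstrap_null(list(signals.values()), frame, B=5000,
                                 seed=1)
        df = classify_subject(signals, cutoffs, frame)
        df["truth"] = [truth.classes[(subject, o)] for o in df["omic"]]
        return df

    def test_every_eligible_signal_labeled(self, classified):
        assert len(classified) == 120
        assert set(classified["kind"]) <= {"Lag", "SpikeMax", "SpikeMin",
                                           "NoTrend"}
        assert (classified.loc[classified["kind"] == "Lag", "lag"] >= 1).all()

    def test_planted_lag1_mostly_recovered(self, classified):
        lag1 = classified[classified["truth"] == "Lag1"]
        assert (lag1["class"] == "Lag1").mean() >= 0.8

    def test_planted_spikes_mostly_recovered(self, classified):
        spk = classified[classified["truth"] == "SpikeMax"]
        assert (spk["class"] == "SpikeMax").mean() >= 0.5

    def test_p_values_valid_and_monotone_with_q(self, classified):
        trend = classified[classified["kind"] != "NoTrend"]
        assert trend["p"].between(0, 1).all()
        assert (trend["q"] >= trend["p"] - 1e-12).all()

    def test_notrend_never_significant(self, classified):
        nt = classified[classified["kind"] == "NoTrend"]
        assert not nt["significant"].any()
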