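"""Spectral categorization of omics time series.

Each signal is represented by a Lomb-Scargle periodogram evaluated at the
harmonics of its time frame, inverted to a lag-domain autocorrelation
vector, and assigned to a temporal class by a bootstrap-calibrated ladder:

1. *Lag l* — the smallest lag whose autocorrelation reaches its null cutoff
   (0.95 quantile of a value-resampling bootstrap null);
2. otherwise *SpikeMax* / *SpikeMin* — a single visit above the null maxima
   cutoff (or below the minima cutoff) for the series' length, with the
   extremes taken on the unit-normalized series so that pooled per-length
   cutoffs are comparable across omics of different units and scales;
3. otherwise *NoTrend*.

Frequency grid.  A frame of N stamps spanning T days has nominal spacing
δ = T/(N−1) and circular period W = N·δ; powers are evaluated at
f_k = k/W for k = 1..⌊N/2⌋.  The autocorrelation at lag j (time offset
j·δ) is then the normalized inverse cosine transform of the powers,
ρ_j = Σ_k P_k cos(2πkj/N) / Σ_k P_k, which reproduces the circular sample
autocorrelation exactly for harmonic signals on complete uniform grids.

Significance.  Every statistic in the ladder is probability-integral
transformed against its bootstrap null; a signal's empirical p-value is the
null exceedance probability of the *maximum* transformed statistic over the
whole ladder, so p is uniform under the null despite the selection over
lags and spike sides.  Benjamini-Hochberg is applied per subject within
each assigned class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_model import TimeSeries
from .preprocess import CommonTimeFrame

__all__ = [
    "Periodogram", "AutocorrVector", "CutoffSet", "ClassLabel",
    "frame_frequencies", "lomb_scargle", "autocorrelations",
    "bootstrap_null", "assign_class", "classify_subject",
]

MIN_OBSERVED = 4  # minimum observed points for a periodogram


@dataclass
class Periodogram:
    frequencies: np.ndarray  # cycles/day, k/W for k = 1..⌊(N−1)/2⌋
    powers: np.ndarray       # non-negative
    n_grid: int              # N, the frame size the grid derives from


@dataclass
class AutocorrVector:
    lags: np.ndarray    # 0..⌊N/2⌋
    values: np.ndarray  # ρ_0 == 1


@dataclass
class ClassLabel:
    kind: str            # "Lag" | "SpikeMax" | "SpikeMin" | "NoTrend"
    lag: int = 0         # ≥ 1 only for Lag
    statistic: float = np.nan
    p: float = np.nan
    q: float = np.nan
    significant: bool = False

    @property
    def label(self) -> str:
        return f"Lag{self.lag}" if self.kind == "Lag" else self.kind


# ---------------------------------------------------------------------------
# Frequency grid and Lomb-Scargle
# ---------------------------------------------------------------------------

def frame_frequencies(frame: CommonTimeFrame | np.ndarray
                      ) -> tuple[np.ndarray, int]:
    """Harmonic frequency grid f_k = k/(N·δ), k = 1..⌊(N−1)/2⌋, of a frame."""
    days = frame.days if isinstance(frame, CommonTimeFrame) else np.asarray(frame, float)
    n = len(days)
    if n < MIN_OBSERVED:
        raise ValueError(f"frame needs ≥ {MIN_OBSERVED} stamps, got {n}")
    span = days[-1] - days[0]
    if span <= 0:
        raise ValueError("frame span must be positive")
    delta = span / (n - 1)
    # the Nyquist harmonic k = n/2 (even n) is omitted: its sine basis is
    # near-degenerate on quasi-regular uneven grids and the power estimate
    # blows up, contaminating the inverse-transform autocorrelations
    k = np.arange(1, (n - 1) // 2 + 1)
    return k / (n * delta), n


def _lombscargle_batch(times: np.ndarray, values: np.ndarray,
                       freqs: np.ndarray) -> np.ndarray:
    """Classical Lomb-Scargle power for many series sharing one time vector.

    ``values`` is (B, n); rows are mean-centered internally.  Returns (B, m)
    powers; P = (A²N/4) for a harmonic of amplitude A on a complete grid.
    """
    t = np.asarray(times, float)
    y = np.atleast_2d(np.asarray(values, float))
    y = y - y.mean(axis=1, keepdims=True)
    omega = 2.0 * np.pi * np.asarray(freqs, float)

    wt = omega[:, None] * t[None, :]                    # (m, n)
    tau = 0.5 * np.arctan2(np.sin(2 * wt).sum(axis=1),
                           np.cos(2 * wt).sum(axis=1)) / omega
    arg = wt - (omega * tau)[:, None]
    c, s = np.cos(arg), np.sin(arg)
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    yc = y @ c.T                                        # (B, m)
    ys = y @ s.T
    # at exact Nyquist alignment ss (or cc) → 0 with the numerator; drop term
    eps = 1e-12 * len(t)
    pc = np.where(cc > eps, yc * yc / np.where(cc > eps, cc, 1.0), 0.0)
    ps = np.where(ss > eps, ys * ys / np.where(ss > eps, ss, 1.0), 0.0)
    return 0.5 * (pc + ps)


def lomb_scargle(times: np.ndarray, values: np.ndarray,
                 frame: CommonTimeFrame | np.ndarray) -> Periodogram:
    """Lomb-Scargle periodogram of one observed series on a frame's harmonics.

    ``times``/``values`` are the observed samples (no NaN); the frame fixes
    the frequency grid so periodograms are comparable across signals.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < MIN_OBSERVED:
        raise ValueError(f"need ≥ {MIN_OBSERVED} observed points")
    if np.ptp(values) == 0:
        raise ValueError("constant series has no periodogram; flag upstream")
    freqs, n_grid = frame_frequencies(frame)
    powers = _lombscargle_batch(times, values[None, :], freqs)[0]
    return Periodogram(frequencies=freqs, powers=powers, n_grid=n_grid)


# ---------------------------------------------------------------------------
# Autocorrelations
# ---------------------------------------------------------------------------

def _autocorr_from_powers(powers: np.ndarray, n_grid: int) -> np.ndarray:
    """Rows of normalized inverse-cosine-transform autocorrelations."""
    p = np.atleast_2d(powers)
    m = p.shape[1]
    k = np.arange(1, m + 1)
    j = np.arange(0, n_grid // 2 + 1)
    cosmat = np.cos(2.0 * np.pi * np.outer(k, j) / n_grid)   # (m, lags)
    total = p.sum(axis=1, keepdims=True)
    return (p @ cosmat) / total


def autocorrelations(p: Periodogram) -> AutocorrVector:
    """Lag-domain autocorrelations ρ_j, j = 0..⌊N/2⌋, with ρ_0 = 1."""
    if np.all(p.powers == 0):
        raise ValueError("all-zero periodogram")
    rho = _autocorr_from_powers(p.powers, p.n_grid)[0]
    return AutocorrVector(lags=np.arange(len(rho)), values=rho)


# ---------------------------------------------------------------------------
# Bootstrap null calibration
# ---------------------------------------------------------------------------

def _normalize_rows(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-subtract and unit-normalize rows; returns (deltas, Q, ok)."""
    deltas = raw - raw[:, :1]
    norms = np.linalg.norm(deltas, axis=1)
    ok = norms > 0
    q = np.where(ok[:, None], deltas / np.where(ok, norms, 1.0)[:, None], 0.0)
    return deltas, q, ok


@dataclass
class CutoffSet:
    """Bootstrap-calibrated cutoffs and the null distributions behind them.

    ``rho_cutoffs[k-1]`` is the q_auto quantile of null ρ_k; ``spike_max[n]``
    / ``spike_min[n]`` the q_spike / (1−q_spike) quantiles of null extremes
    for series length n.  Sorted null samples are retained to evaluate
    probability-integral transforms and ladder p-values.
    """

    rho_cutoffs: np.ndarray
    spike_max: dict[int, float]
    spike_min: dict[int, float]
    q_auto: float
    q_spike: float
    B: int
    seed: int | None
    null_rho_sorted: np.ndarray = field(repr=False, default=None)
    null_max_sorted: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    null_min_sorted: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    null_lag_u_sorted: np.ndarray = field(repr=False, default=None)
    null_spike_u_sorted: np.ndarray = field(repr=False, default=None)
    null_all_u_sorted: np.ndarray = field(repr=False, default=None)

    @property
    def n_lags(self) -> int:
        return len(self.rho_cutoffs)

    def _pit_rho(self, rho_tail: np.ndarray) -> np.ndarray:
        """Null CDF values of ρ_1..ρ_L (rows)."""
        rho_tail = np.atleast_2d(rho_tail)
        out = np.empty_like(rho_tail)
        for k in range(rho_tail.shape[1]):
            col = self.null_rho_sorted[:, k]
            out[:, k] = np.searchsorted(col, rho_tail[:, k], side="right")
        return out / self.null_rho_sorted.shape[0]

    def lag_statistic(self, rho_tail: np.ndarray) -> float:
        """Max probability-integral-transformed autocorrelation over lags."""
        return float(self._pit_rho(np.asarray(rho_tail))[0].max())

    def spike_statistic(self, xmax: float, xmin: float, n: int) -> float:
        """Max transformed extreme over the two spike sides, given length."""
        smax = self.null_max_sorted[n]
        smin = self.null_min_sorted[n]
        fmax = np.searchsorted(smax, xmax, side="right") / len(smax)
        fmin = 1.0 - np.searchsorted(smin, xmin, side="left") / len(smin)
        return float(max(fmax, fmin))

    @staticmethod
    def _exceedance(null_sorted: np.ndarray, u: float) -> float:
        b = len(null_sorted)
        n_ge = b - np.searchsorted(null_sorted, u, side="left")
        return (1.0 + n_ge) / (b + 1.0)

    def p_value(self, kind: str, u_lag: float, u_spike: float) -> float:
        """Selection-aware empirical p-value of one signal.

        The null exceedance is evaluated against the statistic family the
        class decision actually used: the max-over-lags transformed
        autocorrelation for Lag classes, the max-over-sides transformed
        extreme for spike classes, and the overall ladder maximum for
        NoTrend, so p is uniform under the null despite the selection
        inside each family.
        """
        if kind == "Lag":
            return self._exceedance(self.null_lag_u_sorted, u_lag)
        if kind in ("SpikeMax", "SpikeMin"):
            return self._exceedance(self.null_spike_u_sorted, u_spike)
        return self._exceedance(self.null_all_u_sorted, max(u_lag, u_spike))


def bootstrap_null(pool: list[TimeSeries] | dict[str, TimeSeries],
                   frame: CommonTimeFrame | np.ndarray,
                   B: int = 100_000,
                   q_auto: float = 0.95,
                   q_spike: float = 0.95,
                   seed: int | None = None) -> CutoffSet:
    """Calibrate autocorrelation and spike cutoffs on a bootstrap null.

    Each replicate picks a pool series uniformly at random and resamples its
    observed values with replacement onto its own time stamps, destroying
    temporal order while preserving the marginal distribution.  Replicates
    are baseline-subtracted, unit-normalized, and pushed through the same
    periodogram → autocorrelation path as real signals.
    """
    if isinstance(pool, dict):
        pool = list(pool.values())
    pool = [ts for ts in pool
            if ts.n_observed >= MIN_OBSERVED and np.ptp(ts.observed_values) > 0]
    if not pool:
        raise ValueError("bootstrap pool is empty")
    if B < 1000:
        raise ValueError("B must be ≥ 1000")

    freqs, n_grid = frame_frequencies(frame)
    n_lags = n_grid // 2
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pool), size=B)

    rho_null = np.empty((B, n_lags))
    max_null = np.empty(B)
    min_null = np.empty(B)
    lengths = np.empty(B, dtype=int)

    for i, ts in enumerate(pool):
        rows = np.flatnonzero(draws == i)
        if rows.size == 0:
            continue
        vals = ts.observed_values
        t_obs = ts.observed_times
        n = len(vals)
        raw = rng.choice(vals, size=(rows.size, n), replace=True)
        deltas, q, ok = _normalize_rows(raw)
        while not ok.all():  # resampled-constant rows: redraw (vanishing prob)
            bad = np.flatnonzero(~ok)
            raw[bad] = rng.choice(vals, size=(bad.size, n), replace=True)
            deltas, q, ok = _normalize_rows(raw)
        powers = _lombscargle_batch(t_obs, q, freqs)
        rho = _autocorr_from_powers(powers, n_grid)
        rho_null[rows] = rho[:, 1:]
        # spike extremes on the unit-normalized scale: pooled per-length
        # cutoffs are only comparable across omics after normalization
        max_null[rows] = q.max(axis=1)
        min_null[rows] = q.min(axis=1)
        lengths[rows] = n

    rho_cutoffs = np.quantile(rho_null, q_auto, axis=0)
    null_rho_sorted = np.sort(rho_null, axis=0)

    spike_max: dict[int, float] = {}
    spike_min: dict[int, float] = {}
    null_max_sorted: dict[int, np.ndarray] = {}
    null_min_sorted: dict[int, np.ndarray] = {}
    for n in np.unique(lengths):
        sel = lengths == n
        spike_max[int(n)] = float(np.quantile(max_null[sel], q_spike))
        spike_min[int(n)] = float(np.quantile(min_null[sel], 1.0 - q_spike))
        null_max_sorted[int(n)] = np.sort(max_null[sel])
        null_min_sorted[int(n)] = np.sort(min_null[sel])

    cutoffs = CutoffSet(rho_cutoffs=rho_cutoffs, spike_max=spike_max,
                        spike_min=spike_min, q_auto=q_auto, q_spike=q_spike,
                        B=B, seed=seed,
                        null_rho_sorted=null_rho_sorted,
                        null_max_sorted=null_max_sorted,
                        null_min_sorted=null_min_sorted)

    # ladder statistics of every null replicate, for selection-aware p-values
    u_lag = cutoffs._pit_rho(rho_null).max(axis=1)
    u_spike = np.empty(B)
    for n in np.unique(lengths):
        sel = lengths == n
        smax, smin = null_max_sorted[int(n)], null_min_sorted[int(n)]
        fmax = np.searchsorted(smax, max_null[sel], side="right") / len(smax)
        fmin = 1.0 - np.searchsorted(smin, min_null[sel], side="left") / len(smin)
        u_spike[sel] = np.maximum(fmax, fmin)
    cutoffs.null_lag_u_sorted = np.sort(u_lag)
    cutoffs.null_spike_u_sorted = np.sort(u_spike)
    cutoffs.null_all_u_sorted = np.sort(np.maximum(u_lag, u_spike))
    return cutoffs


# ---------------------------------------------------------------------------
# Class assignment
# ---------------------------------------------------------------------------

def assign_class(ac: AutocorrVector,
                 extremes: tuple[float, float, int],
                 cutoffs: CutoffSet) -> ClassLabel:
    """Apply the classification ladder: Lag (min passing lag, ≥ cutoff),
    then SpikeMax (strict >), then SpikeMin (strict <), else NoTrend."""
    rho_tail = ac.values[1:]
    n_lags = min(len(rho_tail), cutoffs.n_lags)
    if len(rho_tail) > cutoffs.n_lags:
        raise ValueError("cutoffs do not cover all lags of the signal")
    passing = np.flatnonzero(rho_tail[:n_lags] >= cutoffs.rho_cutoffs[:n_lags])
    xmax, xmin, n = extremes
    if n not in cutoffs.spike_max:
        raise ValueError(f"no spike cutoff for series length {n}")
    if passing.size:
        lag = int(passing[0]) + 1
        return ClassLabel(kind="Lag", lag=lag, statistic=float(rho_tail[lag - 1]))
    if xmax > cutoffs.spike_max[n]:
        return ClassLabel(kind="SpikeMax", statistic=float(xmax))
    if xmin < cutoffs.spike_min[n]:
        return ClassLabel(kind="SpikeMin", statistic=float(xmin))
    return ClassLabel(kind="NoTrend")


def classify_subject(subject_signals: dict[str, TimeSeries],
                     cutoffs: CutoffSet,
                     frame: CommonTimeFrame | np.ndarray,
                     fdr_level: float = 0.05) -> pd.DataFrame:
    """Label every eligible signal of one subject and assess significance.

    Returns a table with one row per eligible (non-constant, ≥ 4 observed
    values) signal: omic, kind, lag, statistic, p, q, significant.  BH is
    applied across the subject's signals within each assigned class; only
    trend classes can be significant.
    """
    freqs, n_grid = frame_frequencies(frame)

    # group signals by observed-time pattern so periodograms batch
    groups: dict[tuple, list[str]] = {}
    for omic, ts in subject_signals.items():
        if ts.n_observed < MIN_OBSERVED or np.ptp(ts.observed_values) == 0:
            continue
        groups.setdefault(tuple(ts.observed_times.tolist()), []).append(omic)

    rows = []
    for t_key, omics in groups.items():
        t_obs = np.array(t_key)
        raw = np.stack([subject_signals[o].observed_values for o in omics])
        deltas, q, ok = _normalize_rows(raw)
        powers = _lombscargle_batch(t_obs, q, freqs)
        rho = _autocorr_from_powers(powers, n_grid)
        n = len(t_obs)
        for r, omic in enumerate(omics):
            if not ok[r]:  # constant after baseline subtraction
                continue
            ac = AutocorrVector(lags=np.arange(rho.shape[1]), values=rho[r])
            xmax = float(q[r].max())
            xmin = float(q[r].min())
            label = assign_class(ac, (xmax, xmin, n), cutoffs)
            u_lag = cutoffs.lag_statistic(rho[r, 1:])
            u_spike = cutoffs.spike_statistic(xmax, xmin, n)
            label.p = cutoffs.p_value(label.kind, u_lag, u_spike)
            rows.append((omic, label.kind, label.lag, label.label,
                         label.statistic, label.p, n))

    df = pd.DataFrame(rows, columns=["omic", "kind", "lag", "class",
                                     "statistic", "p", "n_observed"])
    df["q"] = np.nan
    df["significant"] = False
    for cls, idx in df.groupby("class").groups.items():
        if cls == "NoTrend":
            continue
        pvals = df.loc[idx, "p"].to_numpy()
        reject, qvals, _, _ = multipletests(pvals, alpha=fdr_level,
                                            method="fdr_bh")
        df.loc[idx, "q"] = qvals
        df.loc[idx, "significant"] = reject
    return df
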