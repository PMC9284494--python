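"""Subject/signal filtering, common time frame, and per-signal normalization.

The workflow has two branches.  The single-subject branch filters each
subject's signals by missingness against the subject's own visit grid and
normalizes each retained series.  The multi-subject branch pools every
subject's visit days into one common time frame so that periodograms are
evaluated on a shared frequency grid and are therefore comparable across
subjects.

Normalization: a series X is referenced to its baseline, X̃(t_j) = X(t_j) −
X(t_first observed), then scaled to unit Euclidean norm, Q = X̃ / ‖X̃‖₂.
A constant series has ‖X̃‖₂ = 0 and is flagged rather than normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import MultiOmicsDataset, TimeSeries

logger = logging.getLogger(__name__)


@dataclass
class NormalizedSeries:
    """Baseline deltas X̃ and the unit-norm series Q at the observed times."""

    times: np.ndarray            # observed times only
    baseline_deltas: np.ndarray  # X̃, first observed entry == 0
    unit_series: np.ndarray      # Q, ‖Q‖₂ == 1
    origin_value: float          # X at the baseline visit


class ConstantFlag:
    """Marker for a series with zero variation; never classified as a trend."""

    def __repr__(self) -> str:  # pragma: no cover
        return "ConstantFlag()"


@dataclass
class CommonTimeFrame:
    """Sorted unique day stamps pooled across all subjects."""

    days: np.ndarray

    def __len__(self) -> int:
        return len(self.days)


def filter_subjects(ds: MultiOmicsDataset,
                    min_timepoints: int = 4,
                    min_omics: int = 500,
                    max_timepoints: int | None = None) -> MultiOmicsDataset:
    """Keep subjects with ≥ min_timepoints distinct visit days, strictly more
    than min_omics distinct omics, and (optionally) ≤ max_timepoints visits.

    The omics bound is strict (a subject with exactly ``min_omics`` omics is
    dropped); retained series are passed through untouched.
    """
    keep: list[str] = []
    for subject in ds.subjects:
        days = ds.subject_days(subject)
        omics = {omic for (s, omic) in ds.signals if s == subject}
        n_t, n_o = len(days), len(omics)
        if n_t < min_timepoints or n_o <= min_omics:
            continue
        if max_timepoints is not None and n_t > max_timepoints:
            continue
        keep.append(subject)
    if not keep:
        warnings.warn("subject filter removed every subject", stacklevel=2)

    out = MultiOmicsDataset()
    for subject in keep:
        for omic, ts in ds.subject_signals(subject).items():
            out.add(ts)
    return out


def filter_missingness(subject_signals: dict[str, TimeSeries],
                       max_missing_fraction: float = 0.25
                       ) -> dict[str, TimeSeries]:
    """Keep signals with missing fraction strictly below the threshold,
    computed against the signal's own visit grid."""
    return {omic: ts for omic, ts in subject_signals.items()
            if ts.missing_fraction() < max_missing_fraction}


def common_timeframe(ds: MultiOmicsDataset) -> CommonTimeFrame:
    """Sorted union of all subjects' visit days."""
    if not ds.subjects:
        raise ValueError("dataset has no subjects")
    days: set[float] = set()
    for ts in ds.signals.values():
        days.update(ts.times.tolist())
    return CommonTimeFrame(days=np.array(sorted(days)))


def normalize_signal(ts: TimeSeries) -> NormalizedSeries | ConstantFlag:
    """Baseline-subtract and unit-normalize one series.

    The baseline is the value at the first *observed* visit (if the first
    visit is missing, the first non-missing value stands in; logged).
    """
    t_obs = ts.observed_times
    x_obs = ts.observed_values
    if len(x_obs) < 2:
        raise ValueError(
            f"({ts.subject_id}, {ts.omic_id}): need ≥ 2 observed values")
    if np.isnan(ts.values[0]):
        logger.debug("(%s, %s): first visit missing; baseline = first "
                     "observed value", ts.subject_id, ts.omic_id)
    origin = x_obs[0]
    deltas = x_obs - origin
    norm = float(np.linalg.norm(deltas))
    if norm == 0.0:
        return ConstantFlag()
    return NormalizedSeries(times=t_obs, baseline_deltas=deltas,
                            unit_series=deltas / norm, origin_value=origin)
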