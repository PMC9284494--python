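"""Synthetic longitudinal multiomics cohorts with full ground truth.

The generator emulates the statistical shape of a real profiling cohort —
uneven visit schedules, heterogeneous observation windows (200-1200 days),
five modalities dominated by transcripts (> 90% of series), missing values
— and plants known structure for parameter-recovery tests:

* *lag responders*: sinusoids whose dominant autocorrelation on the nominal
  visit grid sits at a requested lag, plus Gaussian noise;
* *spikes*: flat noise with one visit displaced by a configurable number of
  noise standard deviations (positive or negative);
* *communities*: subject subsets sharing broad-band multi-harmonic temporal
  templates on designated omics, so their periodograms correlate;
* *metadata shifts*: BMI and SSPG offsets applied to one planted community.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` substreams (design, classes, templates,
values, missing, metadata), so a fixed config yields byte-identical output.

It does **not** attempt assay realism (RNA-seq count distributions, batch
effects, compositionality): it targets the temporal/statistical structure
the analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (MultiOmicsDataset, SubjectMetadata, TimeSeries,
                         write_long_table, write_subject_metadata)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort",
           "plant_lag_signal", "plant_spike_signal", "write_ground_truth"]

_SUBSTREAMS = ("design", "classes", "templates", "values", "missing", "metadata")

DEFAULT_OMICS = {"transcript": 560, "cytokine": 15, "clinical": 10,
                 "gut_microbe": 8, "nares_microbe": 7}


@dataclass
class SyntheticConfig:
    """Cohort-level knobs; defaults mimic the target study's data shape."""

    n_subjects: int = 20
    n_omics_per_modality: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OMICS))
    visits_per_subject: tuple[int, int] = (4, 20)
    window_days: tuple[int, int] = (200, 1200)
    visit_cadence_days: float = 28.0  # scheduled visit cadence
    visit_skip_fraction: float = 0.15  # probability a scheduled visit is missed
    frac_lag_responders: dict[int, float] = field(default_factory=dict)
    frac_spike_max: float = 0.0
    frac_spike_min: float = 0.0
    signal_amplitude: float = 3.0     # lag-responder amplitude, in noise SDs
    noise_sd: float = 1.0
    spike_height_sd: float = 6.0      # spike displacement, in noise SDs
    n_communities: int = 1
    n_shared_omics: int = 0           # template omics per community
    template_harmonics: int = 6
    community_metadata_shift: dict[str, float] = field(
        default_factory=lambda: {"bmi": 5.0, "sspg": 60.0})
    missing_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fracs = list(self.frac_lag_responders.values()) + [
            self.frac_spike_max, self.frac_spike_min]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("planted fractions sum to more than 1")
        if any(l < 1 for l in self.frac_lag_responders):
            raise ValueError("lags must be ≥ 1")
        if self.n_subjects < self.n_communities:
            raise ValueError("need n_subjects ≥ n_communities")
        if self.visits_per_subject[0] < 2:
            raise ValueError("need at least 2 visits")
        n_transcripts = self.n_omics_per_modality.get("transcript", 0)
        if self.n_shared_omics * self.n_communities > n_transcripts:
            raise ValueError("shared template omics exceed the transcript pool")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planting record: true class per (subject, omic), community per
    subject, template omics per community, and the metadata shift applied."""

    classes: dict[tuple[str, str], str]       # "Lag1", "SpikeMax", ...
    communities: dict[str, int]
    template_omics: dict[int, list[str]]
    metadata_shift: dict[str, float]
    shifted_community: int | None

    def is_template(self, subject: str, omic: str) -> bool:
        c = self.communities[subject]
        return omic in set(self.template_omics.get(c, ()))


# ---------------------------------------------------------------------------
# Signal builders
# ---------------------------------------------------------------------------

def _nominal_spacing(times: np.ndarray) -> float:
    return (times[-1] - times[0]) / (len(times) - 1)


def plant_lag_signal(times: np.ndarray, lag: int, amplitude: float,
                     noise_sd: float,
                     seed: int | np.random.Generator | None = None
                     ) -> np.ndarray:
    """Unit-RMS sinusoid whose dominant autocorrelation on the nominal grid
    sits at ``lag`` (period lag·δ for lag ≥ 2; one window cycle for lag 1),
    scaled by ``amplitude`` and overlaid with Gaussian noise.  With the
    template at unit RMS, ``amplitude / noise_sd`` is the signal-to-noise
    standard-deviation ratio."""
    times = np.asarray(times, float)
    n = len(times)
    if lag < 1 or lag > n // 2:
        raise ValueError(f"lag {lag} out of range for {n} visits")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    delta = _nominal_spacing(times)
    freq = 1.0 / (n * delta) if lag == 1 else 1.0 / (lag * delta)
    phase = rng.uniform(0, 2 * np.pi)
    template = np.sqrt(2.0) * np.cos(2 * np.pi * freq * times + phase)
    return amplitude * template + rng.normal(0.0, noise_sd, size=n)


def plant_spike_signal(times: np.ndarray, sign: int,
                       spike_height_sd_units: float, noise_sd: float,
                       seed: int | np.random.Generator | None = None
                       ) -> np.ndarray:
    """Flat noise with one visit displaced by sign · height · noise_sd.

    The spiked visit is drawn uniformly among visits *after the first*: a
    displacement at the baseline visit is unidentifiable once the analysis
    subtracts the baseline (it reads as a shift of every other point).
    """
    times = np.asarray(times, float)
    n = len(times)
    if n < 4:
        raise ValueError("need ≥ 4 visits to plant a spike")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=n)
    pos = int(rng.integers(1, n))
    values[pos] += sign * spike_height_sd_units * noise_sd
    return values


def _community_template(cadence_days: float, n_harmonics: int,
                        rms_amplitude: float, rng: np.random.Generator):
    """Multi-harmonic temporal template g(t), shared by community members.

    Harmonic periods are drawn log-uniformly inside the band the visit
    cadence can resolve (from about two visit intervals up to a typical
    enrollment length), so the template's spectral signature is measurable
    for every subject; the template has RMS ``rms_amplitude``.
    """
    p_hi = 800.0                      # slowest period, ~typical enrollment
    p_lo = max(2.2 * cadence_days, 42.0)   # fastest resolvable period
    freqs = np.exp(rng.uniform(np.log(1.0 / p_hi), np.log(1.0 / p_lo),
                               size=n_harmonics))
    amps = rng.uniform(0.7, 1.0, size=n_harmonics)
    amps *= rms_amplitude / np.sqrt(0.5 * (amps ** 2).sum())
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    def g(t: np.ndarray) -> np.ndarray:
        return (amps[None, :] * np.cos(2 * np.pi * np.outer(t, freqs)
                                       + phases[None, :])).sum(axis=1)
    return g


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_visits(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Visit days of one subject on the cohort's scheduled cadence.

    Profiling cohorts run scheduled visits (here every ``visit_cadence_days``
    days); a subject attends until ``n_visits`` visits are accrued, missing
    each scheduled slot with probability ``visit_skip_fraction``.  This
    yields uneven per-subject day grids (skips create gaps), heterogeneous
    observation windows that grow with enrollment length, and — because the
    cadence is shared — a cohort-wide common time frame of realistic size.
    The window is capped at ``window_days[1]`` (visits become consecutive
    once the cap binds).
    """
    lo_v, hi_v = cfg.visits_per_subject
    n_visits = int(rng.integers(lo_v, hi_v + 1))
    max_slot = int(cfg.window_days[1] // cfg.visit_cadence_days)
    n_visits = min(n_visits, max_slot + 1)
    slots = [0]
    s = 0
    while len(slots) < n_visits:
        s += 1
        if s >= max_slot:  # cap reached: attend the remaining slots
            slots.append(s)
        elif rng.random() > cfg.visit_skip_fraction:
            slots.append(s)
    return cfg.visit_cadence_days * np.array(slots, dtype=float)


def _draw_metadata(sid: str, shifted: bool, cfg: SyntheticConfig,
                   rng: np.random.Generator) -> SubjectMetadata:
    sex = "F" if rng.random() < 0.5 else "M"
    age = float(np.round(rng.uniform(29, 75), 1))
    status = str(rng.choice(["prediabetic", "diabetic", "crossover", "control"],
                            p=[0.6, 0.05, 0.2, 0.15]))
    bmi = float(rng.normal(28.0, 3.5))
    sspg = float(rng.normal(120.0, 30.0))
    if shifted:
        bmi += cfg.community_metadata_shift.get("bmi", 0.0)
        sspg += cfg.community_metadata_shift.get("sspg", 0.0)
    return SubjectMetadata(
        subject_id=sid, sex=sex, age=age, status=status,
        bmi=round(bmi, 2), sspg=round(max(sspg, 30.0), 1),
        matsuda=round(max(float(rng.normal(4.0, 1.5)), 0.5), 2),
        di=round(max(float(rng.normal(2.0, 0.7)), 0.2), 2),
        isrmax=round(max(float(rng.normal(300.0, 80.0)), 50.0), 1),
    )


def generate_cohort(cfg: SyntheticConfig
                    ) -> tuple[MultiOmicsDataset, dict[str, SubjectMetadata],
                               GroundTruth]:
    """Generate a cohort, its metadata table, and the full planting record."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    streams = dict(zip(_SUBSTREAMS,
                       (np.random.default_rng(s)
                        for s in root.spawn(len(_SUBSTREAMS)))))
    rng_design = streams["design"]
    rng_classes = streams["classes"]
    rng_values = streams["values"]
    rng_missing = streams["missing"]

    subjects = [f"S{idx:03d}" for idx in range(cfg.n_subjects)]
    omics: list[tuple[str, str]] = []   # (omic_id, modality)
    for modality, count in cfg.n_omics_per_modality.items():
        omics += [(f"{modality[:2]}_{j:04d}", modality) for j in range(count)]

    # balanced community assignment
    communities = {sid: i * cfg.n_communities // cfg.n_subjects
                   for i, sid in enumerate(subjects)}

    # disjoint template omic sets, drawn from the transcript pool
    transcript_ids = [o for o, m in omics if m == "transcript"]
    template_omics: dict[int, list[str]] = {}
    templates: dict[tuple[int, str], callable] = {}
    if cfg.n_communities >= 1 and cfg.n_shared_omics > 0:
        chosen = streams["templates"].choice(
            transcript_ids, size=cfg.n_shared_omics * cfg.n_communities,
            replace=False)
        for c in range(cfg.n_communities):
            ids = list(chosen[c * cfg.n_shared_omics:(c + 1) * cfg.n_shared_omics])
            template_omics[c] = ids
            for omic in ids:
                templates[(c, omic)] = _community_template(
                    cfg.visit_cadence_days, cfg.template_harmonics,
                    cfg.signal_amplitude * cfg.noise_sd, streams["templates"])

    # planted-class lottery boundaries
    lag_items = sorted(cfg.frac_lag_responders.items())
    edges, labels = [], []
    acc = 0.0
    for lag, frac in lag_items:
        acc += frac
        edges.append(acc)
        labels.append(("Lag", lag))
    for frac, lab in ((cfg.frac_spike_max, ("SpikeMax", 0)),
                      (cfg.frac_spike_min, ("SpikeMin", 0))):
        acc += frac
        edges.append(acc)
        labels.append(lab)

    ds = MultiOmicsDataset()
    truth_classes: dict[tuple[str, str], str] = {}
    template_sets = {c: set(ids) for c, ids in template_omics.items()}

    for sid in subjects:
        days = _subject_visits(cfg, rng_design)
        n = len(days)
        c = communities[sid]
        for omic, modality in omics:
            if omic in template_sets.get(c, ()):  # community template signal
                values = (templates[(c, omic)](days)
                          + rng_values.normal(0.0, cfg.noise_sd, size=n))
                truth_classes[(sid, omic)] = "NoTrend"
            else:
                u = rng_classes.random()
                kind, lag = "NoTrend", 0
                for edge, lab in zip(edges, labels):
                    if u < edge:
                        kind, lag = lab
                        break
                if kind == "Lag" and lag <= n // 2:
                    values = plant_lag_signal(
                        days, lag, cfg.signal_amplitude * cfg.noise_sd,
                        cfg.noise_sd, rng_values)
                    truth_classes[(sid, omic)] = f"Lag{lag}"
                elif kind == "SpikeMax":
                    values = plant_spike_signal(days, +1, cfg.spike_height_sd,
                                                cfg.noise_sd, rng_values)
                    truth_classes[(sid, omic)] = "SpikeMax"
                elif kind == "SpikeMin":
                    values = plant_spike_signal(days, -1, cfg.spike_height_sd,
                                                cfg.noise_sd, rng_values)
                    truth_classes[(sid, omic)] = "SpikeMin"
                else:
                    values = rng_values.normal(0.0, cfg.noise_sd, size=n)
                    truth_classes[(sid, omic)] = "NoTrend"
            if cfg.missing_fraction > 0:
                mask = rng_missing.random(n) < cfg.missing_fraction
                if mask.all():
                    mask[int(rng_missing.integers(0, n))] = False
                values = np.where(mask, np.nan, values)
            ds.add(TimeSeries(sid, omic, modality, days, values))

    shifted = cfg.n_communities - 1 if cfg.n_communities > 1 else None
    meta = {sid: _draw_metadata(sid, communities[sid] == shifted, cfg,
                                streams["metadata"])
            for sid in subjects}
    truth = GroundTruth(classes=truth_classes, communities=communities,
                        template_omics=template_omics,
                        metadata_shift=dict(cfg.community_metadata_shift),
                        shifted_community=shifted)
    return ds, meta, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject\tomic\ttrue_class\tcommunity\tis_template\n")
        for (sid, omic), cls in truth.classes.items():
            fh.write(f"{sid}\t{omic}\t{cls}\t{truth.communities[sid]}\t"
                     f"{int(truth.is_template(sid, omic))}\n")


def write_cohort(ds: MultiOmicsDataset, meta: dict[str, SubjectMetadata],
                 truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_long_table(ds, outdir / "data.tsv")
    write_subject_metadata(meta, outdir / "metadata.tsv")
    write_ground_truth(truth, outdir / "ground_truth.tsv")
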