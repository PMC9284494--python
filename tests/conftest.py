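import numpy as np
import pytest

from chronomics import MultiOmicsDataset, SyntheticConfig, TimeSeries, generate_cohort

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_series(subject="s1", omic="g1", modality="transcript",
                times=(0.0, 10.0, 20.0, 30.0), values=(1.0, 2.0, 1.5, 3.0)):
    return TimeSeries(subject, omic, modality,
                      np.array(times, float), np.array(values, float))


@pytest.fixture()
def toy_dataset():
    """Three subjects, two omics each, shared visit grids."""
    ds = MultiOmicsDataset()
    rng = np.random.default_rng(0)
    for s in ("s1", "s2", "s3"):
        times = np.array([0.0, 20.0, 45.0, 70.0, 100.0])
        for omic, modality in (("g1", "transcript"), ("c1", "cytokine")):
            ds.add(TimeSeries(s, omic, modality, times,
                              rng.normal(size=len(times))))
    return ds


@pytest.fixture(scope="session")
def small_cohort():
    """Session-scoped synthetic cohort with planted structure (fast)."""
    cfg = SyntheticConfig(
        n_subjects=4,
        n_omics_per_modality={"transcript": 50, "cytokine": 6},
        visits_per_subject=(10, 14),
        frac_lag_responders={1: 0.15},
        frac_spike_max=0.08,
        frac_spike_min=0.05,
        n_communities=1,
        n_shared_omics=0,
        missing_fraction=0.05,
        seed=123,
    )
    return generate_cohort(cfg)
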