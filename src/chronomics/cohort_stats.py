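"""Cross-subject aggregation, community phenotype tests, and the pipeline.

``occurrence_table`` counts, for every omic, the subjects in which it shows
a BH-significant temporal trend of any class, and flags omics recurrent in
strictly more than half the cohort.  ``community_measure_tests`` compares
phenotype measures (BMI, SSPG, Matsuda, DI, isrMax) between every pair of
network communities with two-sided Mann-Whitney U tests, stratified by sex
(female / male / total); p-values are exact for small untied samples and
tie-corrected otherwise, and raw p at alpha decides significance (a
BH-adjusted column is emitted alongside for transparency).

``run_pipeline`` composes the two analysis branches: per-subject spectral
classification + grouping, and the cross-subject similarity network +
communities + phenotype tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import __version__
from .core_model import (MultiOmicsDataset, SubjectMetadata,
                         load_long_table, load_subject_metadata,
                         validate_dataset)
from .grouping import Grouping, two_tier_cluster
from .preprocess import (CommonTimeFrame, ConstantFlag, common_timeframe,
                         filter_missingness, filter_subjects,
                         normalize_signal)
from .similarity_network import (CommunityAssignment, SimilarityNetwork,
                                 build_network, detect_communities,
                                 periodogram_matrix, spearman_cutoff)
from .spectral_classify import (bootstrap_null, classify_subject,
                                frame_frequencies, _autocorr_from_powers,
                                _lombscargle_batch)

logger = logging.getLogger(__name__)

DEFAULT_MEASURES = ("bmi", "sspg", "matsuda", "di", "isrmax")


# ---------------------------------------------------------------------------
# Occurrence aggregation (recurrent significant trends)
# ---------------------------------------------------------------------------

def occurrence_table(classifications: dict[str, pd.DataFrame],
                     modality_of: dict[str, str] | None = None,
                     min_fraction: float = 0.5) -> pd.DataFrame:
    """Per-omic count of subjects with a BH-significant trend of any class.

    ``retained`` marks omics whose subject fraction is strictly greater
    than ``min_fraction``; the full unfiltered table is returned so both
    views stay reproducible.
    """
    if not classifications:
        raise ValueError("no classified subjects")
    n_subjects = len(classifications)
    counts: dict[str, int] = {}
    for df in classifications.values():
        hits = set(df.loc[df["significant"], "omic"])
        for omic in hits:
            counts[omic] = counts.get(omic, 0) + 1
    rows = [(omic,
             (modality_of or {}).get(omic, ""),
             c, c / n_subjects, c / n_subjects > min_fraction)
            for omic, c in counts.items()]
    out = pd.DataFrame(rows, columns=["omic", "modality", "occurrences",
                                      "fraction", "retained"])
    return out.sort_values(["occurrences", "omic"],
                           ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mann-Whitney community comparisons
# ---------------------------------------------------------------------------

def community_measure_tests(meta: dict[str, SubjectMetadata],
                            communities: CommunityAssignment | dict[str, int],
                            measures: tuple[str, ...] = DEFAULT_MEASURES,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every measure × community pair × stratum.

    Missing measures are dropped listwise per test; strata with an empty
    side are omitted with a log entry.  U is reported for the first
    community of the pair.
    """
    comm = communities.communities if isinstance(
        communities, CommunityAssignment) else dict(communities)
    ids = sorted(set(comm.values()))
    rows = []
    for ca, cb in combinations(ids, 2):
        for stratum in ("female", "male", "total"):
            for measure in measures:
                def values(c):
                    vals = []
                    for sid, cc in comm.items():
                        if cc != c or sid not in meta:
                            continue
                        rec = meta[sid]
                        if stratum == "female" and rec.sex != "F":
                            continue
                        if stratum == "male" and rec.sex != "M":
                            continue
                        v = rec.measure(measure)
                        if not np.isnan(v):
                            vals.append(v)
                    return np.array(vals)

                x, y = values(ca), values(cb)
                if len(x) < 1 or len(y) < 1:
                    logger.info("skipping C%d vs C%d %s %s: empty stratum",
                                ca, cb, stratum, measure)
                    continue
                res = mannwhitneyu(x, y, alternative="two-sided")
                rows.append((measure, ca, cb, stratum, len(x), len(y),
                             float(res.statistic), float(res.pvalue),
                             res.pvalue < alpha))
    out = pd.DataFrame(rows, columns=["measure", "community_a", "community_b",
                                      "stratum", "n_a", "n_b", "U", "p",
                                      "significant"])
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def community_top_omics(net: SimilarityNetwork,
                        communities: CommunityAssignment | dict[str, int],
                        modality_of: dict[str, str] | None = None,
                        modality: str | None = "transcript",
                        top_fraction: float = 0.25) -> dict[int, list[str]]:
    """Ranked omic list per community: omics ordered by how many
    within-community edges their indicator matrix supports, truncated to the
    top fraction.  Feeds external enrichment tools; no enrichment is run."""
    comm = communities.communities if isinstance(
        communities, CommunityAssignment) else dict(communities)
    index = {s: i for i, s in enumerate(net.subjects)}
    out: dict[int, list[str]] = {}
    for c in sorted(set(comm.values())):
        nodes = [index[s] for s in net.subjects if comm.get(s) == c]
        scores: dict[str, int] = {}
        for omic, r in net.indicator_matrices.items():
            if modality and modality_of and modality_of.get(omic) != modality:
                continue
            w = int(r[np.ix_(nodes, nodes)].sum()) // 2
            if w > 0:
                scores[omic] = w
        ranked = sorted(scores, key=lambda o: (-scores[o], o))
        n_top = int(np.ceil(top_fraction * len(ranked)))
        out[c] = ranked[:n_top]
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the two branches need; seeds derive from ``seed``."""

    min_timepoints: int = 4
    min_omics: int = 500
    max_timepoints: int | None = None
    max_missing_fraction: float = 0.25
    bootstrap_classification: int = 100_000
    bootstrap_network: int = 50_000
    q_auto: float = 0.95
    q_spike: float = 0.95
    q_network: float = 0.99
    fdr_level: float = 0.05
    alpha: float = 0.05
    n_communities: int | None = None     # None → silhouette selection
    run_grouping: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    dataset: MultiOmicsDataset
    classifications: dict[str, pd.DataFrame]
    groupings: dict[str, dict[str, Grouping]]
    occurrence: pd.DataFrame
    frame: CommonTimeFrame
    s_c: float
    network: SimilarityNetwork
    communities: CommunityAssignment
    tests: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _subject_seed(root: int, i: int) -> int:
    return int(np.random.SeedSequence([root, i]).generate_state(1)[0] % (2**31))


def _grouping_inputs(signals, frame_days, classification):
    """Autocorrelation and Q matrices for the subject's classified signals."""
    freqs, n_grid = frame_frequencies(frame_days)
    out = {}
    for cls, sub in classification.groupby("class"):
        if cls == "NoTrend":
            continue
        members, rhos, qs = [], [], []
        for omic in sub["omic"]:
            ts = signals[omic]
            norm = normalize_signal(ts)
            if isinstance(norm, ConstantFlag):
                continue
            p = _lombscargle_batch(norm.times, norm.unit_series[None], freqs)
            rhos.append(_autocorr_from_powers(p, n_grid)[0])
            q_full = np.full(len(frame_days), np.nan)
            q_full[np.searchsorted(frame_days, norm.times)] = norm.unit_series
            qs.append(q_full)
            members.append(omic)
        if members:
            out[cls] = (members, np.stack(rhos), np.stack(qs))
    return out


def run_pipeline(ds: MultiOmicsDataset,
                 meta: dict[str, SubjectMetadata],
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run both analysis branches on a loaded dataset.

    Branch (ii), per subject: missingness filter on the subject's own grid,
    bootstrap cutoff calibration, spectral classification, two-tier
    grouping.  Branch (iii): periodograms on the common time frame, the
    Spearman null cutoff s_c, the weighted similarity network, k-means
    communities and Mann-Whitney phenotype comparisons.
    """
    cfg = config or PipelineConfig()
    report = validate_dataset(ds)
    if not report.ok:
        raise ValueError(f"invalid dataset: {report.violations[:5]}")

    filtered = filter_subjects(ds, cfg.min_timepoints, cfg.min_omics,
                               cfg.max_timepoints)
    if not filtered.subjects:
        raise ValueError("no subjects pass the cohort filters")

    # branch ii — single-subject classification + grouping
    classifications: dict[str, pd.DataFrame] = {}
    groupings: dict[str, dict[str, Grouping]] = {}
    for i, subject in enumerate(filtered.subjects):
        signals = filter_missingness(filtered.subject_signals(subject),
                                     cfg.max_missing_fraction)
        frame_days = filtered.subject_days(subject)
        cutoffs = bootstrap_null(list(signals.values()), frame_days,
                                 B=cfg.bootstrap_classification,
                                 q_auto=cfg.q_auto, q_spike=cfg.q_spike,
                                 seed=_subject_seed(cfg.seed, i))
        classification = classify_subject(signals, cutoffs, frame_days,
                                          fdr_level=cfg.fdr_level)
        classifications[subject] = classification
        if cfg.run_grouping:
            groupings[subject] = {
                cls: two_tier_cluster(members, rhos, qs, class_label=cls)
                for cls, (members, rhos, qs)
                in _grouping_inputs(signals, frame_days, classification).items()
            }
    occurrence = occurrence_table(classifications, filtered.omics_catalogue)

    # branch iii — similarity network + communities + phenotype tests
    frame = common_timeframe(filtered)
    s_c = spearman_cutoff(filtered, frame, B=cfg.bootstrap_network,
                          q=cfg.q_network,
                          seed=_subject_seed(cfg.seed, 10_000))
    periodograms = periodogram_matrix(filtered, frame)
    network = build_network(periodograms, s_c)
    communities = detect_communities(network, k=cfg.n_communities,
                                     seed=cfg.seed % (2**31))
    tests = community_measure_tests(meta, communities, alpha=cfg.alpha)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_subjects_input": len(ds.subjects),
        "n_subjects_filtered": len(filtered.subjects),
        "n_signals": filtered.n_signals(),
        "s_c": s_c,
        "k_communities": communities.k,
        "config": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in vars(cfg).items()},
    }
    result = PipelineResult(filtered, classifications, groupings, occurrence,
                            frame, s_c, network, communities, tests, manifest)
    if outdir is not None:
        write_results(result, outdir)
    return result


def run_pipeline_from_files(data_path: str | Path, meta_path: str | Path,
                            config: PipelineConfig | None = None,
                            outdir: str | Path | None = None) -> PipelineResult:
    ds = load_long_table(data_path)
    meta = load_subject_metadata(meta_path)
    return run_pipeline(ds, meta, config, outdir)


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage output plus the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([df.assign(subject=s) for s, df in
               result.classifications.items()]).to_csv(
        outdir / "classes.tsv", sep="\t", index=False)
    result.occurrence.to_csv(outdir / "occurrence.tsv", sep="\t", index=False)
    result.tests.to_csv(outdir / "community_tests.tsv", sep="\t", index=False)
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("subject_p\tsubject_q\tweight\n")
        for p, q, w in result.network.edge_list():
            fh.write(f"{p}\t{q}\t{w}\n")
    with open(outdir / "nodes.tsv", "w") as fh:
        fh.write("subject\tcommunity\n")
        for s in result.network.subjects:
            fh.write(f"{s}\t{result.communities.communities[s]}\n")
    grouping_rows = []
    for subject, by_class in result.groupings.items():
        for cls, grouping in by_class.items():
            for omic in grouping.members:
                g, sub = grouping.subgroup[omic]
                grouping_rows.append((subject, cls, omic, g, sub))
    pd.DataFrame(grouping_rows,
                 columns=["subject", "class", "omic", "group", "subgroup"]
                 ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    try:
        import networkx as nx
        nx.write_graphml(result.network.to_networkx(),
                         outdir / "network.graphml")
    except ImportError:  # pragma: no cover
        pass
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
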