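"""Per-gene differential-variability testing and cross-dataset consensus.

``run_dv_analysis`` scores every gene of a cohort for a difference in spread
between a test and a reference tumour group: Brown-Forsythe p-value,
BH adjustment across all genes tested in the cohort (the BH universe is one
dataset/comparison, never pooled), MAD ratio with CI, and a direction
(+ when the test group is more variable).  Downstream helpers call
significant genes, intersect calls across datasets requiring a shared
direction, rank a top fraction by significance, and intersect candidate
sets between analyses.

Genes whose deviations are all zero in both groups (constant expression)
are degenerate: they are reported with p = 1 and kept in the BH universe so
the multiplicity correction is not silently changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, SampleAnnotation
from .variability_stats import bh_adjust, brown_forsythe_arrays

__all__ = [
    "CIConfig",
    "DVRecord",
    "ConsensusResult",
    "run_dv_analysis",
    "records_to_frame",
    "frame_to_records",
    "call_significant",
    "cross_dataset_consensus",
    "top_fraction_by_significance",
    "candidate_intersection",
]


@dataclass(frozen=True)
class CIConfig:
    """How MAD-ratio confidence intervals are computed in the pipeline.

    ``method`` is one of ``"bootstrap"`` (stratified BCa bootstrap,
    resampling samples within each group, B = ``n_boot``, per-gene seeds
    spawned deterministically from ``seed``), ``"percentile"`` (plain
    stratified percentile bootstrap), ``"asymptotic-log"`` (normal-theory
    interval on the log ratio), or ``"none"`` (skip intervals; bounds
    reported as NaN).  p-values are unaffected by the choice.
    """

    method: str = "bootstrap"
    n_boot: int = 2000
    level: float = 0.95
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("bootstrap", "percentile", "asymptotic-log", "none"):
            raise ValueError(f"unknown CI method: {self.method!r}")


@dataclass(frozen=True)
class DVRecord:
    """One gene's differential-variability test result."""

    gene_id: str
    test_group: str
    reference_group: str
    mad_ratio: float
    ci_low: float
    ci_high: float
    F: float
    p: float
    adj_p: float
    direction: str
    dataset_id: str = ""
    flag: str = ""


@dataclass(frozen=True)
class ConsensusResult:
    """Cross-dataset agreement of significant DV calls."""

    per_dataset_calls: tuple          # tuple of dict gene_id -> direction
    consensus_genes: dict             # gene_id -> shared direction
    n_common: int                     # genes present in every dataset's calls
    n_direction_consistent: int       # of those, how many share one direction
    top_fraction_sets: tuple = field(default=())
    candidate_genes: tuple = field(default=())


_LOG_MAD_AVAR = 1.361  # Normal asymptotic Var(log MAD) per observation


def run_dv_analysis(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    test_group: str,
    reference_group: str,
    ci_config: CIConfig = CIConfig(),
) -> list:
    """Test every gene for differential spread between two groups.

    Both groups need at least 3 annotated samples present in the matrix.
    Returns one :class:`DVRecord` per gene, in matrix row order, with
    ``adj_p`` BH-adjusted across all genes of this comparison.
    """
    groups = {}
    for label in (test_group, reference_group):
        samples = annotation.samples_in_group(
            label, dataset_id=matrix.dataset_id or None
        )
        if not samples:
            samples = annotation.samples_in_group(label)
        missing = [s for s in samples if s not in matrix.sample_ids]
        if missing:
            raise ValueError(
                f"samples annotated to group {label!r} absent from matrix: {missing}"
            )
        if len(samples) < 3:
            raise ValueError(
                f"group {label!r} has {len(samples)} samples; need at least 3"
            )
        groups[label] = matrix.subset_samples(samples)
    sub_t, sub_r = groups[test_group], groups[reference_group]

    F, p, degenerate = brown_forsythe_arrays(sub_t, sub_r)
    mad_t = np.median(np.abs(sub_t - np.median(sub_t, axis=1, keepdims=True)), axis=1)
    mad_r = np.median(np.abs(sub_r - np.median(sub_r, axis=1, keepdims=True)), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mad_t / mad_r
    adj_p = bh_adjust(p)
    lo, hi = _mad_ratio_ci(sub_t, sub_r, mad_t, mad_r, ratio, ci_config)

    records = []
    for i, gene in enumerate(matrix.gene_ids):
        r = float(ratio[i])
        if degenerate[i]:
            flag, direction = "degenerate", "0"
        elif mad_r[i] == 0:
            flag, direction = "zero-reference-mad", "+"
        elif mad_t[i] == 0:
            flag, direction = "zero-test-mad", "-"
        else:
            flag = ""
            direction = "+" if r > 1 else ("-" if r < 1 else "0")
        records.append(
            DVRecord(
                gene_id=gene,
                test_group=test_group,
                reference_group=reference_group,
                mad_ratio=r,
                ci_low=float(lo[i]),
                ci_high=float(hi[i]),
                F=float(F[i]),
                p=float(p[i]),
                adj_p=float(adj_p[i]),
                direction=direction,
                dataset_id=matrix.dataset_id,
                flag=flag,
            )
        )
    return records


def _mad_ratio_ci(sub_t, sub_r, mad_t, mad_r, ratio, cfg: CIConfig):
    """Per-gene CI bounds for the MAD ratios of a whole matrix pair.

    Bootstrap methods delegate to :func:`mad_ratio_with_ci` gene by gene,
    with an independent child seed per gene spawned from ``cfg.seed`` so the
    whole table reproduces from one seed.  Genes whose ratio is undefined
    (zero reference MAD) get NaN bounds.
    """
    n_genes = sub_t.shape[0]
    if cfg.method == "none":
        nan = np.full(n_genes, np.nan)
        return nan, nan.copy()
    if cfg.method == "asymptotic-log":
        from scipy import stats

        se = math.sqrt(_LOG_MAD_AVAR * (1 / sub_t.shape[1] + 1 / sub_r.shape[1]))
        zq = stats.norm.ppf(1 - (1 - cfg.level) / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = ratio * np.exp(-zq * se)
            hi = ratio * np.exp(zq * se)
        return lo, hi
    from .variability_stats import mad_ratio_with_ci

    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_genes)
    lo = np.full(n_genes, np.nan)
    hi = np.full(n_genes, np.nan)
    for i in range(n_genes):
        if mad_r[i] == 0:
            continue
        est = mad_ratio_with_ci(
            sub_t[i],
            sub_r[i],
            level=cfg.level,
            method=cfg.method,
            seed=int(child_seeds[i]),
            n_boot=cfg.n_boot,
        )
        lo[i], hi[i] = est.ci_low, est.ci_high
    return lo, hi


_FRAME_COLUMNS = [
    "gene_id", "test_group", "reference_group", "mad_ratio", "ci_low",
    "ci_high", "F", "p", "adj_p", "direction", "dataset_id", "flag",
]


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate DV records (one row per gene, Table-2-style columns)."""
    return pd.DataFrame([vars(r) for r in records], columns=_FRAME_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame` (e.g. after reading a TSV)."""
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        d["flag"] = "" if pd.isna(d.get("flag")) else str(d["flag"])
        d["direction"] = str(d["direction"])
        out.append(DVRecord(**{k: d[k] for k in _FRAME_COLUMNS}))
    return out


def call_significant(records, alpha: float = 0.05) -> dict:
    """Genes with BH-adjusted p below ``alpha``, with their directions."""
    records = list(records)
    if not records:
        raise ValueError("no DV records to call from")
    keys = {(r.dataset_id, r.test_group, r.reference_group) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple comparisons: {sorted(keys)}")
    return {r.gene_id: r.direction for r in records if r.adj_p < alpha}


def cross_dataset_consensus(per_dataset_calls) -> ConsensusResult:
    """Genes significant in every dataset with one shared direction.

    ``per_dataset_calls`` is a sequence of ``{gene_id: direction}`` mappings,
    one per dataset.  A gene present everywhere but with conflicting
    directions counts toward ``n_common`` but not the consensus.
    """
    calls = [dict(c) for c in per_dataset_calls]
    if not calls:
        raise ValueError("need calls from at least one dataset")
    common = set(calls[0])
    for c in calls[1:]:
        common &= set(c)
    consensus = {
        g: calls[0][g]
        for g in sorted(common)
        if all(c[g] == calls[0][g] for c in calls)
    }
    return ConsensusResult(
        per_dataset_calls=tuple(calls),
        consensus_genes=consensus,
        n_common=len(common),
        n_direction_consistent=len(consensus),
    )


def top_fraction_by_significance(records, q: float = 0.015) -> list:
    """The ceil(q * m) most significant genes of one comparison.

    Ranked by raw p ascending; ties broken by larger ``|log(mad_ratio)|``
    (stronger spread change first), then lexicographic gene id.  Returns a
    sorted gene-id list.
    """
    records = list(records)
    if not records:
        raise ValueError("no DV records to rank")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = math.ceil(q * len(records))

    def tie_strength(r):
        if not np.isfinite(r.mad_ratio) or r.mad_ratio <= 0:
            return math.inf if r.flag == "zero-reference-mad" else 0.0
        return abs(math.log(r.mad_ratio))

    ranked = sorted(records, key=lambda r: (r.p, -tie_strength(r), r.gene_id))
    return sorted(r.gene_id for r in ranked[:k])


def candidate_intersection(set_a, set_b) -> list:
    """Genes shared by two analyses' candidate sets, sorted."""
    return sorted(set(set_a) & set(set_b))
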