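"""Transcription-regulator enrichment of DV gene sets.

Given ChIP-seq-derived target gene sets (GMT format, one set per regulator
experiment), each set is tested for over/underrepresentation of DV genes
against the non-DV control (universe minus DV genes) with a two-sided Fisher
exact test; log odds ratio > 0 means the DV genes are overrepresented among
the regulator's targets.  Set-level results are then summarised per
regulator by a rank-sum test of its sets' log-OR ranks against all other
sets, so a regulator whose target sets consistently sit at the enriched end
of the distribution ranks first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variability_stats import bh_adjust

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "test_enrichment",
    "rank_regulators",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    regulator: str
    genes: frozenset
    source: str = ""


@dataclass(frozen=True)
class GeneSetCollection:
    """Unique, non-empty gene sets keyed by set id."""

    sets: dict

    def __post_init__(self):
        for set_id, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene set's 2x2 contingency result against the DV/control split.

    a = DV genes in the set, b = DV genes outside it, c = control genes in
    the set, d = control genes outside it (membership restricted to the
    universe).
    """

    set_id: str
    regulator: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log_or: float
    p: float
    adj_p: float = float("nan")


def read_gmt(path, regulator_delimiter: str = ".") -> GeneSetCollection:
    """Parse a GMT file: name<TAB>description<TAB>gene...

    The regulator is the leading token of the set name, split on
    ``regulator_delimiter`` (e.g. ``EZH2.HMEC`` -> regulator ``EZH2``).
    Duplicate set names and lines with fewer than three fields raise.
    """
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name, source = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate gene-set name {name!r}")
            if not genes:
                raise ValueError(f"line {lineno}: gene set {name!r} has no genes")
            regulator = name.split(regulator_delimiter)[0]
            sets[name] = GeneSet(set_id=name, regulator=regulator, genes=genes,
                                 source=source)
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return GeneSetCollection(sets=sets)


def test_enrichment(dv_genes, universe, collection: GeneSetCollection) -> list:
    """Fisher exact enrichment of DV genes in every set of a collection.

    The universe is the genes analysed in the DV comparison; set membership
    is restricted to it, and the control is ``universe - dv_genes``.  The
    p-value is always the uncorrected two-sided Fisher exact probability;
    the odds ratio gets the Haldane-Anscombe 0.5 correction only when some
    cell is zero, so ``log_or`` stays finite.  ``adj_p`` is BH across all
    sets of the collection.
    """
    dv = set(dv_genes)
    uni = set(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not dv:
        raise ValueError("DV gene set is empty")
    if not dv <= uni:
        extra = sorted(dv - uni)[:5]
        raise ValueError(f"DV genes outside the universe, e.g. {extra}")
    if dv == uni:
        raise ValueError("DV set equals the universe: no control genes")
    control = uni - dv
    records = []
    for gs in sorted(collection, key=lambda s: s.set_id):
        members = gs.genes & uni
        a = len(dv & members)
        b = len(dv) - a
        c = len(members) - a
        d = len(control) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        records.append(
            EnrichmentRecord(
                set_id=gs.set_id, regulator=gs.regulator,
                a=a, b=b, c=c, d=d,
                odds_ratio=float(odds), log_or=float(math.log(odds)),
                p=float(p),
            )
        )
    adj = bh_adjust([r.p for r in records])
    return [
        EnrichmentRecord(**{**vars(r), "adj_p": float(q)})
        for r, q in zip(records, adj)
    ]


def rank_regulators(records) -> pd.DataFrame:
    """Aggregate set-level enrichment to the regulator level.

    For each regulator, a two-sided Wilcoxon rank-sum test compares the
    log-ORs of its sets against those of all other sets; regulators are
    sorted by that p-value, then by median log-OR descending.  A regulator
    backed by a single set is flagged ``low_evidence`` (a rank-sum test on
    n = 1 carries little information).
    """
    records = list(records)
    if not records:
        raise ValueError("no enrichment records")
    frame = pd.DataFrame(
        {"regulator": [r.regulator for r in records],
         "log_or": [r.log_or for r in records]}
    )
    rows = []
    for regulator, grp in frame.groupby("regulator"):
        others = frame.loc[frame["regulator"] != regulator, "log_or"]
        if others.empty:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(
                grp["log_or"], others, alternative="two-sided"
            )
        rows.append(
            {
                "regulator": regulator,
                "n_sets": len(grp),
                "median_log_or": float(grp["log_or"].median()),
                "rank_sum_p": float(p),
                "low_evidence": len(grp) == 1,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["rank_sum_p", "median_log_or"],
        ascending=[True, False],
        kind="mergesort",
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
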