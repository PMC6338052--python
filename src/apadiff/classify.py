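"""Shortened/lengthened classification and consensus across comparisons.

A gene is called in one comparison when all three criteria hold:

1. roar > 1 (SHORTENED) or roar < 1 (LENGTHENED), strictly;
2. every replicate pairing yields a nominal Fisher p < alpha;
3. the common-region (PRE) FPKM exceeds the cutoff in *both* conditions.

Genes failing the FPKM cutoff or carrying an invalid statistic are
NOT_TESTABLE; genes that are testable but miss a criterion are UNCHANGED.
The consensus across a time course intersects per-comparison call sets
(a gene is "always lengthened" when LENGTHENED in every comparison).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .stats import GeneApaStat

CALLS = ("SHORTENED", "LENGTHENED", "UNCHANGED", "NOT_TESTABLE")


@dataclass(frozen=True)
class ApaCall:
    gene_id: str
    comparison: str
    call: str
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class Thresholds:
    roar_boundary: float = 1.0
    alpha: float = 0.05
    fpkm_min: float = 1.0

    def __post_init__(self) -> None:
        if self.roar_boundary <= 0 or self.alpha <= 0 or self.fpkm_min < 0:
            raise ValueError("thresholds must be positive")


def classify_gene(
    stat: GeneApaStat,
    comparison: str = "baseline_vs_contrast",
    thresholds: Thresholds = Thresholds(),
) -> ApaCall:
    """Apply the three criteria to one gene's statistics.

    Inequalities are strict exactly as stated: roar equal to the boundary or a
    p equal to alpha fails the respective criterion.
    """
    reasons: list[str] = []
    if stat.flag != "ok":
        reasons.append(f"flag:{stat.flag}")
    if (
        stat.fpkm_baseline <= thresholds.fpkm_min
        or stat.fpkm_contrast <= thresholds.fpkm_min
    ):
        reasons.append("fpkm")
    if reasons:
        return ApaCall(stat.gene_id, comparison, "NOT_TESTABLE", tuple(reasons))

    assert stat.roar is not None
    all_significant = all(
        not math.isnan(p) and p < thresholds.alpha for p in stat.pairwise_pvalues
    )
    if stat.roar > thresholds.roar_boundary and all_significant:
        return ApaCall(stat.gene_id, comparison, "SHORTENED")
    if stat.roar < thresholds.roar_boundary and all_significant:
        return ApaCall(stat.gene_id, comparison, "LENGTHENED")
    if stat.roar == thresholds.roar_boundary:
        reasons.append("roar_boundary")
    if not all_significant:
        reasons.append("pairwise_p")
    return ApaCall(stat.gene_id, comparison, "UNCHANGED", tuple(reasons))


@dataclass
class ConsensusResult:
    """Per-comparison call sets, their intersections and Venn region counts."""

    comparisons: tuple[str, ...]
    shortened_sets: dict[str, frozenset[str]]
    lengthened_sets: dict[str, frozenset[str]]
    always_shortened: frozenset[str]
    always_lengthened: frozenset[str]
    venn_shortened: dict[tuple[str, ...], int]
    venn_lengthened: dict[tuple[str, ...], int]


def _venn_counts(
    sets: Mapping[str, frozenset[str]], comparisons: Sequence[str]
) -> dict[tuple[str, ...], int]:
    """Count genes in each exclusive Venn region (non-empty membership pattern)."""
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(comparisons) + 1):
        for inside in combinations(comparisons, r):
            members = set.intersection(*(set(sets[c]) for c in inside))
            for c in comparisons:
                if c not in inside:
                    members -= sets[c]
            out[tuple(inside)] = len(members)
    return out


def consensus(
    calls: Mapping[str, Mapping[str, ApaCall]], comparisons: Sequence[str]
) -> ConsensusResult:
    """Intersect SHORTENED/LENGTHENED sets across comparisons.

    ``calls`` maps comparison -> gene_id -> ApaCall; every comparison must
    cover the same gene universe.  Genes NOT_TESTABLE in any comparison cannot
    be in an intersection (they are absent from that comparison's call set).
    """
    comparisons = tuple(comparisons)
    if not comparisons:
        raise ValueError("no comparisons")
    universes = {c: frozenset(calls[c]) for c in comparisons}
    first = universes[comparisons[0]]
    for c, u in universes.items():
        if u != first:
            raise ValueError(f"gene universe mismatch in comparison {c}")

    shortened = {
        c: frozenset(g for g, call in calls[c].items() if call.call == "SHORTENED")
        for c in comparisons
    }
    lengthened = {
        c: frozenset(g for g, call in calls[c].items() if call.call == "LENGTHENED")
        for c in comparisons
    }
    always_short = frozenset(set.intersection(*(set(shortened[c]) for c in comparisons)))
    always_long = frozenset(set.intersection(*(set(lengthened[c]) for c in comparisons)))
    return ConsensusResult(
        comparisons=comparisons,
        shortened_sets=shortened,
        lengthened_sets=lengthened,
        always_shortened=always_short,
        always_lengthened=always_long,
        venn_shortened=_venn_counts(shortened, comparisons),
        venn_lengthened=_venn_counts(lengthened, comparisons),
    )


def write_calls_tsv(
    calls: Mapping[str, Mapping[str, ApaCall]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcomparison\tcall\treasons\n")
        for comparison in sorted(calls):
            for gene_id in sorted(calls[comparison]):
                c = calls[comparison][gene_id]
                fh.write(
                    f"{gene_id}\t{comparison}\t{c.call}\t{','.join(c.reasons)}\n"
                )


def write_consensus_tsv(result: ConsensusResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tconsensus\n")
        for g in sorted(result.always_shortened):
            fh.write(f"{g}\tALWAYS_SHORTENED\n")
        for g in sorted(result.always_lengthened):
            fh.write(f"{g}\tALWAYS_LENGTHENED\n")


def venn_to_json(result: ConsensusResult) -> str:
    def keyed(venn: Mapping[tuple[str, ...], int]) -> dict[str, int]:
        return {"&".join(k): v for k, v in sorted(venn.items())}

    return json.dumps(
        {
            "comparisons": list(result.comparisons),
            "shortened": keyed(result.venn_shortened),
            "lengthened": keyed(result.venn_lengthened),
            "always_shortened": sorted(result.always_shortened),
            "always_lengthened": sorted(result.always_lengthened),
        },
        indent=2,
        sort_keys=True,
    )


def write_report(
    result: ConsensusResult,
    calls: Mapping[str, Mapping[str, ApaCall]],
    calls_path,
    consensus_path,
    venn_path=None,
) -> None:
    """Write the calls TSV, consensus TSV and optional Venn JSON, sorted."""
    write_calls_tsv(calls, calls_path)
    write_consensus_tsv(result, consensus_path)
    if venn_path is not None:
        with open(venn_path, "w") as fh:
            fh.write(venn_to_json(result) + "\n")
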