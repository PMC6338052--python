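"""Enrichment of CLIP binding sites in shortened/lengthened gene sets.

Binding-site clusters (e.g. HITS-CLIP of an RNA-binding protein) carry two
quality scores: an FDR and a biological-complexity score BC (number of
independent experiments supporting the cluster).  The robust-cluster filter
keeps sites with FDR < 0.01 *or* BC >= 5.  Overlap is evaluated on whole
genomic gene spans, strand-blind, and enrichment of overlap among target
genes versus the rest of the analyzed universe is tested with a one-sided
Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .stats import fisher_pre_post

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    chrom: str
    start: int
    end: int
    strand: str = "."
    fdr: Optional[float] = None
    bc: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty binding-site interval")


@dataclass
class EnrichmentResult:
    """2x2 overlap table, sample odds ratio and one-sided Fisher p."""

    target_overlap: int
    target_no_overlap: int
    rest_overlap: int
    rest_no_overlap: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.target_overlap, self.target_no_overlap],
            [self.rest_overlap, self.rest_no_overlap],
        ]


def filter_robust(
    sites: Iterable[BindingSite], fdr_max: float = 0.01, bc_min: int = 5
) -> list[BindingSite]:
    """Keep robust clusters: fdr < fdr_max OR bc >= bc_min.

    Sites carrying neither score are dropped (their number is logged).
    Idempotent: filtering an already-filtered list is a no-op.
    """
    kept: list[BindingSite] = []
    n_unscored = 0
    for s in sites:
        if s.fdr is None and s.bc is None:
            n_unscored += 1
            continue
        if (s.fdr is not None and s.fdr < fdr_max) or (
            s.bc is not None and s.bc >= bc_min
        ):
            kept.append(s)
    if n_unscored:
        logger.info("dropped %d binding sites without FDR or BC scores", n_unscored)
    return kept


def gene_overlaps(
    gene_spans: Mapping[str, tuple[str, int, int]],
    sites: Iterable[BindingSite],
) -> dict[str, bool]:
    """Flag genes whose genomic span overlaps >= 1 site by >= 1 base.

    ``gene_spans`` maps gene_id -> (chrom, start, end) with the span taken
    from the canonical transcript (min exon start to max exon end).  Strand is
    ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree())[s.start : s.end] = True
    return {
        gene_id: bool(chrom in trees and trees[chrom].overlap(start, end))
        for gene_id, (chrom, start, end) in gene_spans.items()
    }


def enrichment_test(
    target_genes: set[str] | frozenset[str],
    universe_genes: set[str] | frozenset[str],
    overlap_flags: Mapping[str, bool],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher test for over-representation of site overlap in the target set.

    One-sided ('greater') by default; 'two-sided' available.  The odds ratio
    is the sample OR of the 2x2 table (inf when the off-diagonal is zero).
    """
    if not universe_genes:
        raise ValueError("empty universe")
    if not target_genes:
        raise ValueError("empty target set")
    if not set(target_genes) <= set(universe_genes):
        raise ValueError("target genes must be a subset of the universe")
    missing = set(universe_genes) - set(overlap_flags)
    if missing:
        raise ValueError(f"missing overlap flags for {len(missing)} genes")

    rest = set(universe_genes) - set(target_genes)
    a = sum(1 for g in target_genes if overlap_flags[g])
    b = len(target_genes) - a
    c = sum(1 for g in rest if overlap_flags[g])
    d = len(rest) - c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if (a + b) and (c + d) and (a + c) and (b + d):
        p = fisher_pre_post(a, b, c, d, alternative=alternative)
    else:
        # a degenerate margin admits only the observed table: tail mass 1
        p = 1.0
    return EnrichmentResult(a, b, c, d, odds, p)


def read_sites_bed(path: str | Path) -> list[BindingSite]:
    """Read binding sites from a BED-like TSV.

    Columns: chrom, start, end[, name, score, strand, fdr, bc].  Trailing
    columns are optional; '.' or empty marks a missing fdr/bc.
    """
    sites: list[BindingSite] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 columns")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            fdr = None
            bc = None
            if len(f) > 6 and f[6] not in (".", ""):
                fdr = float(f[6])
            if len(f) > 7 and f[7] not in (".", ""):
                bc = int(f[7])
            sites.append(
                BindingSite(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=strand, fdr=fdr, bc=bc,
                )
            )
    return sites
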