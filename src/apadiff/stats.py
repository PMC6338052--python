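"""The ratio-of-ratios (roar) APA statistic and exact Fisher testing.

Per condition the short/long molar ratio m/M of a gene is estimated from
per-base coverage of the PRE (short+long) and POST (long only) regions:

    m/M = (pre_count/pre_length) / (post_count/post_length) - 1

The roar value of a gene is the ratio of m/M between two conditions,
contrast (differentiated/later) over baseline (proliferating/earlier):

    roar = (m/M)_contrast / (m/M)_baseline

so roar > 1 means relative 3'UTR shortening during differentiation and
roar < 1 relative lengthening.  Significance comes from two-sided Fisher
exact tests of the 2x2 table [[pre_a, post_a], [pre_b, post_b]], computed for
every pairing of baseline and contrast replicates; no multiple-testing
correction is applied (the downstream classifier requires every nominal p to
clear the threshold).

The Fisher p-value here is computed by exact integer enumeration of the
hypergeometric distribution (probability mass compared as exact integer
numerators over a common denominator), so results agree with full
enumeration to floating-point rounding only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .annotation import ApaSegmentation
from .quant import RegionCounts, fpkm

VALID_FLAGS = ("ok", "negative_mM", "zero_post", "zero_pre", "undefined_roar")


def fisher_pre_post(
    pre_a: int, post_a: int, pre_b: int, post_b: int, alternative: str = "two-sided"
) -> float:
    """Fisher exact p-value for the 2x2 table [[pre_a,post_a],[pre_b,post_b]].

    ``two-sided``: sum of hypergeometric probabilities of all tables (with the
    observed margins) no more likely than the observed one.  ``greater``:
    upper tail on pre_a.  Probabilities are compared as exact integers; the
    only rounding is the final conversion to float.  Returns ``nan`` for a
    table with an all-zero row or column (the test is undefined there).
    """
    for v in (pre_a, post_a, pre_b, post_b):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"invalid alternative {alternative!r}")
    r1 = pre_a + post_a
    r2 = pre_b + post_b
    c1 = pre_a + pre_b
    c2 = post_a + post_b
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return math.nan
    n = r1 + r2
    k_obs = pre_a
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # numerator of P(K = k) over the common denominator C(n, c1)
    n_obs = math.comb(r1, k_obs) * math.comb(r2, c1 - k_obs)
    total = 0
    if alternative == "greater":
        for k in range(k_obs, hi + 1):
            total += math.comb(r1, k) * math.comb(r2, c1 - k)
    else:
        for k in range(lo, hi + 1):
            num = math.comb(r1, k) * math.comb(r2, c1 - k)
            if num <= n_obs:
                total += num
    return float(Fraction(total, math.comb(n, c1)))


def m_over_M(
    pre_count: int, post_count: int, pre_length: int, post_length: int
) -> Optional[float]:
    """Short/long molar-ratio estimate from PRE/POST per-base coverage.

    Undefined (``None``) when post_count is 0.  A negative value signals a
    violation of the generative model (POST coverage above PRE coverage) and
    is returned as-is for the caller to flag.
    """
    if pre_length <= 0 or post_length <= 0:
        raise ValueError("region lengths must be positive")
    if pre_count < 0 or post_count < 0:
        raise ValueError("counts must be non-negative")
    if post_count == 0:
        return None
    return (pre_count / pre_length) / (post_count / post_length) - 1.0


def roar_value(
    mM_baseline: Optional[float], mM_contrast: Optional[float]
) -> Optional[float]:
    """Ratio of m/M between conditions: contrast / baseline.

    Defined only when both m/M values are defined and the baseline is
    positive; ``None`` otherwise.  roar > 1 is shortening in the contrast
    condition, roar < 1 lengthening.
    """
    if mM_baseline is None or mM_contrast is None or mM_baseline <= 0:
        return None
    return mM_contrast / mM_baseline


def all_pairings_pvalues(
    baseline_replicates: Sequence[RegionCounts],
    contrast_replicates: Sequence[RegionCounts],
    gene_id: str,
) -> list[float]:
    """Fisher p for every (baseline, contrast) replicate pairing of one gene.

    Ordered by (baseline index, contrast index).
    """
    if not baseline_replicates or not contrast_replicates:
        raise ValueError("need at least one replicate per condition")
    pvalues = []
    for rb in baseline_replicates:
        for rc in contrast_replicates:
            try:
                pre_b, post_b = rb.counts[gene_id]
                pre_c, post_c = rc.counts[gene_id]
            except KeyError as exc:
                raise ValueError(f"gene/sample mismatch for {gene_id}") from exc
            pvalues.append(fisher_pre_post(pre_b, post_b, pre_c, post_c))
    return pvalues


@dataclass
class GeneApaStat:
    """Per-gene APA statistics for one baseline-vs-contrast comparison."""

    gene_id: str
    mM_baseline: Optional[float]
    mM_contrast: Optional[float]
    roar: Optional[float]
    pairwise_pvalues: list[float]
    fpkm_baseline: float
    fpkm_contrast: float
    flag: str

    def __post_init__(self) -> None:
        if self.flag not in VALID_FLAGS:
            raise ValueError(f"invalid validity flag {self.flag!r}")


def _pooled(replicates: Sequence[RegionCounts], gene_id: str) -> tuple[int, int, int]:
    pre = post = lib = 0
    for rc in replicates:
        try:
            p, q = rc.counts[gene_id]
        except KeyError as exc:
            raise ValueError(f"gene/sample mismatch for {gene_id}") from exc
        pre += p
        post += q
        lib += rc.library_size
    return pre, post, lib


def pooled_gene_stat(
    baseline_replicates: Sequence[RegionCounts],
    contrast_replicates: Sequence[RegionCounts],
    segmentation: ApaSegmentation,
    gene_id: str,
) -> GeneApaStat:
    """m/M, roar, common-region FPKMs and all-pairings p-values for one gene.

    m/M and roar are computed on counts pooled across replicates within each
    condition; the expression filter is the FPKM of the PRE (common) region on
    pooled counts and pooled library sizes; significance is assessed per
    replicate pairing.
    """
    pre_b, post_b, lib_b = _pooled(baseline_replicates, gene_id)
    pre_c, post_c, lib_c = _pooled(contrast_replicates, gene_id)
    pre_len = segmentation.pre_length
    post_len = segmentation.post_length

    mM_b = m_over_M(pre_b, post_b, pre_len, post_len)
    mM_c = m_over_M(pre_c, post_c, pre_len, post_len)
    roar = roar_value(mM_b, mM_c)

    if post_b == 0 or post_c == 0:
        flag = "zero_post"
    elif pre_b == 0 or pre_c == 0:
        flag = "zero_pre"
    elif (mM_b is not None and mM_b < 0) or (mM_c is not None and mM_c < 0):
        flag = "negative_mM"
    elif roar is None:
        flag = "undefined_roar"
    else:
        flag = "ok"

    return GeneApaStat(
        gene_id=gene_id,
        mM_baseline=mM_b,
        mM_contrast=mM_c,
        roar=roar,
        pairwise_pvalues=all_pairings_pvalues(
            baseline_replicates, contrast_replicates, gene_id
        ),
        fpkm_baseline=fpkm(pre_b, pre_len, lib_b),
        fpkm_contrast=fpkm(pre_c, pre_len, lib_c),
        flag=flag,
    )


def stats_to_frame(stats: Mapping[str, GeneApaStat]):
    """Tabulate GeneApaStat values as a pandas DataFrame (p_1..p_k columns)."""
    import pandas as pd

    rows = []
    for gene_id in sorted(stats):
        s = stats[gene_id]
        row = {
            "gene_id": s.gene_id,
            "mM_baseline": s.mM_baseline,
            "mM_contrast": s.mM_contrast,
            "roar": s.roar,
        }
        for i, p in enumerate(s.pairwise_pvalues, 1):
            row[f"p_{i}"] = p
        row["fpkm_baseline"] = s.fpkm_baseline
        row["fpkm_contrast"] = s.fpkm_contrast
        row["flag"] = s.flag
        rows.append(row)
    return pd.DataFrame(rows)


def write_stats_tsv(stats: Mapping[str, GeneApaStat], path) -> None:
    frame = stats_to_frame(stats)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
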