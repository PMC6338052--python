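"""Synthetic genomes, polyA sites, ground truth and count/alignment simulation.

The generator emulates the statistical structure the APA analysis assumes: a
two-condition (optionally four-time-point) design with biological replicates,
per-gene long-isoform fractions that stay constant (UNCHANGED), rise
(LENGTHENED) or fall (SHORTENED) along the time course, per-gene expression
levels, and negative-binomial fragment-count noise
(variance = mean + dispersion * mean^2; dispersion 0 degenerates to Poisson).

Counts are split between PRE and POST by per-base rates: every molecule
covers PRE, only the long isoform covers POST, so with long molar fraction f
the expected PRE weight is pre_length and the POST weight f * post_length —
hence the true short/long molar ratio is m/M = (1 - f) / f.

A fraction of genes (default 6.7%, mirroring the share of transcripts whose
annotated polyA site falls outside the 3'UTR) carries its proximal site
upstream of the 3'UTR to exercise the segmentation fallback rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import ApaSegmentation, PolyASite, TranscriptModel
from .quant import RegionCounts

TIME_COURSE_CONDITIONS = ("T0", "T1", "T2", "T3")
TIME_COURSE_REPLICATES = (3, 3, 3, 2)

CLASSES = ("UNCHANGED", "LENGTHENED", "SHORTENED")


@dataclass(frozen=True)
class SyntheticGeneTruth:
    gene_id: str
    expression_level: float  # expected fragments per replicate at unit depth scale
    long_fraction: dict[str, float]  # condition -> long molar fraction f in (0, 1]
    true_class: str
    pre_length: int
    post_length: int

    def true_mM(self, condition: str) -> float:
        f = self.long_fraction[condition]
        return (1.0 - f) / f


@dataclass
class SyntheticTruth:
    conditions: tuple[str, ...]
    genes: dict[str, SyntheticGeneTruth]

    def classes(self) -> dict[str, str]:
        return {g: t.true_class for g, t in self.genes.items()}


@dataclass
class SyntheticGenome:
    transcripts: list[TranscriptModel]
    sites: list[PolyASite]
    truth: SyntheticTruth
    chrom_lengths: dict[str, int]


def _class_fractions(
    rng: np.random.Generator,
    n_conditions: int,
    true_class: str,
    f_low: float,
    f_high: float,
) -> list[float]:
    if true_class == "LENGTHENED":
        lo, hi = f_low, f_high
    elif true_class == "SHORTENED":
        lo, hi = f_high, f_low
    else:
        f = float(rng.uniform(0.3, 0.9))
        return [f] * n_conditions
    if n_conditions == 1:
        return [lo]
    return [lo + (hi - lo) * i / (n_conditions - 1) for i in range(n_conditions)]


def generate_genome(
    n_genes: int,
    conditions: Sequence[str] = ("T0", "T1"),
    frac_no_utr3_apa: float = 0.067,
    frac_lengthened: float = 0.1,
    frac_shortened: float = 0.1,
    long_fraction_low: float = 0.2,
    long_fraction_high: float = 0.8,
    frac_multi_transcript: float = 0.2,
    expression_sigma: float = 0.6,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticGenome:
    """Generate gene models, polyA sites and a ground-truth table.

    Deterministic given ``seed``.  Genes sit on both strands of five synthetic
    chromosomes with 1-4 exons each; every gene gets one proximal polyA site
    (inside the 3'UTR, or upstream of it for the ``frac_no_utr3_apa`` share)
    and sometimes a decoy distal site.  Expression levels are lognormal with
    unit mean (``expression_sigma`` = 0 makes them exactly 1); they scale the
    sequencing depth requested at simulation time.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, frac in (
        ("frac_no_utr3_apa", frac_no_utr3_apa),
        ("frac_lengthened", frac_lengthened),
        ("frac_shortened", frac_shortened),
        ("frac_multi_transcript", frac_multi_transcript),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if frac_lengthened + frac_shortened > 1:
        raise ValueError("class fractions exceed 1")
    if not 0 < long_fraction_low < long_fraction_high <= 1:
        raise ValueError("need 0 < long_fraction_low < long_fraction_high <= 1")

    rng = rng if rng is not None else np.random.default_rng(seed)
    conditions = tuple(conditions)
    n_chroms = 5
    cursors = {f"chr{i + 1}": 1000 for i in range(n_chroms)}

    n_len = int(round(frac_lengthened * n_genes))
    n_sho = int(round(frac_shortened * n_genes))
    n_sho = min(n_sho, n_genes - n_len)
    labels = (
        ["LENGTHENED"] * n_len
        + ["SHORTENED"] * n_sho
        + ["UNCHANGED"] * (n_genes - n_len - n_sho)
    )
    labels = [labels[i] for i in rng.permutation(n_genes)]
    fallback = rng.random(n_genes) < frac_no_utr3_apa
    multi = rng.random(n_genes) < frac_multi_transcript

    transcripts: list[TranscriptModel] = []
    sites: list[PolyASite] = []
    genes: dict[str, SyntheticGeneTruth] = {}

    for i in range(n_genes):
        gene_id = f"g{i + 1:05d}"
        chrom = f"chr{(i % n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        # the transcript-orientation last exon is larger: it hosts the 3'UTR,
        # whose distal (POST) segment is a sizeable fraction of the transcript
        lengths = [int(rng.integers(200, 1200)) for _ in range(n_exons)]
        lengths[-1 if strand == "+" else 0] = int(rng.integers(700, 2000))
        start = cursors[chrom]
        exons: list[tuple[int, int]] = []
        pos = start
        for length in lengths:
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(200, 2000))
        cursors[chrom] = exons[-1][1] + 10000

        # 3'UTR inside the transcript-orientation last exon
        last = exons[-1] if strand == "+" else exons[0]
        utr_len = int((last[1] - last[0]) * rng.uniform(0.6, 0.8))
        if strand == "+":
            utr3 = (last[1] - utr_len, last[1])
        else:
            utr3 = (last[0], last[0] + utr_len)

        # proximal site: inside the UTR, or upstream of it for fallback genes
        post_len_target = max(50, int(utr_len * rng.uniform(0.4, 0.7)))
        if not fallback[i]:
            if strand == "+":
                prox = utr3[1] - post_len_target
            else:
                prox = utr3[0] + post_len_target
        else:
            # upstream of the 3'UTR but still exonic and 3' of the 5' end
            total_exonic = sum(e - s for s, e in exons)
            upstream = min(utr_len + int(rng.integers(20, 200)), total_exonic - 2)
            prox = _exonic_offset_from_3p(exons, strand, upstream)
        sites.append(PolyASite(chrom, prox, strand, f"pas_{gene_id}_prox"))
        if not fallback[i] and rng.random() < 0.3:
            # decoy distal site between the proximal site and the canonical end
            offset = int(rng.integers(10, max(11, post_len_target - 10)))
            decoy = prox + offset if strand == "+" else prox - offset
            if (strand == "+" and decoy < exons[-1][1]) or (
                strand == "-" and decoy >= exons[0][0]
            ):
                sites.append(PolyASite(chrom, decoy, strand, f"pas_{gene_id}_dist"))

        exons_t = tuple(exons)
        transcripts.append(
            TranscriptModel(gene_id, f"{gene_id}.t1", chrom, strand, exons_t, utr3)
        )
        if multi[i] and n_exons > 1:
            # a shorter secondary isoform: drop the transcript-5' exon
            sub = exons_t[1:] if strand == "+" else exons_t[:-1]
            transcripts.append(
                TranscriptModel(gene_id, f"{gene_id}.t2", chrom, strand, sub, None)
            )

        pre_len, post_len = _true_split_lengths(exons_t, strand, prox)
        fractions = _class_fractions(
            rng, len(conditions), labels[i], long_fraction_low, long_fraction_high
        )
        expr = (
            1.0
            if expression_sigma == 0
            else float(rng.lognormal(-0.5 * expression_sigma**2, expression_sigma))
        )
        genes[gene_id] = SyntheticGeneTruth(
            gene_id=gene_id,
            expression_level=expr,
            long_fraction=dict(zip(conditions, fractions)),
            true_class=labels[i],
            pre_length=pre_len,
            post_length=post_len,
        )

    chrom_lengths = {c: cursors[c] + 1000 for c in sorted(cursors)}
    return SyntheticGenome(
        transcripts=transcripts,
        sites=sites,
        truth=SyntheticTruth(conditions=conditions, genes=genes),
        chrom_lengths=chrom_lengths,
    )


def _exonic_offset_from_3p(
    exons: Sequence[tuple[int, int]], strand: str, offset: int
) -> int:
    """Genomic coordinate of the exonic base ``offset`` bases 5' of the 3' end."""
    remaining = offset
    if strand == "+":
        for s, e in reversed(exons):
            if remaining < e - s:
                return e - 1 - remaining
            remaining -= e - s
        return exons[0][0]
    for s, e in exons:
        if remaining < e - s:
            return s + remaining
        remaining -= e - s
    return exons[-1][1] - 1


def _true_split_lengths(
    exons: Sequence[tuple[int, int]], strand: str, position: int
) -> tuple[int, int]:
    """PRE/POST lengths by direct per-base arithmetic (generator-side truth)."""
    below = sum(min(e, position) - s for s, e in exons if s < position)
    total = sum(e - s for s, e in exons)
    if strand == "+":
        return below, total - below
    return total - below, below


def simulate_counts(
    truth: SyntheticTruth,
    conditions: Optional[Sequence[str]] = None,
    n_replicates: int | Sequence[int] = 3,
    mean_depth: float = 300.0,
    dispersion: float = 0.1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[RegionCounts]:
    """Draw per-replicate PRE/POST counts from the ground truth.

    Total fragments per gene and replicate follow a negative binomial with
    mean ``expression_level * mean_depth`` and the given dispersion
    (variance = mu + dispersion * mu^2; Poisson when dispersion is 0); the
    PRE/POST split is binomial with PRE weight pre_length and POST weight
    long_fraction * post_length.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    conditions = tuple(conditions) if conditions is not None else truth.conditions
    if isinstance(n_replicates, int):
        reps = [n_replicates] * len(conditions)
    else:
        reps = list(n_replicates)
        if len(reps) != len(conditions):
            raise ValueError("n_replicates list must match conditions")

    gene_ids = sorted(truth.genes)
    out: list[RegionCounts] = []
    for cond, n_rep in zip(conditions, reps):
        for r in range(n_rep):
            counts: dict[str, tuple[int, int]] = {}
            lib = 0
            for gene_id in gene_ids:
                t = truth.genes[gene_id]
                mu = t.expression_level * mean_depth
                if dispersion == 0:
                    total = int(rng.poisson(mu))
                else:
                    shape = 1.0 / dispersion
                    p = shape / (shape + mu)
                    total = int(rng.negative_binomial(shape, p))
                f = t.long_fraction[cond]
                w_pre = float(t.pre_length)
                w_post = f * t.post_length
                pre = int(rng.binomial(total, w_pre / (w_pre + w_post)))
                post = total - pre
                counts[gene_id] = (pre, post)
                lib += total
            out.append(
                RegionCounts(
                    sample_id=f"{cond}_rep{r + 1}",
                    condition=cond,
                    counts=counts,
                    library_size=lib,
                )
            )
    return out


def emit_alignments(
    segmentations: Mapping[str, ApaSegmentation],
    counts: RegionCounts,
    chrom_lengths: Mapping[str, int],
    read_length: int = 50,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Render one sample's counts as SAM text.

    Each PRE-assigned read is placed uniformly, fully inside one PRE interval
    of its gene (and symmetrically for POST), so re-counting the emitted
    alignments reproduces the input counts exactly.  Reads longer than the
    chosen interval are shortened to fit (logged via the record itself).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")

    for gene_id in sorted(counts.counts):
        if gene_id not in segmentations:
            raise ValueError(f"no segmentation for counted gene {gene_id}")
        seg = segmentations[gene_id]
        pre_n, post_n = counts.counts[gene_id]
        flag = 0 if seg.strand == "+" else 16
        for label, n, intervals in (
            ("PRE", pre_n, seg.pre_intervals),
            ("POST", post_n, seg.post_intervals),
        ):
            lengths = np.array([e - s for s, e in intervals], dtype=float)
            probs = lengths / lengths.sum()
            for i in range(n):
                idx = int(rng.choice(len(intervals), p=probs))
                s, e = intervals[idx]
                rlen = min(read_length, e - s)
                start = int(rng.integers(s, e - rlen + 1))
                lines.append(
                    "\t".join(
                        [
                            f"{gene_id}_{label}_{i + 1}",
                            str(flag),
                            seg.chrom,
                            str(start + 1),
                            "60",
                            f"{rlen}M",
                            "*",
                            "0",
                            "0",
                            "A" * rlen,
                            "*",
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------


def write_gtf(genome: SyntheticGenome, path: str | Path) -> None:
    """Write the synthetic transcripts as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in genome.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [
                        t.chrom, "apadiff", "transcript",
                        str(t.span[0] + 1), str(t.span[1]), ".", t.strand, ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, "apadiff", "exon", str(s + 1), str(e), ".",
                         t.strand, ".", attrs]
                    )
                    + "\n"
                )
            if t.utr3 is not None:
                fh.write(
                    "\t".join(
                        [t.chrom, "apadiff", "three_prime_utr",
                         str(t.utr3[0] + 1), str(t.utr3[1]), ".", t.strand, ".",
                         attrs]
                    )
                    + "\n"
                )


def write_polya_bed(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in genome.sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.site_id}\t0\t{s.strand}\n"
            )


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    conds = truth.conditions
    with open(path, "w") as fh:
        cols = ["gene_id", "expression_level"]
        cols += [f"long_fraction_{c}" for c in conds]
        cols += ["true_class", "pre_length", "post_length"]
        fh.write("\t".join(cols) + "\n")
        for gene_id in sorted(truth.genes):
            t = truth.genes[gene_id]
            row = [gene_id, f"{t.expression_level:.6g}"]
            row += [f"{t.long_fraction[c]:.6g}" for c in conds]
            row += [t.true_class, str(t.pre_length), str(t.post_length)]
            fh.write("\t".join(row) + "\n")


def generate_clip_sites(
    genome: SyntheticGenome,
    segmentations: Mapping[str, ApaSegmentation],
    frac_target_lengthened: float = 0.7,
    frac_background: float = 0.1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Plant binding sites preferentially on LENGTHENED genes (demo helper).

    Synthetic stand-in for an experimentally determined binding-site
    catalogue; sites receive plausible FDR/BC scores, some failing the
    robust-cluster filter.
    """
    from .clip import BindingSite

    rng = rng if rng is not None else np.random.default_rng(seed)
    sites: list[BindingSite] = []
    for gene_id in sorted(segmentations):
        seg = segmentations[gene_id]
        cls = genome.truth.genes[gene_id].true_class
        hit_prob = frac_target_lengthened if cls == "LENGTHENED" else frac_background
        if rng.random() >= hit_prob:
            continue
        span = seg.gene_span
        start = int(rng.integers(span[0], max(span[0] + 1, span[1] - 30)))
        robust = rng.random() < 0.8
        fdr = float(rng.uniform(0.0, 0.009)) if robust else float(rng.uniform(0.05, 0.5))
        bc = int(rng.integers(5, 10)) if robust else int(rng.integers(1, 4))
        sites.append(
            BindingSite(seg.chrom, start, start + 30, seg.strand, fdr=fdr, bc=bc)
        )
    return sites


def write_clip_bed(sites, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites, 1):
            fdr = "." if s.fdr is None else f"{s.fdr:.6g}"
            bc = "." if s.bc is None else str(s.bc)
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i}\t0\t{s.strand}\t{fdr}\t{bc}\n"
            )
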