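"""Read counting into PRE/POST regions and the common-region FPKM filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .annotation import ApaSegmentation

logger = logging.getLogger(__name__)


@dataclass
class RegionCounts:
    """Per-sample PRE/POST read counts for every gene, plus library size.

    ``counts`` maps gene_id -> (pre_count, post_count).  ``library_size`` is
    the number of primary mapped alignments in the sample (not the number of
    assigned reads).
    """

    sample_id: str
    condition: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        for gene_id, (pre, post) in self.counts.items():
            if pre < 0 or post < 0 or pre != int(pre) or post != int(post):
                raise ValueError(f"malformed counts for gene {gene_id}")
        if self.library_size < 0:
            raise ValueError("negative library size")

    def pre(self, gene_id: str) -> int:
        return self.counts[gene_id][0]

    def post(self, gene_id: str) -> int:
        return self.counts[gene_id][1]


def count_reads(
    alignments: str | Path,
    segmentations: Mapping[str, ApaSegmentation],
    sample_id: str = "sample",
    condition: str = "NA",
    stranded: str = "none",
    boundary: str = "post",
) -> RegionCounts:
    """Assign primary mapped alignments to PRE/POST regions.

    An alignment overlapping a gene's PRE or POST by >= 1 base is assigned to
    that gene.  Under the default ``boundary='post'`` rule a read overlapping
    both regions counts only toward POST (such reads can only come from the
    long isoform); ``boundary='both'`` counts it in both.  ``stranded`` is one
    of ``none`` (ignore read strand), ``forward`` (read strand must match the
    gene) or ``reverse`` (must be opposite).  Secondary, supplementary and
    unmapped records are ignored; every counted-or-not primary mapped record
    contributes to ``library_size``.
    """
    import pysam

    if not segmentations:
        raise ValueError("empty segmentation")
    if stranded not in ("none", "forward", "reverse"):
        raise ValueError(f"invalid strandedness {stranded!r}")
    if boundary not in ("post", "both"):
        raise ValueError(f"invalid boundary rule {boundary!r}")

    trees: dict[str, IntervalTree] = {}
    for gene_id, seg in segmentations.items():
        tree = trees.setdefault(seg.chrom, IntervalTree())
        for s, e in seg.pre_intervals:
            tree[s:e] = (gene_id, "PRE", seg.strand)
        for s, e in seg.post_intervals:
            tree[s:e] = (gene_id, "POST", seg.strand)

    counts: dict[str, list[int]] = {g: [0, 0] for g in segmentations}
    library_size = 0
    n_multi_gene = 0
    n_malformed = 0

    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        it = iter(af)
        while True:
            try:
                read = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:  # malformed record
                n_malformed += 1
                logger.warning("skipping malformed alignment record: %s", exc)
                if n_malformed > 100:
                    raise
                continue
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            library_size += 1
            chrom = read.reference_name
            if chrom not in trees:
                continue
            read_strand = "-" if read.is_reverse else "+"
            hits = trees[chrom][read.reference_start : read.reference_end]
            per_gene: dict[str, set[str]] = {}
            for hit in hits:
                gene_id, label, gene_strand = hit.data
                if stranded == "forward" and read_strand != gene_strand:
                    continue
                if stranded == "reverse" and read_strand == gene_strand:
                    continue
                per_gene.setdefault(gene_id, set()).add(label)
            if len(per_gene) > 1:
                n_multi_gene += 1
            for gene_id, labels in per_gene.items():
                if "POST" in labels and "PRE" in labels:
                    if boundary == "post":
                        counts[gene_id][1] += 1
                    else:
                        counts[gene_id][0] += 1
                        counts[gene_id][1] += 1
                elif "POST" in labels:
                    counts[gene_id][1] += 1
                else:
                    counts[gene_id][0] += 1

    if n_multi_gene:
        logger.info("%d reads overlapped regions of multiple genes", n_multi_gene)
    return RegionCounts(
        sample_id=sample_id,
        condition=condition,
        counts={g: (c[0], c[1]) for g, c in counts.items()},
        library_size=library_size,
    )


def write_counts_table(rc: RegionCounts, path: str | Path) -> None:
    """Write a RegionCounts as the package's TSV dialect.

    Header comment lines carry sample_id, condition and library_size; the
    body has columns gene_id, pre_count, post_count sorted by gene_id.
    """
    with open(path, "w") as fh:
        fh.write(f"# sample_id={rc.sample_id}\n")
        fh.write(f"# condition={rc.condition}\n")
        fh.write(f"# library_size={rc.library_size}\n")
        fh.write("gene_id\tpre_count\tpost_count\n")
        for gene_id in sorted(rc.counts):
            pre, post = rc.counts[gene_id]
            fh.write(f"{gene_id}\t{pre}\t{post}\n")


def read_counts_table(path: str | Path) -> RegionCounts:
    """Parse a counts TSV written by :func:`write_counts_table`."""
    header: dict[str, str] = {}
    counts: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                header[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) != 3:
                raise ValueError(f"malformed counts row: {line!r}")
            gene_id, pre_s, post_s = fields
            try:
                pre, post = int(pre_s), int(post_s)
            except ValueError as exc:
                raise ValueError(f"malformed counts for gene {gene_id}") from exc
            if pre < 0 or post < 0:
                raise ValueError(f"malformed counts for gene {gene_id}")
            if gene_id in counts:
                raise ValueError(f"duplicate gene_id {gene_id}")
            counts[gene_id] = (pre, post)
    for key in ("sample_id", "condition", "library_size"):
        if key not in header:
            raise ValueError(f"counts table missing header field {key}")
    return RegionCounts(
        sample_id=header["sample_id"],
        condition=header["condition"],
        counts=counts,
        library_size=int(header["library_size"]),
    )


def fpkm(count: int, length: int, library_size: int) -> float:
    """Fragments per kilobase of region per million mapped reads."""
    if length <= 0:
        raise ValueError("region length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / ((length / 1000.0) * (library_size / 1e6))
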