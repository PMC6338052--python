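"""PRE/POST 3'UTR segmentation from transcript models and polyA sites.

Alternative polyadenylation (APA) produces transcript isoforms that differ in
3'UTR length.  For each gene we define, on its canonical (longest) transcript:

* the *long* isoform, ending at the canonical transcript 3' end;
* the *short* isoform, ending at the most 5'-proximal annotated polyA site in
  the 3'UTR;
* the **PRE** region, exonic bases shared by both isoforms (transcript 5' end
  up to the proximal site), and the **POST** region, exonic bases present only
  in the long isoform (proximal site to the canonical end).

All coordinates are 0-based half-open genomic intervals; GTF input (1-based,
closed) is converted at the parser boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class SegmentationError(ValueError):
    """Raised when a gene cannot be segmented (degenerate PRE/POST, no site)."""


def _check_exons(exons: Sequence[Interval]) -> tuple[Interval, ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError("transcript has no exons")
    prev_end = None
    for s, e in exons:
        if e <= s:
            raise ValueError(f"empty exon interval [{s},{e})")
        if prev_end is not None and s < prev_end:
            raise ValueError("exons overlap or are unsorted")
        prev_end = e
    return exons


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus an optional 3'UTR interval.

    ``utr3`` is the genomic span of the annotated 3'UTR (half-open); it must
    lie within the transcript span and intersect the exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    utr3: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "exons", _check_exons(self.exons))
        if self.utr3 is not None:
            u0, u1 = int(self.utr3[0]), int(self.utr3[1])
            if u1 <= u0:
                raise ValueError("empty 3'UTR interval")
            if u0 < self.span[0] or u1 > self.span[1]:
                raise ValueError("3'UTR outside transcript span")
            if not any(max(s, u0) < min(e, u1) for s, e in self.exons):
                raise ValueError("3'UTR does not intersect any exon")
            object.__setattr__(self, "utr3", (u0, u1))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def canonical_end(self) -> int:
        """Genomic coordinate of the transcript 3' end (canonical polyA)."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def contains_exonic(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)


@dataclass(frozen=True)
class PolyASite:
    """A single-base polyadenylation site."""

    chrom: str
    position: int
    strand: str
    site_id: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("negative polyA-site position")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ApaSegmentation:
    """PRE (common) and POST (long-only) exonic intervals of one gene."""

    gene_id: str
    chrom: str
    strand: str
    pre_intervals: tuple[Interval, ...]
    post_intervals: tuple[Interval, ...]
    proximal_site: PolyASite
    canonical_end: int

    @property
    def pre_length(self) -> int:
        return sum(e - s for s, e in self.pre_intervals)

    @property
    def post_length(self) -> int:
        return sum(e - s for s, e in self.post_intervals)

    @property
    def gene_span(self) -> Interval:
        ivs = self.pre_intervals + self.post_intervals
        return (min(s for s, _ in ivs), max(e for _, e in ivs))


def select_canonical_transcript(
    transcripts: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Pick the canonical transcript of a gene: maximal exonic length.

    Ties are broken by lexicographically smallest transcript_id so the choice
    is reproducible.
    """
    if not transcripts:
        raise ValueError("no transcripts for gene")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    return min(transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))


def choose_proximal_site(
    transcript: TranscriptModel, sites: Iterable[PolyASite]
) -> Optional[PolyASite]:
    """Most 5'-proximal polyA site of a transcript, in transcript orientation.

    Sites on the wrong chromosome or strand are ignored.  Sites inside the
    annotated 3'UTR take precedence; if the transcript has none there (or has
    no annotated 3'UTR), the same most-5' rule is applied to sites anywhere in
    the transcript's exons.  Returns ``None`` when no usable site exists.
    """
    usable = [
        s
        for s in sites
        if s.chrom == transcript.chrom and s.strand == transcript.strand
    ]
    if transcript.utr3 is not None:
        u0, u1 = transcript.utr3
        in_utr = [s for s in usable if u0 <= s.position < u1]
    else:
        in_utr = []
    candidates = in_utr or [
        s for s in usable if transcript.contains_exonic(s.position)
    ]
    if not candidates:
        return None
    if transcript.strand == "+":
        return min(candidates, key=lambda s: (s.position, s.site_id))
    return min(candidates, key=lambda s: (-s.position, s.site_id))


def _split_exonic(
    exons: Sequence[Interval], position: int
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    """Partition exonic bases at a genomic coordinate: (< position, >= position)."""
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in exons:
        if e <= position:
            left.append((s, e))
        elif s >= position:
            right.append((s, e))
        else:
            left.append((s, position))
            right.append((position, e))
    return tuple(left), tuple(right)


def build_segmentation(
    transcript: TranscriptModel, proximal: PolyASite
) -> ApaSegmentation:
    """Split the canonical transcript's exonic bases into PRE and POST.

    The cut is made at the proximal site's coordinate: on the + strand PRE
    holds exonic bases strictly left of the site and POST the rest; mirrored
    on the - strand.  Raises :class:`SegmentationError` when either side would
    be empty ("degenerate PRE"/"degenerate POST").
    """
    if proximal.chrom != transcript.chrom or proximal.strand != transcript.strand:
        raise SegmentationError("proximal site on wrong chrom/strand")
    left, right = _split_exonic(transcript.exons, proximal.position)
    if transcript.strand == "+":
        pre, post = left, right
    else:
        pre, post = right, left
    if not post:
        raise SegmentationError("degenerate POST")
    if not pre:
        raise SegmentationError("degenerate PRE")
    seg = ApaSegmentation(
        gene_id=transcript.gene_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        pre_intervals=pre,
        post_intervals=post,
        proximal_site=proximal,
        canonical_end=transcript.canonical_end,
    )
    assert seg.pre_length + seg.post_length == transcript.exonic_length
    return seg


def build_all_segmentations(
    transcripts: Iterable[TranscriptModel], sites: Iterable[PolyASite]
) -> tuple[dict[str, ApaSegmentation], dict[str, str]]:
    """Segment every gene with a usable proximal site.

    Returns ``(segmentations, exclusions)`` where exclusions maps gene_id to a
    machine-readable reason: ``no_apa_site``, ``degenerate_post`` or
    ``degenerate_pre``.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    sites_by_chrom: dict[tuple[str, str], list[PolyASite]] = {}
    for s in sites:
        sites_by_chrom.setdefault((s.chrom, s.strand), []).append(s)

    segmentations: dict[str, ApaSegmentation] = {}
    exclusions: dict[str, str] = {}
    for gene_id in sorted(by_gene):
        canonical = select_canonical_transcript(by_gene[gene_id])
        cand = sites_by_chrom.get((canonical.chrom, canonical.strand), [])
        proximal = choose_proximal_site(canonical, cand)
        if proximal is None:
            exclusions[gene_id] = "no_apa_site"
            continue
        try:
            segmentations[gene_id] = build_segmentation(canonical, proximal)
        except SegmentationError as exc:
            reason = "degenerate_post" if "POST" in str(exc) else "degenerate_pre"
            exclusions[gene_id] = reason
    return segmentations, exclusions


# ---------------------------------------------------------------------------
# I/O: GTF transcripts, BED polyA sites, BED segmentation output
# ---------------------------------------------------------------------------

_UTR3_TYPES = ("three_prime_utr", "three_prime_UTR", "3UTR")


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exons are grouped by (gene_id, transcript_id).  The 3'UTR comes from
    explicit three_prime_utr/3UTR features when present; otherwise it is
    inferred from the stop_codon as the exonic span 3' of it.  GTF 1-based
    closed coordinates are converted to 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[tuple[str, str], list[Interval]] = {}
    meta: dict[tuple[str, str], tuple[str, str]] = {}
    utrs: dict[tuple[str, str], list[Interval]] = {}
    stops: dict[tuple[str, str], list[Interval]] = {}

    for feat in db.all_features():
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            continue
        key = (gid, tid)
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(key, []).append(iv)
            meta[key] = (feat.seqid, feat.strand)
        elif feat.featuretype in _UTR3_TYPES:
            utrs.setdefault(key, []).append(iv)
        elif feat.featuretype == "stop_codon":
            stops.setdefault(key, []).append(iv)

    out: list[TranscriptModel] = []
    for key in sorted(exons):
        gid, tid = key
        chrom, strand = meta[key]
        ex = tuple(sorted(exons[key]))
        utr3: Optional[Interval] = None
        if key in utrs:
            chunks = utrs[key]
            utr3 = (min(s for s, _ in chunks), max(e for _, e in chunks))
        elif key in stops:
            stop = sorted(stops[key])
            span = (ex[0][0], ex[-1][1])
            if strand == "+":
                u = (stop[-1][1], span[1])
            else:
                u = (span[0], stop[0][0])
            if u[1] > u[0]:
                utr3 = u
        out.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=ex,
                utr3=utr3,
            )
        )
    return out


def read_polya_bed(path: str | Path) -> list[PolyASite]:
    """Read polyA sites from 6-column BED (name = site_id, strand in col 6)."""
    sites: list[PolyASite] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, _end, name, _score, strand = fields[:6]
            sites.append(
                PolyASite(
                    chrom=chrom,
                    position=int(start),
                    strand=strand,
                    site_id=name,
                )
            )
    return sites


def write_segmentation_bed(
    segmentations: Mapping[str, ApaSegmentation], path: str | Path
) -> None:
    """Write PRE/POST intervals as 6-column BED, names ``geneID|PRE`` etc."""
    rows = []
    for gene_id in sorted(segmentations):
        seg = segmentations[gene_id]
        for label, ivs in (("PRE", seg.pre_intervals), ("POST", seg.post_intervals)):
            for s, e in ivs:
                rows.append(
                    (seg.chrom, s, e, f"{gene_id}|{label}", 0, seg.strand)
                )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_segmentation_bed(path: str | Path) -> dict[str, ApaSegmentation]:
    """Inverse of :func:`write_segmentation_bed` (proximal site reconstructed)."""
    pre: dict[str, list[Interval]] = {}
    post: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            gene_id, label = name.rsplit("|", 1)
            meta[gene_id] = (chrom, strand)
            (pre if label == "PRE" else post).setdefault(gene_id, []).append(
                (int(s), int(e))
            )
    out: dict[str, ApaSegmentation] = {}
    for gene_id in sorted(meta):
        chrom, strand = meta[gene_id]
        pre_ivs = tuple(sorted(pre.get(gene_id, [])))
        post_ivs = tuple(sorted(post.get(gene_id, [])))
        if not pre_ivs or not post_ivs:
            raise ValueError(f"gene {gene_id}: incomplete segmentation in BED")
        if strand == "+":
            prox_pos = post_ivs[0][0]
            canonical = post_ivs[-1][1]
        else:
            prox_pos = post_ivs[-1][1]
            canonical = post_ivs[0][0]
        out[gene_id] = ApaSegmentation(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            pre_intervals=pre_ivs,
            post_intervals=post_ivs,
            proximal_site=PolyASite(chrom, prox_pos, strand, f"{gene_id}|proximal"),
            canonical_end=canonical,
        )
    return out


def write_exclusions_tsv(exclusions: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for gene_id in sorted(exclusions):
            fh.write(f"{gene_id}\t{exclusions[gene_id]}\n")
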