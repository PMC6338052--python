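"""PRE/POST segmentation: canonical transcript, proximal site, splitting, I/O."""

import pytest

from apadiff.annotation import (
    ApaSegmentation,
    PolyASite,
    SegmentationError,
    TranscriptModel,
    build_all_segmentations,
    build_segmentation,
    choose_proximal_site,
    read_gtf,
    read_polya_bed,
    read_segmentation_bed,
    select_canonical_transcript,
    write_segmentation_bed,
)


def tx(gene="g1", tid="t1", chrom="chr1", strand="+", exons=((1000, 2000),), utr3=None):
    return TranscriptModel(gene, tid, chrom, strand, tuple(exons), utr3)


class TestCanonicalSelection:
    def test_longest_exonic_length_wins(self):
        a = tx(tid="NM_a", exons=((0, 1200),))
        b = tx(tid="NM_b", exons=((0, 400), (500, 1000)))  # 900 exonic
        assert select_canonical_transcript([a, b]) is a

    def test_single_transcript_is_itself(self):
        a = tx(tid="NM_a")
        assert select_canonical_transcript([a]) is a

    def test_tie_broken_by_lexicographic_id(self):
        a = tx(tid="NM_2", exons=((0, 1000),))
        b = tx(tid="NM_1", exons=((5000, 6000),))
        assert select_canonical_transcript([a, b]).transcript_id == "NM_1"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no transcripts"):
            select_canonical_transcript([])

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError, match="multiple genes"):
            select_canonical_transcript([tx(gene="g1"), tx(gene="g2")])


class TestProximalSite:
    def test_plus_strand_takes_smallest_coordinate_in_utr(self):
        t = tx(exons=((1000, 2000),), utr3=(1800, 2000))
        sites = [
            PolyASite("chr1", 1900, "+", "s2"),
            PolyASite("chr1", 1850, "+", "s1"),
        ]
        assert choose_proximal_site(t, sites).position == 1850

    def test_minus_strand_takes_largest_coordinate_in_utr(self):
        t = tx(strand="-", exons=((100, 1000),), utr3=(100, 300))
        sites = [
            PolyASite("chr1", 150, "-", "s1"),
            PolyASite("chr1", 250, "-", "s2"),
        ]
        assert choose_proximal_site(t, sites).position == 250

    def test_fallback_to_exonic_site_outside_utr(self):
        t = tx(exons=((1000, 2000),), utr3=(1800, 2000))
        site = PolyASite("chr1", 1500, "+", "s1")
        assert choose_proximal_site(t, [site]) is site

    def test_utr_site_preferred_over_upstream_site(self):
        t = tx(exons=((1000, 2000),), utr3=(1800, 2000))
        sites = [
            PolyASite("chr1", 1200, "+", "up"),
            PolyASite("chr1", 1900, "+", "in_utr"),
        ]
        assert choose_proximal_site(t, sites).site_id == "in_utr"

    def test_wrong_strand_or_chrom_excluded(self):
        t = tx(exons=((1000, 2000),), utr3=(1800, 2000))
        sites = [
            PolyASite("chr1", 1850, "-", "wrong_strand"),
            PolyASite("chr2", 1850, "+", "wrong_chrom"),
        ]
        assert choose_proximal_site(t, sites) is None

    def test_intronic_site_not_usable(self):
        t = tx(exons=((0, 100), (200, 300)))
        assert choose_proximal_site(t, [PolyASite("chr1", 150, "+", "s")]) is None


class TestBuildSegmentation:
    def test_plus_strand_single_exon_split(self):
        seg = build_segmentation(
            tx(exons=((1000, 2000),)), PolyASite("chr1", 1850, "+", "s")
        )
        assert seg.pre_intervals == ((1000, 1850),)
        assert seg.post_intervals == ((1850, 2000),)
        assert (seg.pre_length, seg.post_length) == (850, 150)
        assert seg.canonical_end == 2000

    def test_minus_strand_single_exon_split(self):
        seg = build_segmentation(
            tx(strand="-", exons=((1000, 2000),)), PolyASite("chr1", 1200, "-", "s")
        )
        assert seg.pre_intervals == ((1200, 2000),)
        assert seg.post_intervals == ((1000, 1200),)
        assert (seg.pre_length, seg.post_length) == (800, 200)
        assert seg.canonical_end == 1000

    def test_multi_exon_split_matches_per_base_enumeration(self):
        exons = ((0, 100), (200, 300))
        seg = build_segmentation(tx(exons=exons), PolyASite("chr1", 250, "+", "s"))
        exonic = [b for s, e in exons for b in range(s, e)]
        assert seg.pre_length == sum(1 for b in exonic if b < 250) == 150
        assert seg.post_length == sum(1 for b in exonic if b >= 250) == 50
        assert seg.pre_intervals == ((0, 100), (200, 250))
        assert seg.post_intervals == ((250, 300),)

    def test_site_at_canonical_end_degenerates_post(self):
        with pytest.raises(SegmentationError, match="degenerate POST"):
            build_segmentation(tx(exons=((1000, 2000),)), PolyASite("chr1", 2000, "+", "s"))

    def test_site_at_five_prime_end_degenerates_pre(self):
        with pytest.raises(SegmentationError, match="degenerate PRE"):
            build_segmentation(tx(exons=((1000, 2000),)), PolyASite("chr1", 1000, "+", "s"))


class TestBuildAll:
    def test_exclusions_are_reported_not_raised(self):
        transcripts = [
            tx(gene="gA", tid="a", exons=((0, 1000),), utr3=(800, 1000)),
            tx(gene="gB", tid="b", exons=((5000, 6000),), utr3=(5800, 6000)),
            tx(gene="gC", tid="c", exons=((9000, 9500),)),
        ]
        sites = [
            PolyASite("chr1", 900, "+", "sA"),
            PolyASite("chr1", 5900, "+", "sB"),
        ]
        segs, excl = build_all_segmentations(transcripts, sites)
        assert sorted(segs) == ["gA", "gB"]
        assert excl == {"gC": "no_apa_site"}

    def test_degenerate_sites_excluded_with_reason(self):
        # minus-strand gene: a site at the exon start coincides with the
        # canonical 3' end -> empty POST; plus-strand gene: a site at the exon
        # start is the transcript 5' end -> empty PRE
        transcripts = [
            tx(gene="gA", tid="a", strand="-", exons=((0, 1000),), utr3=(0, 200)),
            tx(gene="gB", tid="b", exons=((5000, 6000),), utr3=(5800, 6000)),
        ]
        sites = [
            PolyASite("chr1", 0, "-", "sA"),
            PolyASite("chr1", 5000, "+", "sB"),
        ]
        segs, excl = build_all_segmentations(transcripts, sites)
        assert not segs
        assert excl == {"gA": "degenerate_post", "gB": "degenerate_pre"}

    def test_matches_generator_truth(self, small_genome):
        genome, segs = small_genome
        assert set(segs) == set(genome.truth.genes)
        for gene_id, seg in segs.items():
            truth = genome.truth.genes[gene_id]
            assert seg.pre_length == truth.pre_length
            assert seg.post_length == truth.post_length


class TestInvariants:
    def test_partition_invariant_all_genes(self, small_genome):
        genome, segs = small_genome
        canonical = {
            t.gene_id: t
            for t in genome.transcripts
            if t.transcript_id.endswith(".t1")
        }
        for gene_id, seg in segs.items():
            assert seg.pre_length + seg.post_length == canonical[gene_id].exonic_length
            assert seg.pre_length > 0 and seg.post_length > 0
            ivs = sorted(seg.pre_intervals + seg.post_intervals)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2  # disjoint

    def test_strand_order_invariant(self, small_genome):
        _, segs = small_genome
        for seg in segs.values():
            pre_max = max(e for _, e in seg.pre_intervals)
            post_min = min(s for s, _ in seg.post_intervals)
            if seg.strand == "+":
                assert pre_max <= post_min
            else:
                assert min(s for s, _ in seg.pre_intervals) >= max(
                    e for _, e in seg.post_intervals
                )

    def test_strand_involution(self):
        """Mirroring coordinates and flipping strand mirrors the segmentation."""
        exons = ((100, 400), (600, 900))
        site_pos = 700
        seg = build_segmentation(tx(exons=exons), PolyASite("chr1", site_pos, "+", "s"))
        m = 10_000  # mirror: x -> m - x, interval [s,e) -> [m-e, m-s)
        mirrored_exons = tuple(sorted((m - e, m - s) for s, e in exons))
        # base x maps to m-1-x, so the site base lands at m-1-site_pos; on the
        # mirrored minus strand the cut coordinate is that base + 1
        mseg = build_segmentation(
            tx(strand="-", exons=mirrored_exons),
            PolyASite("chr1", m - site_pos, "-", "s"),
        )
        assert mseg.pre_length == seg.pre_length
        assert mseg.post_length == seg.post_length
        assert tuple(sorted((m - e, m - s) for s, e in seg.pre_intervals)) == mseg.pre_intervals


class TestIO:
    def test_gtf_round_trip(self, small_genome, tmp_path):
        from apadiff.synthetic import write_gtf

        genome, _ = small_genome
        path = tmp_path / "anno.gtf"
        write_gtf(genome, path)
        parsed = {(t.gene_id, t.transcript_id): t for t in read_gtf(path)}
        for t in genome.transcripts:
            p = parsed[(t.gene_id, t.transcript_id)]
            assert p.exons == t.exons
            assert p.strand == t.strand
            assert p.utr3 == t.utr3

    def test_utr_inferred_from_stop_codon(self, tmp_path):
        gtf = tmp_path / "sc.gtf"
        attrs = 'gene_id "g"; transcript_id "t";'
        gtf.write_text(
            "\n".join(
                [
                    f"chr1\tx\texon\t101\t2000\t.\t+\t.\t{attrs}",
                    f"chr1\tx\tCDS\t101\t1600\t.\t+\t0\t{attrs}",
                    f"chr1\tx\tstop_codon\t1601\t1603\t.\t+\t0\t{attrs}",
                ]
            )
            + "\n"
        )
        (t,) = read_gtf(gtf)
        assert t.utr3 == (1603, 2000)

    def test_polya_bed_round_trip(self, small_genome, tmp_path):
        from apadiff.synthetic import write_polya_bed

        genome, _ = small_genome
        path = tmp_path / "sites.bed"
        write_polya_bed(genome, path)
        parsed = read_polya_bed(path)
        assert parsed == genome.sites

    def test_segmentation_bed_deterministic_and_invertible(self, small_genome, tmp_path):
        _, segs = small_genome
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_segmentation_bed(segs, p1)
        write_segmentation_bed(segs, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_segmentation_bed(p1)
        assert set(back) == set(segs)
        for gene_id, seg in segs.items():
            assert back[gene_id].pre_intervals == seg.pre_intervals
            assert back[gene_id].post_intervals == seg.post_intervals
            assert back[gene_id].strand == seg.strand
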