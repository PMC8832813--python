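import numpy as np
import pytest
from oracles import brute_force_labels

from methlink.regions import (
    EXON150,
    RegionLabel,
    TranscriptModel,
    assign_sites,
    build_partition,
    read_gff3,
    select_longest_isoform,
    split_exon150,
    write_gff3,
    write_partition_bed,
)
from methlink.simulate import SimDesign, make_genome


def _tm(gene, tid, start, end, exons=None, strand="+", chrom="chr1"):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid,
        chrom=chrom,
        strand=strand,
        mrna_start=start,
        mrna_end=end,
        exons=tuple(exons) if exons else ((start, end),),
    )


class TestTranscriptModel:
    def test_tss_strand_aware(self):
        assert _tm("g", "t", 100, 200).tss == 100
        assert _tm("g", "t", 100, 200, strand="-").tss == 200

    def test_rejects_exon_outside_span(self):
        with pytest.raises(ValueError, match="outside mRNA span"):
            _tm("g", "t", 100, 200, exons=[(90, 150)])

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError, match="overlap"):
            _tm("g", "t", 100, 300, exons=[(100, 200), (150, 300)])


class TestSelectLongestIsoform:
    def test_longest_kept(self):
        short = _tm("g1", "t1", 1000, 3000)
        long = _tm("g1", "t2", 1000, 4500)
        assert select_longest_isoform([short, long])["g1"] is long

    def test_single_isoform_identity(self):
        only = _tm("g1", "t1", 1000, 3000)
        assert select_longest_isoform([only])["g1"] is only

    def test_equal_length_tie_break_on_transcript_id(self):
        a = _tm("g1", "tB", 1000, 3000)
        b = _tm("g1", "tA", 2000, 4000)
        assert select_longest_isoform([a, b])["g1"] is b
        assert select_longest_isoform([b, a])["g1"] is b


class TestBuildPartition:
    """Hand-computed worked example from the printed tier bounds."""

    @pytest.fixture
    def part(self, plus_gene):
        return build_partition({"gA": plus_gene}, {"chr1": 50_000})

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (9_900, RegionLabel.P250),
            (9_000, RegionLabel.P5K),  # 1001 bp upstream
            (10_050, RegionLabel.EXON),
            (11_000, RegionLabel.INTRON),
            (4_500, RegionLabel.FLANK),
            (25_000, RegionLabel.IGR),
            (9_751, RegionLabel.P250),  # 250 bp upstream, innermost tier edge
            (9_001, RegionLabel.P1K),  # 1000 bp upstream
        ],
    )
    def test_worked_positions(self, part, pos, expected):
        assert part.label_at("chr1", pos) is expected

    def test_exon_precedence_over_promoter(self):
        # gene A exon overlapping gene B's P250 window
        a = _tm("gA", "tA", 1_000, 2_000)
        b = _tm("gB", "tB", 2_100, 3_000)  # + strand TSS 2100; P250 1850-2099
        part = build_partition({"gA": a, "gB": b}, {"chr1": 20_000})
        assert part.label_at("chr1", 1_900) is RegionLabel.EXON
        assert part.genes_at("chr1", 1_900) == ("gA",)

    def test_empty_models_whole_genome_igr(self):
        part = build_partition({}, {"chr1": 5_000})
        assert (part.labels["chr1"] == RegionLabel.IGR).all()

    def test_model_outside_bounds_names_gene(self):
        g = _tm("gX", "t", 100, 9_000)
        with pytest.raises(ValueError, match="gX"):
            build_partition({"gX": g}, {"chr1": 5_000})

    def test_promoter_truncated_at_chromosome_edge(self):
        # P5K window would reach below position 1; it is clipped, not an error
        g = _tm("g", "t", 3_000, 4_000)
        part = build_partition({"g": g}, {"chr1": 10_000})
        assert part.label_at("chr1", 1) is RegionLabel.P5K
        assert part.label_at("chr1", 10_000) is RegionLabel.FLANK


class TestAssignSites:
    def test_site_at_tss_is_exon_distance_zero(self, plus_gene):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        (ann,) = assign_sites([("chr1", 10_001)], part)
        assert ann.label is RegionLabel.EXON
        assert ann.distance_to_tss == 0
        assert ann.gene_ids == ("gA",)

    def test_p250_boundary(self, plus_gene):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        a250, a251 = assign_sites([("chr1", 9_751), ("chr1", 9_750)], part)
        assert a250.label is RegionLabel.P250 and a250.distance_to_tss == -250
        assert a251.label is RegionLabel.P1K and a251.distance_to_tss == -251

    def test_minus_strand_upstream_mirror(self):
        g = _tm("g", "t", 15_000, 20_000, strand="-")  # TSS = 20000
        part = build_partition({"g": g}, {"chr1": 40_000})
        (ann,) = assign_sites([("chr1", 20_100)], part)
        assert ann.label is RegionLabel.P250
        assert ann.distance_to_tss == -100

    def test_igr_site_has_no_genes(self, plus_gene):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        (ann,) = assign_sites([("chr1", 45_000)], part)
        assert ann.label is RegionLabel.IGR
        assert ann.gene_ids == ()
        assert ann.distance_to_tss is None

    def test_unknown_chromosome_listed(self, plus_gene):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        with pytest.raises(ValueError, match="chrX:5"):
            assign_sites([("chrX", 5)], part)


class TestSplitExon150:
    def _ann(self, plus_gene, pos):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        return split_exon150(assign_sites([("chr1", pos)], part))[0]

    def test_distance_49_gains_sublabel(self, plus_gene):
        ann = self._ann(plus_gene, 10_050)
        assert ann.label is RegionLabel.EXON and ann.sublabel == EXON150
        assert ann.region_name == "Exon150"

    def test_distance_150_stays_plain_exon(self, plus_gene):
        ann = self._ann(plus_gene, 10_151)
        assert ann.distance_to_tss == 150
        assert ann.sublabel is None and ann.region_name == "Exon"

    def test_non_exon_unchanged(self, plus_gene):
        ann = self._ann(plus_gene, 11_600 - 550)  # intron position
        assert ann.label is RegionLabel.INTRON and ann.sublabel is None


class TestPartitionProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_per_base_oracle_agreement(self, seed):
        design = SimDesign(
            n_chroms=1, chrom_length=60_000, n_genes=4, seed=seed
        )
        genome, models = make_genome(design)
        sizes = {c: len(s) for c, s in genome.items()}
        part = build_partition(models, sizes)
        for chrom, n in sizes.items():
            expected = brute_force_labels(models, chrom, n)
            got = np.array(
                [RegionLabel(int(v)).name for v in part.labels[chrom]],
                dtype=object,
            )
            assert (got == expected).all()

    def test_exhaustive_and_exclusive(self, toy_partition):
        for arr in toy_partition.labels.values():
            assert arr.min() >= 1 and arr.max() <= 7  # every base labeled once

    def test_gene_backrefs_match_labels(self, toy_partition):
        rng = np.random.default_rng(0)
        for chrom, size in toy_partition.chrom_sizes.items():
            for pos in rng.integers(1, size + 1, size=50):
                genes = toy_partition.genes_at(chrom, int(pos))
                is_igr = toy_partition.label_at(chrom, int(pos)) is RegionLabel.IGR
                assert (len(genes) == 0) == is_igr

    def test_strand_symmetry(self):
        """Mirroring the genome and flipping strands mirrors the labels."""
        g = _tm("g", "t", 15_000, 22_000, strand="+",
                exons=[(15_000, 16_000), (18_000, 22_000)])
        size = 40_000
        mirrored = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="-",
            mrna_start=size + 1 - 22_000, mrna_end=size + 1 - 15_000,
            exons=((size + 1 - 22_000, size + 1 - 18_000),
                   (size + 1 - 16_000, size + 1 - 15_000)),
        )
        p1 = build_partition({"g": g}, {"chr1": size})
        p2 = build_partition({"g": mirrored}, {"chr1": size})
        assert (p1.labels["chr1"] == p2.labels["chr1"][::-1]).all()

    def test_tier_additivity_per_gene(self, toy_partition):
        promoter = {RegionLabel.P250, RegionLabel.P1K, RegionLabel.P5K}
        counts: dict[str, int] = {}
        for chrom, arr in toy_partition.labels.items():
            for pos in np.nonzero(np.isin(arr, [3, 4, 5]))[0] + 1:
                lab = toy_partition.label_at(chrom, int(pos))
                if lab in promoter:
                    for gid in toy_partition.genes_at(chrom, int(pos)):
                        counts[gid] = counts.get(gid, 0) + 1
        assert counts, "expected some promoter bases"
        assert all(v <= 5_000 for v in counts.values())


class TestRoundtrips:
    def test_gff3_roundtrip(self, toy_models, tmp_path):
        path = tmp_path / "models.gff3"
        write_gff3(toy_models, path)
        back = read_gff3(path)
        assert set(back) == set(toy_models)
        for gid, m in toy_models.items():
            b = back[gid]
            assert (b.chrom, b.strand, b.mrna_start, b.mrna_end, b.exons) == (
                m.chrom, m.strand, m.mrna_start, m.mrna_end, m.exons
            )

    def test_longest_isoform_applied_on_read(self, tmp_path):
        path = tmp_path / "iso.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("chr1\t.\tgene\t100\t5000\t.\t+\t.\tID=g1\n")
            fh.write("chr1\t.\tmRNA\t100\t2099\t.\t+\t.\tID=t1;Parent=g1\n")
            fh.write("chr1\t.\texon\t100\t2099\t.\t+\t.\tID=e1;Parent=t1\n")
            fh.write("chr1\t.\tmRNA\t100\t3599\t.\t+\t.\tID=t2;Parent=g1\n")
            fh.write("chr1\t.\texon\t100\t3599\t.\t+\t.\tID=e2;Parent=t2\n")
        models = read_gff3(path)
        assert models["g1"].transcript_id == "t2"
        assert models["g1"].length == 3_500

    def test_bed_export_covers_genome(self, tmp_path, plus_gene):
        part = build_partition({"gA": plus_gene}, {"chr1": 50_000})
        bed = tmp_path / "part.bed"
        write_partition_bed(part, bed)
        total = 0
        prev_end = 0
        for line in open(bed):
            chrom, start, end, name = line.split("\t")
            assert int(start) == prev_end  # contiguous, no overlap
            prev_end = int(end)
            total += int(end) - int(start)
        assert total == 50_000
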