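"""Hairpin anatomy: parsing, subregions, enumeration, naming, placement."""

import numpy as np
import pytest

from mirlog.anatomy import (
    AllelicSNV,
    MatureArm,
    MirnaHairpin,
    Subregion,
    assign_subregions,
    cluster_flag,
    enumerate_allelic_snvs,
    flanking_regions,
    hgvs_name,
    locate_variant,
    parse_hairpins,
    parse_hgvs,
)
from mirlog.simulate import SimConfig, gen_hairpins, write_fasta, write_gff3


def _hairpin(seq, strand="+", chrom="chr1", start=1000, matures=()):
    return MirnaHairpin(
        id="syn-mir-t",
        chrom=chrom,
        strand=strand,
        start=start,
        end=start + len(seq) - 1,
        sequence=seq,
        matures=list(matures),
    )


def _write_pair(tmp_path, hairpins):
    gff3, fa = tmp_path / "h.gff3", tmp_path / "h.fa"
    write_gff3(hairpins, gff3)
    write_fasta(hairpins, fa)
    return gff3, fa


class TestParsing:
    def test_plus_strand_mature_offset(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGU"), size=80))
        h = MirnaHairpin("syn-mir-t", "chr1", "+", 1000, 1079, seq,
                         [MatureArm("syn-miR-t-5p", 10, 22)])
        gff3, fa = _write_pair(tmp_path, [h])
        (parsed,) = parse_hairpins(gff3, fa)
        # mature written at chr1:1009-1030 maps back to offset 10, length 22
        assert parsed.matures[0].offset == 10
        assert parsed.matures[0].length == 22

    def test_minus_strand_mature_offset(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGU"), size=80))
        h = MirnaHairpin("syn-mir-t", "chr1", "-", 1000, 1079, seq,
                         [MatureArm("syn-miR-t-3p", 9, 22)])
        gff3, fa = _write_pair(tmp_path, [h])
        # on the minus strand offset 9 corresponds to genomic 1050-1071
        text = gff3.read_text()
        assert "\t1050\t1071\t" in text
        (parsed,) = parse_hairpins(gff3, fa)
        assert parsed.matures[0].offset == 9
        assert parsed.sequence == seq

    def test_generated_files_round_trip(self, tmp_path):
        hairpins = gen_hairpins(SimConfig(seed=5, n_hairpins=12))
        gff3, fa = _write_pair(tmp_path, hairpins)
        parsed = {h.id: h for h in parse_hairpins(gff3, fa)}
        assert len(parsed) == 12
        for h in hairpins:
            p = parsed[h.id]
            assert (p.sequence, p.strand, p.start, p.end) == (h.sequence, h.strand, h.start, h.end)
            assert p.matures == h.matures

    def test_length_mismatch_is_hard_error(self, tmp_path, rng):
        h = _hairpin("".join(rng.choice(list("ACGU"), size=60)))
        gff3, fa = _write_pair(tmp_path, [h])
        fa.write_text(">syn-mir-t\nACGU\n")
        with pytest.raises(ValueError, match="syn-mir-t"):
            parse_hairpins(gff3, fa)

    def test_orphan_mature_rejected_with_warning(self, tmp_path, rng):
        h = _hairpin(
            "".join(rng.choice(list("ACGU"), size=60)),
            matures=[MatureArm("syn-miR-t-5p", 5, 20)],
        )
        gff3, fa = _write_pair(tmp_path, [h])
        with open(gff3, "a") as fh:
            fh.write("chr9\t.\tmiRNA\t50\t71\t.\t+\t.\tID=x;Name=syn-miR-orphan\n")
        with pytest.warns(UserWarning, match="orphan"):
            (parsed,) = parse_hairpins(gff3, fa)
        assert len(parsed.matures) == 1


class TestSubregions:
    def test_two_mature_partition_matches_definitions(self, two_mature_hairpin):
        labels = assign_subregions(two_mature_hairpin)
        seed = {i for i, l in labels.items() if l is Subregion.SEED}
        loop = {i for i, l in labels.items() if l is Subregion.LOOP}
        out = {i for i, l in labels.items() if l is Subregion.OUT_OF_LOOP}
        assert seed == set(range(10, 18)) | set(range(40, 48))
        assert loop == set(range(32, 40))
        assert out == set(range(1, 10)) | set(range(62, 71))

    def test_single_mature_partition(self, single_mature_hairpin):
        labels = assign_subregions(single_mature_hairpin)
        assert all(labels[i] is Subregion.SEED for i in range(5, 13))
        assert all(labels[i] is Subregion.REST_OF_MATURE for i in range(13, 27))
        rest = [i for i, l in labels.items() if l is Subregion.REST_OF_PREMIRNA]
        assert set(rest) == set(range(1, 5)) | set(range(27, 81))
        assert Subregion.LOOP not in labels.values()

    def test_labels_partition_every_position(self):
        for h in gen_hairpins(SimConfig(seed=7, n_hairpins=25)):
            labels = assign_subregions(h)
            assert set(labels) == set(range(1, len(h) + 1))
            by_region = {}
            for lab in labels.values():
                by_region[lab] = by_region.get(lab, 0) + 1
            assert sum(by_region.values()) == len(h)

    def test_short_mature_has_no_seed(self):
        with pytest.warns(UserWarning):
            h = _hairpin("ACGU" * 15, matures=[MatureArm("m", 5, 6)])
        with pytest.raises(ValueError, match="seed"):
            assign_subregions(h)


class TestEnumeration:
    def test_three_snvs_per_position(self):
        h = _hairpin("ACGUG" + "ACGU" * 9)  # 41 nt
        snvs = enumerate_allelic_snvs(h)
        assert len(snvs) == 3 * 41
        keys = {(v.chrom, v.pos, v.alt) for v in snvs}
        assert len(keys) == len(snvs)
        assert all(v.alt != v.ref for v in snvs)

    def test_ambiguous_base_skipped(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=50))
        h = _hairpin(seq[:20] + "N" + seq[21:])
        with pytest.warns(UserWarning, match="ambiguous"):
            snvs = enumerate_allelic_snvs(h)
        assert len(snvs) == 3 * 49

    def test_minus_strand_ref_is_plus_strand_base(self):
        h = _hairpin("ACGU" * 11, strand="-")
        snvs = enumerate_allelic_snvs(h)
        first = [v for v in snvs if v.hairpin_offset == 1]
        # hairpin 5' base A sits at the genomic end; + strand base is T
        assert all(v.pos == h.end for v in first)
        assert all(v.ref == "T" for v in first)


class TestHgvs:
    def test_plus_strand_name(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=44))
        seq = seq[:33] + "A" + seq[34:]
        h = _hairpin(seq)
        snvs = [v for v in enumerate_allelic_snvs(h) if v.hairpin_offset == 34 and v.alt == "G"]
        assert snvs[0].hgvs == "syn-mir-t:n.34A>G"

    def test_minus_strand_name_uses_hairpin_sense(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=44))
        seq = seq[:11] + "G" + seq[12:]  # offset 12 is G, genomic + base C
        h = _hairpin(seq, strand="-")
        snvs = [v for v in enumerate_allelic_snvs(h) if v.hairpin_offset == 12 and v.alt == "T"]
        # genomic C>T reads G>A in hairpin sense
        assert snvs[0].ref == "C"
        assert snvs[0].hgvs == "syn-mir-t:n.12G>A"

    def test_round_trip_recovers_offset_and_alleles(self):
        for h in gen_hairpins(SimConfig(seed=9, n_hairpins=6)):
            for v in enumerate_allelic_snvs(h):
                hid, offset, ref_rna, alt_rna = parse_hgvs(v.hgvs)
                assert (hid, offset) == (h.id, v.hairpin_offset)
                assert ref_rna == h.sequence[offset - 1]


class TestPlacement:
    def test_locate_inside_single_hairpin(self, two_mature_hairpin):
        h = two_mature_hairpin
        pos = h.genomic_position(12)  # inside the 5p seed
        ref = h.plus_strand_base(12)
        alt = next(b for b in "ACGT" if b != ref)
        (hit,) = locate_variant(h.chrom, pos, ref, alt, [h])
        assert hit.region is Subregion.SEED
        assert hit.ref_matches

    def test_locate_outside_and_overlap_and_mismatch(self, two_mature_hairpin, rng):
        h = two_mature_hairpin
        other = _hairpin("".join(rng.choice(list("ACGU"), size=60)), start=1010)
        assert locate_variant("chr1", 999, "A", "C", [h]) == []
        hits = locate_variant(h.chrom, 1020, "A", "C", [h, other])
        assert len(hits) == 2
        wrong_ref = next(b for b in "ACGT" if b != h.plus_strand_base(1))
        alt = next(b for b in "ACGT" if b not in (wrong_ref,))
        (hit,) = locate_variant(h.chrom, 1000, wrong_ref, alt, [h])
        assert not hit.ref_matches
        with pytest.raises(ValueError, match="malformed"):
            locate_variant("chr1", 1000, "AT", "C", [h])

    def test_cluster_flag_window(self, rng):
        def mk(start):
            return _hairpin("".join(rng.choice(list("ACGU"), size=50)), start=start)

        a, b = mk(1000), mk(1199)  # gap = 149 nt
        assert cluster_flag(a, [a, b]) and cluster_flag(b, [a, b])
        c, d = mk(1000), mk(1299)  # gap = 249 nt
        assert not cluster_flag(c, [c, d])
        e, f = mk(1000), mk(1020)  # overlapping
        assert cluster_flag(e, [e, f])

    def test_flanking_regions_layout(self, rng):
        h = _hairpin("".join(rng.choice(list("ACGU"), size=81)), start=1000)  # span 1000-1080
        regions = {label: (s, e) for _, s, e, label in flanking_regions(h)}
        assert regions["upstream_1"] == (900, 999)
        assert regions["upstream_3"] == (700, 799)
        assert regions["downstream_1"] == (1081, 1180)
        assert regions["downstream_3"] == (1281, 1380)
        assert sum(e - s + 1 for s, e in regions.values()) == 600

    def test_flanking_regions_truncated_at_chromosome_start(self, rng):
        h = _hairpin("".join(rng.choice(list("ACGU"), size=50)), start=150)
        with pytest.warns(UserWarning):
            regions = flanking_regions(h)
        labels = [r[3] for r in regions]
        assert "upstream_3" not in labels  # fully off-chromosome, dropped
        up2 = next(r for r in regions if r[3] == "upstream_2")
        assert up2[1] == 1  # truncated
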