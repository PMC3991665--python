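"""Annotation: genome mapping, perfect-match miRNA id, category resolution."""

from itertools import combinations

import pytest

from mirseed._seq import revcomp
from mirseed.annotation import (
    PRIORITY_ORDER,
    CleanTag,
    GenomeHit,
    GenomeIndex,
    classify_other,
    identify_sirna_candidates,
    map_to_genome,
    match_known_mirnas,
    resolve_priority,
)

TAG = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


class TestGenomeMapping:
    def test_planted_matures_hit_their_truth_intervals(self, sim, tags, annotated):
        _, hits, _ = annotated
        mirnas = sim.truth[sim.truth.locus_class == "miRNA"]
        for row in mirnas.itertuples():
            tag_hits = hits.get(row.tag_seq, [])
            assert any(
                h.start == row.tag_start and h.end == row.tag_end and h.strand == row.strand
                for h in tag_hits
            ), f"{row.locus_id} not recovered at its planted interval"

    def test_absent_sequence_has_no_hits(self, sim):
        index = GenomeIndex(sim.genome)
        scrambled = "TATATATATGCGCGCGCGCAT"
        assert scrambled not in sim.genome["chr1"]
        assert index.find(scrambled) == []

    def test_minus_strand_hit_matches_reverse_complement(self):
        genome = {"c": "CCCCCCCCCC" + revcomp(TAG) + "GGGGGGGGGG"}
        hits, _ = map_to_genome([CleanTag(TAG, 1, 0)], genome)
        (hit,) = hits[TAG]
        assert hit.strand == "-"
        # oracle: the hit substring reverse-complemented equals the tag
        assert revcomp(genome["c"][hit.start : hit.end]) == TAG

    def test_high_copy_tags_flagged(self):
        genome = {"c": ("TTTTT" + TAG) * 21 + "G" * 30}
        hits, high_copy = map_to_genome([CleanTag(TAG, 1, 0)], genome, max_copies=20)
        assert TAG in high_copy
        assert len(hits[TAG]) == 21

    def test_empty_genome_is_configuration_error(self):
        with pytest.raises(ValueError):
            GenomeIndex({"c": ""})


class TestKnownMirnas:
    REF = {"fam-1": TAG}

    def test_perfect_match_assigned(self):
        assert match_known_mirnas([CleanTag(TAG, 1, 0)], self.REF) == {TAG: "fam-1"}

    def test_single_mismatch_not_assigned(self):
        near = "A" + TAG[1:]
        assert match_known_mirnas([CleanTag(near, 1, 0)], self.REF) == {}

    def test_u_t_encoding_is_normalized(self):
        ref_rna = {"fam-1": TAG.replace("T", "U")}
        assert match_known_mirnas([CleanTag(TAG, 1, 0)], ref_rna) == {TAG: "fam-1"}

    def test_precursor_substring_matches(self):
        pre = {"pre-1": "GGGG" + TAG + "CCCC"}
        assert match_known_mirnas([CleanTag(TAG, 1, 0)], {}, pre) == {TAG: "pre-1"}

    def test_duplicate_reference_ids_rejected(self):
        with pytest.raises(ValueError):
            match_known_mirnas([CleanTag(TAG, 1, 0)], {"a": TAG}, {"a": TAG})


class TestClassification:
    def test_planted_ncrna_and_gene_loci_recovered(self, sim, tags, annotated):
        records, _, _ = annotated
        by_tag = {r.tag_id: r.category for r in records}
        for row in sim.truth.itertuples():
            if row.tag_seq not in by_tag:
                continue  # locus drew no clean reads
            cat = by_tag[row.tag_seq]
            expected = {
                "rRNA": "rRNA_etc_genbank",
                "tRNA": "rRNA_etc_genbank",
                "snoRNA": "rRNA_etc_rfam",
                "snRNA": "rRNA_etc_rfam",
                "exon": "exon",
                "intron": "intron",
                "decoy": "unannotated",
            }.get(row.locus_class)
            if expected is None:  # miRNA: known subset vs novel search space
                expected = "known_miRNA" if row.known else "unannotated"
            assert cat == expected, f"{row.locus_id}: {cat} != {expected}"

    def test_exon_overlap_requires_same_strand(self):
        from mirseed.annotation import GeneFeature

        genome = {"c": "A" * 10 + TAG + "A" * 10}
        tag = CleanTag(TAG, 1, 0)
        hits, _ = map_to_genome([tag], genome)
        same = classify_other([tag], hits, gene_features=[GeneFeature("c", 0, 40, "+", "exon")])
        other = classify_other([tag], hits, gene_features=[GeneFeature("c", 0, 40, "-", "exon")])
        assert same[TAG] == {"exon"}
        assert other[TAG] == set()

    def test_feature_outside_genome_rejected(self):
        from mirseed.annotation import GeneFeature

        with pytest.raises(ValueError):
            classify_other(
                [], {}, gene_features=[GeneFeature("c", 0, 99, "+", "exon")],
                genome_lengths={"c": 50},
            )


class TestSirnaCandidates:
    def make_pair(self, offset):
        """A 22-nt duplex on a toy locus with the minus tag shifted by ``offset``."""
        genome = "G" * 30 + "ACGGTTGACATCGATCAAGCTT" + "G" * 30
        plus = genome[30:52]
        minus = revcomp(genome[30 - offset : 52 - offset])
        return genome, plus, minus

    def brute_force_pairs(self, tags, hits):
        """Oracle: test every tag pair against the literal structural rule."""
        flat = [h for hs in hits.values() for h in hs]
        found = []
        for a, b in combinations(flat, 2):
            for p, m in ((a, b), (b, a)):
                if (
                    p.strand == "+" and m.strand == "-" and p.chrom == m.chrom
                    and 22 <= p.end - p.start <= 24 and 22 <= m.end - m.start <= 24
                    and p.start == m.start + 2 and p.end == m.end + 2
                ):
                    found.append((p, m))
        return found

    @pytest.mark.parametrize("offset, expected", [(2, 1), (3, 0), (0, 0)])
    def test_two_nt_overhang_geometry(self, offset, expected):
        genome, plus, minus = self.make_pair(offset)
        tags = [CleanTag(plus, 1, 0), CleanTag(minus, 1, 0)]
        hits, _ = map_to_genome(tags, {"c": genome})
        pairs = identify_sirna_candidates(tags, hits)
        assert len(pairs) == expected
        assert len(self.brute_force_pairs(tags, hits)) == expected

    def test_21mers_never_pair(self):
        genome, plus, minus = self.make_pair(2)
        tags = [CleanTag(plus[:21], 1, 0), CleanTag(revcomp(revcomp(minus)[:21]), 1, 0)]
        hits, _ = map_to_genome(tags, {"c": genome})
        assert identify_sirna_candidates(tags, hits) == []


class TestPriorityResolution:
    def test_exhaustive_subsets_resolve_to_highest_priority(self):
        # all 2^6 subsets of the category chain
        for r in range(len(PRIORITY_ORDER) + 1):
            for subset in combinations(PRIORITY_ORDER, r):
                (rec,) = resolve_priority({"t": set(subset)})
                expected = (
                    next(c for c in PRIORITY_ORDER if c in subset)
                    if subset
                    else "unannotated"
                )
                assert rec.category == expected

    def test_resolution_is_permutation_invariant(self):
        cats = {"exon", "intron", "known_miRNA"}
        (a,) = resolve_priority({"t": set(list(cats))})
        (b,) = resolve_priority({"t": set(reversed(list(cats)))})
        assert a.category == b.category == "known_miRNA"

    def test_category_partition_covers_all_tags(self, tags, annotated):
        records, _, _ = annotated
        assert len(records) == len(tags)
        assert all(r.category for r in records)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            resolve_priority({"t": {"mystery"}})
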