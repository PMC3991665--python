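"""Hairpin folding, duplex metrics, MFEI and the candidate criteria."""

import dataclasses

import pytest

from mirseed._seq import revcomp, to_rna
from mirseed.annotation import GenomeHit
from mirseed.hairpin import (
    DuplexMetrics,
    FoldResult,
    HairpinCandidate,
    NovelMirnaParams,
    apply_criteria,
    compute_mfei,
    evaluate_window,
    excise_windows,
    fold,
    measure_duplex,
    pair_table,
    predict_novel,
)

STEM = "GCGACUGCAUCCGGAACUGUGAUGCGCACG"  # 30 nt, folds back on its complement


class TestFold:
    def test_designed_perfect_stem_folds_into_hairpin(self):
        seq = STEM + "GAAACA" + revcomp(STEM.replace("U", "T"))
        result = fold(seq)
        assert result.mfe < -18.0
        assert result.structure.count("(") >= 25
        # hairpin shape: all openings before all closings
        assert result.structure.rfind("(") < result.structure.index(")")

    def test_homopolymer_has_no_stable_structure(self):
        result = fold("A" * 60)
        assert result.mfe >= -1.0

    def test_fold_is_deterministic(self):
        seq = STEM + "GAAACA" + revcomp(STEM.replace("U", "T"))
        assert fold(seq) == fold(seq)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fold("ACGU" * 5)  # < 40 nt
        with pytest.raises(ValueError):
            fold("ACGX" * 15)


class TestPairTable:
    def test_balanced_parse(self):
        pt = pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            pair_table("((.)")


def engineered_fold(mature, star, loop="GAAACA", mature_first=True):
    """A synthetic FoldResult built from an engineered dot-bracket, used as a
    structure-parsing oracle independent of the folding engine."""
    arms = (mature, star) if mature_first else (star, mature)
    seq = to_rna(arms[0] + loop + arms[1])
    pairs = min(len(mature), len(star))
    struct = (
        "(" * len(arms[0]) + "." * len(loop) + ")" * len(arms[1])
    )
    return FoldResult(seq, struct, -40.0)


class TestMeasureDuplex:
    MATURE = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt

    def test_perfect_stem_has_clean_duplex(self):
        fr = engineered_fold(self.MATURE, revcomp(self.MATURE))
        metrics, star = measure_duplex(fr, 0, 21)
        assert metrics == DuplexMetrics(
            n_base_pairs=21, n_mismatches=0, max_bulge=0, asymmetry=0,
            spacing=6, star_contains_loop=False,
        )
        assert star == revcomp(self.MATURE)

    def test_engineered_bulge_is_measured(self):
        # 5 unpaired mature bases in the middle of the stem
        m = self.MATURE
        struct = "(" * 8 + "." * 5 + "(" * 8 + "." * 6 + ")" * 16
        seq = to_rna(m + "GAAACA" + revcomp(m[:8] + m[13:]))
        fr = FoldResult(seq, struct, -30.0)
        metrics, _ = measure_duplex(fr, 0, 21)
        assert metrics.max_bulge == 5
        assert metrics.n_mismatches == 5
        assert metrics.asymmetry == 5

    def test_mature_across_terminal_loop_is_flagged(self):
        fr = engineered_fold(self.MATURE, revcomp(self.MATURE))
        # a 'mature' window straddling the loop: positions 15..36
        metrics, star = measure_duplex(fr, 15, 21)
        assert metrics.star_contains_loop
        assert star == ""

    def test_unpaired_mature_yields_zero_pairs(self):
        fr = FoldResult("A" * 60, "." * 60, 0.0)
        metrics, star = measure_duplex(fr, 10, 21)
        assert metrics.n_base_pairs == 0 and star == ""


class TestMfei:
    def test_arithmetic_definition(self):
        # (|-50| / 100 * 100) / 50% = 1.0
        seq = "GC" * 25 + "AT" * 25  # 100 nt, GC 50%
        assert compute_mfei(seq, -50.0) == pytest.approx(1.0)

    def test_zero_mfe_gives_zero(self):
        assert compute_mfei("GCAT" * 25, 0.0) == 0.0

    def test_linear_in_mfe(self):
        seq = "GCAT" * 25
        assert compute_mfei(seq, -60.0) == pytest.approx(2 * compute_mfei(seq, -30.0))

    def test_undefined_without_gc(self):
        with pytest.raises(ValueError):
            compute_mfei("AT" * 50, -10.0)


def make_candidate(**overrides):
    mature = "TGGAGCTCCCTTCATTCCAAT"
    fr = engineered_fold(mature, revcomp(mature))
    metrics, star = measure_duplex(fr, 0, 21)
    fields = dict(
        chrom="c", start=0, end=len(fr.sequence), strand="+",
        precursor=fr.sequence.replace("U", "T"), mature=mature, mature_offset=0,
        star=star, fold=fr, duplex=metrics, mfei=1.0, au_content=0.5,
    )
    fields.update(overrides)
    return HairpinCandidate(**fields)


class TestCriteria:
    def test_compliant_candidate_accepted_with_all_flags(self):
        cand = apply_criteria(make_candidate())
        assert cand.accepted
        assert all(cand.criteria.values())

    @pytest.mark.parametrize(
        "overrides, failing_flag",
        [
            ({"fold": dataclasses.replace(make_candidate().fold, mfe=-17.5)}, "mfe"),
            ({"au_content": 0.75}, "au_content"),
            ({"au_content": 0.25}, "au_content"),
            ({"mfei": 0.5}, "mfei"),
            ({"duplex": dataclasses.replace(make_candidate().duplex, n_mismatches=6)}, "mismatches"),
            ({"duplex": dataclasses.replace(make_candidate().duplex, n_base_pairs=15)}, "min_pairs"),
            ({"duplex": dataclasses.replace(make_candidate().duplex, max_bulge=5)}, "max_bulge"),
            ({"duplex": dataclasses.replace(make_candidate().duplex, asymmetry=5)}, "asymmetry"),
            ({"duplex": dataclasses.replace(make_candidate().duplex, spacing=301)}, "spacing"),
            ({"star": "ACGTACGTACGTACGTACGTACGT"}, "star_length"),
        ],
    )
    def test_each_threshold_rejects(self, overrides, failing_flag):
        cand = apply_criteria(make_candidate(**overrides))
        assert not cand.accepted
        assert cand.criteria[failing_flag] is False

    def test_homology_filter_only_shrinks(self):
        base = make_candidate()
        no_filter = apply_criteria(base)
        on_near = apply_criteria(
            base, NovelMirnaParams(homology_ref=(base.mature[:-1] + "A",))
        )
        on_far = apply_criteria(
            base, NovelMirnaParams(homology_ref=("TTTTTTTTTTTTTTTTTTTTT",))
        )
        assert no_filter.accepted and on_near.accepted
        assert not on_far.accepted  # filter can only remove candidates


class TestExciseWindows:
    HIT = GenomeHit("t", "c", 5000, 5021, "+")

    def test_window_length_bounded_by_space_and_flank(self):
        genome = "ACGT" * 3000
        params = NovelMirnaParams()
        for seq, ws, we, off, trunc in excise_windows(genome, self.HIT, params):
            assert len(seq) <= 21 + params.max_space + 2 * params.flank
            assert not trunc
            assert seq[off : off + 21] == genome[5000:5021]

    def test_edge_truncation_flagged(self):
        genome = "ACGT" * 3000
        hit = GenomeHit("t", "c", 5, 26, "+")
        assert any(trunc for _, _, _, _, trunc in excise_windows(genome, hit))

    def test_minus_strand_window_carries_mature_forward(self):
        genome = "ACGTT" * 2400
        hit = GenomeHit("t", "c", 5000, 5021, "-")
        for seq, ws, we, off, _ in excise_windows(genome, hit):
            assert seq[off : off + 21] == revcomp(genome[5000:5021])


class TestPrediction:
    def _search_space(self, sim, tags, annotated):
        records, hits, high_copy = annotated
        unannot = {
            r.tag_id: hits[r.tag_id]
            for r in records
            if r.category == "unannotated" and r.tag_id in hits and r.tag_id not in high_copy
        }
        counts = {t.sequence: (t.count_control, t.count_treatment) for t in tags}
        return unannot, counts

    def test_round_trip_every_planted_hairpin_passes_at_its_window(self, sim):
        params = NovelMirnaParams()
        genome = sim.genome["chr1"]
        mirnas = sim.truth[sim.truth.locus_class == "miRNA"]
        for row in mirnas.itertuples():
            w_lo = max(0, int(row.start) - params.flank)
            w_hi = min(len(genome), int(row.end) + params.flank)
            window = genome[w_lo:w_hi]
            if row.strand == "-":
                window = revcomp(window)
                offset = w_hi - int(row.tag_end)
            else:
                offset = int(row.tag_start) - w_lo
            cand = evaluate_window(window, offset, len(row.tag_seq), params)
            assert cand is not None and cand.accepted, (
                f"{row.locus_id} fails: "
                f"{sorted(k for k, v in (cand.criteria if cand else {}).items() if not v)}"
            )

    def test_planted_novel_mirnas_recovered_and_no_decoys(self, sim, tags, annotated):
        unannot, counts = self._search_space(sim, tags, annotated)
        preds = predict_novel(sim.genome, unannot, counts)
        truth = sim.truth[(sim.truth.locus_class == "miRNA") & (~sim.truth.known)]
        planted = set(truth.tag_seq)
        recovered = {p.mature for p in preds} & planted
        assert len(recovered) == len(planted)
        assert all(p.mature in planted for p in preds), "a decoy locus was accepted"

    def test_prediction_is_deterministic(self, sim, tags, annotated):
        unannot, counts = self._search_space(sim, tags, annotated)
        first = predict_novel(sim.genome, unannot, counts)
        second = predict_novel(sim.genome, unannot, counts)
        assert [(p.chrom, p.start, p.end, p.mature) for p in first] == [
            (p.chrom, p.start, p.end, p.mature) for p in second
        ]

    def test_tightening_thresholds_never_adds_predictions(self, sim, tags, annotated):
        unannot, counts = self._search_space(sim, tags, annotated)
        loose = predict_novel(sim.genome, unannot, counts, NovelMirnaParams())
        tight = predict_novel(
            sim.genome, unannot, counts,
            NovelMirnaParams(max_mfe=-30.0, min_pairs=18, min_mfei=1.0),
        )
        assert {p.mature for p in tight} <= {p.mature for p in loose}

    def test_high_copy_tags_are_skipped(self):
        tag = "TGGAGCTCCCTTCATTCCAAT"
        hit = GenomeHit(tag, "c", 100, 121, "+", copy_number=21)
        genome = {"c": "ACGT" * 1000}
        assert predict_novel(genome, {tag: [hit]}) == []
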