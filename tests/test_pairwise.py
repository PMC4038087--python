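import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesoni.errors import HomologyError
from mesoni.genome_io import GenomeRecord
from mesoni.pairwise import (
    AlignParams,
    PairwiseAlignment,
    align_global,
    count_differences,
    detect_insertions,
    find_repeats,
)
from mesoni.synthetic_data import (
    GenomeSpec,
    evolve_sequence,
    excise_insertion,
    make_genome,
    make_isolate_set,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=25)


def enumerate_alignments(a: str, b: str):
    """Independent oracle: every gapless-column-free global alignment."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(ra: str, rb: str, p: AlignParams) -> float:
    score = 0.0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            score += p.match if x == y else p.mismatch
    for row in (ra, rb):
        for run in re.finditer(r"-+", row):
            score -= p.gap_open + p.gap_extend * (run.end() - run.start())
    return score


def brute_force_best(a: str, b: str, p: AlignParams) -> float:
    return max(score_alignment(ra, rb, p) for ra, rb in enumerate_alignments(a, b))


class TestAlignGlobal:
    def test_identical_sequences(self):
        aln = align_global("ACGT", "ACGT")
        assert aln.score == 20.0 and aln.rows == ("ACGT", "ACGT")

    def test_single_gap_column(self):
        aln = align_global("ACGT", "AGT")
        assert sum(c == "-" for c in aln.rows[1]) == 1
        assert aln.rows[0].replace("-", "") == "ACGT"
        assert aln.rows[1].replace("-", "") == "AGT"

    def test_rows_recover_inputs_and_no_gap_gap_columns(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 30)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 30)))
            aln = align_global(a, b)
            ra, rb = aln.rows
            assert ra.replace("-", "") == a and rb.replace("-", "") == b
            assert not any(x == "-" and y == "-" for x, y in zip(ra, rb))

    def test_matches_exhaustive_enumeration_on_tiny_pairs(self):
        p = AlignParams()
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            want = brute_force_best(a, b, p)
            assert align_global(a, b).score == pytest.approx(want)
            assert align_global(a, b, band=7).score == pytest.approx(want)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(DNA, DNA)
    def test_score_symmetric(self, a, b):
        assert align_global(a, b).score == pytest.approx(align_global(b, a).score)

    def test_banded_equals_full_on_divergent_homologs(self):
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), 1500))
        other = evolve_sequence(base, 0.05, "JC-nt", 3)
        other = other[:700] + other[715:]  # 15-nt deletion
        full = align_global(base, other)
        banded = align_global(base, other, band=100)
        assert banded.score == pytest.approx(full.score)
        assert banded.rows == full.rows

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            align_global("ACGT", "AC1T")

    def test_ambiguity_codes_mismatch_everything(self):
        # N never matches, not even another N: 3 matches + 1 mismatch
        aln = align_global("ACGN", "ACGN")
        assert aln.score == pytest.approx(3 * 5 - 4)

    def test_protein_route_uses_substitution_matrix(self):
        aln = align_global("MKVLY", "MKVLY")
        assert aln.rows == ("MKVLY", "MKVLY")
        assert aln.score > 0


class TestCountDifferences:
    def make(self, ra, rb):
        return PairwiseAlignment(rows=(ra, rb), score=0.0, params=AlignParams())

    def test_single_substitution(self):
        d = count_differences(self.make("ACGT", "ACGA"))
        assert (d.substitutions, d.indel_events) == (1, [])
        assert d.aligned_identity == pytest.approx(3 / 4)

    def test_gap_run_is_one_event_not_substitutions(self):
        d = count_differences(self.make("AC--GT", "ACTTGT"))
        assert (d.substitutions, d.indel_events) == (0, [2])

    def test_symmetry(self):
        d1 = count_differences(self.make("AC-GTA", "ACTG-A"))
        d2 = count_differences(self.make("ACTG-A", "AC-GTA"))
        assert d1.substitutions == d2.substitutions
        assert d1.indel_events == d2.indel_events

    def test_planted_substitution_count_recovered(self):
        base, isos, truth, infos = make_isolate_set(
            GenomeSpec(seed=21), n=1, substitutions_per_isolate=[25], seed=21
        )
        aln = align_global(base.seq, isos[0].seq, band=50)
        d = count_differences(aln)
        assert d.substitutions == 25 and d.indel_events == []

    def test_isolate_with_substitutions_and_two_indels(self):
        # emulates the closely-related-isolate comparison: exactly 68
        # substitutions plus 3-nt and 6-nt deletions
        base, isos, truth, infos = make_isolate_set(
            GenomeSpec(seed=8),
            n=1,
            substitutions_per_isolate=[68],
            seed=8,
            indel_lengths=[[3, 6]],
        )
        d = count_differences(align_global(base.seq, isos[0].seq, band=120))
        assert d.substitutions == 68
        assert sorted(d.indel_events) == [3, 6]


class TestDetectInsertions:
    def test_planted_small_block(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 300))
        query = ref[:150] + "GATTACAGA" + ref[150:]
        blocks = detect_insertions(
            GenomeRecord("q", query), GenomeRecord("r", ref), min_block=9
        )
        assert [(b.query_span, b.length_nt) for b in blocks] == [((150, 159), 9)]
        assert blocks[0].length_aa == 3

    def test_identical_sequences_no_blocks(self):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("ACGT"), 400))
        assert detect_insertions(GenomeRecord("q", s), GenomeRecord("r", s)) == []

    def test_identity_floor_enforced(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = evolve_sequence(a, 0.1, "JC-nt", 1)
        with pytest.raises(HomologyError):
            detect_insertions(
                GenomeRecord("q", a), GenomeRecord("r", b), min_identity=0.99
            )

    @pytest.mark.parametrize("length", [30, 180, 573, 588])
    def test_planted_block_lengths_recovered(self, length):
        rec, truth = make_genome(GenomeSpec(seed=3, insertion_len=length))
        sibling = excise_insertion(rec, truth)
        blocks = detect_insertions(
            rec,
            sibling,
            region=(truth.utr5[1], truth.utr5[1] + 2600),
            frame_start=truth.orfs["ORF1a"]["start"],
        )
        assert [b.length_nt for b in blocks] == [length]
        lo, hi = truth.insertion_span
        qs, qe = blocks[0].query_span
        assert abs(qs - lo) <= 3 and abs(qe - hi) <= 3
        assert blocks[0].length_aa == length // 3

    def test_repeats_annotated_in_large_blocks(self):
        rec, truth = make_genome(GenomeSpec(seed=9, insertion_len=588))
        sibling = excise_insertion(rec, truth)
        blocks = detect_insertions(
            rec,
            sibling,
            region=(truth.utr5[1], truth.utr5[1] + 2600),
            frame_start=truth.orfs["ORF1a"]["start"],
        )
        positions = {r.position for r in blocks[0].repeats}
        for pos, mism in truth.repeats:
            assert any(abs(pos - p) <= 3 for p in positions)


class TestFindRepeats:
    def test_exact_repeats(self):
        hits = find_repeats("SKRKGKAAASKRKGK", "SKRKGK", 0)
        assert [h.position for h in hits] == [0, 9]

    def test_one_mismatch(self):
        hits = find_repeats("SKRKGR", "SKRKGK", 1)
        assert [(h.position, h.mismatches) for h in hits] == [(0, 1)]

    def test_brute_force_count_on_shuffled_sequence(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.permutation(list("SKRKGK" * 20)))
        seed = "SKRKGK"
        want = sum(
            1
            for i in range(len(seq) - len(seed) + 1)
            if seq[i : i + len(seed)] == seed
        )
        assert len(find_repeats(seq, seed, 0)) == want

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_repeats("AAAA", "AB", 0)
        with pytest.raises(ValueError):
            find_repeats("AAAA", "ABC", 3)
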