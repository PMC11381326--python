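"""Global alignment, bit-vector calling and profile aggregation."""

import numpy as np
import pytest

from qmapseq.constructs import reverse_complement_dna
from qmapseq.profiling import (
    AMBIGUOUS,
    LOW_QUALITY,
    MATCH,
    MUTATION,
    UNCOVERED,
    AlignmentQCFail,
    aggregate,
    align_pair,
    call_bitvector,
    profile_pairs,
)
from qmapseq.simulate import SimulationSpec, simulate_condition

REF = "ATGGCACTCGCATATGGGCAGCGAAAGCTG"  # 30-nt toy reference


def biopython_score(read: str, ref: str) -> float:
    """Independent optimal-score oracle with the same affine scoring."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6   # first gap base: open -5 + extend -1
    aligner.extend_gap_score = -1
    return aligner.score(ref, read)


class TestAlignPair:
    def test_identical_read_scores_2L(self):
        aln = align_pair(REF, REF)
        assert aln.score == 2 * len(REF)
        assert all(i == j for i, j in aln.columns)

    def test_single_substitution(self):
        read = REF[:10] + ("A" if REF[10] != "A" else "C") + REF[11:]
        aln = align_pair(read, REF)
        assert aln.score == 2 * len(REF) - 3
        mism = [
            (i, j) for i, j in aln.columns
            if i is not None and j is not None and read[j] != REF[i]
        ]
        assert mism == [(10, 10)]

    def test_two_nt_deletion_scores_per_affine_model(self):
        read = REF[:12] + REF[14:]
        aln = align_pair(read, REF)
        assert aln.score == 2 * (len(REF) - 2) - 5 - 2
        gaps = [i for i, j in aln.columns if j is None]
        assert len(gaps) == 2 and gaps[1] == gaps[0] + 1

    def test_insertion_handled(self):
        read = REF[:15] + "A" + REF[15:]
        aln = align_pair(read, REF)
        assert aln.score == 2 * len(REF) - 5 - 1
        assert sum(1 for i, _ in aln.columns if i is None) == 1

    @pytest.mark.parametrize("n_events", [0, 1, 2, 3])
    def test_score_matches_independent_aligner(self, n_events):
        rng = np.random.default_rng(n_events * 7 + 1)
        bases = "ACGT"
        for _ in range(50):
            read = list(REF)
            for _ in range(n_events):
                kind = rng.integers(3)
                pos = int(rng.integers(1, len(read) - 1))
                if kind == 0:
                    read[pos] = bases[rng.integers(4)]
                elif kind == 1 and len(read) > 20:
                    del read[pos]
                else:
                    read.insert(pos, bases[rng.integers(4)])
            read = "".join(read)
            aln = align_pair(read, REF, min_score_frac=0.0)
            assert aln.score == biopython_score(read, REF)

    def test_alignment_columns_are_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            read = list(REF)
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(1, len(read) - 1))
                k = rng.integers(3)
                if k == 0:
                    read[pos] = "ACGT"[rng.integers(4)]
                elif k == 1 and len(read) > 25:
                    del read[pos]
                else:
                    read.insert(pos, "ACGT"[rng.integers(4)])
            read = "".join(read)
            aln = align_pair(read, REF, min_score_frac=0.0)
            ref_idx = [i for i, _ in aln.columns if i is not None]
            read_idx = [j for _, j in aln.columns if j is not None]
            assert ref_idx == list(range(len(REF)))
            assert read_idx == list(range(len(read)))

    def test_score_floor_discards_garbage(self):
        with pytest.raises(AlignmentQCFail):
            align_pair("T" * len(REF.replace("T", "A")), REF.replace("T", "A"))


def _perfect_alignments(read1=None, read2=None):
    r1 = read1 or REF
    r2 = read2 or REF
    return align_pair(r1, REF, 0.0), r1, align_pair(r2, REF, 0.0), r2


class TestCallBitvector:
    def test_error_free_pair_is_all_match(self):
        a1, r1, a2, r2 = _perfect_alignments()
        bv = call_bitvector(a1, r1, a2, r2, REF)
        assert np.all(bv == MATCH)

    def test_substitution_is_mutation(self):
        read = REF[:5] + ("G" if REF[5] != "G" else "T") + REF[6:]
        a1, r1, a2, r2 = _perfect_alignments(read1=read, read2=read)
        bv = call_bitvector(a1, r1, a2, r2, REF)
        assert bv[5] == MUTATION
        assert np.sum(bv == MUTATION) == 1

    def test_mate_disagreement_is_ambiguous(self):
        read1 = REF[:5] + ("G" if REF[5] != "G" else "T") + REF[6:]
        a1, r1, a2, r2 = _perfect_alignments(read1=read1)
        bv = call_bitvector(a1, r1, a2, r2, REF)
        assert bv[5] == AMBIGUOUS

    def test_deletion_neighbourhood_is_ambiguous(self):
        # both mates sequence the same molecule, so both carry the deletion
        read = REF[:12] + REF[13:]  # 1-nt deletion at ref position 12
        a = align_pair(read, REF, 0.0)
        bv = call_bitvector(a, read, a, read, REF)
        # the deleted base is scored as a mutation; its flanks are untrusted
        assert bv[12] == MUTATION
        assert np.all(bv[9:12] == AMBIGUOUS) and np.all(bv[13:16] == AMBIGUOUS)
        assert bv[8] in (MATCH, MUTATION) and bv[16] in (MATCH, MUTATION)

    def test_one_clean_mate_rescues_indel_neighbourhood(self):
        # if only one mate shows an indel, the clean mate's calls stand
        read = REF[:12] + REF[13:]
        a1 = align_pair(read, REF, 0.0)
        a2 = align_pair(REF, REF)
        bv = call_bitvector(a1, read, a2, REF, REF)
        assert np.all(bv[9:12] == MATCH) and np.all(bv[13:16] == MATCH)
        assert bv[12] == AMBIGUOUS  # deletion vs match: mates disagree

    def test_substitution_near_deletion_excluded(self):
        read = list(REF)
        del read[12]
        read[10] = "G" if REF[11] != "G" else "T"  # read idx 10 ~ ref 10
        read = "".join(read)
        a = align_pair(read, REF, 0.0)
        bv = call_bitvector(a, read, a, read, REF)
        assert bv[10] == AMBIGUOUS  # not MUTATION: within radius of the indel

    def test_low_quality_masks_single_mate(self):
        a1, r1, a2, r2 = _perfect_alignments()
        q_bad = "!" * len(REF)  # Phred 0
        bv = call_bitvector(a1, r1, a2, r2, REF, quals1=q_bad, quals2=None)
        assert np.all(bv == MATCH)  # second mate still informative
        bv = call_bitvector(a1, r1, a2, r2, REF, quals1=q_bad, quals2=q_bad)
        assert np.all(bv == LOW_QUALITY)


class TestAggregate:
    def test_no_mutations_gives_zero_fraction(self):
        bvs = [np.zeros(20, dtype=np.uint8) for _ in range(100)]
        prof = aggregate(bvs)
        assert np.all(prof.mut_fraction == 0)
        assert np.all(prof.depth == 100)

    def test_uncovered_position_is_missing_not_zero(self):
        bv = np.zeros(10, dtype=np.uint8)
        bv[7] = UNCOVERED
        prof = aggregate([bv])
        assert np.isnan(prof.mut_fraction[7])
        assert prof.mut_fraction[0] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        bvs = [rng.integers(0, 5, size=15).astype(np.uint8) for _ in range(50)]
        p1 = aggregate(bvs)
        perm = [bvs[i] for i in rng.permutation(50)]
        p2 = aggregate(perm)
        assert np.array_equal(p1.depth, p2.depth)
        assert np.array_equal(p1.mut_count, p2.mut_count)

    def test_hypermutated_reads_excluded(self):
        clean = np.zeros(20, dtype=np.uint8)
        hot = np.full(20, MUTATION, dtype=np.uint8)
        prof = aggregate([clean] * 10 + [hot], max_mutations=2)
        assert prof.n_reads == 10 and prof.n_discarded == 1
        assert np.all(prof.mut_count == 0)

    def test_simulated_rate_recovery(self):
        rng = np.random.default_rng(11)
        rate = 0.05
        n = 1000
        bvs = [
            (rng.random(30) < rate).astype(np.uint8) for _ in range(n)
        ]
        prof = aggregate(bvs, max_mutations=30)
        se = np.sqrt(rate * (1 - rate) / n)
        assert np.all(np.abs(prof.mut_fraction - rate) <= 4 * se)


class TestProfilePairs:
    def test_recovers_simulated_rates_within_binomial_error(self, wt_construct):
        depth = 10_000
        spec = SimulationSpec(
            construct=wt_construct,
            mg_concentrations=[0.22],
            depth=depth,
            seed=17,
        )
        pairs = simulate_condition(spec, 0.22)
        prof = profile_pairs(
            [(p.seq1[12:], p.seq2) for p in pairs],
            wt_construct.dna_amplicon,
            construct="WT",
        )
        rates = spec.position_rates(0.22)
        # either mate's sequencing error produces a mutation or a mate
        # disagreement; disagreements are ambiguous, so the informative-only
        # fraction stays close to rate + joint-error term
        eps = spec.background_error
        expected = rates * (1 - eps) ** 2 + (1 - rates) * eps**2 / 3
        se = np.sqrt(expected * (1 - expected) / depth)
        frac = prof.mut_fraction
        assert prof.n_reads == depth
        assert np.all(np.abs(frac - expected) <= 4 * np.maximum(se, 2e-4))

    def test_json_roundtrip(self, tmp_path, wt_construct):
        from qmapseq.profiling import MutationProfile

        spec = SimulationSpec(
            construct=wt_construct, mg_concentrations=[0.0], depth=50, seed=1
        )
        pairs = simulate_condition(spec, 0.0)
        prof = profile_pairs(
            [(p.seq1[12:], p.seq2) for p in pairs],
            wt_construct.dna_amplicon,
            construct="WT",
            sequence=wt_construct.rna_sequence,
            dot_bracket=wt_construct.dot_bracket,
        )
        path = tmp_path / "p.json"
        prof.save_json(path)
        back = MutationProfile.load_json(path)
        assert np.array_equal(back.depth, prof.depth)
        assert np.array_equal(back.mut_count, prof.mut_count)
        assert back.construct == prof.construct
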