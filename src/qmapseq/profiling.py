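"""Per-nucleotide mutation fractions from demultiplexed read pairs.

Reads are demultiplexed to a single known reference before profiling, so a
global (Needleman-Wunsch) alignment with affine gaps is exact at amplicon
scale and keeps the pipeline free of external aligner binaries.  Each
aligned pair is reduced to a bit vector over reference positions
(match / mutation / ambiguous / low-quality / uncovered), and bit vectors
are aggregated into depth, mutation count and mutation fraction - the
population-average DMS reactivity profile.

Bit-vector rules follow common mutational-profiling practice: substitutions
and deletions count as mutations, positions within a small radius of any
indel are ambiguous (reverse transcriptase behaviour near indels is not
positionally trustworthy), low-quality calls are uninformative, and mates
that overlap but disagree are ambiguous - one molecule, one vote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# bit-vector codes
MATCH = 0
MUTATION = 1
AMBIGUOUS = 2
UNCOVERED = 3
LOW_QUALITY = 4

# alignment scoring (match, mismatch, gap open, gap extend)
MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = -5
GAP_EXTEND = -1

_NEG = -(10**9)


@dataclass
class AlignedPair:
    """Global alignment of one read to the reference.

    ``columns`` is a list of (ref_index | None, read_index | None); exactly
    one side may be None (insertion/deletion).
    """

    columns: list[tuple[int | None, int | None]]
    score: int


class AlignmentQCFail(Exception):
    """Read discarded: best global alignment scores below the floor."""


def _gapless_alignment(read: str, reference: str) -> AlignedPair:
    cols = [(i, i) for i in range(len(read))]
    matches = sum(r == q for r, q in zip(reference, read))
    score = MATCH_SCORE * matches + MISMATCH_SCORE * (len(read) - matches)
    return AlignedPair(columns=cols, score=score)


def align_pair(read: str, reference: str, min_score_frac: float = 0.5) -> AlignedPair:
    """Optimal global alignment of one read against its reference.

    Scores: match +2, mismatch -1, gap open -5, gap extend -1 (an opened gap
    of length g costs 5 + g).  Ties prefer mismatches over gaps, then
    5'-most gap placement.  Raises :class:`AlignmentQCFail` when the optimal
    score falls below ``min_score_frac * 2 * len(reference)``.

    Equal-length reads with few mismatches take a gapless fast path; with
    m <= 4 mismatches no gapped alignment can beat the gapless score under
    these penalties, so the fast path is exact.
    """
    read, reference = read.upper(), reference.upper()
    floor = min_score_frac * MATCH_SCORE * len(reference)
    if len(read) == len(reference):
        gapless = _gapless_alignment(read, reference)
        mismatches = (MATCH_SCORE * len(read) - gapless.score) // (
            MATCH_SCORE - MISMATCH_SCORE
        )
        if mismatches <= 4:
            if gapless.score < floor:
                raise AlignmentQCFail(
                    f"alignment score {gapless.score} below floor {floor:.0f}"
                )
            return gapless
    aln = _needleman_wunsch(read, reference)
    if aln.score < floor:
        raise AlignmentQCFail(f"alignment score {aln.score} below floor {floor:.0f}")
    return aln


def _needleman_wunsch(read: str, reference: str) -> AlignedPair:
    """Affine-gap global DP (Gotoh).  Reference indexes rows' columns; read rows.

    Traceback tie order prefers the match/mismatch state, then the gap state
    that places gaps 5'-most.
    """
    n, m = len(read), len(reference)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    f = np.frombuffer(reference.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)   # read[i-1] ~ ref[j-1]
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in read (deletion)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in ref (insertion)
    M[0, 0] = 0
    for j in range(1, m + 1):
        Ix[0, j] = GAP_OPEN + GAP_EXTEND * j
    for i in range(1, n + 1):
        Iy[i, 0] = GAP_OPEN + GAP_EXTEND * i

    sub_all = np.where(r[:, None] == f[None, :], MATCH_SCORE, MISMATCH_SCORE)
    for i in range(1, n + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        diag_best = np.maximum(np.maximum(prevM, prevIx), prevIy)
        M[i, 1:] = diag_best[:-1] + sub_all[i - 1]
        # Iy depends only on row i-1
        Iy[i, 1:] = np.maximum(
            prevM[1:] + GAP_OPEN + GAP_EXTEND, prevIy[1:] + GAP_EXTEND
        )
        Iy[i, 0] = GAP_OPEN + GAP_EXTEND * i
        # Ix has a within-row recurrence
        rowM, rowIx = M[i], Ix[i]
        for j in range(1, m + 1):
            rowIx[j] = max(
                rowM[j - 1] + GAP_OPEN + GAP_EXTEND, rowIx[j - 1] + GAP_EXTEND
            )

    score = int(max(M[n, m], Ix[n, m], Iy[n, m]))
    # traceback; preference order M > Ix > Iy realises "mismatch over gap"
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("Ix", Ix[n, m]), ("Iy", Iy[n, m])),
        key=lambda t: (t[1], t[0] == "M", t[0] == "Ix"),
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            cols.append((j - 1, i - 1))
            s = sub_all[i - 1, j - 1]
            i, j = i - 1, j - 1
            candidates = [("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])]
            target = M[i + 1, j + 1] - s
            state = _pick_state(candidates, target)
        elif state == "Ix":  # deletion: ref consumed, read not
            cols.append((j - 1, None))
            j -= 1
            candidates = [
                ("M", M[i, j] + GAP_OPEN + GAP_EXTEND),
                ("Ix", Ix[i, j] + GAP_EXTEND),
            ]
            target = Ix[i, j + 1]
            state = _pick_state(candidates, target)
        else:  # Iy, insertion: read consumed, ref not
            cols.append((None, i - 1))
            i -= 1
            candidates = [
                ("M", M[i, j] + GAP_OPEN + GAP_EXTEND),
                ("Iy", Iy[i, j] + GAP_EXTEND),
            ]
            target = Iy[i + 1, j]
            state = _pick_state(candidates, target)
        if i == 0 and j == 0:
            break
        if i == 0 and state == "M":
            state = "Ix"
        if j == 0 and state == "M":
            state = "Iy"
    cols.reverse()
    return AlignedPair(columns=cols, score=score)


def _pick_state(candidates: list[tuple[str, int]], target: int) -> str:
    # keep extending the current gap (prefer non-M continuation) realises
    # 5'-most gap placement during right-to-left traceback
    for name, val in reversed(candidates):
        if val == target:
            return name
    # numerical safety: fall back to the best candidate
    return max(candidates, key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# Bit-vector calling
# ---------------------------------------------------------------------------


def _call_single_mate(
    aln: AlignedPair,
    read: str,
    quals: str | None,
    reference: str,
    quality_min: int,
    ambiguity_radius: int,
) -> np.ndarray:
    """Per-reference-position call for one mate."""
    L = len(reference)
    calls = np.full(L, UNCOVERED, dtype=np.uint8)
    indel_refpos: list[int] = []
    last_ref = -1
    for ref_i, read_i in aln.columns:
        if ref_i is None:
            # insertion in the read; mark the flanking reference position
            indel_refpos.append(max(last_ref, 0))
            continue
        last_ref = ref_i
        if read_i is None:
            calls[ref_i] = MUTATION  # deletion counts as a mutation
            indel_refpos.append(ref_i)
            continue
        q = 1000 if quals is None else ord(quals[read_i]) - 33
        if q < quality_min:
            calls[ref_i] = LOW_QUALITY
        elif read[read_i].upper() == reference[ref_i].upper():
            calls[ref_i] = MATCH
        elif read[read_i].upper() == "N":
            calls[ref_i] = AMBIGUOUS
        else:
            calls[ref_i] = MUTATION
    deleted = {p for p in indel_refpos if calls[p] == MUTATION}
    for p in indel_refpos:
        lo = max(0, p - ambiguity_radius)
        hi = min(L, p + ambiguity_radius + 1)
        covered = calls[lo:hi] != UNCOVERED
        calls[lo:hi][covered] = AMBIGUOUS
    # the deleted position itself is the signal; only its flanks are untrusted
    for p in deleted:
        calls[p] = MUTATION
    return calls


def call_bitvector(
    aln1: AlignedPair,
    read1: str,
    aln2: AlignedPair,
    read2_sense: str,
    reference: str,
    quals1: str | None = None,
    quals2: str | None = None,
    quality_min: int = 25,
    ambiguity_radius: int = 3,
) -> np.ndarray:
    """Merge two mate alignments into one per-molecule bit vector.

    Both alignments must be in reference orientation (reverse-complement the
    second mate before aligning).  Where mates overlap and disagree the
    position is ambiguous; where only one mate is informative its call wins.
    """
    c1 = _call_single_mate(aln1, read1, quals1, reference, quality_min, ambiguity_radius)
    c2 = _call_single_mate(aln2, read2_sense, quals2, reference, quality_min, ambiguity_radius)
    out = np.full(len(reference), UNCOVERED, dtype=np.uint8)
    for i in range(len(reference)):
        a, b = c1[i], c2[i]
        informative_a = a in (MATCH, MUTATION)
        informative_b = b in (MATCH, MUTATION)
        if informative_a and informative_b:
            out[i] = a if a == b else AMBIGUOUS
        elif informative_a:
            out[i] = a
        elif informative_b:
            out[i] = b
        elif AMBIGUOUS in (a, b):
            out[i] = AMBIGUOUS
        elif LOW_QUALITY in (a, b):
            out[i] = LOW_QUALITY
        else:
            out[i] = UNCOVERED
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class MutationProfile:
    """Population-average mutation fractions for one construct/condition."""

    construct: str
    sequence: str
    dot_bracket: str
    depth: np.ndarray
    mut_count: np.ndarray
    n_reads: int = 0
    n_discarded: int = 0

    @property
    def mut_fraction(self) -> np.ndarray:
        """Mutation fraction; NaN where no read is informative."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(self.depth > 0, self.mut_count / self.depth, np.nan)
        return frac

    def mean_reactivity(self, positions: Sequence[int]) -> float:
        """Unweighted mean mutation fraction over selected positions."""
        return float(np.nanmean(self.mut_fraction[list(positions)]))

    def reactivity_se(self, positions: Sequence[int]) -> float:
        """Binomial standard error of the mean reactivity over positions."""
        pos = list(positions)
        frac = self.mut_fraction[pos]
        depth = self.depth[pos].astype(float)
        var = np.where(depth > 0, frac * (1 - frac) / np.maximum(depth, 1), np.nan)
        k = np.sum(~np.isnan(var))
        if k == 0:
            return float("nan")
        return float(np.sqrt(np.nansum(var)) / k)

    def to_dict(self) -> dict:
        return {
            "construct": self.construct,
            "sequence": self.sequence,
            "structure": self.dot_bracket,
            "depth": self.depth.tolist(),
            "mut_count": self.mut_count.tolist(),
            "mut_fraction": [
                None if np.isnan(x) else float(x) for x in self.mut_fraction
            ],
            "n_reads": self.n_reads,
            "n_discarded": self.n_discarded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutationProfile":
        return cls(
            construct=d["construct"],
            sequence=d["sequence"],
            dot_bracket=d["structure"],
            depth=np.asarray(d["depth"], dtype=int),
            mut_count=np.asarray(d["mut_count"], dtype=int),
            n_reads=d.get("n_reads", 0),
            n_discarded=d.get("n_discarded", 0),
        )

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path: str | Path) -> "MutationProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def aggregate(
    bitvectors: Iterable[np.ndarray],
    construct: str = "",
    sequence: str = "",
    dot_bracket: str = "",
    max_mutations: int | None = None,
) -> MutationProfile:
    """Aggregate bit vectors into a mutation profile.

    Reads with more than ``max_mutations`` mutation calls (default 10% of
    the reference length) are discarded entirely - an excess of mutations
    signals a chimeric or misassigned molecule rather than DMS signal.
    """
    bitvectors = list(bitvectors)
    if not bitvectors:
        raise ValueError("aggregate requires at least one bit vector")
    L = len(bitvectors[0])
    if max_mutations is None:
        max_mutations = max(1, int(0.1 * L))
    depth = np.zeros(L, dtype=int)
    muts = np.zeros(L, dtype=int)
    n_used = n_discarded = 0
    for bv in bitvectors:
        n_mut = int(np.sum(bv == MUTATION))
        if n_mut > max_mutations:
            n_discarded += 1
            continue
        informative = (bv == MATCH) | (bv == MUTATION)
        depth += informative
        muts += bv == MUTATION
        n_used += 1
    return MutationProfile(
        construct=construct,
        sequence=sequence,
        dot_bracket=dot_bracket,
        depth=depth,
        mut_count=muts,
        n_reads=n_used,
        n_discarded=n_discarded,
    )


def profile_pairs(
    pairs: Iterable[tuple[str, str]],
    reference: str,
    construct: str = "",
    sequence: str = "",
    dot_bracket: str = "",
    quals: Iterable[tuple[str | None, str | None]] | None = None,
    quality_min: int = 25,
    ambiguity_radius: int = 3,
    min_score_frac: float = 0.5,
    max_mutations: int | None = None,
) -> MutationProfile:
    """Profile (seq1, seq2) read pairs against a DNA reference.

    ``seq1`` must be in reference orientation (sample barcode stripped);
    ``seq2`` is reverse-complemented internally.  Alignment-QC failures are
    counted as discarded reads.
    """
    from .constructs import reverse_complement_dna

    bitvectors = []
    n_qc_fail = 0
    qual_iter = iter(quals) if quals is not None else None
    for s1, s2 in pairs:
        q1 = q2 = None
        if qual_iter is not None:
            q1, q2 = next(qual_iter)
        s2_sense = reverse_complement_dna(s2)
        q2_sense = q2[::-1] if q2 is not None else None
        try:
            a1 = align_pair(s1, reference, min_score_frac)
            a2 = align_pair(s2_sense, reference, min_score_frac)
        except AlignmentQCFail:
            n_qc_fail += 1
            continue
        bitvectors.append(
            call_bitvector(
                a1, s1, a2, s2_sense, reference,
                quals1=q1, quals2=q2_sense,
                quality_min=quality_min, ambiguity_radius=ambiguity_radius,
            )
        )
    if not bitvectors:
        raise ValueError("no read pair passed alignment QC")
    profile = aggregate(
        bitvectors,
        construct=construct,
        sequence=sequence,
        dot_bracket=dot_bracket,
        max_mutations=max_mutations,
    )
    profile.n_discarded += n_qc_fail
    return profile


def iter_fastq_profile(
    fq1: str | Path,
    fq2: str | Path,
    record,
    rtb_strip: int = 0,
    **kwargs,
) -> MutationProfile:
    """Profile demultiplexed paired FASTQ files against one construct.

    ``record`` is a :class:`~qmapseq.constructs.ConstructRecord`; reads in
    ``fq1`` must be in reference orientation with sample barcodes already
    stripped (the demultiplexer's output convention), or pass ``rtb_strip``
    to remove a fixed-length 5' barcode here.
    """
    from .demux import iter_fastq_pairs

    pairs, quals = [], []
    for _rid, s1, q1, s2, q2 in iter_fastq_pairs(fq1, fq2):
        pairs.append((s1[rtb_strip:], s2))
        quals.append((q1[rtb_strip:], q2))
    return profile_pairs(
        pairs,
        reference=record.dna_amplicon,
        construct=record.name,
        sequence=record.rna_sequence,
        dot_bracket=record.dot_bracket,
        quals=quals,
        **kwargs,
    )


def profiles_to_wide_csv(profiles: Sequence[MutationProfile], path: str | Path) -> None:
    """Wide CSV: one row per (construct, position) with fraction/depth/count."""
    import pandas as pd

    rows = []
    for p in profiles:
        frac = p.mut_fraction
        for i in range(len(p.depth)):
            rows.append(
                {
                    "construct": p.construct,
                    "position": i,
                    "nucleotide": p.sequence[i] if p.sequence else "",
                    "depth": int(p.depth[i]),
                    "mut_count": int(p.mut_count[i]),
                    "mut_fraction": frac[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_reactivity(profile: MutationProfile, ax=None, path: str | Path | None = None):
    """Bar chart of mutation fraction coloured by nucleotide (A/C/G/U)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#d62728", "C": "#1f77b4", "G": "#7f7f7f", "U": "#bcbd22",
              "T": "#bcbd22"}
    if ax is None:
        _fig, ax = plt.subplots(figsize=(max(6, len(profile.depth) / 8), 3))
    frac = np.nan_to_num(profile.mut_fraction)
    seq = profile.sequence or "N" * len(frac)
    ax.bar(
        np.arange(len(frac)),
        frac,
        color=[colors.get(ch.upper(), "#333333") for ch in seq],
    )
    ax.set_xlabel("position")
    ax.set_ylabel("mutation fraction")
    ax.set_title(profile.construct)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
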