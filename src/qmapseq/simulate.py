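"""Synthetic paired-read simulator for Mg2+-titration DMS probing.

The generative model is the two-state interpretation of tertiary-contact
probing: at Mg2+ concentration x a fraction

    p(x) = A * (x/K)^n / (1 + (x/K)^n)

of molecules have formed the contact (K = [Mg2+]1/2, n = Hill coefficient,
A = amplitude <= 1).  Probe adenines in docked molecules mutate during
reverse transcription at the low ``protected_rate``; in undocked molecules
at their ``unprotected_rate``.  All other positions mutate at
structure-dependent background rates independent of Mg2+.  Sequencing error
is added independently per mate, so mate disagreement carries information
the profiler can use.

Two simulators are provided: a read-level one that writes paired FASTQ
(exercising demultiplexing, alignment and bit-vector calling) and a
profile-level one that draws binomial mutation counts directly (cheap enough
for large parameter-recovery studies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .constructs import ConstructRecord, reverse_complement_dna, rna_to_dna

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# row = index of reference base in ACGT, columns = the 3 alternatives
_ALTERNATIVES = np.array(
    [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.uint8
)

#: Default per-position DMS mutation rates by structural class.  DMS
#: methylates N1 of adenine and N3 of cytosine when solvent-accessible;
#: Watson-Crick pairing shields those nitrogens, and G/U are near-silent.
DEFAULT_CLASS_RATES = {
    "unpaired_A": 0.05,
    "unpaired_C": 0.03,
    "paired": 0.002,
    "other": 0.002,
}


@dataclass
class SimulationSpec:
    """Ground-truth parameters for one construct across a titration."""

    construct: ConstructRecord
    mg_concentrations: Sequence[float]
    true_mg_half: float = 0.22          # mM
    true_hill_n: float = 2.0
    true_amplitude: float = 1.0
    unprotected_rate: float = 0.05      # probe adenines, contact unformed
    protected_rate: float = 0.002       # probe adenines, contact formed
    background_error: float = 0.001     # per-base sequencing error, per mate
    depth: int = 2000                   # read pairs per condition
    rtb_barcode: str = "CCAATGGGTGTA"   # 12-nt RT sample barcode on read 1
    seed: int = 0
    class_rates: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_RATES))

    def __post_init__(self) -> None:
        mg = np.asarray(self.mg_concentrations, dtype=float)
        if np.any(mg < 0):
            raise ValueError("Mg2+ concentrations must be non-negative")
        if len(np.unique(mg)) != len(mg):
            raise ValueError("Mg2+ concentrations must be unique")
        for r in (
            self.unprotected_rate,
            self.protected_rate,
            self.background_error,
        ):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.protected_rate > self.unprotected_rate:
            raise ValueError("protected_rate must not exceed unprotected_rate")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 < self.true_amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")

    # -- per-position rates -------------------------------------------------

    def position_rates(self, mg: float) -> np.ndarray:
        """Per-position mutation probability at one Mg2+ concentration."""
        base = self.base_rates()
        p = occupancy(mg, self)
        probe_rate = p * self.protected_rate + (1.0 - p) * self.unprotected_rate
        rates = base.copy()
        rates[self.construct.probe_positions] = probe_rate
        return rates

    def base_rates(self) -> np.ndarray:
        """Mg2+-independent rates from the structural class of each position."""
        seq = self.construct.flat_sequence
        db = self.construct.dot_bracket.replace("&", "")
        rates = np.empty(len(seq))
        for i, (s, d) in enumerate(zip(seq, db)):
            if d != ".":
                rates[i] = self.class_rates["paired"]
            elif s == "A":
                rates[i] = self.class_rates["unpaired_A"]
            elif s == "C":
                rates[i] = self.class_rates["unpaired_C"]
            else:
                rates[i] = self.class_rates["other"]
        rates[self.construct.probe_positions] = self.unprotected_rate
        return rates


def occupancy(mg: float, spec: SimulationSpec) -> float:
    """Fraction of molecules with the tertiary contact formed at ``mg`` mM."""
    return hill_fraction(
        mg, spec.true_amplitude, spec.true_mg_half, spec.true_hill_n
    )


def hill_fraction(mg, amplitude, mg_half, hill_n):
    """A * (mg/K)^n / (1 + (mg/K)^n); exactly 0 at mg = 0."""
    mg = np.asarray(mg, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(mg > 0, (mg / mg_half) ** hill_n, 0.0)
    out = amplitude * ratio / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def fastq_block(self, mate: int) -> str:
        seq = self.seq1 if mate == 1 else self.seq2
        qual = self.qual1 if mate == 1 else self.qual2
        return f"@{self.read_id}/{mate}\n{seq}\n+\n{qual}\n"


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for k, b in enumerate(_BASES):
        codes[arr == b] = k
    if np.any(codes == 255):
        raise ValueError(f"non-ACGT base in sequence {seq!r}")
    return codes


def _decode(codes: np.ndarray) -> list[str]:
    return ["".join(chr(_BASES[c]) for c in row) for row in codes]


def _apply_errors(codes: np.ndarray, prob, rng: np.random.Generator) -> np.ndarray:
    """Independently flip bases to a uniform alternative with probability prob."""
    hit = rng.random(codes.shape) < prob
    if not np.any(hit):
        return codes
    out = codes.copy()
    alt_idx = rng.integers(0, 3, size=codes.shape)
    out[hit] = _ALTERNATIVES[codes[hit], alt_idx[hit]]
    return out


def simulate_condition(
    spec: SimulationSpec, mg: float, condition_index: int = 0
) -> list[ReadPair]:
    """Simulate ``spec.depth`` read pairs for one Mg2+ condition.

    Read 1 begins with the RT sample barcode followed by the amplicon sense
    strand; read 2 is the reverse-complement strand.  DMS-induced mutations
    are drawn once per molecule (both mates report them); sequencing errors
    are drawn independently per mate.  Deterministic for a fixed
    (seed, condition_index).
    """
    rng = np.random.default_rng([spec.seed, condition_index])
    n = spec.depth
    if n == 0:
        return []
    ref = rna_to_dna(spec.construct.flat_sequence)
    ref_codes = _encode(ref)
    rates = spec.position_rates(mg)

    molecules = np.tile(ref_codes, (n, 1))
    molecules = _apply_errors_with_rates(molecules, rates, rng)

    mate1 = _apply_errors(molecules, spec.background_error, rng)
    mate2_sense = _apply_errors(molecules, spec.background_error, rng)
    # reverse complement: complement code is 3 - code for ACGT ordering
    mate2 = (3 - mate2_sense)[:, ::-1]

    qual1 = "F" * (len(spec.rtb_barcode) + len(ref))   # Phred 37
    qual2 = "F" * len(ref)
    seqs1 = _decode(mate1)
    seqs2 = _decode(mate2)
    name = spec.construct.name
    return [
        ReadPair(
            read_id=f"{name}:mg{condition_index}:{i}",
            seq1=spec.rtb_barcode + seqs1[i],
            seq2=seqs2[i],
            qual1=qual1,
            qual2=qual2,
        )
        for i in range(n)
    ]


def _apply_errors_with_rates(
    codes: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    hit = rng.random(codes.shape) < rates[None, :]
    out = codes.copy()
    if np.any(hit):
        alt_idx = rng.integers(0, 3, size=codes.shape)
        out[hit] = _ALTERNATIVES[codes[hit], alt_idx[hit]]
    return out


def _open_out(path: str | Path):
    if str(path).endswith(".gz"):
        import gzip

        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write standard 4-line FASTQ, one file per mate (.gz by extension)."""
    with _open_out(path1) as f1, _open_out(path2) as f2:
        for p in pairs:
            f1.write(p.fastq_block(1))
            f2.write(p.fastq_block(2))


def simulate_titration_reads(
    spec: SimulationSpec, out_dir: str | Path, prefix: str | None = None
) -> dict:
    """Write paired FASTQ per Mg2+ condition plus a ground-truth JSON.

    Returns the ground-truth dictionary (also written to
    ``<prefix>_truth.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or spec.construct.name
    files = []
    for k, mg in enumerate(spec.mg_concentrations):
        pairs = simulate_condition(spec, mg, condition_index=k)
        p1 = out_dir / f"{prefix}_cond{k:02d}_R1.fastq"
        p2 = out_dir / f"{prefix}_cond{k:02d}_R2.fastq"
        write_fastq(pairs, p1, p2)
        files.append({"mg_mM": mg, "r1": p1.name, "r2": p2.name})
    truth = ground_truth(spec)
    truth["files"] = files
    with (out_dir / f"{prefix}_truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


def ground_truth(spec: SimulationSpec) -> dict:
    return {
        "construct": spec.construct.name,
        "mg_concentrations_mM": list(map(float, spec.mg_concentrations)),
        "true_mg_half_mM": spec.true_mg_half,
        "true_hill_n": spec.true_hill_n,
        "true_amplitude": spec.true_amplitude,
        "unprotected_rate": spec.unprotected_rate,
        "protected_rate": spec.protected_rate,
        "background_error": spec.background_error,
        "depth": spec.depth,
        "rtb_barcode": spec.rtb_barcode,
        "seed": spec.seed,
        "position_rates_mg0": spec.position_rates(0.0).tolist(),
    }


# ---------------------------------------------------------------------------
# Profile-level simulation (binomial counts; no reads)
# ---------------------------------------------------------------------------


def simulate_profile_counts(
    spec: SimulationSpec, mg: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-position (depth, mutation count) at one condition.

    Mutation counts are binomial at the model rate; the sequencing-error
    floor adds to every position (a mutation OR an error is scored, mates
    assumed concordant).
    """
    rates = spec.position_rates(mg)
    eff = rates + (1 - rates) * spec.background_error
    depth = np.full(len(rates), spec.depth, dtype=int)
    muts = rng.binomial(depth, eff)
    return depth, muts
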