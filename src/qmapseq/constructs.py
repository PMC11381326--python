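"""Designed RNA constructs: dot-bracket parsing, helix barcodes, pooled libraries.

Pooled chemical-probing libraries are demultiplexed in two stages: a sample
barcode on the RT primer, then a construct-level barcode that is itself a
helix of the folded RNA ("internal helix barcode").  This module owns the
construct records, the helix bookkeeping needed to read barcodes off a
dot-bracket structure, and the library designer that assigns unique helices
so that all members of a pool stay mutually distinguishable.

Coordinates are 0-based half-open everywhere in code; human-readable reports
use 1-based closed intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

RNA_ALPHABET = set("ACGU")
_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")
_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Watson-Crick plus wobble; dot-bracket pairs are trusted as written, so this
# set is only used for optional sanity checks, never to re-predict structure.
VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


class StructureError(ValueError):
    """Raised for unbalanced or malformed dot-bracket structures."""


class DesignError(ValueError):
    """Raised when a library design request cannot be satisfied."""


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Coding-strand DNA of an RNA sequence (U -> T)."""
    return seq.replace("U", "T").replace("u", "t")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (case-insensitive)."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    a, b = a.upper(), b.upper()
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Dot-bracket parsing
# ---------------------------------------------------------------------------


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions).

    Indices are global over the concatenated sequence with ``&`` strand
    separators skipped, so they line up with the concatenated sequence string
    with ``&`` removed.
    """
    stack: list[int] = []
    pairs: dict[int, int] = {}
    idx = 0
    for raw_pos, ch in enumerate(structure):
        if ch == "&":
            continue
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced ')' at structure index {raw_pos}"
                )
            i = stack.pop()
            pairs[i] = idx
            pairs[idx] = i
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at index {raw_pos}")
        idx += 1
    if stack:
        raise StructureError(f"unclosed '(' at structure index {stack[-1]}")
    return pairs


def parse_dot_bracket(structure: str) -> list[list[tuple[int, int]]]:
    """Decompose a dot-bracket string into helices.

    A helix is a maximal stack of nested base pairs with no intervening
    unpaired position on either strand: pair (i, j) extends the helix of
    (i-1, j+1); any bulge or internal loop terminates the stack.  Helices are
    returned in order of their 5'-most position, each as a list of (i, j)
    index pairs with i < j, stacked 5'->3'.
    """
    pairs = pair_table(structure)
    opens = sorted(i for i, j in pairs.items() if i < j)
    helices: list[list[tuple[int, int]]] = []
    for i in opens:
        j = pairs[i]
        if helices and helices[-1][-1] == (i - 1, j + 1):
            helices[-1].append((i, j))
        else:
            helices.append([(i, j)])
    return helices


# ---------------------------------------------------------------------------
# Construct records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeHelix:
    """Location of the internal helix barcode: which helix, which base pairs."""

    helix_ordinal: int
    bp_start: int
    bp_end: int  # half-open

    def __str__(self) -> str:
        return f"{self.helix_ordinal}:{self.bp_start}:{self.bp_end}"

    @classmethod
    def parse(cls, text: str) -> "BarcodeHelix":
        ordinal, start, end = (int(x) for x in text.split(":"))
        return cls(ordinal, start, end)


@dataclass(frozen=True)
class HelixBarcode:
    """Barcode sequences read off both strands of a helix."""

    fwd: str
    rev: str
    fwd_span: tuple[int, int]  # half-open, reference coordinates
    rev_span: tuple[int, int]


@dataclass
class ConstructRecord:
    """One designed RNA in a pool.

    ``probe_positions`` are the adenines whose DMS reactivity reports on
    tertiary-contact formation (e.g. the GAAA tetraloop adenines).
    ``barcode_helix`` locates the construct's unique internal helix barcode.
    """

    name: str
    rna_sequence: str
    dot_bracket: str
    probe_positions: list[int] = field(default_factory=list)
    barcode_helix: BarcodeHelix | None = None

    def __post_init__(self) -> None:
        self.rna_sequence = self.rna_sequence.upper().replace("T", "U")
        seq_strands = self.rna_sequence.split("&")
        db_strands = self.dot_bracket.split("&")
        if len(seq_strands) != len(db_strands):
            raise StructureError(
                f"{self.name}: sequence has {len(seq_strands)} strands, "
                f"structure has {len(db_strands)}"
            )
        for k, (s, d) in enumerate(zip(seq_strands, db_strands)):
            if len(s) != len(d):
                raise StructureError(
                    f"{self.name}: strand {k}: sequence length {len(s)} != "
                    f"structure length {len(d)}"
                )
        bad = set(self.flat_sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)}")
        pair_table(self.dot_bracket)  # raises on unbalanced structure
        for p in self.probe_positions:
            if not 0 <= p < len(self.flat_sequence):
                raise ValueError(f"{self.name}: probe position {p} out of range")
            if self.flat_sequence[p] != "A":
                raise ValueError(
                    f"{self.name}: probe position {p} is "
                    f"{self.flat_sequence[p]!r}, expected 'A'"
                )
        if self.barcode_helix is not None:
            self.helix_barcode()  # validates ordinal and bp range

    @property
    def flat_sequence(self) -> str:
        """Sequence with strand separators removed (global coordinates)."""
        return self.rna_sequence.replace("&", "")

    @property
    def dna_amplicon(self) -> str:
        """T7 template sense strand for the (single-strand) construct."""
        return rna_to_dna(self.flat_sequence)

    def helices(self) -> list[list[tuple[int, int]]]:
        return parse_dot_bracket(self.dot_bracket)

    def helix_barcode(self) -> HelixBarcode:
        if self.barcode_helix is None:
            raise DesignError(f"{self.name}: no barcode helix designated")
        return extract_helix_barcode(self, self.barcode_helix)


def extract_helix_barcode(
    record: ConstructRecord, loc: BarcodeHelix | None = None
) -> HelixBarcode:
    """Read the forward- and reverse-strand barcode of a helix.

    The forward barcode is the 5'-strand bases of base pairs
    [bp_start, bp_end) of the chosen helix; the reverse barcode is the paired
    3'-strand bases, reported 5'->3' in reference orientation.
    """
    loc = loc or record.barcode_helix
    if loc is None:
        raise DesignError(f"{record.name}: no barcode helix designated")
    helices = record.helices()
    if not 0 <= loc.helix_ordinal < len(helices):
        raise DesignError(
            f"{record.name}: helix ordinal {loc.helix_ordinal} out of range "
            f"(structure has {len(helices)} helices)"
        )
    helix = helices[loc.helix_ordinal]
    if loc.bp_end > len(helix) or loc.bp_start < 0 or loc.bp_start >= loc.bp_end:
        raise DesignError(
            f"{record.name}: barcode out of range: base pairs "
            f"[{loc.bp_start}, {loc.bp_end}) on a {len(helix)}-bp helix"
        )
    pairs = helix[loc.bp_start : loc.bp_end]
    seq = record.flat_sequence
    fwd_positions = [i for i, _ in pairs]
    rev_positions = [j for _, j in pairs]
    fwd_span = (fwd_positions[0], fwd_positions[-1] + 1)
    rev_span = (rev_positions[-1], rev_positions[0] + 1)
    return HelixBarcode(
        fwd=seq[fwd_span[0] : fwd_span[1]],
        rev=seq[rev_span[0] : rev_span[1]],
        fwd_span=fwd_span,
        rev_span=rev_span,
    )


# ---------------------------------------------------------------------------
# Library design
# ---------------------------------------------------------------------------


@dataclass
class LibraryDesign:
    """A pooled library whose members are mutually distinguishable."""

    constructs: list[ConstructRecord]
    min_pairwise_hamming: int = 0
    barcode_length: int = 7
    seed: int | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DesignError(f"duplicate construct names: {dupes}")
        d = self.min_observed_hamming()
        if d is not None and d < self.min_pairwise_hamming:
            raise DesignError(
                f"library violates hamming constraint: observed minimum {d} "
                f"< required {self.min_pairwise_hamming}"
            )

    def min_observed_hamming(self) -> int | None:
        """All-pairs minimum hamming distance over equal-length members."""
        seqs = [c.flat_sequence for c in self.constructs]
        best: int | None = None
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if len(seqs[i]) != len(seqs[j]):
                    continue
                d = hamming(seqs[i], seqs[j])
                best = d if best is None else min(best, d)
        return best

    def __iter__(self):
        return iter(self.constructs)

    def __len__(self) -> int:
        return len(self.constructs)

    def get(self, name: str) -> ConstructRecord:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(name)


def assign_unique_helices(
    mutants: Sequence[tuple[str, str, str]],
    helix_pool: Sequence[str],
    min_hamming: int,
    seed: int,
    barcode_helix: BarcodeHelix | None = None,
    probe_positions_offset: bool = True,
) -> LibraryDesign:
    """Assign each mutant a unique flanking helix from a candidate pool.

    Each mutant is given as ``(name, core_sequence, core_structure)``; the
    emitted construct is ``helix + core + reverse_complement(helix)`` with a
    fully paired flanking helix, so the helix contributes twice its length to
    the pairwise distance between members.  Candidates are consumed in a
    seeded random order and accepted greedily only if the full sequence keeps
    an all-pairs hamming distance >= ``min_hamming`` against every
    equal-length member already placed.

    Raises :class:`DesignError` reporting the best distance achieved if the
    pool is exhausted before the constraint is met.
    """
    if min_hamming < 1:
        raise DesignError("min_hamming must be >= 1")
    rng = np.random.default_rng(seed)
    pool = list(dict.fromkeys(helix_pool))  # dedupe, keep order
    rng.shuffle(pool)
    helix_len = {len(h) for h in pool}
    if len(helix_len) > 1:
        raise DesignError("helix pool must contain equal-length candidates")

    chosen: list[ConstructRecord] = []
    barcode_len = min(7, next(iter(helix_len))) if pool else 7
    for name, core_seq, core_db in mutants:
        placed = False
        best_d = -1
        for cand in pool:
            helix = cand.upper().replace("T", "U")
            full_seq = helix + core_seq + reverse_complement_rna(helix)
            full_db = "(" * len(helix) + core_db + ")" * len(helix)
            dists = [
                hamming(full_seq, c.flat_sequence)
                for c in chosen
                if len(c.flat_sequence) == len(full_seq)
            ]
            d = min(dists, default=None)
            if d is not None:
                best_d = max(best_d, d)
            if d is None or d >= min_hamming:
                loc = barcode_helix or BarcodeHelix(0, 0, barcode_len)
                probes = []
                if probe_positions_offset:
                    probes = [
                        len(helix) + k
                        for k, (s, b) in enumerate(zip(core_seq, core_db))
                        if s == "A" and b == "."
                    ]
                chosen.append(
                    ConstructRecord(
                        name=name,
                        rna_sequence=full_seq,
                        dot_bracket=full_db,
                        probe_positions=probes,
                        barcode_helix=loc,
                    )
                )
                pool.remove(cand)
                placed = True
                break
        if not placed:
            raise DesignError(
                f"design infeasible: no helix candidate satisfies "
                f"min_hamming={min_hamming} for {name!r} "
                f"(best distance achieved: {best_d})"
            )
    return LibraryDesign(
        constructs=chosen,
        min_pairwise_hamming=min_hamming,
        barcode_length=barcode_len,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scaffold builder (miniTTR-like hairpin used by simulations and tests)
# ---------------------------------------------------------------------------

#: 3' strand of the tetraloop-receptor internal loop (contains the A-A
#: platform adenines); 5' strand faces it across the loop.
_RECEPTOR_5P = "UAUGG"
_RECEPTOR_3P = "CCUAAG"


def build_tlr_construct(
    name: str,
    barcode: str = "GGCACUC",
    receptor_5p: str = _RECEPTOR_5P,
    receptor_3p: str = _RECEPTOR_3P,
    stem2: str = "GCAGC",
    h1_extra: str = "GCA",
) -> ConstructRecord:
    """Build a minimal hairpin scaffold with a GAAA tetraloop and receptor.

    Layout 5'->3': helix-1 5' strand (7-nt barcode + extension), receptor 5'
    strand (unpaired), helix-2 5' strand, GAAA tetraloop, helix-2 3' strand,
    receptor 3' strand (unpaired), helix-1 3' strand.  The three tetraloop
    adenines are the probe positions; helix 1 carries the barcode in base
    pairs [0, 7).
    """
    barcode = barcode.upper().replace("T", "U")
    h1 = barcode + h1_extra
    seq = (
        h1
        + receptor_5p
        + stem2
        + "GAAA"
        + reverse_complement_rna(stem2)
        + receptor_3p
        + reverse_complement_rna(h1)
    )
    db = (
        "(" * len(h1)
        + "." * len(receptor_5p)
        + "(" * len(stem2)
        + "...."
        + ")" * len(stem2)
        + "." * len(receptor_3p)
        + ")" * len(h1)
    )
    tl_start = len(h1) + len(receptor_5p) + len(stem2)
    probes = [tl_start + 1, tl_start + 2, tl_start + 3]
    return ConstructRecord(
        name=name,
        rna_sequence=seq,
        dot_bracket=db,
        probe_positions=probes,
        barcode_helix=BarcodeHelix(0, 0, len(barcode)),
    )


def receptor_positions(record: ConstructRecord) -> dict[str, int]:
    """Convenience map of scaffold landmarks for QC and clustering.

    Returns reference indices of the tetraloop closing pair and the receptor
    3'-strand adenines for constructs built by :func:`build_tlr_construct`.
    """
    helices = record.helices()
    inner = helices[-1]
    close_5p, close_3p = inner[-1]
    seq = record.flat_sequence
    rec_start = close_3p + 1
    rec_adenines = [
        rec_start + k
        for k, ch in enumerate(seq[rec_start:])
        if ch == "A" and record.dot_bracket[rec_start + k] == "."
    ]
    return {
        "closing_pair_5p": close_5p,
        "closing_pair_3p": close_3p,
        "receptor_adenines": rec_adenines,  # type: ignore[dict-item]
    }


# ---------------------------------------------------------------------------
# Constructs table I/O (name,sequence,structure CSV)
# ---------------------------------------------------------------------------


def write_constructs_csv(library: Iterable[ConstructRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "sequence", "structure", "probe_positions", "barcode_helix"])
        for rec in library:
            writer.writerow(
                [
                    rec.name,
                    rec.rna_sequence,
                    rec.dot_bracket,
                    ";".join(str(p) for p in rec.probe_positions),
                    str(rec.barcode_helix) if rec.barcode_helix else "",
                ]
            )


def read_constructs_csv(path: str | Path) -> list[ConstructRecord]:
    path = Path(path)
    records: list[ConstructRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "sequence", "structure"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: constructs table must have columns name,sequence,structure"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                probes = [
                    int(x) for x in (row.get("probe_positions") or "").split(";") if x
                ]
                bh = row.get("barcode_helix") or ""
                records.append(
                    ConstructRecord(
                        name=row["name"],
                        rna_sequence=row["sequence"],
                        dot_bracket=row["structure"],
                        probe_positions=probes,
                        barcode_helix=BarcodeHelix.parse(bh) if bh else None,
                    )
                )
            except (ValueError, StructureError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_amplicons_fasta(library: Iterable[ConstructRecord], path: str | Path) -> None:
    """FASTA of DNA amplicons (coding strand) for read simulation/alignment."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(c.dna_amplicon), id=c.name, description="")
        for c in library
    ]
    seqio_write(recs, str(path), "fasta")
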