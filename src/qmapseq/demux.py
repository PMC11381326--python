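"""Two-stage demultiplexing of pooled probing reads.

Stage 1 assigns read pairs to a sample by the 12-nt RT barcode (RTB) at the
5' end of read 1, with an inclusive hamming-distance threshold.  Stage 2
assigns pairs within a pool to an individual construct by its internal helix
barcode: the forward-strand barcode is searched in the mate carrying the
RNA sequence 5'->3' within a small window around its expected reference
offset, and the paired reverse-strand barcode likewise in the other mate.
Ties at equal minimal distance are rejected rather than arbitrarily
resolved: a few percent of misassigned reads would add noise to every
downstream mutation fraction, whereas dropped reads only cost depth.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .constructs import ConstructRecord, LibraryDesign, extract_helix_barcode

UNASSIGNED = "UNASSIGNED"

#: failure reasons recorded per unassigned pair
NO_RTB = "no_rtb"
AMBIGUOUS = "ambiguous"
HELIX_NOT_FOUND = "helix_not_found"
TOO_DISTANT = "too_distant"


class BarcodeTableError(ValueError):
    """Raised when a barcode table violates its unambiguity invariant."""


def _hamming(a: str, b: str) -> int:
    """Case-insensitive hamming distance; N never matches."""
    d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x != y or x == "N":
            d += 1
    return d


@dataclass
class BarcodeTable:
    """RT sample barcodes with novobarcode-style Distance/Format semantics.

    ``max_distance`` is the inclusive hamming threshold ("Distance"); the
    barcode sits at the 5' end of read 1 ("Format 5").
    """

    entries: dict[str, str]
    max_distance: int = 4

    def __post_init__(self) -> None:
        if not self.entries:
            raise BarcodeTableError("empty barcode table")
        lengths = {len(b) for b in self.entries.values()}
        if len(lengths) != 1:
            raise BarcodeTableError(f"barcodes of unequal length: {sorted(lengths)}")
        names = list(self.entries)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = _hamming(self.entries[names[i]], self.entries[names[j]])
                if d <= 2 * self.max_distance:
                    raise BarcodeTableError(
                        f"barcodes {names[i]}/{names[j]} at distance {d} <= "
                        f"2*max_distance ({2 * self.max_distance}): assignment ambiguous"
                    )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @classmethod
    def load(cls, path: str | Path) -> "BarcodeTable":
        """Read the two-column text format with Distance/Format headers."""
        entries: dict[str, str] = {}
        max_distance = 4
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0]
                if key.lower() == "distance":
                    max_distance = int(parts[1])
                elif key.lower() == "format":
                    continue  # placement is fixed: 5' end of read 1
                else:
                    entries[key] = parts[1].upper()
        return cls(entries=entries, max_distance=max_distance)


def match_rtb(read1: str, table: BarcodeTable) -> str:
    """Assign read 1 to a sample by its 5' barcode prefix.

    Returns the unique entry within ``max_distance`` of the prefix, or
    UNASSIGNED if none qualifies or two entries tie at minimal distance.
    """
    k = table.barcode_length
    if len(read1) < k:
        return UNASSIGNED
    prefix = read1[:k]
    best_name, best_d, tie = UNASSIGNED, k + 1, False
    for name, bc in table.entries.items():
        d = _hamming(prefix, bc)
        if d < best_d:
            best_name, best_d, tie = name, d, False
        elif d == best_d:
            tie = True
    if best_d > table.max_distance or tie:
        return UNASSIGNED
    return best_name


# ---------------------------------------------------------------------------
# Internal helix barcode demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class InternalDemuxParams:
    helix_ordinal: int = 0
    bp_start: int = 0
    bp_end: int = 7
    max_hamming: int = 1
    window: int = 3  # +- positions searched around the expected offset


def _best_windowed_distance(
    read: str, barcode: str, expected: int, window: int
) -> int | None:
    """Minimum hamming distance of ``barcode`` over offsets within +-window.

    Returns None if no offset places the barcode fully inside the read.
    """
    k = len(barcode)
    best: int | None = None
    for off in range(expected - window, expected + window + 1):
        if off < 0 or off + k > len(read):
            continue
        d = _hamming(read[off : off + k], barcode)
        if best is None or d < best:
            best = d
    return best


def demux_internal(
    seq_fwd: str,
    seq_rev: str,
    library: LibraryDesign | Sequence[ConstructRecord],
    params: InternalDemuxParams | None = None,
) -> tuple[str, str | None]:
    """Assign one read pair to a construct by its internal helix barcode.

    ``seq_fwd`` is the mate carrying the RNA sequence 5'->3' (sample barcode
    already stripped); ``seq_rev`` is the reverse-complement mate.  A
    construct matches when its forward barcode is within ``max_hamming`` in
    the forward mate (searched in a +-window around the expected offset) and
    the reverse-strand barcode matches in the other mate, or that mate does
    not cover the barcode span.  Returns ``(name, None)`` on success or
    ``(UNASSIGNED, reason)``.
    """
    from .constructs import BarcodeHelix, reverse_complement_rna, rna_to_dna

    params = params or InternalDemuxParams()
    loc = BarcodeHelix(params.helix_ordinal, params.bp_start, params.bp_end)
    matches: list[tuple[str, int]] = []
    any_window = False
    for rec in library:
        bc = extract_helix_barcode(rec, loc)
        fwd = rna_to_dna(bc.fwd)
        rev_rc = rna_to_dna(reverse_complement_rna(bc.rev))
        ref_len = len(rec.flat_sequence)
        d_fwd = _best_windowed_distance(
            seq_fwd, fwd, bc.fwd_span[0], params.window
        )
        if d_fwd is None:
            continue
        any_window = True
        if d_fwd > params.max_hamming:
            continue
        # expected offset of the reverse barcode in the reverse-complement mate
        exp_rev = ref_len - bc.rev_span[1]
        d_rev = _best_windowed_distance(seq_rev, rev_rc, exp_rev, params.window)
        rev_ok = d_rev is None or d_rev <= params.max_hamming
        if rev_ok:
            matches.append((rec.name, d_fwd + (d_rev or 0)))
    if not matches:
        return UNASSIGNED, (TOO_DISTANT if any_window else HELIX_NOT_FOUND)
    if len(matches) > 1:
        return UNASSIGNED, AMBIGUOUS
    return matches[0][0], None


# ---------------------------------------------------------------------------
# Driver over read pairs / FASTQ files
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Partition of input read pairs into constructs plus failure bookkeeping."""

    assignments: dict[str, str] = field(default_factory=dict)
    counts: Counter = field(default_factory=Counter)
    reasons: Counter = field(default_factory=Counter)
    n_total: int = 0

    @property
    def n_unassigned(self) -> int:
        return self.counts.get(UNASSIGNED, 0)

    def check_conservation(self) -> bool:
        return sum(self.counts.values()) == self.n_total

    def summary_rows(self) -> list[dict]:
        rows = []
        for name, count in sorted(self.counts.items()):
            rows.append(
                {
                    "construct": name,
                    "count": count,
                    "fraction": count / self.n_total if self.n_total else 0.0,
                }
            )
        return rows


def demux_pairs(
    pairs: Iterable[tuple[str, str, str]],
    library: LibraryDesign | Sequence[ConstructRecord],
    params: InternalDemuxParams | None = None,
    rtb_table: BarcodeTable | None = None,
    rtb_strip: int | None = None,
) -> DemuxResult:
    """Demultiplex (read_id, seq1, seq2) tuples to constructs.

    If ``rtb_table`` is given, read 1 must first match a sample barcode
    (reason ``no_rtb`` otherwise) and the barcode prefix is stripped before
    the internal search; alternatively ``rtb_strip`` removes a fixed prefix
    length.
    """
    result = DemuxResult()
    for read_id, seq1, seq2 in pairs:
        result.n_total += 1
        fwd = seq1
        if rtb_table is not None:
            sample = match_rtb(seq1, rtb_table)
            if sample == UNASSIGNED:
                result.assignments[read_id] = UNASSIGNED
                result.counts[UNASSIGNED] += 1
                result.reasons[NO_RTB] += 1
                continue
            fwd = seq1[rtb_table.barcode_length :]
        elif rtb_strip:
            fwd = seq1[rtb_strip:]
        name, reason = demux_internal(fwd, seq2, library, params)
        result.assignments[read_id] = name
        result.counts[name] += 1
        if reason is not None:
            result.reasons[reason] += 1
    return result


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (id, seq1, qual1, seq2, qual2) from paired FASTQ (.gz ok)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path1) as f1, _open_text(path2) as f2:
        for (id1, s1, q1), (_id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            rid = id1.split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            yield rid, s1, q1, s2, q2


def demux_fastq_files(
    fq1: str | Path,
    fq2: str | Path,
    library: LibraryDesign | Sequence[ConstructRecord],
    out_dir: str | Path,
    params: InternalDemuxParams | None = None,
    rtb_table: BarcodeTable | None = None,
    rtb_strip: int | None = None,
) -> DemuxResult:
    """Split paired FASTQ into per-construct paired FASTQ plus a summary TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, tuple] = {}

    def get_handles(name: str):
        if name not in handles:
            safe = name.replace("/", "_")
            handles[name] = (
                open(out_dir / f"{safe}_R1.fastq", "w"),
                open(out_dir / f"{safe}_R2.fastq", "w"),
            )
        return handles[name]

    result = DemuxResult()
    try:
        for read_id, s1, q1, s2, q2 in iter_fastq_pairs(fq1, fq2):
            result.n_total += 1
            fwd, strip = s1, 0
            if rtb_table is not None:
                sample = match_rtb(s1, rtb_table)
                if sample == UNASSIGNED:
                    result.assignments[read_id] = UNASSIGNED
                    result.counts[UNASSIGNED] += 1
                    result.reasons[NO_RTB] += 1
                    continue
                strip = rtb_table.barcode_length
                fwd = s1[strip:]
            elif rtb_strip:
                strip = rtb_strip
                fwd = s1[strip:]
            name, reason = demux_internal(fwd, s2, library, params)
            result.assignments[read_id] = name
            result.counts[name] += 1
            if reason is not None:
                result.reasons[reason] += 1
            if name != UNASSIGNED:
                h1, h2 = get_handles(name)
                h1.write(f"@{read_id}/1\n{fwd}\n+\n{q1[strip:]}\n")
                h2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()

    with (out_dir / "demux_summary.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["construct", "count", "fraction"])
        for row in result.summary_rows():
            writer.writerow([row["construct"], row["count"], f"{row['fraction']:.6f}"])
        writer.writerow([])
        writer.writerow(["failure_reason", "count", ""])
        for reason, count in sorted(result.reasons.items()):
            writer.writerow([reason, count, ""])
    return result
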