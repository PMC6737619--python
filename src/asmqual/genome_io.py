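"""Sequence and alignment I/O: FASTA reading/writing, scaffolding-gap
detection, PAF parsing, and balanced partitioning of an assembly for
parallel alignment.

All coordinates are 0-based half-open on the forward strand, matching PAF.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_GAP_LEN = 10

_GAP_RUN = re.compile(r"[Nn]+")


@dataclass
class SequenceEntry:
    """One FASTA record: a scaffold, contig, or reference chromosome.

    ``gap_intervals`` holds the scaffolding gaps — maximal runs of N/n of
    length >= the configured minimum — as sorted, non-overlapping half-open
    intervals. Gap bases are excluded from the reward denominator.
    """

    id: str
    length: int
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)
    residues: str | None = None

    @property
    def gap_bp(self) -> int:
        return sum(e - s for s, e in self.gap_intervals)


@dataclass
class AlignmentRecord:
    """One local alignment of a query scaffold against a reference
    chromosome (one PAF line). Query coordinates are always on the forward
    query strand regardless of ``strand``."""

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    strand: str  # '+' or '-'
    ref_id: str
    ref_len: int
    r_start: int
    r_end: int
    matches: int
    block_len: int

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_span(self) -> int:
        return self.r_end - self.r_start


@dataclass
class PartitionPlan:
    """Assignment of scaffolds to ``n_parts`` near-balanced partitions."""

    n_parts: int
    assignments: dict[str, int]

    def members(self, part: int) -> list[str]:
        return sorted(s for s, p in self.assignments.items() if p == part)


def detect_gaps(residues: str, min_gap_len: int = DEFAULT_MIN_GAP_LEN) -> list[tuple[int, int]]:
    """Find scaffolding gaps: maximal runs of N/n with length >= min_gap_len.

    Returns sorted half-open intervals. Characters other than N/n (including
    other IUPAC ambiguity codes) are treated as non-gap.
    """
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    return [
        (m.start(), m.end())
        for m in _GAP_RUN.finditer(residues)
        if m.end() - m.start() >= min_gap_len
    ]


def read_fasta(
    path: str | Path,
    min_gap_len: int = DEFAULT_MIN_GAP_LEN,
    keep_residues: bool = True,
) -> list[SequenceEntry]:
    """Read a (multi-)FASTA file into SequenceEntry objects, in file order.

    Raises on a missing file, a duplicate identifier, or an empty record,
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    entries: list[SequenceEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if len(residues) == 0:
            raise ValueError(f"empty FASTA record: {rec.id!r} in {path}")
        entries.append(
            SequenceEntry(
                id=rec.id,
                length=len(residues),
                gap_intervals=detect_gaps(residues, min_gap_len),
                residues=residues if keep_residues else None,
            )
        )
    return entries


def write_fasta(entries: Iterable[SequenceEntry], path: str | Path, width: int = 60) -> None:
    """Write entries (which must carry residues) as FASTA."""
    records = []
    for e in entries:
        if e.residues is None:
            raise ValueError(f"entry {e.id!r} has no residues to write")
        records.append(SeqRecord(Seq(e.residues), id=e.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (12 mandatory tab-separated columns; extras ignored).

    Malformed lines raise with the 1-based line number. A Unicode minus in
    the strand column is normalised to '-'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PAF file not found: {path}")
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: PAF line has {len(cols)} columns, expected >= 12"
                )
            try:
                qid, qlen, qs, qe = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
                strand = cols[4].replace("−", "-")
                rid, rlen, rs, re_ = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
                matches, block = int(cols[9]), int(cols[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line: {exc}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {cols[4]!r}")
            if not (0 <= qs < qe <= qlen):
                raise ValueError(
                    f"{path}:{lineno}: bad query interval [{qs},{qe}) for length {qlen}"
                )
            if not (0 <= rs < re_ <= rlen):
                raise ValueError(
                    f"{path}:{lineno}: bad reference interval [{rs},{re_}) for length {rlen}"
                )
            records.append(
                AlignmentRecord(qid, qlen, qs, qe, strand, rid, rlen, rs, re_, matches, block)
            )
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write alignment records as 12-column PAF (mapping quality fixed at 60)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.query_len, r.q_start, r.q_end, r.strand,
                        r.ref_id, r.ref_len, r.r_start, r.r_end,
                        r.matches, r.block_len, 60,
                    )
                )
                + "\n"
            )


def partition_assembly(entries: Sequence[SequenceEntry], n_parts: int = 1) -> PartitionPlan:
    """Distribute scaffolds across ``n_parts`` partitions balancing total bp.

    Greedy longest-first assignment to the currently lightest partition,
    which bounds the load spread by the longest scaffold length. Ties are
    broken deterministically (by id for scaffolds, by index for partitions).
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    order = sorted(entries, key=lambda e: (-e.length, e.id))
    heap: list[tuple[int, int]] = [(0, i) for i in range(n_parts)]
    heapq.heapify(heap)
    assignments: dict[str, int] = {}
    for e in order:
        load, idx = heapq.heappop(heap)
        assignments[e.id] = idx
        heapq.heappush(heap, (load + e.length, idx))
    return PartitionPlan(n_parts=n_parts, assignments=assignments)


def partition_reference(reference: Sequence[SequenceEntry]) -> list[list[str]]:
    """Reference partitioning: one unit per chromosome."""
    return [[e.id] for e in reference]
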