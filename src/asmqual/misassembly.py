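"""Misassembly classification.

Every pair of consecutive alignments in a scaffold's filtered chain is
examined for an inconsistency with the reference:

* translocation — the two segments align to different chromosomes;
* inversion — same chromosome, opposite strands;
* relocation — same chromosome and strand, but the segments are separated
  (or overlap) on the reference by more than the relocation threshold ``t``
  beyond what their query-side spacing explains.

Exactly one classification is made per adjacent pair, with precedence
translocation > inversion > relocation: the three types are disjoint
readings of a single breakpoint.

The relocation distance is, by default, d = (reference separation) -
(query separation): a joint whose reference distance is fully explained by
its query-side spacing (e.g. an N-gap joint spanning true genomic
distance) is not penalised. ``query_aware=False`` switches to the raw
reference separation. Reference separation is measured strand-consistently:
for a '-' strand pair the reference runs in descending order along the
query.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .align_filter import FilteredChain
from .genome_io import AlignmentRecord

DEFAULT_RELOCATION_THRESHOLD = 1000


class MisassemblyType(enum.Enum):
    NONE = "none"
    RELOCATION = "relocation"
    TRANSLOCATION = "translocation"
    INVERSION = "inversion"


@dataclass
class MisassemblyCount:
    """Per-scaffold misassembly tally m_s and the assigned chromosome
    (the reference chromosome receiving the most aligned query bases)."""

    query_id: str
    n_relocation: int = 0
    n_translocation: int = 0
    n_inversion: int = 0
    assigned_chrom: str | None = None

    @property
    def m_total(self) -> int:
        return self.n_relocation + self.n_translocation + self.n_inversion


def relocation_distance(a: AlignmentRecord, b: AlignmentRecord, query_aware: bool = True) -> int:
    """Signed relocation distance d between consecutive same-chromosome,
    same-strand alignments a then b (query order)."""
    query_sep = b.q_start - a.q_end
    if a.strand == "+":
        ref_sep = b.r_start - a.r_end
    else:
        ref_sep = a.r_start - b.r_end
    return ref_sep - query_sep if query_aware else ref_sep


def classify_pair(
    a: AlignmentRecord,
    b: AlignmentRecord,
    t: int = DEFAULT_RELOCATION_THRESHOLD,
    query_aware: bool = True,
) -> MisassemblyType:
    """Classify the breakpoint between consecutive alignments a, b.

    ``t`` is the relocation threshold in bp (default 1000): a distance or
    overlap of at most t is not a relocation.
    """
    if t < 1:
        raise ValueError("relocation threshold t must be >= 1")
    if a.ref_id != b.ref_id:
        return MisassemblyType.TRANSLOCATION
    if a.strand != b.strand:
        return MisassemblyType.INVERSION
    d = relocation_distance(a, b, query_aware=query_aware)
    if abs(d) > t:
        return MisassemblyType.RELOCATION
    return MisassemblyType.NONE


def count_misassemblies(
    chain: FilteredChain,
    t: int = DEFAULT_RELOCATION_THRESHOLD,
    query_aware: bool = True,
) -> MisassemblyCount:
    """Tally misassemblies over all adjacent pairs of a filtered chain.

    Empty and singleton chains have no adjacent pairs, hence zero counts.
    The assigned chromosome is the argmax of per-chromosome aligned bases
    (ties broken by lexicographically smallest id).
    """
    count = MisassemblyCount(query_id=chain.query_id)
    if chain.per_ref_aligned_bp:
        count.assigned_chrom = min(
            chain.per_ref_aligned_bp, key=lambda rid: (-chain.per_ref_aligned_bp[rid], rid)
        )
    for a, b in zip(chain.alignments, chain.alignments[1:]):
        cls = classify_pair(a, b, t=t, query_aware=query_aware)
        if cls is MisassemblyType.RELOCATION:
            count.n_relocation += 1
        elif cls is MisassemblyType.TRANSLOCATION:
            count.n_translocation += 1
        elif cls is MisassemblyType.INVERSION:
            count.n_inversion += 1
    return count


def pair_events(
    chain: FilteredChain,
    t: int = DEFAULT_RELOCATION_THRESHOLD,
    query_aware: bool = True,
) -> list[dict]:
    """Per-junction diagnostic rows (one per adjacent pair) for the
    events TSV: classification, relocation distance, flanking reference ids."""
    rows = []
    for i, (a, b) in enumerate(zip(chain.alignments, chain.alignments[1:])):
        cls = classify_pair(a, b, t=t, query_aware=query_aware)
        d = (
            relocation_distance(a, b, query_aware=query_aware)
            if a.ref_id == b.ref_id and a.strand == b.strand
            else None
        )
        rows.append(
            {
                "query_id": chain.query_id,
                "pair_index": i,
                "class": cls.value,
                "d": d,
                "ref_a": a.ref_id,
                "ref_b": b.ref_id,
            }
        )
    return rows
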