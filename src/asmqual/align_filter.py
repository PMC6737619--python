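"""Alignment chain filtering.

Raw scaffold-to-reference alignments are redundant: repeats produce many
overlapping hits for the same stretch of query sequence. Before
misassembly counting and reward computation, each scaffold's alignments
are reduced to the best consistent query-ordered chain, in the spirit of
MUMmer's delta-filter query-axis mode: a maximum-total-weight subset
(weight = exact matches) in which any two retained alignments overlap on
the query by at most ``overlap_frac`` of the shorter alignment's query
span, and no retained alignment is contained in another retained
alignment's query interval.

Crucially the filter imposes NO constraint on reference coordinates or
strand: translocations and inversions must survive filtering so the
misassembly classifier can see them.

The optimum is found by dynamic programming over alignments sorted by
query end. Because containment between retained alignments is forbidden,
query starts are nondecreasing along any valid chain, so pairwise
compatibility of consecutive chain members implies compatibility of every
pair; the DP over immediate predecessors is therefore exact (a brute-force
subset oracle confirms this in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import AlignmentRecord

DEFAULT_OVERLAP_FRAC = 0.5


@dataclass
class FilteredChain:
    """The filtered, query-ordered alignment set for one scaffold.

    ``total_aligned_query_bp`` is the exact size of the union of retained
    query intervals (no double counting); ``per_ref_aligned_bp`` maps each
    reference chromosome to the union size of this scaffold's retained
    reference intervals on it (within-scaffold overlaps counted once).
    """

    query_id: str
    query_len: int = 0
    alignments: list[AlignmentRecord] = field(default_factory=list)
    total_aligned_query_bp: int = 0
    per_ref_aligned_bp: dict[str, int] = field(default_factory=dict)

    @property
    def total_weight(self) -> int:
        return sum(a.matches for a in self.alignments)

    @property
    def aligned_ref_bp(self) -> int:
        return sum(self.per_ref_aligned_bp.values())


def interval_union_size(intervals: list[tuple[int, int]]) -> int:
    """Size of the union of half-open intervals."""
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        elif e > cur_end:
            cur_end = e
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def _contained(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    """True if a's query interval lies within b's."""
    return b.q_start <= a.q_start and a.q_end <= b.q_end


def _compatible(a: AlignmentRecord, b: AlignmentRecord, overlap_frac: float) -> bool:
    """May a and b be retained together? No containment either way, and the
    query overlap must not exceed overlap_frac x the shorter query span."""
    if _contained(a, b) or _contained(b, a):
        return False
    overlap = min(a.q_end, b.q_end) - max(a.q_start, b.q_start)
    if overlap <= 0:
        return True
    return overlap <= overlap_frac * min(a.q_span, b.q_span)


def resolve_residual_overlaps(chain: FilteredChain) -> FilteredChain:
    """Recompute the chain's aligned-base tallies as exact interval unions.

    Query bases covered by more than one retained alignment are counted
    once, and reference bases likewise per chromosome, so downstream reward
    and redundancy computations never double count.
    """
    chain.total_aligned_query_bp = interval_union_size(
        [(a.q_start, a.q_end) for a in chain.alignments]
    )
    per_ref: dict[str, list[tuple[int, int]]] = {}
    for a in chain.alignments:
        per_ref.setdefault(a.ref_id, []).append((a.r_start, a.r_end))
    chain.per_ref_aligned_bp = {
        rid: interval_union_size(ivs) for rid, ivs in sorted(per_ref.items())
    }
    return chain


def filter_chain(
    records: list[AlignmentRecord],
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    query_len: int | None = None,
) -> FilteredChain:
    """Reduce one scaffold's alignments to its best consistent chain.

    Parameters
    ----------
    records
        All raw alignments for a single scaffold (same query_id).
    overlap_frac
        Maximum allowed pairwise query overlap as a fraction of the shorter
        alignment's query span. Default 0.5.
    query_len
        Scaffold length; inferred from the records when omitted.

    Returns an empty chain for an unaligned scaffold.
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    if not records:
        return FilteredChain(query_id="", query_len=query_len or 0)
    qids = {r.query_id for r in records}
    if len(qids) > 1:
        raise ValueError(f"filter_chain got mixed query ids: {sorted(qids)}")
    qlen = query_len if query_len is not None else records[0].query_len

    # Deterministic processing order; DP over predecessors.
    order = sorted(
        records, key=lambda r: (r.q_end, r.q_start, r.ref_id, r.r_start, r.strand)
    )
    n = len(order)
    # best[i]: (total weight, total aligned query bp) of the best chain ending at i
    best: list[tuple[int, int]] = [(0, 0)] * n
    pred: list[int] = [-1] * n
    for i, ri in enumerate(order):
        best[i] = (ri.matches, ri.q_span)
        for j in range(i):
            if not _compatible(order[j], ri, overlap_frac):
                continue
            gain = ri.q_end - max(ri.q_start, order[j].q_end)
            cand = (best[j][0] + ri.matches, best[j][1] + max(gain, 0))
            if cand > best[i]:
                best[i] = cand
                pred[i] = j
    end = max(range(n), key=lambda i: best[i])
    kept: list[AlignmentRecord] = []
    while end != -1:
        kept.append(order[end])
        end = pred[end]
    kept.sort(key=lambda r: (r.q_start, r.q_end, r.ref_id, r.r_start))
    chain = FilteredChain(query_id=order[0].query_id, query_len=qlen, alignments=kept)
    return resolve_residual_overlaps(chain)


def group_by_query(records: list[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    """Bucket alignment records by scaffold id."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        groups.setdefault(r.query_id, []).append(r)
    return groups
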