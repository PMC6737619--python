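"""Synthetic references and assemblies with ground-truth alignments.

Every stage of the scorer is testable without downloads or an external
aligner: a toy reference is generated as random nucleotide sequence, and
assemblies are sampled from it under four designs that each stress one
component of the quality score —

* mean_length — scaffold lengths drawn from a normal distribution at a
  chosen mean/SD, 1X coverage (length scaling L);
* misassembly — a fixed number of misassembly events planted per scaffold
  (penalty P);
* coverage — fractional 1X-style sampling of the genome (Omega);
* redundancy — the genome covered N times over (Pi).

Scaffold sequences are copied verbatim from the reference, so each
scaffold's true placement is known exactly and is emitted as truth PAF;
an optional per-base substitution rate exists for aligner-in-the-loop
tests only. Scaffolds are drawn as a random disjoint tiling of each
chromosome (tiles subsampled to the requested coverage fraction), so the
stated identities hold: covered fraction ~= coverage_fold at truth
alignments, and inverted redundancy ~= 1/fold for fold-replicated
assemblies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import AlignmentRecord, SequenceEntry, detect_gaps, write_fasta, write_paf

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DESIGNS = ("mean_length", "misassembly", "coverage", "redundancy")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic assembly design."""

    design: str
    mean_len: int = 10_000
    sd_len: int = 100
    misassemblies_per_scaffold: int = 0
    coverage_fold: float = 1.0
    redundancy_fold: int = 1
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SyntheticAssembly:
    """A generated assembly with its ground-truth alignments."""

    scaffolds: list[SequenceEntry] = field(default_factory=list)
    truth: list[AlignmentRecord] = field(default_factory=list)

    def write(self, fasta_path: str | Path, paf_path: str | Path) -> None:
        write_fasta(self.scaffolds, fasta_path)
        write_paf(self.truth, paf_path)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def generate_reference(
    n_chrom: int = 5,
    chrom_lengths: list[int] | None = None,
    gc: float = 0.41,
    seed: int = 0,
) -> list[SequenceEntry]:
    """Random nucleotide reference; the shortest chromosome defines theta_G.

    Base composition is i.i.d. with the requested GC fraction (default 0.41,
    mammalian-like). Deterministic given the seed.
    """
    if chrom_lengths is None:
        chrom_lengths = [500_000] * n_chrom
    if len(chrom_lengths) != n_chrom:
        raise ValueError("chrom_lengths must have n_chrom entries")
    if any(length < 1000 for length in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1000")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    entries = []
    for i, length in enumerate(chrom_lengths):
        residues = "".join(rng.choice(bases, size=length, p=probs))
        entries.append(
            SequenceEntry(id=f"chr{i + 1}", length=length, gap_intervals=[], residues=residues)
        )
    return entries


def _truncated_normal_len(rng: np.random.Generator, mean: float, sd: float, upper: int) -> int:
    """One scaffold length ~ N(mean, sd) truncated to [1, upper]."""
    if sd <= 0:
        return int(min(max(round(mean), 1), upper))
    return int(min(max(round(rng.normal(mean, sd)), 1), upper))


def _tile_chromosome(
    rng: np.random.Generator, chrom_len: int, mean: float, sd: float
) -> list[tuple[int, int]]:
    """Random disjoint tiling of [0, chrom_len) with lengths ~ N(mean, sd)."""
    tiles: list[tuple[int, int]] = []
    pos = 0
    while pos < chrom_len:
        length = _truncated_normal_len(rng, mean, sd, chrom_len - pos)
        tiles.append((pos, pos + length))
        pos += length
    return tiles


def sample_scaffolds(
    reference: list[SequenceEntry],
    mean_len: int,
    sd_len: int,
    coverage_fold: float = 1.0,
    seed: int = 0,
    name_prefix: str = "scf",
    error_rate: float = 0.0,
) -> SyntheticAssembly:
    """Sample scaffolds covering the reference at ``coverage_fold`` <= 1X.

    Each chromosome is tiled by disjoint intervals with lengths drawn from
    a normal distribution truncated at [1, remaining chromosome length];
    for fractional coverage a random subset of tiles is kept until the
    sampled bases reach coverage_fold x the reference length (within one
    scaffold length). One truth PAF record is emitted per scaffold.
    ``error_rate`` introduces i.i.d. substitutions for aligner-in-the-loop
    tests; truth coordinates are unchanged.
    """
    if not 0 < coverage_fold <= 1.0:
        raise ValueError("coverage_fold must be in (0, 1]")
    shortest = min(e.length for e in reference)
    if mean_len >= shortest:
        raise ValueError("mean_len must be smaller than the shortest chromosome")
    rng = np.random.default_rng(seed)
    tiles: list[tuple[SequenceEntry, int, int]] = []
    for chrom in reference:
        for s, e in _tile_chromosome(rng, chrom.length, mean_len, sd_len):
            tiles.append((chrom, s, e))
    order = rng.permutation(len(tiles))
    target = coverage_fold * sum(e.length for e in reference)
    assembly = SyntheticAssembly()
    total = 0
    for idx in order:
        if total >= target:
            break
        chrom, s, e = tiles[idx]
        total += e - s
        sid = f"{name_prefix}_{len(assembly.scaffolds):05d}"
        residues = chrom.residues[s:e]
        if error_rate > 0:
            residues = _mutate(rng, residues, error_rate)
        length = e - s
        assembly.scaffolds.append(
            SequenceEntry(id=sid, length=length, gap_intervals=[], residues=residues)
        )
        assembly.truth.append(
            AlignmentRecord(sid, length, 0, length, "+", chrom.id, chrom.length, s, e, length, length)
        )
    return assembly


def _mutate(rng: np.random.Generator, residues: str, rate: float) -> str:
    arr = np.array(list(residues))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i].upper()]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def tile_reference(reference: list[SequenceEntry], name_prefix: str = "tile") -> SyntheticAssembly:
    """The degenerate perfect assembly: one scaffold per chromosome, each a
    verbatim copy with a full-length truth alignment."""
    assembly = SyntheticAssembly()
    for i, chrom in enumerate(reference):
        sid = f"{name_prefix}_{i:03d}"
        assembly.scaffolds.append(
            SequenceEntry(
                id=sid,
                length=chrom.length,
                gap_intervals=list(chrom.gap_intervals),
                residues=chrom.residues,
            )
        )
        assembly.truth.append(
            AlignmentRecord(
                sid, chrom.length, 0, chrom.length, "+", chrom.id, chrom.length,
                0, chrom.length, chrom.length, chrom.length,
            )
        )
    return assembly


def _split_lengths(rng: np.random.Generator, total: int, parts: int, min_seg: int) -> list[int]:
    """Split ``total`` into ``parts`` segment lengths, each >= min_seg."""
    if parts * min_seg > total:
        raise ValueError(f"scaffold of {total} bp too short for {parts} segments of >= {min_seg} bp")
    slack = total - parts * min_seg
    if slack == 0:
        return [min_seg] * parts
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [slack])))
    return [min_seg + int(p) for p in pieces]


def plant_misassemblies(
    reference: list[SequenceEntry],
    scaffold: SequenceEntry,
    truth: AlignmentRecord,
    k: int,
    seed: int = 0,
    t: int = 1000,
    min_seg: int = 1000,
) -> tuple[SequenceEntry, list[AlignmentRecord]]:
    """Rebuild a scaffold so its truth chain carries exactly ``k`` planted
    misassembly events (uniform mix of relocation, translocation, inversion).

    The scaffold becomes a concatenation of k+1 reference segments, each
    adjacent pair violating collinearity by exactly one event: relocations
    shift the reference position by an offset with |d| in (t, 10t],
    translocations jump to a different chromosome, inversions flip strand.
    Truth PAF gains one record per segment. Requires a scaffold of at
    least (k+1) x min_seg bp and, for translocations, > 1 chromosome.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return scaffold, [truth]
    rng = np.random.default_rng(seed)
    chrom_by_id = {c.id: c for c in reference}
    seg_lens = _split_lengths(rng, scaffold.length, k + 1, min_seg)
    event_types = ["relocation", "translocation", "inversion"]
    if len(reference) < 2:
        event_types.remove("translocation")

    cur_chrom = chrom_by_id[truth.ref_id]
    cur_strand = "+"
    # place the first segment at the scaffold's original locus
    seg_start = min(truth.r_start, cur_chrom.length - seg_lens[0])
    placements: list[tuple[SequenceEntry, int, int, str]] = [
        (cur_chrom, seg_start, seg_start + seg_lens[0], cur_strand)
    ]
    for seg_len in seg_lens[1:]:
        prev_chrom, prev_s, prev_e, prev_strand = placements[-1]
        event = event_types[int(rng.integers(len(event_types)))]
        if event == "translocation":
            others = [c for c in reference if c.id != prev_chrom.id and c.length > seg_len]
            chrom = others[int(rng.integers(len(others)))]
            start = int(rng.integers(0, chrom.length - seg_len + 1))
            placements.append((chrom, start, start + seg_len, prev_strand))
        elif event == "inversion":
            chrom = prev_chrom
            strand = "-" if prev_strand == "+" else "+"
            start = int(rng.integers(0, chrom.length - seg_len + 1))
            placements.append((chrom, start, start + seg_len, strand))
        else:  # relocation: same chromosome & strand, |d| in (t, 10t]
            chrom = prev_chrom
            delta = int(rng.integers(t + 1, 10 * t + 1))
            if rng.random() < 0.5:
                delta = -delta
            # query gap between consecutive segments is 0, so d = ref separation
            if prev_strand == "+":
                start = prev_e + delta
            else:
                start = prev_s - delta - seg_len
            if not (0 <= start <= chrom.length - seg_len):
                delta = -delta
                start = prev_e + delta if prev_strand == "+" else prev_s - delta - seg_len
            if not (0 <= start <= chrom.length - seg_len):
                # no room for a local offset on either side (segment near a
                # chromosome edge): any placement with |d| > t still reads as
                # a relocation, so draw starts until the distance qualifies
                for _ in range(1000):
                    start = int(rng.integers(0, chrom.length - seg_len + 1))
                    d = (start - prev_e) if prev_strand == "+" else (prev_s - (start + seg_len))
                    if abs(d) > t:
                        break
                else:
                    raise ValueError(
                        f"chromosome {chrom.id!r} too short to place a relocation beyond t={t}"
                    )
            placements.append((chrom, start, start + seg_len, prev_strand))

    residues_parts: list[str] = []
    records: list[AlignmentRecord] = []
    q_pos = 0
    for chrom, s, e, strand in placements:
        seg = chrom.residues[s:e]
        residues_parts.append(seg if strand == "+" else reverse_complement(seg))
        length = e - s
        records.append(
            AlignmentRecord(
                scaffold.id, scaffold.length, q_pos, q_pos + length, strand,
                chrom.id, chrom.length, s, e, length, length,
            )
        )
        q_pos += length
    residues = "".join(residues_parts)
    new_scaffold = SequenceEntry(
        id=scaffold.id,
        length=len(residues),
        gap_intervals=detect_gaps(residues),
        residues=residues,
    )
    return new_scaffold, records


def replicate_redundancy(
    reference: list[SequenceEntry],
    mean_len: int,
    sd_len: int,
    fold: int,
    seed: int = 0,
    name_prefix: str = "red",
) -> SyntheticAssembly:
    """Concatenate ``fold`` independent 1X samplings: under truth alignments
    the inverted redundancy ratio is ~= 1/fold."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    ss = np.random.SeedSequence(seed)
    assembly = SyntheticAssembly()
    for copy, child in enumerate(ss.spawn(fold)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub = sample_scaffolds(
            reference, mean_len, sd_len, coverage_fold=1.0, seed=sub_seed,
            name_prefix=f"{name_prefix}{copy}",
        )
        assembly.scaffolds.extend(sub.scaffolds)
        assembly.truth.extend(sub.truth)
    return assembly


def duplicate_assembly(assembly: SyntheticAssembly, copies: int) -> SyntheticAssembly:
    """Exact k-fold duplication (renamed scaffolds, identical truth
    intervals): inverted redundancy is exactly 1/copies."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    out = SyntheticAssembly()
    for c in range(copies):
        for scf, rec in zip(assembly.scaffolds, assembly.truth):
            sid = scf.id if c == 0 else f"{scf.id}_dup{c}"
            out.scaffolds.append(
                SequenceEntry(sid, scf.length, list(scf.gap_intervals), scf.residues)
            )
            out.truth.append(
                AlignmentRecord(
                    sid, rec.query_len, rec.q_start, rec.q_end, rec.strand,
                    rec.ref_id, rec.ref_len, rec.r_start, rec.r_end,
                    rec.matches, rec.block_len,
                )
            )
    return out


def generate_assembly(
    reference: list[SequenceEntry], spec: SyntheticSpec
) -> SyntheticAssembly:
    """Build one assembly replicate for a design spec."""
    if spec.design == "mean_length":
        return sample_scaffolds(
            reference, spec.mean_len, spec.sd_len, coverage_fold=1.0, seed=spec.seed
        )
    if spec.design == "coverage":
        return sample_scaffolds(
            reference, spec.mean_len, spec.sd_len,
            coverage_fold=spec.coverage_fold, seed=spec.seed,
        )
    if spec.design == "redundancy":
        return replicate_redundancy(
            reference, spec.mean_len, spec.sd_len, spec.redundancy_fold, seed=spec.seed
        )
    # misassembly design: 1X sampling, then plant k events per scaffold
    k = spec.misassemblies_per_scaffold
    min_seg = 1000
    base = sample_scaffolds(
        reference, spec.mean_len, spec.sd_len, coverage_fold=1.0, seed=spec.seed
    )
    ss = np.random.SeedSequence(spec.seed + 1)
    out = SyntheticAssembly()
    for scf, rec, child in zip(base.scaffolds, base.truth, ss.spawn(len(base.scaffolds))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        if scf.length >= (k + 1) * min_seg:
            new_scf, new_recs = plant_misassemblies(
                reference, scf, rec, k, seed=sub_seed, min_seg=min_seg
            )
        else:  # tile too short to carry k events; keep it un-misassembled
            new_scf, new_recs = scf, [rec]
        out.scaffolds.append(new_scf)
        out.truth.extend(new_recs)
    return out


def write_manifest(spec: SyntheticSpec, path: str | Path, extra: dict | None = None) -> None:
    """JSON manifest of the generation parameters and seeds."""
    payload = {
        "design": spec.design,
        "mean_len": spec.mean_len,
        "sd_len": spec.sd_len,
        "misassemblies_per_scaffold": spec.misassemblies_per_scaffold,
        "coverage_fold": spec.coverage_fold,
        "redundancy_fold": spec.redundancy_fold,
        "seed": spec.seed,
        "replicates": spec.replicates,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
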