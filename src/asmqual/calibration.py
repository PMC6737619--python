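"""Expected-artifact calibration.

Even a perfect sequence accrues apparent misassemblies when aligned back
to its own reference: repeats, ambiguous bases and aligner limitations
fragment the alignment. To avoid penalising scaffolds for these
artifacts, the expected artifact count for a scaffold of length l scored
at relocation threshold t is modelled per reference chromosome c as

    epsilon = alpha_c * l + beta_c * t + k_c

fit by ordinary least squares. Observations come from self-alignment:
each chromosome is cut into random contiguous fragments covering it at
exactly 1X; the fragments (plus the whole chromosome itself, when an
external aligner is in the loop) are aligned back to the whole reference,
and the misassembly count of each fragment's filtered chain is recorded
for every threshold on a fixed grid (100..10,000 bp, step 100).

At scoring time the prediction is clamped below at zero, and an unknown
chromosome receives zero expected artifact (conservative: no credit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align_filter import FilteredChain
from .genome_io import AlignmentRecord, SequenceEntry
from .misassembly import count_misassemblies

T_GRID_DEFAULT: tuple[int, ...] = tuple(range(100, 10001, 100))
DEFAULT_FRAGMENT_MIN_LEN = 50_000
DEFAULT_FRAGMENT_MAX_LEN = 1_000_000


@dataclass
class ArtifactObservation:
    """One calibration data point: a fragment of a chromosome, a relocation
    threshold, and the misassembly count observed for its filtered chain."""

    chrom: str
    fragment_len: int
    threshold: int
    artifact: int


@dataclass
class ArtifactModel:
    """Per-chromosome (alpha, beta, intercept) of the artifact regression."""

    coefficients: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\talpha\tbeta\tintercept\n")
            for chrom in sorted(self.coefficients):
                a, b, k = self.coefficients[chrom]
                fh.write(f"{chrom}\t{a:.12g}\t{b:.12g}\t{k:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArtifactModel":
        coef: dict[str, tuple[float, float, float]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"unexpected calibration header in {path}: {header!r}")
            for line in fh:
                chrom, a, b, k = line.rstrip("\n").split("\t")
                coef[chrom] = (float(a), float(b), float(k))
        return cls(coefficients=coef)

    @classmethod
    def zero(cls) -> "ArtifactModel":
        """Model granting no artifact credit anywhere (epsilon_s = 0)."""
        return cls(coefficients={})


def fragment_chromosome(
    chrom: SequenceEntry,
    seed: int,
    min_len: int = DEFAULT_FRAGMENT_MIN_LEN,
    max_len: int = DEFAULT_FRAGMENT_MAX_LEN,
) -> list[tuple[int, int]]:
    """Cut a chromosome into contiguous random fragments covering it at 1X.

    Fragment lengths are uniform in [min_len, max_len] except possibly the
    last, which absorbs the remainder. Deterministic given the seed. A
    chromosome shorter than min_len yields a single fragment.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    rng = np.random.default_rng(seed)
    fragments: list[tuple[int, int]] = []
    pos = 0
    while pos < chrom.length:
        length = int(rng.integers(min_len, max_len + 1))
        end = min(pos + length, chrom.length)
        fragments.append((pos, end))
        pos = end
    return fragments


def truth_fragment_chain(chrom: SequenceEntry, start: int, end: int, fragment_id: str) -> FilteredChain:
    """Perfect single-alignment chain for a fragment, used when calibration
    runs in truth mode (no external aligner)."""
    length = end - start
    rec = AlignmentRecord(
        query_id=fragment_id,
        query_len=length,
        q_start=0,
        q_end=length,
        strand="+",
        ref_id=chrom.id,
        ref_len=chrom.length,
        r_start=start,
        r_end=end,
        matches=length,
        block_len=length,
    )
    return FilteredChain(
        query_id=fragment_id,
        query_len=length,
        alignments=[rec],
        total_aligned_query_bp=length,
        per_ref_aligned_bp={chrom.id: length},
    )


def artifact_observations(
    chains: list[FilteredChain],
    t_grid: tuple[int, ...] = T_GRID_DEFAULT,
    chrom_of: dict[str, str] | None = None,
) -> list[ArtifactObservation]:
    """Evaluate each fragment chain at every threshold of the grid.

    The alignment (and filtering) is done once per fragment; only the
    relocation classification is re-evaluated per threshold. A fragment
    with an empty chain contributes zero artifacts with a warning. The
    fragment's chromosome is the chain's assigned chromosome unless
    overridden via ``chrom_of`` (fragment id -> chromosome).
    """
    obs: list[ArtifactObservation] = []
    for chain in chains:
        if not chain.alignments:
            warnings.warn(
                f"fragment {chain.query_id!r} has no alignments; recording zero artifacts",
                stacklevel=2,
            )
        for t in t_grid:
            count = count_misassemblies(chain, t=t)
            chrom = None
            if chrom_of is not None:
                chrom = chrom_of.get(chain.query_id)
            if chrom is None:
                chrom = count.assigned_chrom or "unplaced"
            obs.append(
                ArtifactObservation(
                    chrom=chrom,
                    fragment_len=chain.query_len,
                    threshold=t,
                    artifact=count.m_total,
                )
            )
    return obs


def fit_artifact_model(observations: list[ArtifactObservation]) -> ArtifactModel:
    """Per-chromosome OLS of the artifact count on (fragment length,
    threshold, 1). A rank-deficient design (e.g. collinear l and t, or a
    single fragment) falls back to an intercept-only fit with a warning."""
    by_chrom: dict[str, list[ArtifactObservation]] = {}
    for o in observations:
        by_chrom.setdefault(o.chrom, []).append(o)
    coef: dict[str, tuple[float, float, float]] = {}
    for chrom, rows in sorted(by_chrom.items()):
        X = np.array([[o.fragment_len, o.threshold, 1.0] for o in rows], dtype=float)
        y = np.array([o.artifact for o in rows], dtype=float)
        if len(rows) < 3 or np.linalg.matrix_rank(X) < 3:
            warnings.warn(
                f"rank-deficient calibration design for {chrom!r}; using intercept-only fit",
                stacklevel=2,
            )
            coef[chrom] = (0.0, 0.0, float(y.mean()) if len(y) else 0.0)
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coef[chrom] = (float(beta[0]), float(beta[1]), float(beta[2]))
    return ArtifactModel(coefficients=coef)


def expected_artifact(model: ArtifactModel, chrom: str | None, l_s: int, t_u: int) -> float:
    """Predicted artifact count for a scaffold, clamped below at zero.

    An unknown (or unassigned) chromosome yields zero with a warning: the
    scaffold receives no artifact credit rather than an extrapolated one.
    """
    if chrom is None or chrom not in model.coefficients:
        if model.coefficients:  # an intentionally empty model stays silent
            warnings.warn(
                f"no artifact model for chromosome {chrom!r}; expected artifact set to 0",
                stacklevel=2,
            )
        return 0.0
    alpha, beta, k = model.coefficients[chrom]
    return max(0.0, alpha * l_s + beta * t_u + k)


def calibrate_truth(
    reference: list[SequenceEntry],
    seed: int,
    t_grid: tuple[int, ...] = T_GRID_DEFAULT,
    min_len: int = DEFAULT_FRAGMENT_MIN_LEN,
    max_len: int = DEFAULT_FRAGMENT_MAX_LEN,
) -> ArtifactModel:
    """Calibrate against truth self-alignments (no external aligner): each
    fragment's chain is its perfect placement, so fitted coefficients are
    near zero. Fragment seeds are derived per chromosome from ``seed``."""
    chains: list[FilteredChain] = []
    chrom_of: dict[str, str] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(reference))
    for chrom, child in zip(reference, child_seeds):
        frag_seed = int(child.generate_state(1)[0] % (2**31))
        for i, (s, e) in enumerate(fragment_chromosome(chrom, frag_seed, min_len, max_len)):
            fid = f"{chrom.id}_frag{i:04d}"
            chains.append(truth_fragment_chain(chrom, s, e, fid))
            chrom_of[fid] = chrom.id
    obs = artifact_observations(chains, t_grid=t_grid, chrom_of=chrom_of)
    return fit_artifact_model(obs)
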