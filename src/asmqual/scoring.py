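"""Quality scoring for scaffolds and whole assemblies.

Per-scaffold score
------------------
A scaffold s of length l_s with filtered chain lambda gets

    Q(s) = L(s) * R(s) / (1 + P(s))

where

* R(s) (reward) is the fraction of the scaffold's non-gap bases that
  align to the reference: aligned bp / (l_s - scaffolding-gap bp);
* P(s) (penalty) is log base 100 of (m_s - epsilon_s) when that excess of
  observed misassemblies m_s over the calibrated artifact expectation
  epsilon_s exceeds 1, else 0;
* L(s) (length scaling) is 1 for scaffolds at least as long as the
  shortest reference chromosome theta_G, and -1/(log10(l_s/theta_G) - 1)
  otherwise — a gentle ramp that avoids punishing mid-sized scaffolds as
  harshly as the raw length ratio would.

Assembly score
--------------
Three components, each in [0, 1], are combined as a geometric mean:

    Q(A) = (Delta_A * Omega_A * Pi_A)^(1/3)

* Delta_A: area under the curve of the assembly base-pair fraction held
  in scaffolds with Q(s) >= q, over q = 0.00..1.00 step 0.01;
* Omega_A: area under the curve of reference coverage (union of reference
  intervals, over the total reference length including ambiguous bases)
  by scaffolds with Q(s) >= q;
* Pi_A (inverted redundancy): Phi_A / sum(lambda_i), the union of covered
  reference bases over the summed per-scaffold aligned reference bases —
  1 when nothing is assembled twice, 1/k when a region is assembled k
  times.

Areas are trapezoidal on the 101-point grid, which is exact for these
step functions up to the grid resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align_filter import FilteredChain, interval_union_size
from .genome_io import SequenceEntry

QUALITY_GRID: np.ndarray = np.arange(101) / 100.0


@dataclass
class ScaffoldScore:
    """Per-scaffold quality score and its supporting tallies."""

    query_id: str
    l_s: int
    reward: float
    penalty: float
    length_scaling: float
    quality: float
    m_s: int = 0
    epsilon_s: float = 0.0
    assigned_chrom: str | None = None
    aligned_query_bp: int = 0
    aligned_ref_bp: int = 0


@dataclass
class AssemblyScore:
    """Consolidated assembly quality and its three components."""

    delta: float
    omega: float
    pi: float
    quality: float
    quality_curve: list[tuple[float, float]] = field(default_factory=list)
    coverage_curve: list[tuple[float, float]] = field(default_factory=list)
    phi: int = 0
    sum_lambda: int = 0
    theta_g: int = 0


def reward(scaffold: SequenceEntry, chain: FilteredChain) -> float:
    """Aligned fraction of the scaffold's non-gap bases, clamped to <= 1.

    Scaffolding-gap bases are excluded from the denominator so a scaffold
    is not docked for the Ns it honestly declares. An all-gap scaffold
    (zero denominator) scores 0 with a warning.
    """
    denom = scaffold.length - scaffold.gap_bp
    if denom <= 0:
        warnings.warn(
            f"scaffold {scaffold.id!r} has no non-gap bases; reward set to 0",
            stacklevel=2,
        )
        return 0.0
    return min(1.0, chain.total_aligned_query_bp / denom)


def penalty(m_s: int, epsilon_s: float) -> float:
    """log base 100 of the excess misassemblies m_s - epsilon_s, or 0 when
    the excess is at most 1 (no penalty for artifact-level counts)."""
    excess = m_s - epsilon_s
    if excess <= 1.0:
        return 0.0
    return math.log(excess, 100)


def length_scaling(l_s: int, theta_g: int) -> float:
    """Length-scaling coefficient L(s) against the shortest reference
    chromosome length theta_G: 1 when l_s >= theta_G, else
    -1/(log10(l_s/theta_G) - 1), which rises from 0 towards 1."""
    if l_s < 1 or theta_g < 1:
        raise ValueError("lengths must be >= 1")
    if l_s >= theta_g:
        return 1.0
    return -1.0 / (math.log10(l_s / theta_g) - 1.0)


def scaffold_quality(r: float, p: float, length_coef: float) -> float:
    """Q(s) = L(s) * R(s) / (1 + P(s))."""
    return length_coef * r / (1.0 + p)


def score_scaffold(
    scaffold: SequenceEntry,
    chain: FilteredChain,
    theta_g: int,
    m_s: int = 0,
    epsilon_s: float = 0.0,
    assigned_chrom: str | None = None,
) -> ScaffoldScore:
    """Assemble the full per-scaffold score record from its components."""
    r = reward(scaffold, chain)
    p = penalty(m_s, epsilon_s)
    length_coef = length_scaling(scaffold.length, theta_g)
    return ScaffoldScore(
        query_id=scaffold.id,
        l_s=scaffold.length,
        reward=r,
        penalty=p,
        length_scaling=length_coef,
        quality=scaffold_quality(r, p, length_coef),
        m_s=m_s,
        epsilon_s=epsilon_s,
        assigned_chrom=assigned_chrom,
        aligned_query_bp=chain.total_aligned_query_bp,
        aligned_ref_bp=chain.aligned_ref_bp,
    )


def quality_curve_area(scores: list[ScaffoldScore]) -> tuple[float, list[tuple[float, float]]]:
    """Cumulative quality-distribution curve and its area Delta_A.

    At each threshold q on the 0.00..1.00 grid the curve holds the fraction
    of total assembly base pairs in scaffolds with Q(s) >= q; unaligned
    scaffolds count in the denominator only.
    """
    if not scores:
        raise ValueError("quality_curve_area requires at least one scaffold")
    total_bp = sum(s.l_s for s in scores)
    values = [
        sum(s.l_s for s in scores if s.quality >= q) / total_bp for q in QUALITY_GRID
    ]
    delta = float(np.trapezoid(values, QUALITY_GRID))
    return delta, list(zip(QUALITY_GRID.tolist(), values))


def coverage_curve_area(
    scores: list[ScaffoldScore],
    chains: dict[str, FilteredChain],
    reference: list[SequenceEntry],
) -> tuple[float, list[tuple[float, float]], int]:
    """Cumulative genome-coverage curve, its area Omega_A, and Phi_A.

    At each threshold q the curve holds |union of reference intervals of
    scaffolds with Q(s) >= q| / total reference length (ambiguous bases
    included in the denominator). Phi_A is the union size at q = 0.
    """
    ref_total = sum(e.length for e in reference)
    if ref_total <= 0:
        raise ValueError("empty reference")
    # reference intervals per scaffold, sorted once by descending quality
    ranked = sorted(scores, key=lambda s: -s.quality)
    qualities = np.array([s.quality for s in ranked])
    per_ref: dict[str, list[tuple[int, int]]] = {}
    values: list[float] = []
    union_cache: dict[int, int] = {}
    for q in QUALITY_GRID[::-1]:
        n_active = int(np.searchsorted(-qualities, -q, side="right"))
        if n_active not in union_cache:
            per_ref = {}
            for s in ranked[:n_active]:
                chain = chains.get(s.query_id)
                if chain is None:
                    continue
                for a in chain.alignments:
                    per_ref.setdefault(a.ref_id, []).append((a.r_start, a.r_end))
            union_cache[n_active] = sum(
                interval_union_size(ivs) for ivs in per_ref.values()
            )
        values.append(union_cache[n_active] / ref_total)
    values.reverse()
    omega = float(np.trapezoid(values, QUALITY_GRID))
    phi = union_cache.get(len(ranked))
    if phi is None:
        # q = 0 always activates every scaffold, so this only happens if the
        # grid were empty; recompute defensively
        per_ref = {}
        for chain in chains.values():
            for a in chain.alignments:
                per_ref.setdefault(a.ref_id, []).append((a.r_start, a.r_end))
        phi = sum(interval_union_size(ivs) for ivs in per_ref.values())
    return omega, list(zip(QUALITY_GRID.tolist(), values)), int(phi)


def inverted_redundancy(scores: list[ScaffoldScore], phi: int) -> float:
    """Pi_A = Phi_A / sum(lambda_i). Raises when nothing aligned."""
    sum_lambda = sum(s.aligned_ref_bp for s in scores)
    if sum_lambda <= 0:
        raise ZeroDivisionError("no aligned reference bases: Pi_A undefined")
    return phi / sum_lambda


def assembly_quality(delta: float, omega: float, pi: float) -> float:
    """Q(A): geometric mean of the three components, each in [0, 1]."""
    return (delta * omega * pi) ** (1.0 / 3.0)


def score_assembly(
    scores: list[ScaffoldScore],
    chains: dict[str, FilteredChain],
    reference: list[SequenceEntry],
) -> AssemblyScore:
    """Compute the consolidated assembly score from per-scaffold scores.

    When no scaffold aligns at all, the inverted redundancy is undefined
    and the assembly score falls back to 0 with a warning.
    """
    theta_g = min(e.length for e in reference)
    delta, qcurve = quality_curve_area(scores)
    omega, ccurve, phi = coverage_curve_area(scores, chains, reference)
    sum_lambda = sum(s.aligned_ref_bp for s in scores)
    if sum_lambda <= 0:
        warnings.warn("no aligned reference bases; assembly quality set to 0", stacklevel=2)
        pi = 0.0
        quality = 0.0
    else:
        pi = inverted_redundancy(scores, phi)
        quality = assembly_quality(delta, omega, pi)
    return AssemblyScore(
        delta=delta,
        omega=omega,
        pi=pi,
        quality=quality,
        quality_curve=qcurve,
        coverage_curve=ccurve,
        phi=phi,
        sum_lambda=sum_lambda,
        theta_g=theta_g,
    )
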