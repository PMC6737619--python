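"""Pipeline orchestration and report generation.

`run_pipeline` glues the stages together — ingest reference and assembly,
parse alignments (truth PAF or an externally produced PAF), filter each
scaffold's chain, count misassemblies, apply the artifact calibration,
score scaffolds and the assembly — and writes the report files:

* scaffolds.tsv      per-scaffold scores and tallies
* assembly.json      assembly score, components, parameters (deterministic)
* quality_curve.csv  cumulative quality-distribution curve
* coverage_curve.csv cumulative genome-coverage curve
* bins.tsv           ten-bin quality histogram (by count and by bp)
* events.tsv         per-junction misassembly diagnostics
* calibration.tsv    artifact model coefficients (when calibrated here)

Partitioning affects scheduling only: scaffolds are processed partition by
partition but reduced in scaffold-id order, so results are identical for
any partition count.
"""

from __future__ import annotations

import json
import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align_filter import FilteredChain, filter_chain, group_by_query
from .calibration import ArtifactModel, calibrate_truth, expected_artifact
from .genome_io import (
    DEFAULT_MIN_GAP_LEN,
    SequenceEntry,
    parse_paf,
    partition_assembly,
    read_fasta,
)
from .misassembly import DEFAULT_RELOCATION_THRESHOLD, count_misassemblies, pair_events
from .scoring import AssemblyScore, ScaffoldScore, score_assembly, score_scaffold

BIN_EDGES = [i / 10 for i in range(11)]

DEFAULT_ALIGNER_TEMPLATE = "minimap2 -x asm5 --secondary=no {reference} {assembly}"


@dataclass
class RunConfig:
    """Configuration of one scoring run."""

    reference: str | Path
    assembly: str | Path
    alignments: str | Path | None = None
    out_dir: str | Path | None = None
    relocation_threshold: int = DEFAULT_RELOCATION_THRESHOLD
    n_parts: int = 1
    overlap_frac: float = 0.5
    min_gap_len: int = DEFAULT_MIN_GAP_LEN
    seed: int = 0
    aligner_mode: str = "truth-paf"  # or "external"
    calibration: str | Path | None = None
    query_aware_relocation: bool = True

    def __post_init__(self) -> None:
        if self.relocation_threshold < 1:
            raise ValueError("relocation_threshold must be >= 1")
        if self.aligner_mode not in ("truth-paf", "external"):
            raise ValueError(f"unknown aligner_mode {self.aligner_mode!r}")


@dataclass
class PipelineResult:
    assembly_score: AssemblyScore
    scaffold_scores: list[ScaffoldScore]
    chains: dict[str, FilteredChain] = field(default_factory=dict)


def run_external_aligner(
    reference: str | Path,
    assembly: str | Path,
    out_paf: str | Path,
    template: str = DEFAULT_ALIGNER_TEMPLATE,
) -> Path:
    """Invoke a PAF-emitting long-sequence mapper via a command template.

    The template receives {reference} and {assembly}; stdout is captured to
    ``out_paf``. Kept as a thin boundary so tests can mock it.
    """
    cmd = template.format(reference=str(reference), assembly=str(assembly)).split()
    with open(out_paf, "w") as fh:
        subprocess.run(cmd, stdout=fh, check=True)
    return Path(out_paf)


def bin_quality_scores(scores: list[ScaffoldScore]) -> pd.DataFrame:
    """Ten-bin quality histogram: nine left-closed right-open bins plus the
    closed top bin [0.9, 1]. Percentages by scaffold count and by base
    pairs; each column sums to 100."""
    if not scores:
        raise ValueError("bin_quality_scores requires at least one scaffold")
    counts = [0] * 10
    bps = [0] * 10
    for s in scores:
        # guard: 0.3 etc. are not exactly representable, keep them in their bin
        idx = min(int(math.floor(s.quality * 10 + 1e-9)), 9)
        counts[idx] += 1
        bps[idx] += s.l_s
    n = len(scores)
    total_bp = sum(s.l_s for s in scores)
    rows = []
    for i in range(10):
        hi_bracket = "]" if i == 9 else ")"
        rows.append(
            {
                "bin": f"[{BIN_EDGES[i]:.1f},{BIN_EDGES[i + 1]:.1f}{hi_bracket}",
                "pct_scaffolds": 100.0 * counts[i] / n,
                "pct_bp": 100.0 * bps[i] / total_bp,
            }
        )
    return pd.DataFrame(rows)


def _score_one(
    scaffold: SequenceEntry,
    records,
    config: RunConfig,
    model: ArtifactModel,
    theta_g: int,
) -> tuple[ScaffoldScore, FilteredChain, list[dict]]:
    chain = filter_chain(records, overlap_frac=config.overlap_frac, query_len=scaffold.length)
    if not chain.query_id:
        chain.query_id = scaffold.id
    count = count_misassemblies(
        chain, t=config.relocation_threshold, query_aware=config.query_aware_relocation
    )
    eps = expected_artifact(
        model, count.assigned_chrom, scaffold.length, config.relocation_threshold
    )
    score = score_scaffold(
        scaffold, chain, theta_g,
        m_s=count.m_total, epsilon_s=eps, assigned_chrom=count.assigned_chrom,
    )
    events = pair_events(
        chain, t=config.relocation_threshold, query_aware=config.query_aware_relocation
    )
    return score, chain, events


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full scoring pipeline and write reports to out_dir.

    Deterministic given the configuration and seed in truth-PAF mode;
    re-running with the same config writes byte-identical reports.
    """
    reference = read_fasta(config.reference, min_gap_len=config.min_gap_len)
    assembly = read_fasta(config.assembly, min_gap_len=config.min_gap_len, keep_residues=False)
    if not assembly:
        raise ValueError(f"assembly {config.assembly} contains no scaffolds")

    if config.alignments is None:
        if config.aligner_mode == "external":
            raise FileNotFoundError(
                "aligner_mode 'external' requires an alignments PAF path "
                "(run the aligner first, e.g. via run_external_aligner)"
            )
        raise FileNotFoundError("truth-paf mode requires the truth PAF path")
    records = parse_paf(config.alignments)
    groups = group_by_query(records)

    if config.calibration is not None:
        model = ArtifactModel.from_tsv(config.calibration)
    else:
        model = ArtifactModel.zero()

    theta_g = min(e.length for e in reference)
    plan = partition_assembly(assembly, config.n_parts)
    by_id = {e.id: e for e in assembly}

    scores: dict[str, ScaffoldScore] = {}
    chains: dict[str, FilteredChain] = {}
    all_events: list[dict] = []
    for part in range(plan.n_parts):
        for sid in plan.members(part):
            scaffold = by_id[sid]
            score, chain, events = _score_one(
                scaffold, groups.get(sid, []), config, model, theta_g
            )
            scores[sid] = score
            chains[sid] = chain
            all_events.extend(events)

    # reduction order fixed by scaffold id regardless of partitioning
    ordered = [scores[sid] for sid in sorted(scores)]
    assembly_score = score_assembly(ordered, chains, reference)
    result = PipelineResult(assembly_score=assembly_score, scaffold_scores=ordered, chains=chains)
    if config.out_dir is not None:
        write_reports(result, config, Path(config.out_dir), all_events)
    return result


def write_reports(
    result: PipelineResult, config: RunConfig, out_dir: Path, events: list[dict]
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "query_id": s.query_id,
                "l_s": s.l_s,
                "R": s.reward,
                "m_s": s.m_s,
                "epsilon_s": s.epsilon_s,
                "P": s.penalty,
                "L": s.length_scaling,
                "Q": s.quality,
                "assigned_chrom": s.assigned_chrom or "",
                "aligned_query_bp": s.aligned_query_bp,
                "aligned_ref_bp": s.aligned_ref_bp,
            }
            for s in result.scaffold_scores
        ]
    ).to_csv(out_dir / "scaffolds.tsv", sep="\t", index=False)

    a = result.assembly_score
    report = {
        "delta": a.delta,
        "omega": a.omega,
        "pi": a.pi,
        "quality": a.quality,
        "theta_g": a.theta_g,
        "phi": a.phi,
        "sum_lambda": a.sum_lambda,
        "n_scaffolds": len(result.scaffold_scores),
        "parameters": {
            "relocation_threshold": config.relocation_threshold,
            "overlap_frac": config.overlap_frac,
            "min_gap_len": config.min_gap_len,
            "n_parts": config.n_parts,
            "seed": config.seed,
            "aligner_mode": config.aligner_mode,
            "query_aware_relocation": config.query_aware_relocation,
            "reference": str(config.reference),
            "assembly": str(config.assembly),
            "alignments": str(config.alignments),
            "calibration": str(config.calibration) if config.calibration else None,
        },
        "version": __version__,
    }
    with open(out_dir / "assembly.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    pd.DataFrame(a.quality_curve, columns=["threshold", "bp_ratio"]).to_csv(
        out_dir / "quality_curve.csv", index=False
    )
    pd.DataFrame(a.coverage_curve, columns=["threshold", "coverage_ratio"]).to_csv(
        out_dir / "coverage_curve.csv", index=False
    )
    bin_quality_scores(result.scaffold_scores).to_csv(
        out_dir / "bins.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        events, columns=["query_id", "pair_index", "class", "d", "ref_a", "ref_b"]
    ).to_csv(out_dir / "events.tsv", sep="\t", index=False)


def calibrate_and_save(
    reference_path: str | Path, out_tsv: str | Path, seed: int = 0
) -> ArtifactModel:
    """Calibrate the artifact model for a reference (truth self-alignment
    mode) and persist it as TSV for reuse across scoring runs."""
    reference = read_fasta(reference_path)
    model = calibrate_truth(reference, seed=seed)
    model.to_tsv(out_tsv)
    return model
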