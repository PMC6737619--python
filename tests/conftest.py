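import pytest

from asmqual import (
    FilteredChain,
    count_misassemblies,
    generate_reference,
    score_assembly,
    score_scaffold,
)
from asmqual.align_filter import filter_chain, group_by_query


@pytest.fixture(scope="session")
def toy_reference():
    """5 x 500 kb random reference (no N runs); theta_G = 500,000."""
    return generate_reference(n_chrom=5, chrom_lengths=[500_000] * 5, seed=11)


def score_truth_assembly(reference, assembly, t=1000):
    """Score a synthetic assembly from its truth alignments, in memory.

    Returns (AssemblyScore, list[ScaffoldScore], chains).
    """
    groups = group_by_query(assembly.truth)
    chains = {qid: filter_chain(recs) for qid, recs in groups.items()}
    theta_g = min(e.length for e in reference)
    scores = []
    for scf in assembly.scaffolds:
        chain = chains.get(scf.id)
        if chain is None:
            chain = FilteredChain(query_id=scf.id, query_len=scf.length)
            chains[scf.id] = chain
        count = count_misassemblies(chain, t=t)
        scores.append(
            score_scaffold(
                scf, chain, theta_g, m_s=count.m_total, assigned_chrom=count.assigned_chrom
            )
        )
    return score_assembly(scores, chains, reference), scores, chains
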