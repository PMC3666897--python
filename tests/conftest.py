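import pytest

from phpcoevol.seq_io import Alignment, SequenceRecord

# observed residues at the nine panel positions for the characterized
# polymerases and the engineered revertant series
TABLE_ROWS = {
    "Eco": "RHDFDHGDR",
    "3mPHP": "HHDHDHGDH",
    "4mPHP": "HHDHDHCDH",
    "5mPHP": "HHDHEHCDH",
    "Taq": "HHDHEHCDH",
    "Gka": "HHDHEHCNH",
}


@pytest.fixture
def mini_alignment():
    return Alignment(
        records=(
            SequenceRecord(id="r1", residues="MA-KV"),
            SequenceRecord(id="r2", residues="MV-KV"),
            SequenceRecord(id="r3", residues="M--KV"),
        )
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A full synthetic cohort at the default study conditions."""
    from phpcoevol.synth import (
        SimConfig,
        evolve_alignment,
        generate_epsilon_cohort,
        simulate_tree,
    )

    cfg = SimConfig(seed=11)
    tree = simulate_tree(cfg)
    aln, ledger = evolve_alignment(tree, cfg)
    eps, truth = generate_epsilon_cohort(ledger["clade"], [r.id for r in aln.records], cfg)
    return {
        "config": cfg,
        "tree": tree,
        "alignment": aln,
        "ledger": ledger,
        "epsilon": eps,
        "truth": truth,
    }
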