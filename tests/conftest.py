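import numpy as np
import pytest
from hypothesis import settings

import cubtools as ct

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Two-group cohort of eight small genomes, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    specs = []
    for gi, (label, gc3) in enumerate([("lowgc", 0.58), ("highgc", 0.72)]):
        for k in range(4):
            specs.append(
                ct.GenomeSimSpec(
                    genome_id=f"{label}_{k + 1}",
                    group=label,
                    n_genes=80,
                    gene_length_codons=(80, 250),
                    mut_gc3=gc3,
                    neutrality_slope=0.3,
                    sel_fraction=0.05,
                    sel_strength=15.0,
                )
            )
    genomes, groups, truth = ct.simulate_cohort(specs, outdir=outdir, master_seed=42)
    return {"outdir": outdir, "genomes": genomes, "groups": groups, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_codon_counts(rng, max_count=30):
    """Random CodonCounts with independent per-codon counts (zeros allowed)."""
    counts = ct.CodonCounts()
    for codon in counts.counts:
        counts.counts[codon] = int(rng.integers(0, max_count + 1))
    return counts
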