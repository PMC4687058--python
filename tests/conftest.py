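import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from wgdpairs.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small decoy-free dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11, n_wgd_pairs=8, n_tandem_pairs=3, n_singletons=15,
        n_codons_range=(170, 260),
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sense_codons(rng, n):
    """Random internal sense codons (no stops) as a list of triplets."""
    from wgdpairs.genetics import SENSE_CODONS

    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def mutated_copy(rng, codons, p_sub=0.08):
    """Mutate each nucleotide with prob p_sub, avoiding stop codons."""
    from wgdpairs.genetics import STOP_CODONS

    out = []
    bases = "ACGT"
    for codon in codons:
        cur = codon
        for pos in range(3):
            if rng.random() < p_sub:
                new = bases[rng.integers(0, 4)]
                cand = cur[:pos] + new + cur[pos + 1:]
                if cand not in STOP_CODONS:
                    cur = cand
        out.append(cur)
    return out
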