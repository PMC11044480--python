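import numpy as np
import pytest

from mobilome.simulate import (SimConfig, simulate_eccdna_reads,
                               simulate_reference)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq: str, n_subs: int, rng: np.random.Generator):
    """Apply exactly n substitutions; returns (mutated, positions)."""
    pos = rng.choice(len(seq), n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out), sorted(int(p) for p in pos)


def noisy_copy(seq: str, rng: np.random.Generator,
               rates=(0.05, 0.025, 0.025)) -> str:
    from mobilome.seq import decode_seq, encode_seq
    from mobilome.simulate import apply_read_errors

    return decode_seq(apply_read_errors(encode_seq(seq), rng, rates))


@pytest.fixture(scope="session")
def small_reference():
    """One 600 kb chromosome with 2 families x 3 copies, plus truth."""
    cfg = SimConfig(seed=5, chrom_lengths=(600_000,), reads_per_condition=10,
                    introgression=("chr1", 100_000, 300_000, 20.0))
    genome, elements, truth = simulate_reference(cfg)
    return cfg, genome, elements, truth


@pytest.fixture(scope="session")
def structure_reads():
    """Long concatemer reads (error-free and 10% error) plus truth."""
    out = {}
    for tag, err in (("clean", (0.0, 0.0, 0.0)),
                     ("noisy", (0.05, 0.025, 0.025))):
        cfg = SimConfig(seed=21, chrom_lengths=(600_000,),
                        reads_per_condition=40, read_len_mu=9.6,
                        read_len_sigma=0.3, error_rates=err)
        genome, elements, truth = simulate_reference(cfg)
        reads = simulate_eccdna_reads(cfg, truth, "treatment")
        out[tag] = (cfg, elements, truth, reads)
    return out
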