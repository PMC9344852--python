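import numpy as np
import pytest

import shepherd as sh


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240611)


def random_sequences(rng, n, l):
    """n distinct random ACGT strings of length l."""
    out = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), l), dtype=np.uint8)
        out.update(sh.kmer_index.decode_sequences(block))
    return sorted(out)


def mutate(rng, seq, d):
    """A sequence at Hamming distance exactly d from seq."""
    pos = rng.choice(len(seq), size=d, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def brute_force_neighbors(reads, query_idx, epsilon):
    """All-pairs oracle: indices and distances of epsilon-neighbors."""
    q = reads.encoded[query_idx]
    dists = (reads.encoded != q).sum(axis=1)
    out = [
        (i, int(d))
        for i, d in enumerate(dists)
        if i != query_idx and d <= epsilon
    ]
    return out


@pytest.fixture(scope="session")
def scaled_dataset_a():
    """2%-scale analogue of the low-error benchmark: 10^4 barcodes, rho=0.0033."""
    cfg = sh.SimulationConfig(n_barcodes=10_000, rho=0.0033, seed=11)
    reads, truth = sh.generate_dataset(cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def scaled_dataset_a_clustered(scaled_dataset_a):
    """The scaled benchmark run through the full auto-parameter pipeline."""
    cfg, reads, truth = scaled_dataset_a
    rho_hat = sh.estimate_rho(reads)
    epsilon = sh.choose_epsilon(reads, rho_hat)
    scheme = sh.make_scheme(reads.length, epsilon, n_sequences=len(reads))
    model = sh.ErrorModel(rho=rho_hat, l=reads.length, f_max=reads.f_max)
    result = sh.cluster_reads(reads, scheme, model)
    return cfg, reads, truth, result
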