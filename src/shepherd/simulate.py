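"""Synthetic barcode-read generator with full ground truth.

Emulates sequencing-based lineage tracking benchmarks: barcodes of 20
random plus 6 constant nucleotides (total length 26), true counts drawn as
the ceiling of an Exponential with mean 100, and independent per-nucleotide
substitution errors at a constant rate rho (each alternative base equally
likely).  For several timepoints, lineage trajectories follow discrete
exponential growth -- a subset of lineages carries a fitness advantage --
renormalized to a fixed sequencing depth and resampled multinomially, the
standard serial-transfer abstraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_index import ReadSet, decode_sequences, encode_sequences


@dataclass
class SimulationConfig:
    n_barcodes: int = 10_000
    l_random: int = 20
    constant_flank: str = "ACGTAC"  # appended as a suffix
    mean_count: float = 100.0
    rho: float = 0.0033
    n_timepoints: int = 1
    n_advantaged: int = 0
    advantage: float = 1.5  # per-timepoint growth multiplier for advantaged lineages
    depth: int | None = None  # reads per timepoint; default n_barcodes * mean_count
    seed: int = 0

    def __post_init__(self):
        if self.n_advantaged > self.n_barcodes:
            raise ValueError("n_advantaged must be <= n_barcodes")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")

    @property
    def l(self) -> int:
        return self.l_random + len(self.constant_flank)


# Single-timepoint benchmark presets: (rho, n_barcodes).  A's rate mirrors
# Illumina-platform estimates; B and C stress higher-error platforms.
PRESETS = {
    "A": (0.0033, 500_000),
    "B": (0.0066, 500_000),
    "C": (0.02, 100_000),
    "multi": (0.0033, 500_000),
}


def preset_config(name: str, scale: float = 1.0, seed: int = 0) -> SimulationConfig:
    rho, n = PRESETS[name]
    cfg = SimulationConfig(n_barcodes=max(2, int(round(n * scale))), rho=rho, seed=seed)
    if name == "multi":
        cfg.n_timepoints = 4
        cfg.n_advantaged = max(1, int(round(5_000 * scale)))
    return cfg


@dataclass
class GroundTruth:
    """True barcodes, their per-timepoint emitted counts, and read provenance."""

    true_barcodes: list[str]
    true_counts: np.ndarray  # (n_barcodes, n_timepoints) int64
    # observed sequence -> {source barcode index: reads}, per timepoint
    read_provenance: list[dict[str, dict[int, int]]] = field(default_factory=list)


def generate_barcodes(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Draw n unique barcodes: l_random iid-uniform nt plus the constant flank."""
    if cfg.n_barcodes > 4**cfg.l_random:
        raise ValueError("n_barcodes exceeds the random sequence space")
    chosen: dict[str, None] = {}
    while len(chosen) < cfg.n_barcodes:
        need = cfg.n_barcodes - len(chosen)
        block = rng.integers(0, 4, size=(need, cfg.l_random), dtype=np.uint8)
        for s in decode_sequences(block):
            if len(chosen) < cfg.n_barcodes:
                chosen.setdefault(s, None)
    return [s + cfg.constant_flank for s in chosen]


def assign_counts(n_barcodes: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """True counts: ceiling of Exponential(mean_count) draws, iid per barcode."""
    return np.ceil(rng.exponential(cfg.mean_count, size=n_barcodes)).astype(np.int64)


def apply_errors(
    barcodes: list[str],
    counts: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ReadSet, dict[str, dict[int, int]]]:
    """Emit counts[i] reads per barcode, each position mutating w.p. rho.

    Returns the tallied ReadSet and the provenance map
    observed sequence -> {source barcode index: reads}.
    """
    counts = np.asarray(counts, dtype=np.int64)
    l = cfg.l
    live = np.flatnonzero(counts > 0)
    parents = np.repeat(live, counts[live])
    n_reads = parents.size
    enc = encode_sequences(barcodes, l)

    n_errors = rng.binomial(l, cfg.rho, size=n_reads) if cfg.rho > 0 else np.zeros(n_reads, int)
    clean = n_errors == 0
    tally: dict[str, dict[int, int]] = {}

    # error-free reads reproduce their source exactly
    clean_counts = np.bincount(parents[clean], minlength=len(barcodes))
    for b in np.flatnonzero(clean_counts):
        tally[barcodes[b]] = {int(b): int(clean_counts[b])}

    mutated_parents = parents[~clean]
    errs = n_errors[~clean]
    if mutated_parents.size:
        rows = enc[mutated_parents].copy()
        # distinct error positions per read: rank a random matrix per row
        ranks = np.argsort(rng.random((rows.shape[0], l)), axis=1)
        for e in np.unique(errs):
            sel = np.flatnonzero(errs == e)
            pos = ranks[sel, :e]
            shift = rng.integers(1, 4, size=pos.shape, dtype=np.uint8)
            r = np.repeat(sel, e)
            c = pos.ravel()
            rows[r, c] = (rows[r, c] + shift.ravel()) % 4
        obs = decode_sequences(rows)
        for s, b in zip(obs, mutated_parents):
            src = tally.setdefault(s, {})
            b = int(b)
            src[b] = src.get(b, 0) + 1

    seqs = sorted(tally)
    read_counts = np.array([sum(tally[s].values()) for s in seqs], dtype=np.int64)
    reads = ReadSet(seqs, read_counts, l)
    return reads, tally


def generate_dataset(cfg: SimulationConfig) -> tuple[ReadSet, GroundTruth]:
    """Single-timepoint benchmark: barcodes, exponential counts, errors."""
    rng = np.random.default_rng(cfg.seed)
    barcodes = generate_barcodes(cfg, rng)
    counts = assign_counts(cfg.n_barcodes, cfg, rng)
    reads, prov = apply_errors(barcodes, counts, cfg, rng)
    truth = GroundTruth(
        true_barcodes=barcodes,
        true_counts=counts[:, None],
        read_provenance=[prov],
    )
    return reads, truth


def simulate_timeseries(cfg: SimulationConfig) -> tuple[list[ReadSet], GroundTruth]:
    """Multi-timepoint benchmark with selection.

    Lineage weights start at Exponential(mean_count) draws; advantaged
    lineages multiply theirs by ``advantage`` each timepoint.  Each
    timepoint's true counts are a multinomial sample of ``depth`` reads from
    the normalized weights, after which substitution errors are applied.
    """
    if cfg.n_timepoints < 2:
        raise ValueError("need n_timepoints >= 2")
    rng = np.random.default_rng(cfg.seed)
    barcodes = generate_barcodes(cfg, rng)
    base = rng.exponential(cfg.mean_count, size=cfg.n_barcodes)
    advantaged = rng.choice(cfg.n_barcodes, size=cfg.n_advantaged, replace=False)
    depth = cfg.depth or int(round(cfg.n_barcodes * cfg.mean_count))

    true_counts = np.zeros((cfg.n_barcodes, cfg.n_timepoints), dtype=np.int64)
    readsets = []
    provenance = []
    growth = np.ones(cfg.n_barcodes)
    for t in range(cfg.n_timepoints):
        w = base * growth
        true_counts[:, t] = rng.multinomial(depth, w / w.sum())
        reads, prov = apply_errors(barcodes, true_counts[:, t], cfg, rng)
        readsets.append(reads)
        provenance.append(prov)
        growth[advantaged] *= cfg.advantage

    truth = GroundTruth(
        true_barcodes=barcodes, true_counts=true_counts, read_provenance=provenance
    )
    return readsets, truth
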