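"""Substitution error model and the Bayesian true-barcode test.

A sequence within Hamming distance d <= epsilon of a putative barcode is
either an error sequence spawned from it (model M1) or a true barcode in its
own right (model M2).  The log-Bayes factor comparing the two is

    ln K = ln[ C(n_hat, f_c) p_hat^f_c (1 - p_hat)^(n_hat - f_c) ]
           + ln p_hat + l ln 4 + ln f_max

where p_hat = (rho/3)^d (1 - rho)^(l - d) is the probability of converting
the putative barcode into the candidate by substitution errors (each of the
three alternative bases being equally likely), n_hat estimates the true copy
number of the putative barcode, f_c is the candidate's read count and f_max
the highest read count in the data.  The candidate is declared a TRUE
barcode iff ln K < threshold (default -4, i.e. M2 must be ~55x more likely);
ties favor the error-sequence model, since spurious lineages are more
damaging than mildly distorted counts.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .kmer_index import ReadSet

LOG4 = math.log(4.0)
RHO_FLOOR = 1e-6


class EstimationError(RuntimeError):
    """Raised when the error rate cannot be estimated from the data."""


class Classification(enum.Enum):
    ERROR_SEQUENCE = "error_sequence"
    TRUE_BARCODE = "true_barcode"


@dataclass
class ErrorModel:
    """Per-nucleotide substitution rate and classification threshold."""

    rho: float
    l: int
    f_max: int
    log_bf_threshold: float = -4.0

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if not math.isfinite(self.log_bf_threshold):
            raise ValueError("log-Bayes-factor threshold must be finite")
        if self.f_max < 1:
            raise ValueError("f_max must be >= 1")


@dataclass(frozen=True)
class TestCase:
    """One candidate-vs-putative-barcode comparison.

    d is the Hamming distance between them, f_c / f_p the candidate's and
    putative barcode's read counts, n_hat the estimated true copy number of
    the putative barcode (observed counts fluctuate, so n_hat >= f_p is not
    required).
    """

    d: int
    f_c: int
    f_p: int
    n_hat: int

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("test cases require d >= 1")
        if self.f_c < 1:
            raise ValueError("candidate read count must be >= 1")
        if self.n_hat < 0:
            raise ValueError("n_hat must be non-negative")


def log_p_conversion(d: int, model: ErrorModel) -> float:
    """ln of the conversion probability (rho/3)^d (1-rho)^(l-d)."""
    if d < 0 or d > model.l:
        raise ValueError(f"d must lie in [0, {model.l}]")
    return d * math.log(model.rho / 3.0) + (model.l - d) * math.log1p(-model.rho)


def p_conversion(d: int, model: ErrorModel) -> float:
    """Probability of converting a barcode into a specific sequence at distance d."""
    return math.exp(log_p_conversion(d, model))


_EXACT_LOG_COMB_LIMIT = 100_000


def _log_comb(n: int, k: int) -> float:
    """ln C(n, k), accurate to ~1e-9 absolute even for n ~ 1e9.

    The difference of two log-gamma values near 1e10 loses ~1e-6 to
    cancellation, so for moderate k the falling factorial is summed in log
    space directly; the log-gamma route only serves k beyond that.
    """
    if k > n - k:
        k = n - k
    if k == 0:
        return 0.0
    if k <= _EXACT_LOG_COMB_LIMIT:
        terms = np.log(n - np.arange(k, dtype=np.float64))
        return float(terms.sum() - gammaln(k + 1))
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def log_bayes_factor(case: TestCase, model: ErrorModel) -> float:
    """Log-Bayes factor ln K; -inf means M2 (true barcode) is certain.

    All arithmetic is in natural-log space, so counts up to ~1e9 neither
    overflow nor lose the leading digits.
    """
    if case.f_c > case.n_hat:
        # the binomial term vanishes: an error child cannot outnumber the
        # estimated copies of its source
        return -math.inf
    lp = log_p_conversion(case.d, model)
    n, fc = case.n_hat, case.f_c
    log_pmf = _log_comb(n, fc) + fc * lp + (n - fc) * math.log1p(-math.exp(lp))
    return float(log_pmf + lp + model.l * LOG4 + math.log(model.f_max))


def classify(case: TestCase, model: ErrorModel) -> Classification:
    """TRUE_BARCODE iff ln K < threshold; the boundary favors M1."""
    if log_bayes_factor(case, model) < model.log_bf_threshold:
        return Classification.TRUE_BARCODE
    return Classification.ERROR_SEQUENCE


def _rho_from_neighbor_fraction(x: float, l: int) -> float:
    """Invert x = l*rho*(1-rho)^(l-1) / [(1-rho)^l + l*rho*(1-rho)^(l-1)].

    The left side is the expected fraction of an isolated barcode's reads
    that land on its distance-1 neighbors, among reads with <= 1 error.
    Cancelling (1-rho)^(l-1) gives x = l*rho / (1 - rho + l*rho), which is
    exactly invertible.
    """
    return x / (l - x * (l - 1))


def estimate_rho(
    reads: ReadSet,
    epsilon: int = 2,
    anchor_quantile: float = 0.99,
) -> float:
    """Data-driven estimate of the per-nucleotide substitution rate.

    Anchors are sequences in the top (1 - anchor_quantile) tail of the read
    count distribution with no higher-count sequence within Hamming distance
    ``epsilon`` -- unambiguous true barcodes whose local error cloud is
    uncontaminated.  Pooling over anchors, the ratio of distance-1 neighbor
    read mass E1 to anchor read mass E0 identifies rho through
    E1/(E0+E1) = l*rho / (1 - rho + l*rho).
    """
    counts = reads.counts
    threshold = float(np.quantile(counts, anchor_quantile))
    anchor_idx = np.flatnonzero(counts > threshold)
    if anchor_idx.size == 0:
        raise EstimationError(
            "no sequences above the anchor count quantile; "
            "supply rho manually (--rho)"
        )

    # isolation: any sequence strictly out-counting an anchor is itself in the
    # anchor stratum, so a pairwise check among anchors is exact
    enc = reads.encoded[anchor_idx]
    acounts = counts[anchor_idx]
    keep = np.ones(anchor_idx.size, dtype=bool)
    # chunked all-pairs Hamming over the (small) anchor stratum
    for i in range(anchor_idx.size):
        d = (enc != enc[i]).sum(axis=1)
        crowd = (d <= epsilon) & (d > 0) & (acounts > acounts[i])
        if crowd.any():
            keep[i] = False
    anchors = anchor_idx[keep]
    if anchors.size == 0:
        raise EstimationError(
            "no isolated anchor sequences found; supply rho manually (--rho)"
        )

    lookup = {s: int(c) for s, c in zip(reads.sequences, counts)}
    l = reads.length
    e0 = 0
    e1 = 0
    for a in anchors:
        seq = reads.sequences[a]
        e0 += int(counts[a])
        for pos in range(l):
            orig = seq[pos]
            for base in "ACGT":
                if base == orig:
                    continue
                e1 += lookup.get(seq[:pos] + base + seq[pos + 1 :], 0)
    x = e1 / (e0 + e1)
    rho_hat = _rho_from_neighbor_fraction(x, l)
    if rho_hat < RHO_FLOOR:
        warnings.warn(
            f"estimated substitution rate {rho_hat:.3g} is below the floor "
            f"{RHO_FLOOR}; reporting the floor (data look error-free)",
            stacklevel=2,
        )
        return RHO_FLOOR
    return float(rho_hat)
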