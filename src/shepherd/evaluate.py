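"""Scoring clustering output against simulation ground truth.

A false positive is an identified cluster whose center is not a true
barcode (a spurious lineage).  A false negative is a true barcode absorbed
as a non-center member of some other cluster (a lineage wrongly classified
as an error sequence); a true barcode swallowed by a cluster centered on an
error sequence also counts as a false negative here.  Cluster centers match
true barcodes by exact sequence, mirroring how the measures are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import Cluster, ClusteringResult
from .simulate import GroundTruth
from .track import LineageTable


@dataclass
class EvaluationReport:
    fpc: int
    fnc: int
    n_clusters: int
    n_true: int
    exact_count_fraction: float
    r_e: list[float]


def false_positive_count(result: ClusteringResult, truth: GroundTruth) -> int:
    true_set = set(truth.true_barcodes)
    return sum(1 for c in result.clusters if c.center not in true_set)


def false_negative_count(result: ClusteringResult, truth: GroundTruth) -> int:
    true_set = set(truth.true_barcodes)
    fnc = 0
    for seq, j in result.assignment.items():
        if seq in true_set and result.clusters[j].center != seq:
            fnc += 1
    return fnc


def effective_cluster_radius(cluster: Cluster) -> float | None:
    """Mean Hamming distance from the highest-count member to the others.

    The center is the highest-count member by construction (count ties were
    broken lexicographically when the cluster formed).  Singletons have no
    radius and are excluded from distributions; indel-corrected members have
    a different length and are likewise excluded.
    """
    if not cluster.members:
        return None
    return float(np.mean([d for _, _, d in cluster.members]))


def radius_distribution(result: ClusteringResult) -> list[float]:
    """Effective radii of all clusters with at least two same-length members."""
    out = []
    for c in result.clusters:
        r = effective_cluster_radius(c)
        if r is not None:
            out.append(r)
    return out


def matched_count_pairs(
    result: ClusteringResult, truth: GroundTruth, timepoint: int = 0
) -> list[tuple[str, int, int]]:
    """(barcode, true count, estimated count) for exactly-matched centers."""
    true_idx = {b: i for i, b in enumerate(truth.true_barcodes)}
    out = []
    for c in result.clusters:
        i = true_idx.get(c.center)
        if i is not None:
            out.append((c.center, int(truth.true_counts[i, timepoint]), c.total_count))
    return out


def exact_count_fraction(result: ClusteringResult, truth: GroundTruth) -> float:
    """Fraction of matched true barcodes whose estimated count is exact."""
    pairs = matched_count_pairs(result, truth)
    if not pairs:
        raise ValueError("no cluster center matches a true barcode")
    return sum(1 for _, t, e in pairs if t == e) / len(pairs)


def count_mae(table: LineageTable, truth: GroundTruth) -> list[float]:
    """Per-timepoint mean absolute count error over exactly-matched barcodes."""
    true_idx = {b: i for i, b in enumerate(truth.true_barcodes)}
    matched = [
        (j, true_idx[b]) for j, b in enumerate(table.barcodes) if b in true_idx
    ]
    if not matched:
        raise ValueError("no tracked barcode matches a true barcode")
    est_rows = np.array([j for j, _ in matched])
    true_rows = np.array([i for _, i in matched])
    err = np.abs(table.counts[est_rows] - truth.true_counts[true_rows])
    return [float(m) for m in err.mean(axis=0)]


def evaluate_clustering(result: ClusteringResult, truth: GroundTruth) -> EvaluationReport:
    return EvaluationReport(
        fpc=false_positive_count(result, truth),
        fnc=false_negative_count(result, truth),
        n_clusters=len(result.clusters),
        n_true=len(truth.true_barcodes),
        exact_count_fraction=exact_count_fraction(result, truth),
        r_e=radius_distribution(result),
    )
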