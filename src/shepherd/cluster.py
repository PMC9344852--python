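"""Single-timepoint clustering: putative barcode identification and
error-sequence assignment.

Unique sequences are visited in descending read-count order.  The heaviest
sequence is always a putative barcode.  A later sequence with no putative
barcode in its epsilon-neighborhood starts a new cluster; otherwise the
Bayesian test (:mod:`shepherd.error_model`) against the closest putative
barcode decides whether it is an error child (joined to that cluster) or a
true barcode shadowed by a neighbor (new cluster).  Single insertion and
deletion errors are folded in afterwards as a post-processing step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.stats import binom

from .error_model import Classification, ErrorModel, TestCase, classify
from .kmer_index import KmerIndex, KmerScheme, ReadSet, build_index

# sequences out-counting this fraction of f_max bypass the Bayes test and are
# declared putative barcodes outright (unambiguous-case shortcut)
SKIP_TEST_FRACTION = 0.05


@dataclass
class Cluster:
    """A putative barcode with the error sequences assigned to it."""

    center: str
    center_count: int
    members: list[tuple[str, int, int]] = field(default_factory=list)  # (seq, count, dist)
    indel_members: list[tuple[str, int]] = field(default_factory=list)  # (seq, count)

    @property
    def total_count(self) -> int:
        return (
            self.center_count
            + sum(c for _, c, _ in self.members)
            + sum(c for _, c in self.indel_members)
        )

    @property
    def n_members(self) -> int:
        return 1 + len(self.members) + len(self.indel_members)


@dataclass
class ClusteringResult:
    """Clusters plus the sequence -> cluster assignment map and run parameters."""

    clusters: list[Cluster]
    assignment: dict[str, int]
    scheme: KmerScheme
    model: ErrorModel
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def centers(self) -> list[str]:
        return [c.center for c in self.clusters]

    def sort(self) -> None:
        """Order clusters by total count desc, then center sequence."""
        order = sorted(
            range(len(self.clusters)),
            key=lambda i: (-self.clusters[i].total_count, self.clusters[i].center),
        )
        remap = {old: new for new, old in enumerate(order)}
        self.clusters = [self.clusters[i] for i in order]
        self.assignment = {s: remap[c] for s, c in self.assignment.items()}


def choose_epsilon(reads: ReadSet, rho: float) -> int:
    """Smallest epsilon with fewer than one expected read beyond it.

    With T total reads and per-read error counts ~ Bin(l, rho), pick the
    least epsilon such that T * P(Bin(l, rho) > epsilon) < 1, clamped to
    [1, 3] to keep the index tractable.
    """
    t = reads.total_count
    l = reads.length
    eps = l
    for e in range(0, l + 1):
        if t * binom.sf(e, l, rho) < 1.0:
            eps = e
            break
    return max(1, min(3, eps))


def cluster_reads(
    reads: ReadSet,
    scheme: KmerScheme,
    model: ErrorModel,
    skip_test: bool = True,
) -> ClusteringResult:
    """Count-ordered clustering of a deduplicated read set.

    Ties in read count are broken lexicographically by sequence so results
    are bit-reproducible.  The accumulated cluster count F_p at test time
    de-biased by the error-free read probability, n_hat = round(F_p /
    (1-rho)^l), estimates the putative barcode's true copy number.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    index = build_index(reads, scheme)
    counts = reads.counts
    seq_arr = np.asarray(reads.sequences, dtype=f"S{reads.length}")
    order = np.lexsort((seq_arr, -counts))

    skip_threshold = SKIP_TEST_FRACTION * model.f_max if skip_test else math.inf
    debias = (1.0 - model.rho) ** model.l
    eps = scheme.epsilon
    enc = reads.encoded
    table = index.table
    ids = index._ids

    is_center = np.zeros(len(reads), dtype=bool)
    cluster_of = np.full(len(reads), -1, dtype=np.int64)
    cluster_center: list[int] = []  # sequence index of each cluster's center
    cluster_total: list[int] = []  # accumulated read count F_p per cluster
    members: list[list[int]] = []
    member_dists: list[list[int]] = []

    for i in order:
        i = int(i)
        f_c = int(counts[i])
        # gather putative-barcode neighbors within epsilon
        best = -1  # cluster id of closest putative barcode
        best_d = eps + 1
        if f_c <= skip_threshold:
            hood: set[int] = set()
            for cid in ids[i]:
                bucket = table.get(int(cid))
                if bucket:
                    hood.update(bucket)
            hood.discard(i)
            if hood:
                cand = np.fromiter(hood, dtype=np.int64, count=len(hood))
                cand = cand[is_center[cand]]
                if cand.size:
                    dists = (enc[cand] != enc[i]).sum(axis=1)
                    within = dists <= eps
                    cand, dists = cand[within], dists[within]
                    if cand.size:
                        # closest; distance ties -> higher read count, then sequence
                        key = np.lexsort((seq_arr[cand], -counts[cand], dists))[0]
                        best = int(cluster_of[cand[key]])
                        best_d = int(dists[key])

        new_cluster = True
        if best >= 0:
            f_p = int(counts[cluster_center[best]])
            n_hat = int(round(cluster_total[best] / debias))
            case = TestCase(d=best_d, f_c=f_c, f_p=f_p, n_hat=n_hat)
            if classify(case, model) is Classification.ERROR_SEQUENCE:
                new_cluster = False

        if new_cluster:
            cluster_of[i] = len(cluster_center)
            cluster_center.append(i)
            cluster_total.append(f_c)
            members.append([])
            member_dists.append([])
            is_center[i] = True
        else:
            cluster_of[i] = best
            cluster_total[best] += f_c
            members[best].append(i)
            member_dists[best].append(best_d)

    clusters = [
        Cluster(
            center=reads.sequences[c],
            center_count=int(counts[c]),
            members=[
                (reads.sequences[m], int(counts[m]), d)
                for m, d in zip(members[j], member_dists[j])
            ],
        )
        for j, c in enumerate(cluster_center)
    ]
    assignment = {
        reads.sequences[i]: int(cluster_of[i]) for i in range(len(reads))
    }
    result = ClusteringResult(
        clusters=clusters, assignment=assignment, scheme=scheme, model=model
    )
    result.sort()
    return result


def _deletion_variants(seq: str) -> set[str]:
    return {seq[:j] + seq[j + 1 :] for j in range(len(seq))}


def _insertion_variants(seq: str) -> set[str]:
    out = set()
    for j in range(len(seq) + 1):
        for base in "ACGT":
            out.add(seq[:j] + base + seq[j:])
    return out


def correct_indels(
    result: ClusteringResult, off_length: Iterable[tuple[str, int]]
) -> ClusteringResult:
    """Fold single-indel reads into existing clusters (post-processing).

    A length l+1 read joins a cluster if one of its l+1 single deletions is a
    putative barcode; a length l-1 read, if one of its single insertions is.
    Reaching several putative barcodes is resolved by higher cluster total
    count, then lexicographically.  Unmatched or other-length reads are
    dropped and logged.  Main-clustering decisions are never revisited.
    """
    l = result.scheme.l
    clusters = [
        Cluster(c.center, c.center_count, list(c.members), list(c.indel_members))
        for c in result.clusters
    ]
    center_to_cluster = {c.center: j for j, c in enumerate(clusters)}
    totals = {j: c.total_count for j, c in enumerate(clusters)}
    result = replace(
        result,
        clusters=clusters,
        assignment=dict(result.assignment),
        dropped=dict(result.dropped),
    )

    for seq, count in off_length:
        if len(seq) == l + 1:
            variants = _deletion_variants(seq)
        elif len(seq) == l - 1:
            variants = _insertion_variants(seq)
        else:
            result.dropped["off_length_not_l_pm_1"] = (
                result.dropped.get("off_length_not_l_pm_1", 0) + count
            )
            continue
        hits = [center_to_cluster[v] for v in sorted(variants) if v in center_to_cluster]
        if not hits:
            result.dropped["unmatched_indel"] = (
                result.dropped.get("unmatched_indel", 0) + count
            )
            continue
        j = min(hits, key=lambda h: (-totals[h], result.clusters[h].center))
        result.clusters[j].indel_members.append((seq, int(count)))
        totals[j] += count
        result.assignment[seq] = j

    result.sort()
    return result
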