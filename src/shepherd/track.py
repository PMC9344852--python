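"""Multi-timepoint error correction and lineage tracking.

Only the first timepoint is clustered.  Later timepoints are treated as a
classification problem: each sequence is assigned to its closest putative
barcode within epsilon, with the Bayesian test separating genuine emerging
barcodes (and false negatives merged at the first timepoint) from error
sequences.  Sequences outside every epsilon-neighborhood are buffered and
clustered among themselves, yielding new lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cluster import ClusteringResult, cluster_reads
from .error_model import Classification, ErrorModel, TestCase, classify
from .kmer_index import KmerScheme, ReadSet, encode_sequences

PROV_INITIAL = "initial"
PROV_EMERGING = "emerging"
PROV_SPLIT = "split-corrected"


@dataclass
class LineageTable:
    """Barcode-by-timepoint corrected count matrix with emergence times."""

    barcodes: list[str]
    counts: np.ndarray  # (n_barcodes, n_timepoints) int64
    emerged_at: np.ndarray  # first timepoint index (0-based) per barcode
    provenance: list[str]
    dropped_per_timepoint: list[int] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[1]

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


class _CenterIndex:
    """Growable k-mer index over the current putative barcode set."""

    def __init__(self, scheme: KmerScheme):
        self.scheme = scheme
        self.table: dict[int, list[int]] = {}
        self.encoded: list[np.ndarray] = []
        self.seq_to_id: dict[str, int] = {}

    def add(self, seq: str) -> int:
        enc = encode_sequences([seq], self.scheme.l)
        bid = len(self.encoded)
        self.encoded.append(enc[0])
        self.seq_to_id[seq] = bid
        for cid in self.scheme.ids_matrix(enc)[0]:
            self.table.setdefault(int(cid), []).append(bid)
        return bid

    def neighbors(self, ids_row, enc_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Candidate barcodes within epsilon: (barcode ids, distances)."""
        hood: set[int] = set()
        for cid in ids_row:
            bucket = self.table.get(int(cid))
            if bucket:
                hood.update(bucket)
        if not hood:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        cand = np.fromiter(hood, dtype=np.int64, count=len(hood))
        mat = np.stack([self.encoded[c] for c in cand])
        dists = (mat != enc_row).sum(axis=1)
        within = dists <= self.scheme.epsilon
        return cand[within], dists[within]


def detect_emerging(
    unassigned: ReadSet | None,
    existing_centers: list[str],
    scheme: KmerScheme,
    model: ErrorModel,
    buffered_within_eps: list[tuple[str, int, TestCase]] = (),
) -> tuple[list[tuple[str, int]], list[tuple[str, int, bool]]]:
    """Separate emerging barcodes from error sequences at a later timepoint.

    Sequences outside all epsilon-neighborhoods (``unassigned``) are
    clustered among themselves; their cluster centers are new lineages.
    Buffered within-epsilon candidates become new lineages iff the Bayesian
    test classifies them as true barcodes.

    Returns (new_barcodes, decisions) where new_barcodes is a list of
    (sequence, corrected count) and decisions records, per buffered
    candidate, (sequence, count, promoted?).
    """
    new_barcodes: list[tuple[str, int]] = []
    decisions: list[tuple[str, int, bool]] = []
    existing = set(existing_centers)
    for seq, count, case in buffered_within_eps:
        promoted = classify(case, model) is Classification.TRUE_BARCODE
        decisions.append((seq, count, promoted))
        if promoted and seq not in existing:
            new_barcodes.append((seq, count))
    if unassigned is not None and len(unassigned):
        sub = cluster_reads(unassigned, scheme, model)
        for cl in sub.clusters:
            if cl.center not in existing:
                new_barcodes.append((cl.center, cl.total_count))
    return new_barcodes, decisions


def track(
    timepoints: list[ReadSet],
    scheme: KmerScheme,
    model: ErrorModel,
    first_result: ClusteringResult | None = None,
) -> LineageTable:
    """Cluster the first timepoint, classify the rest, track lineage counts.

    ``f_max`` and the copy-number estimate n_hat are recomputed per
    timepoint; rho is platform-level and fixed across timepoints.  A member
    sequence of an existing cluster promoted by the test at timepoint t gets
    provenance "split-corrected": its earlier counts stay with the original
    cluster (the information needed to re-split them reliably is gone) and
    ``emerged_at`` records the split time.
    """
    if not timepoints:
        raise ValueError("need at least one timepoint")
    lengths = {tp.length for tp in timepoints}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent read lengths across timepoints: {lengths}")

    n_t = len(timepoints)
    result = first_result or cluster_reads(timepoints[0], scheme, model)

    barcodes = [c.center for c in result.clusters]
    provenance = [PROV_INITIAL] * len(barcodes)
    emerged = [0] * len(barcodes)
    counts_cols: list[dict[int, int]] = [
        {j: c.total_count for j, c in enumerate(result.clusters)}
    ]
    dropped = [sum(result.dropped.values())]

    cindex = _CenterIndex(scheme)
    for b in barcodes:
        cindex.add(b)
    # member sequences of the first-timepoint clustering, for split-corrected
    # provenance of later promotions
    t1_members = {
        s for s, j in result.assignment.items() if s != result.clusters[j].center
    }
    debias = (1.0 - model.rho) ** model.l

    for t in range(1, n_t):
        reads = timepoints[t]
        model_t = replace(model, f_max=reads.f_max)
        ids = scheme.ids_matrix(reads.encoded)
        seq_arr = np.asarray(reads.sequences, dtype=f"S{reads.length}")
        order = np.lexsort((seq_arr, -reads.counts))
        acc: dict[int, int] = {}
        prev = counts_cols[t - 1]
        unassigned: list[tuple[str, int]] = []

        for i in order:
            i = int(i)
            seq = reads.sequences[i]
            f_c = int(reads.counts[i])
            cand, dists = cindex.neighbors(ids[i], reads.encoded[i])
            if cand.size == 0:
                unassigned.append((seq, f_c))
                continue
            # closest; ties -> higher previous-timepoint cluster count, then sequence
            prev_counts = np.array([prev.get(int(c), 0) for c in cand])
            names = np.array([barcodes[int(c)] for c in cand])
            pick = np.lexsort((names, -prev_counts, dists))[0]
            j = int(cand[pick])
            d = int(dists[pick])
            if d == 0:
                acc[j] = acc.get(j, 0) + f_c
                continue
            # n_hat from this timepoint's accumulated count, falling back to
            # the previous corrected count when the center is unseen so far
            f_here = acc.get(j, 0)
            basis = max(f_here, prev.get(j, 0))
            case = TestCase(d=d, f_c=f_c, f_p=max(f_here, 1), n_hat=int(round(basis / debias)))
            if classify(case, model_t) is Classification.ERROR_SEQUENCE:
                acc[j] = acc.get(j, 0) + f_c
            else:
                bid = cindex.add(seq)
                barcodes.append(seq)
                provenance.append(PROV_SPLIT if seq in t1_members else PROV_EMERGING)
                emerged.append(t)
                acc[bid] = f_c

        if unassigned:
            sub_reads = ReadSet.from_pairs(unassigned, length=reads.length)
            new_barcodes, _ = detect_emerging(
                sub_reads, [], scheme, model_t, buffered_within_eps=[]
            )
            for seq, total in new_barcodes:
                bid = cindex.add(seq)
                barcodes.append(seq)
                provenance.append(PROV_EMERGING)
                emerged.append(t)
                acc[bid] = total

        counts_cols.append(acc)
        dropped.append(0)

    counts = np.zeros((len(barcodes), n_t), dtype=np.int64)
    for t, col in enumerate(counts_cols):
        for j, c in col.items():
            counts[j, t] = c
    return LineageTable(
        barcodes=barcodes,
        counts=counts,
        emerged_at=np.array(emerged, dtype=np.int64),
        provenance=provenance,
        dropped_per_timepoint=dropped,
    )
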