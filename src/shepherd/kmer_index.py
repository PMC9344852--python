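"""k-mer pigeonhole index for Hamming-distance neighborhood search.

Fixed-length sequences are tiled into ``p`` non-overlapping partitions
(substrings of length ``k``, plus one remainder partition of length ``r``
when ``k`` does not divide the barcode length ``l``).  If two sequences are
within Hamming distance ``epsilon`` of each other, the pigeonhole principle
guarantees they agree on at least ``p - epsilon`` whole partitions.  Indexing
every sequence under all C(p, p-epsilon) partition combinations therefore
yields a lookup table whose bucket unions form a superset of every
epsilon-neighborhood, which is then narrowed by exact Hamming filtering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"

# ASCII byte -> 2-bit nucleotide code; 255 marks a non-ACGT byte
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET.encode()):
    _BYTE_TO_CODE[_b] = _i
_CODE_TO_BYTE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class ConfigurationError(ValueError):
    """No feasible k-mer partitioning exists for the requested parameters."""


def encode_sequences(sequences: list[str] | np.ndarray, length: int) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, length) uint8 matrix."""
    if isinstance(sequences, np.ndarray) and sequences.dtype.kind == "S":
        raw = sequences
    else:
        raw = np.asarray(sequences, dtype=f"S{length}")
    if len(raw) == 0:
        return np.empty((0, length), dtype=np.uint8)
    flat = raw.view(np.uint8).reshape(len(raw), -1)
    if flat.shape[1] != length:
        raise ValueError(f"expected sequences of length {length}")
    enc = _BYTE_TO_CODE[flat]
    if enc.max(initial=0) == 255:
        raise AlphabetError("sequence contains a non-ACGT character")
    return enc


def decode_sequences(encoded: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    ascii_mat = np.ascontiguousarray(_CODE_TO_BYTE[encoded])
    packed = ascii_mat.view(f"S{encoded.shape[1]}").ravel()
    return packed.astype(str).tolist()


def hamming(a: str, b: str, cap: int | None = None) -> int:
    """Hamming distance between two equal-length sequences.

    With ``cap`` given, counting may stop once the running total exceeds
    ``cap``; the returned sentinel is then ``cap + 1``.  Callers only ever
    compare the result against thresholds <= cap.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} != {len(b)}")
    if cap is None:
        return sum(x != y for x, y in zip(a, b))
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return cap + 1
    return d


@dataclass
class ReadSet:
    """Deduplicated fixed-length sequences with read counts.

    The uint8 encoding is materialized once and shared by the index and the
    clustering loop for vectorized distance computations.
    """

    sequences: list[str]
    counts: np.ndarray
    length: int
    encoded: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts length mismatch")
        if len(self.counts) and self.counts.min() < 1:
            raise ValueError("read counts must be >= 1")
        if self.encoded is None:
            self.encoded = encode_sequences(self.sequences, self.length)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def f_max(self) -> int:
        return int(self.counts.max())

    @classmethod
    def from_pairs(cls, pairs, length: int | None = None) -> "ReadSet":
        """Build from (sequence, count) pairs, summing duplicate sequences."""
        tally: dict[str, int] = {}
        for seq, cnt in pairs:
            tally[seq] = tally.get(seq, 0) + int(cnt)
        if not tally:
            raise ValueError("empty read set")
        seqs = sorted(tally)
        if length is None:
            length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("sequences are not all the same length")
        return cls(seqs, np.array([tally[s] for s in seqs]), length)


@dataclass(frozen=True)
class KmerScheme:
    """A partitioning of length-``l`` sequences into p k-mers.

    ``partition_bounds`` are half-open [start, end) slices tiling [0, l);
    the last partition has length ``r`` when l is not a multiple of k.
    ``combos`` enumerates the C(p, p-epsilon) subsets of p - epsilon
    partitions in lexicographic order; the position of a subset in this list
    is part of the combination-ID encoding.
    """

    l: int
    k: int
    epsilon: int
    partition_bounds: tuple[tuple[int, int], ...]

    @property
    def p(self) -> int:
        return len(self.partition_bounds)

    @property
    def r(self) -> int:
        s, e = self.partition_bounds[-1]
        tail = e - s
        return 0 if tail == self.k else tail

    @property
    def combos(self) -> tuple[tuple[int, ...], ...]:
        return tuple(itertools.combinations(range(self.p), self.p - self.epsilon))

    @property
    def n_combinations(self) -> int:
        return math.comb(self.p, self.p - self.epsilon)

    def _id_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Weight matrix turning per-partition base-4 values into IDs.

        Returns (combo_weight_matrix, combo_offsets): the matrix is
        (p, n_combos), mapping partition values to each combination's packed
        base-4 payload; ``combo_offsets[c]`` is ``c * 4**L_max``, keeping
        distinct combination patterns disjoint, so the full encoding
        (pattern index, contents) -> ID is injective.
        """
        lens = [e - s for s, e in self.partition_bounds]
        combos = self.combos
        l_max = max(sum(lens[j] for j in combo) for combo in combos)
        if len(combos) * 4**l_max > 2**63 - 1:
            raise ConfigurationError(
                "combination IDs do not fit in 64-bit integers for this scheme; "
                "use a larger k or epsilon"
            )
        w = np.zeros((self.p, len(combos)), dtype=np.int64)
        for c, combo in enumerate(combos):
            off = 0
            for j in reversed(combo):
                w[j, c] = 4**off
                off += lens[j]
        offsets = (np.arange(len(combos), dtype=np.int64)) * (4**l_max)
        return w, offsets

    def ids_matrix(self, encoded: np.ndarray) -> np.ndarray:
        """Combination IDs for every row of an encoded sequence matrix.

        Returns an (n, C(p, p-epsilon)) int64 array.  Two sequences share an
        entry in some column pair iff they agree on every position of the
        corresponding partition subset (injective encoding).
        """
        if encoded.shape[1] != self.l:
            raise ValueError(f"expected length-{self.l} sequences")
        vals = np.empty((encoded.shape[0], self.p), dtype=np.int64)
        for j, (s, e) in enumerate(self.partition_bounds):
            pw = (4 ** np.arange(e - s - 1, -1, -1)).astype(np.int64)
            vals[:, j] = encoded[:, s:e] @ pw
        w, offsets = self._id_weights()
        return vals @ w + offsets


def _partition_bounds(l: int, k: int) -> tuple[tuple[int, int], ...]:
    bounds = [(s, min(s + k, l)) for s in range(0, l, k)]
    return tuple(bounds)


def feasible_k(l: int, epsilon: int) -> list[int]:
    """Substring lengths k for which p - epsilon > 0."""
    out = []
    for k in range(1, l + 1):
        p = len(_partition_bounds(l, k))
        if p - epsilon >= 1:
            out.append(k)
    return out


def _auto_k_cost(l: int, k: int, epsilon: int, n_sequences: int) -> float:
    """Cost proxy for choosing k: index-build term plus expected scan term.

    Build/memory cost is one table entry per combination per sequence,
    i.e. C(p, p-epsilon).  Query cost is the expected number of candidate
    sequences touched, approximated per combination by the occupancy of a
    random bucket, N / 4**L_c with L_c the actual nucleotide length of the
    combination (remainder-aware), floored at one probe.
    """
    bounds = _partition_bounds(l, k)
    p = len(bounds)
    lens = [e - s for s, e in bounds]
    build = math.comb(p, p - epsilon)
    scan = 0.0
    for combo in itertools.combinations(range(p), p - epsilon):
        l_c = sum(lens[j] for j in combo)
        scan += max(1.0, n_sequences / 4.0**l_c)
    return build + scan


def choose_k(l: int, epsilon: int, n_sequences: int = 1_000_000) -> int:
    """Pick the substring length minimizing the cost proxy; ties -> larger k."""
    candidates = feasible_k(l, epsilon)
    if not candidates:
        raise ConfigurationError(
            f"no substring length yields p - epsilon > 0 for l={l}, epsilon={epsilon}"
        )
    best = min(candidates, key=lambda k: (_auto_k_cost(l, k, epsilon, n_sequences), -k))
    return best


def make_scheme(
    l: int, epsilon: int, k: int | None = None, n_sequences: int = 1_000_000
) -> KmerScheme:
    """Build a partitioning scheme; k is chosen automatically when omitted."""
    if l < 1 or epsilon < 1:
        raise ValueError("require l >= 1 and epsilon >= 1")
    if k is None:
        k = choose_k(l, epsilon, n_sequences)
    bounds = _partition_bounds(l, k)
    if len(bounds) - epsilon < 1:
        raise ConfigurationError(
            f"p - epsilon = {len(bounds) - epsilon} <= 0 for l={l}, k={k}, "
            f"epsilon={epsilon}; choose a smaller k or epsilon"
        )
    return KmerScheme(l=l, k=k, epsilon=epsilon, partition_bounds=bounds)


def combination_ids(seq: str, scheme: KmerScheme) -> list[int]:
    """The C(p, p-epsilon) combination IDs of a single sequence."""
    enc = encode_sequences([seq], scheme.l)
    return list(scheme.ids_matrix(enc)[0])


@dataclass
class KmerIndex:
    """Lookup table from combination ID to the set of sequences containing it."""

    scheme: KmerScheme
    reads: ReadSet
    table: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _ids: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def query_ids(self, ids) -> set[int]:
        """Union of the table buckets for the given combination IDs."""
        out: set[int] = set()
        table = self.table
        for cid in ids:
            bucket = table.get(int(cid))
            if bucket:
                out.update(bucket)
        return out

    def ids_of(self, seq_index: int) -> np.ndarray:
        return self._ids[seq_index]


def build_index(reads: ReadSet, scheme: KmerScheme) -> KmerIndex:
    """Single pass over the unique sequences, filing each under all its IDs."""
    if len(reads) == 0:
        raise ValueError("empty read set")
    if reads.length != scheme.l:
        raise ValueError("read length does not match scheme")
    ids = scheme.ids_matrix(reads.encoded)
    table: dict[int, list[int]] = {}
    for i in range(ids.shape[0]):
        for cid in ids[i]:
            cid = int(cid)
            bucket = table.get(cid)
            if bucket is None:
                table[cid] = [i]
            else:
                bucket.append(i)
    return KmerIndex(scheme=scheme, reads=reads, table=table, _ids=ids)


def kmer_neighborhood(seq: str | int, index: KmerIndex) -> set[int]:
    """All indexed sequences sharing >= 1 combination ID with ``seq``.

    ``seq`` may be a sequence string or the index of an indexed sequence.
    The querying sequence itself is excluded.  By the pigeonhole principle
    the result is a superset of the epsilon-neighborhood.
    """
    if isinstance(seq, (int, np.integer)):
        ids = index.ids_of(int(seq))
        hood = index.query_ids(ids)
        hood.discard(int(seq))
        return hood
    ids = combination_ids(seq, index.scheme)
    hood = index.query_ids(ids)
    # exclude an exact occurrence of the query itself
    try:
        self_idx = index.reads.sequences.index(seq)
    except ValueError:
        self_idx = -1
    hood.discard(self_idx)
    return hood


def epsilon_neighborhood(
    seq: str | int, index: KmerIndex
) -> list[tuple[int, int]]:
    """Exact epsilon-neighbors of ``seq`` as (sequence index, distance) pairs.

    The k-mer neighborhood is narrowed by exact Hamming filtering; results
    are sorted by (distance asc, count desc, sequence) so that downstream
    tie-breaking is deterministic.
    """
    hood = kmer_neighborhood(seq, index)
    if not hood:
        return []
    cand = np.fromiter(hood, dtype=np.int64, count=len(hood))
    if isinstance(seq, (int, np.integer)):
        q = index.reads.encoded[int(seq)]
    else:
        q = encode_sequences([seq], index.scheme.l)[0]
    dists = (index.reads.encoded[cand] != q).sum(axis=1)
    keep = dists <= index.scheme.epsilon
    pairs = [(int(c), int(d)) for c, d in zip(cand[keep], dists[keep])]
    reads = index.reads
    pairs.sort(key=lambda cd: (cd[1], -reads.counts[cd[0]], reads.sequences[cd[0]]))
    return pairs
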