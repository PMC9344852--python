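"""Readers and writers for barcode read data and clustering output.

Supported inputs: headerless TSV ("sequence<TAB>count"), FASTA, and 4-line
FASTQ (one barcode per record), optionally gzip-compressed.  Identical
sequences are tallied; reads of the modal length l form the ReadSet, reads
of length l +/- 1 are routed to the indel buffer, and everything else
(including reads with non-ACGT characters) is dropped with a logged count.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .cluster import ClusteringResult
from .kmer_index import ALPHABET, ReadSet
from .track import LineageTable

_VALID = set(ALPHABET)


class FormatError(ValueError):
    """Unparseable input file."""


@dataclass
class DropLog:
    """Accounting of reads excluded from the ReadSet, by reason."""

    non_acgt: int = 0
    off_length: int = 0  # neither l nor l +/- 1
    extra: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.non_acgt + self.off_length + sum(self.extra.values())


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    name = Path(path).name.removesuffix(".gz")
    ext = Path(name).suffix.lower()
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".tsv", ".txt", ".counts"}:
        return "tsv"
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.startswith("@"):
        return "fastq"
    return "tsv"


def _iter_tsv(path):
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sequence<TAB>count'")
            try:
                count = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad count {parts[1]!r}") from exc
            yield parts[0].upper(), count


def _iter_fasta(path):
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            yield str(record.seq).upper(), 1


def _iter_fastq(path):
    with _open_text(path) as fh:
        try:
            for record in SeqIO.parse(fh, "fastq"):
                yield str(record.seq).upper(), 1
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def read_reads(
    path, fmt: str = "auto", length: int | None = None
) -> tuple[ReadSet, list[tuple[str, int]], DropLog]:
    """Load and tally reads.

    Returns (ReadSet of length-l reads, indel buffer of length l+/-1 reads,
    drop log).  ``length`` defaults to the count-weighted modal read length.
    """
    if fmt == "auto":
        fmt = _sniff_format(path)
    iterator = {"tsv": _iter_tsv, "fasta": _iter_fasta, "fastq": _iter_fastq}[fmt]

    tally: Counter[str] = Counter()
    log = DropLog()
    for seq, count in iterator(path):
        if set(seq) - _VALID:
            log.non_acgt += count
            continue
        tally[seq] += count
    if not tally:
        raise FormatError(f"{path}: no usable reads")

    if length is None:
        by_length: Counter[int] = Counter()
        for seq, count in tally.items():
            by_length[len(seq)] += count
        length = by_length.most_common(1)[0][0]

    main: list[tuple[str, int]] = []
    indel: list[tuple[str, int]] = []
    for seq in sorted(tally):
        count = tally[seq]
        if len(seq) == length:
            main.append((seq, count))
        elif abs(len(seq) - length) == 1:
            indel.append((seq, count))
        else:
            log.off_length += count
    if not main:
        raise FormatError(f"{path}: no reads of length {length}")
    return ReadSet.from_pairs(main, length=length), indel, log


def write_clusters(result: ClusteringResult, path, assignment_path=None) -> None:
    """clusters.tsv: center, total count, member count; deterministic order."""
    result.sort()
    with open(path, "w") as fh:
        fh.write("center_sequence\ttotal_count\tn_members\n")
        for c in result.clusters:
            fh.write(f"{c.center}\t{c.total_count}\t{c.n_members}\n")
    if assignment_path is not None:
        rows = []
        for c in result.clusters:
            rows.append((c.center, c.center_count, c.center, 0))
            rows.extend((s, cnt, c.center, d) for s, cnt, d in c.members)
            rows.extend((s, cnt, c.center, -1) for s, cnt in c.indel_members)
        with open(assignment_path, "w") as fh:
            fh.write("sequence\tcount\tcenter_sequence\tdistance\n")
            for seq, cnt, center, d in rows:
                fh.write(f"{seq}\t{cnt}\t{center}\t{d}\n")


def read_clusters(path) -> list[tuple[str, int, int]]:
    """Round-trip reader for clusters.tsv."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("center_sequence"):
            raise FormatError(f"{path}: missing clusters header")
        for line in fh:
            seq, total, n = line.rstrip("\n").split("\t")
            out.append((seq, int(total), int(n)))
    return out


def write_lineages(table: LineageTable, path) -> None:
    """lineages.tsv: barcode, emergence timepoint, per-timepoint counts."""
    t_cols = "\t".join(f"count_t{t + 1}" for t in range(table.n_timepoints))
    order = sorted(
        range(len(table.barcodes)),
        key=lambda j: (-int(table.counts[j].sum()), table.barcodes[j]),
    )
    with open(path, "w") as fh:
        fh.write(f"barcode\temerged_at\tprovenance\t{t_cols}\n")
        for j in order:
            counts = "\t".join(str(int(c)) for c in table.counts[j])
            fh.write(
                f"{table.barcodes[j]}\t{int(table.emerged_at[j]) + 1}\t"
                f"{table.provenance[j]}\t{counts}\n"
            )


def write_truth(truth, path) -> None:
    """Ground-truth TSV: barcode plus per-timepoint true counts."""
    n_t = truth.true_counts.shape[1]
    t_cols = "\t".join(f"count_t{t + 1}" for t in range(n_t))
    with open(path, "w") as fh:
        fh.write(f"barcode\t{t_cols}\n")
        for b, row in zip(truth.true_barcodes, truth.true_counts):
            counts = "\t".join(str(int(c)) for c in row)
            fh.write(f"{b}\t{counts}\n")


def write_reads_tsv(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for seq, count in zip(reads.sequences, reads.counts):
            fh.write(f"{seq}\t{int(count)}\n")


def write_run_metadata(path, **params) -> None:
    """Machine-readable record of the parameters a run actually used."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
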