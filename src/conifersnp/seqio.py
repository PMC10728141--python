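"""Sequence containers and FASTA/FASTQ/SAM/BED readers and writers.

All internal coordinates are 0-based half-open; conversion to 1-based
happens only at the VCF boundary (see :mod:`conifersnp.variants`). FASTQ
qualities are phred+33.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MIN_READ_LEN = 30  # pairs are discarded together when either mate drops below this
_POLY_G_RE = re.compile(r"G{10,}$")
_MIN_ADAPTER_OVERLAP = 6


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the record index."""


@dataclass
class Read:
    """A single sequencing read.

    ``id`` identifies the fragment; ``mate`` is 1 or 2. ``qual`` holds
    per-base phred scores, same length as ``seq``.
    """

    id: str
    mate: int
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}/{self.mate}: seq length {len(self.seq)} "
                f"!= qual length {len(self.qual)}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.id}: mate must be 1 or 2, got {self.mate}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """An ordered collection of reads, possibly paired via shared ids."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def pairs(self) -> dict[str, dict[int, Read]]:
        """Group reads by fragment id -> {mate: read}."""
        out: dict[str, dict[int, Read]] = {}
        for r in self.reads:
            slot = out.setdefault(r.id, {})
            if r.mate in slot:
                raise ValueError(f"duplicate read id+mate: {r.id}/{r.mate}")
            slot[r.mate] = r
        return out

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


# ---------------------------------------------------------------------------
# FASTQ / FASTA io (Biopython-backed)
# ---------------------------------------------------------------------------

_MATE_SUFFIX = re.compile(r"/([12])$")


def _record_to_read(rec: SeqRecord, default_mate: int = 1) -> Read:
    name = rec.id
    mate = default_mate
    m = _MATE_SUFFIX.search(name)
    if m:
        mate = int(m.group(1))
        name = name[: m.start()]
    return Read(
        id=name,
        mate=mate,
        seq=str(rec.seq).upper(),
        qual=tuple(rec.letter_annotations["phred_quality"]),
    )


def read_fastq(path: str | Path, default_mate: int = 1) -> ReadSet:
    """Parse a FASTQ file into a ReadSet.

    Mate numbers are taken from a trailing ``/1`` or ``/2`` on the read id
    when present, else ``default_mate``.
    """
    reads: list[Read] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(_record_to_read(rec, default_mate))
    except ValueError as exc:
        raise FastqParseError(
            f"malformed FASTQ record at index {len(reads)} in {path}: {exc}"
        ) from exc
    return ReadSet(reads)


def write_fastq(reads: ReadSet | Iterable[Read], path: str | Path) -> int:
    """Write reads as phred+33 FASTQ; returns the record count."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=f"{r.id}/{r.mate}", description="")
        rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    return SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> int:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    return SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED3 (0-based half-open)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> int:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------


def _trim_one(seq: str, qual: tuple[int, ...], trim_q: int, adapters: list[str]) -> tuple[str, tuple[int, ...]]:
    """Apply adapter, poly-G and 3' quality trimming to a fixpoint."""
    while True:
        start_len = len(seq)
        # exact adapter-prefix match running to the 3' end
        for ad in adapters:
            cut = None
            max_over = min(len(ad), len(seq))
            for over in range(max_over, _MIN_ADAPTER_OVERLAP - 1, -1):
                if seq.endswith(ad[:over]):
                    cut = len(seq) - over
                    break
            if cut is not None:
                seq, qual = seq[:cut], qual[:cut]
        # terminal G-homopolymer runs of >= 10 bp (3' only; two-channel artifact)
        m = _POLY_G_RE.search(seq)
        if m:
            seq, qual = seq[: m.start()], qual[: m.start()]
        # 3' low-quality run
        end = len(seq)
        while end > 0 and qual[end - 1] < trim_q:
            end -= 1
        seq, qual = seq[:end], qual[:end]
        if len(seq) == start_len:
            return seq, qual


def trim_reads(reads: ReadSet, trim_q: int, adapters: list[str] | None = None) -> ReadSet:
    """Trim adapters, terminal poly-G runs and 3' low-quality bases.

    Rules are applied per read until stable, so trimming is idempotent.
    Pairs where either mate drops below 30 bp are discarded together;
    unpaired reads below 30 bp are dropped individually.
    """
    adapters = [a.upper() for a in (adapters or [])]
    trimmed: dict[tuple[str, int], Read] = {}
    order: list[tuple[str, int]] = []
    for r in reads:
        seq, qual = _trim_one(r.seq, r.qual, trim_q, adapters)
        key = (r.id, r.mate)
        if key in trimmed:
            raise ValueError(f"duplicate read id+mate: {r.id}/{r.mate}")
        trimmed[key] = replace(r, seq=seq, qual=qual)
        order.append(key)

    mates: dict[str, list[int]] = {}
    for rid, mate in order:
        mates.setdefault(rid, []).append(mate)
    keep: list[Read] = []
    for rid, mate_list in mates.items():
        group = [trimmed[(rid, m)] for m in mate_list]
        if all(len(g) >= MIN_READ_LEN for g in group):
            keep.extend(group)
    return ReadSet(keep)


def expected_coverage(n_reads: float, read_len: float, genome_size: float) -> float:
    """Fold coverage = total sequenced bases / haploid genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if n_reads <= 0 or read_len <= 0:
        raise ValueError("n_reads and read_len must be > 0")
    return n_reads * read_len / genome_size
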