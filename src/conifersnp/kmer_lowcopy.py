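"""Canonical k-mer counting and the low-copy read filter.

Reads from the merged haploid pool (~20x) are screened by the fraction of
their k-mers whose pooled count falls inside a fold-coverage band (default
[10, 40], i.e. half to twice the expected pooled coverage). Reads passing
the 90% in-band threshold are taken to originate from low-copy genome
regions and feed the draft assembly and SNP discovery. Counting is exact
(plain hashing, no sketch), which keeps the filter decisions auditable
against a brute-force recount at desk scale.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .config import ConfigError
from .seqio import Read, ReadSet, revcomp


@dataclass
class KmerTable:
    k: int
    counts: Counter
    total_kmers: int  # total k-mer instances counted (with multiplicity)

    def __len__(self) -> int:
        return len(self.counts)


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _read_kmers(seq: str, k: int) -> list[str]:
    """Canonical k-mers of a read, skipping any window containing N."""
    rc = revcomp(seq)
    n = len(seq)
    out = []
    for i in range(n - k + 1):
        fw = seq[i : i + k]
        if "N" in fw:
            continue
        bw = rc[n - k - i : n - i]
        out.append(fw if fw <= bw else bw)
    return out


def count_kmers(reads: ReadSet, k: int) -> KmerTable:
    """Exact canonical k-mer counts over a read set.

    k must be odd (canonical form is then unambiguous) and within [3, 99].
    k-mers containing N are skipped. If k exceeds every read length the
    table is empty and a warning is emitted.
    """
    if k % 2 == 0 or not 3 <= k <= 99:
        raise ConfigError(f"k must be odd and within [3, 99], got {k}")
    counts: Counter = Counter()
    total = 0
    for r in reads:
        kmers = _read_kmers(r.seq, k)
        counts.update(kmers)
        total += len(kmers)
    if reads.reads and not counts:
        warnings.warn(f"k={k} exceeds every read length; empty k-mer table")
    return KmerTable(k=k, counts=counts, total_kmers=total)


def kmer_histogram(table: KmerTable, max_bin: int = 10_000) -> dict[int, int]:
    """Histogram: occurrence count -> number of distinct canonical k-mers.

    Counts above ``max_bin`` are pooled into the final bin.
    """
    hist: Counter = Counter()
    for c in table.counts.values():
        hist[min(c, max_bin)] += 1
    return dict(sorted(hist.items()))


def write_histogram_tsv(hist: dict[int, int], path: str | Path) -> None:
    """Two-column TSV (count, n_kmers), GenomeScope-style."""
    lines = [f"{c}\t{n}" for c, n in sorted(hist.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_in_band_fraction(read: Read, table: KmerTable, band: tuple[int, int]) -> float | None:
    """Fraction of a read's k-mers whose pooled count lies in the band.

    None when the read is shorter than k (no k-mers).
    """
    kmers = _read_kmers(read.seq, table.k)
    if not kmers:
        return None
    low, high = band
    in_band = sum(1 for km in kmers if low <= table.counts.get(km, 0) <= high)
    return in_band / len(kmers)


def filter_low_copy_reads(
    reads: ReadSet,
    table: KmerTable,
    band: tuple[int, int] = (10, 40),
    min_frac: float = 0.9,
) -> tuple[ReadSet, ReadSet]:
    """Split reads into (kept, rejected) by in-band k-mer fraction.

    A read is kept iff >= ``min_frac`` of its k-mers have pooled counts in
    ``band``. Reads shorter than k are rejected. Conservation holds
    exactly: kept + rejected = input.
    """
    kept: list[Read] = []
    rejected: list[Read] = []
    for r in reads:
        frac = read_in_band_fraction(r, table, band)
        if frac is not None and frac >= min_frac:
            kept.append(r)
        else:
            rejected.append(r)
    return ReadSet(kept), ReadSet(rejected)


def repair_pairs(kept: ReadSet) -> tuple[ReadSet, ReadSet]:
    """Separate a filtered read set into proper pairs and singletons.

    Pairs (both mates present, by shared fragment id) come first in input
    order; the rest are singletons. Duplicate id+mate raises.
    """
    groups = kept.pairs()  # raises on duplicate id+mate
    paired: list[Read] = []
    singles: list[Read] = []
    seen: set[str] = set()
    for r in kept:
        if r.id in seen:
            continue
        seen.add(r.id)
        slot = groups[r.id]
        if len(slot) == 2:
            paired.extend([slot[1], slot[2]])
        else:
            singles.extend(slot.values())
    return ReadSet(paired), ReadSet(singles)
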