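"""Reference-free SNP detection via the extended Burrows-Wheeler Transform.

All suffixes of a read collection (terminator-augmented, reverse
complements indexed alongside by default) are sorted into a generalized
suffix array. Suffixes sharing a long common prefix — delimited with the
LCP array — tend to span the same genomic locus (positional clustering),
so the multiset of characters *preceding* them (the eBWT column) exposes
the alleles segregating at the position immediately left of the shared
context. A cluster whose preceding characters split into exactly two
well-supported bases yields a SNP candidate carrying its shared right
context; candidates are anchored to a reference afterwards by locating
that context, which turns them into ordinary VCF records.

Suffix sorting uses prefix doubling over the integer-coded text (unique
terminators sort before all bases, making the transform stable and
independent of input order); the LCP array comes from Kasai's algorithm.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError
from .seqio import ReadSet, revcomp
from .variants import SampleCall, VariantRecord, VariantSet

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class EBWTIndex:
    """Generalized suffix array, LCP and eBWT of a read collection."""

    reads: list[str]  # including reverse complements when indexed
    text: np.ndarray  # int codes: terminator of read r -> r; base b -> n_reads + b
    sa: np.ndarray
    lcp: np.ndarray  # lcp[i] = LCP(suffix sa[i-1], suffix sa[i]); lcp[0] = 0
    bwt: np.ndarray  # int codes, text[sa[i]-1] with wrap-around
    read_of: np.ndarray  # text position -> read index
    read_start: np.ndarray  # read index -> offset of first base
    n_reads: int

    def ebwt_string(self) -> str:
        """The eBWT as a string, '$' for every terminator."""
        out = []
        for c in self.bwt:
            out.append("$" if c < self.n_reads else _BASES[c - self.n_reads])
        return "".join(out)

    def decode(self, start: int, length: int) -> str:
        """Decode a base substring of the text (stops at a terminator)."""
        out = []
        for c in self.text[start : start + length]:
            if c < self.n_reads:
                break
            out.append(_BASES[c - self.n_reads])
        return "".join(out)


def _suffix_array_int(arr: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over an integer array with a unique
    smallest sentinel guaranteed by per-read terminators."""
    n = len(arr)
    _, rank = np.unique(arr, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while rank.max() < n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        k *= 2
    sa = np.empty(n, dtype=np.int64)
    sa[rank] = np.arange(n)
    return sa


def _kasai_lcp(arr: np.ndarray, sa: np.ndarray) -> np.ndarray:
    n = len(arr)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and arr[i + h] == arr[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def build_ebwt(reads: ReadSet | list[str], include_rc: bool = True) -> EBWTIndex:
    """Build the eBWT index of a read collection.

    Reads containing N are split on the Ns; with ``include_rc`` every
    read's reverse complement is indexed too (strand-agnostic clustering).
    Terminators are distinct per read and sort before every base, so the
    transform does not depend on tie-breaking.
    """
    seqs: list[str] = []
    raw = [r.seq for r in reads] if isinstance(reads, ReadSet) else list(reads)
    for s in raw:
        for part in s.upper().split("N"):
            if part:
                seqs.append(part)
    if not seqs:
        raise ConfigError("empty read set")
    if include_rc:
        seqs = seqs + [revcomp(s) for s in seqs]
    m = len(seqs)
    total = sum(len(s) for s in seqs) + m
    text = np.empty(total, dtype=np.int64)
    read_of = np.empty(total, dtype=np.int64)
    read_start = np.empty(m, dtype=np.int64)
    pos = 0
    code = {b: m + i for i, b in enumerate(_BASES)}
    for r, s in enumerate(seqs):
        read_start[r] = pos
        for ch in s:
            text[pos] = code[ch]
            read_of[pos] = r
            pos += 1
        text[pos] = r  # unique terminator, sorts before all bases
        read_of[pos] = r
        pos += 1
    sa = _suffix_array_int(text)
    lcp = _kasai_lcp(text, sa)
    bwt = text[sa - 1]  # wrap-around at sa == 0 indexes the final terminator
    return EBWTIndex(
        reads=seqs,
        text=text,
        sa=sa,
        lcp=lcp,
        bwt=bwt,
        read_of=read_of,
        read_start=read_start,
        n_reads=m,
    )


def invert_ebwt(index: EBWTIndex) -> list[str]:
    """Reproduce the input reads from the eBWT column via LF-mapping."""
    n = len(index.bwt)
    order = np.argsort(index.bwt, kind="stable")
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(n)
    rank = np.empty(n, dtype=np.int64)
    rank[index.sa] = np.arange(n)
    out: list[str] = []
    chars: list[str] = []
    r = int(rank[0])  # row of the suffix starting at text position 0
    for _ in range(n):
        c = int(index.bwt[r])
        if c < index.n_reads:
            chars.append("$")
        else:
            chars.append(_BASES[c - index.n_reads])
        r = int(lf[r])
    full = "".join(reversed(chars))  # the text, terminators included
    for part in full.split("$"):
        if part:
            out.append(part)
    return out


@dataclass
class PositionalCluster:
    """A maximal SA interval whose suffixes share a long right context."""

    lo: int
    hi: int  # half-open
    context_len: int

    @property
    def size(self) -> int:
        return self.hi - self.lo


def detect_clusters(
    index: EBWTIndex, min_context: int = 20, min_size: int = 4
) -> list[PositionalCluster]:
    """Maximal SA intervals with interior LCP >= ``min_context``.

    The interval's suffixes all start with the same ``context_len``-long
    string (the minimum interior LCP); its preceding characters are read
    off the eBWT column by the caller.
    """
    if min_context < 1:
        raise ConfigError("min_context must be >= 1")
    mask = index.lcp >= min_context
    clusters: list[PositionalCluster] = []
    n = len(mask)
    t = 1
    while t < n:
        if mask[t]:
            t0 = t
            while t + 1 < n and mask[t + 1]:
                t += 1
            lo, hi = t0 - 1, t + 1
            if hi - lo >= min_size:
                ctx = int(index.lcp[t0 : t + 1].min())
                clusters.append(PositionalCluster(lo, hi, ctx))
        t += 1
    return clusters


@dataclass
class SNPCandidate:
    """A biallelic candidate: two preceding alleles sharing a right context."""

    alleles: tuple[str, str]  # sorted
    support: tuple[int, int]  # aligned with alleles
    right_context: str
    left_contexts: dict[str, str] = field(default_factory=dict)
    reads: dict[str, list[int]] = field(default_factory=dict)


def call_snps_from_clusters(
    index: EBWTIndex,
    clusters: list[PositionalCluster],
    min_allele_support: int = 2,
    max_context: int = 40,
) -> list[SNPCandidate]:
    """Turn positional clusters into biallelic SNP candidates.

    A cluster yields a candidate iff its preceding-character multiset
    contains exactly two bases, each supported by >= ``min_allele_support``
    reads. The default of 2 suits error-free or low-error haploid pools
    where a singleton allele contributes only a handful of context-bearing
    reads per strand; raise it (roughly pooled coverage / 4) for noisier
    read sets. Left contexts (up to 30 bp) are reconstructed from a
    representative occurrence of each allele. Candidates duplicated across
    clusters (same context and allele pair) are merged; clusters with more
    than two preceding bases are dropped as ambiguous.
    """
    merged: dict[tuple[str, tuple[str, str]], SNPCandidate] = {}
    n_ambiguous = 0
    for cl in clusters:
        counts: Counter = Counter()
        occurrence: dict[str, int] = {}
        readsets: dict[str, set[int]] = {}
        for t in range(cl.lo, cl.hi):
            c = int(index.bwt[t])
            if c < index.n_reads:  # suffix starts a read; no preceding base
                continue
            base = _BASES[c - index.n_reads]
            counts[base] += 1
            occurrence.setdefault(base, t)
            readsets.setdefault(base, set()).add(int(index.read_of[index.sa[t]]))
        if len(counts) != 2:
            if len(counts) > 2:
                n_ambiguous += 1
            continue
        (a, na), (b, nb) = sorted(counts.items())
        if na < min_allele_support or nb < min_allele_support:
            continue
        ctx_len = min(cl.context_len, max_context)
        context = index.decode(int(index.sa[cl.lo]), ctx_len)
        if len(context) < ctx_len:
            continue  # context truncated by a terminator
        lefts: dict[str, str] = {}
        for base, t in occurrence.items():
            p = int(index.sa[t])
            r = int(index.read_of[p])
            start = max(int(index.read_start[r]), p - 1 - 30)
            lefts[base] = index.decode(start, (p - 1) - start)
        key = (context, (a, b))
        prev = merged.get(key)
        if prev is None:
            merged[key] = SNPCandidate(
                alleles=(a, b),
                support=(na, nb),
                right_context=context,
                left_contexts=lefts,
                reads={a: sorted(readsets[a]), b: sorted(readsets[b])},
            )
        else:
            prev.support = (prev.support[0] + na, prev.support[1] + nb)
    if n_ambiguous:
        logger.info("dropped %d clusters with >2 preceding bases", n_ambiguous)
    return list(merged.values())


def write_candidates_fasta(candidates: list[SNPCandidate], path) -> int:
    """Paired-sequence calls file: two context sequences per event."""
    lines = []
    for i, c in enumerate(candidates):
        for j, allele in enumerate(c.alleles):
            lines.append(
                f">cand{i}_{j} allele={allele} support={c.support[j]}"
            )
            lines.append(c.left_contexts.get(allele, "") + allele + c.right_context)
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(candidates)


def anchor_to_reference(
    candidates: list[SNPCandidate],
    ref: dict[str, str],
    min_context: int = 20,
    method: str = "ebwt",
) -> VariantSet:
    """Locate each candidate's right context in a reference and emit VCF
    records.

    The context must match exactly once genome-wide (both strands
    searched); the SNP sits immediately left of a forward match (right of
    a reverse match, alleles complemented). The reference base must be one
    of the two alleles; the other becomes ALT. Multi-hit, unplaced and
    ref-mismatching candidates are dropped with counts logged.
    """
    stats = Counter()
    by_site: dict[tuple[str, int], VariantRecord] = {}
    for cand in candidates:
        ctx = cand.right_context
        if len(ctx) < min_context:
            stats["short_context"] += 1
            continue
        hits: list[tuple[str, int, str]] = []  # (contig, snp_pos, strand)
        rc_ctx = revcomp(ctx)
        for contig, seq in ref.items():
            i = seq.find(ctx)
            while i != -1:
                hits.append((contig, i - 1, "+"))
                i = seq.find(ctx, i + 1)
            i = seq.find(rc_ctx)
            while i != -1:
                hits.append((contig, i + len(ctx), "-"))
                i = seq.find(rc_ctx, i + 1)
        if len(hits) != 1:
            stats["multi_hit" if hits else "no_hit"] += 1
            continue
        contig, pos, strand = hits[0]
        if pos < 0 or pos >= len(ref[contig]):
            stats["out_of_range"] += 1
            continue
        alleles = cand.alleles
        if strand == "-":
            alleles = tuple(sorted(revcomp(a) for a in alleles))
        ref_base = ref[contig][pos]
        if ref_base not in alleles:
            stats["ref_mismatch"] += 1
            continue
        alt = alleles[0] if alleles[1] == ref_base else alleles[1]
        if (contig, pos) in by_site:
            stats["duplicate_site"] += 1
            continue
        by_site[(contig, pos)] = VariantRecord(
            contig=contig,
            pos=pos,
            ref=ref_base,
            alts=(alt,),
            samples={},
            mq=60.0,
            method=method,
        )
        stats["anchored"] += 1
    if stats:
        logger.info("anchoring: %s", dict(stats))
    recs = sorted(by_site.values(), key=lambda r: (r.contig, r.pos))
    return VariantSet(recs, (), method)
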