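"""Seed-and-extend read mapping, pileup calling and the SNP filter cascade.

The mapper is a deliberately simple stand-in for a production short-read
aligner: exact seeds, ungapped extension, one best placement per read.
Reporting a single best hit even for ambiguous reads reproduces, on
repeat-bearing references, the pileup-inflation pathology that motivates
the anchor-region read-subsetting workaround — paralogous reads stack on
the draft contigs and must be removed by restricting input reads to those
whose alignment to the related-species reference falls inside regions
where the draft contigs anchor. Real alignments can be imported from SAM.

Variant calling is per-haploid-sample consensus from the pileup, followed
by the fixed filter cascade: biallelic -> depth/GQ/MQ -> within-individual
heterozygosity -> alternative-allele frequency, then an optional spacing
filter. The maximum-depth mask (d + 4*sqrt(d)) is provided as the
alternative repeat guard; it is not part of the default cascade.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from .config import ConfigError, PipelineConfig
from .seqio import Read, ReadSet, revcomp
from .simgen import _to_arr  # shared base-code table
from .variants import SampleCall, VariantRecord, VariantSet


@dataclass
class Alignment:
    read_id: str
    mate: int
    contig: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mapq: int
    cigar: str
    nm: int
    seq: str = ""  # read sequence in reference orientation
    qual: tuple[int, ...] | None = None

    @property
    def end(self) -> int:
        return self.start + self.aligned_len

    @property
    def aligned_len(self) -> int:
        n = 0
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MD":
                    n += int(num)
                num = ""
        return n


@dataclass
class DepthProfile:
    """Per-position depth along one contig."""

    contig: str
    depth: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def max_depth_threshold(self) -> float:
        d = self.mean
        return d + 4.0 * math.sqrt(d)


# ---------------------------------------------------------------------------
# Seed mapping
# ---------------------------------------------------------------------------


class SeedIndex:
    """Exact-k-mer index of a reference, for seed-and-extend placement."""

    def __init__(self, ref: dict[str, str], seed_len: int = 21, max_hits: int = 200):
        self.seed_len = seed_len
        self.names = list(ref)
        self.arrs = {name: _to_arr(seq) for name, seq in ref.items()}
        self.lengths = {name: len(seq) for name, seq in ref.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        self.max_hits = max_hits
        for name, seq in ref.items():
            for i in range(len(seq) - seed_len + 1):
                km = seq[i : i + seed_len]
                hits = self.index.setdefault(km, [])
                if len(hits) < max_hits:
                    hits.append((name, i))


def seed_map(
    reads: ReadSet,
    ref: dict[str, str] | SeedIndex,
    seed_len: int = 21,
    max_mismatch: int = 8,
    max_candidates: int = 60,
) -> tuple[list[Alignment], list[str]]:
    """Map reads by exact seeding and ungapped extension.

    One best placement per read is reported. MAPQ is 0 when several
    placements tie the best mismatch count, 60 when the placement is
    unique with no runner-up, else scaled by the mismatch gap to the
    runner-up. Returns (alignments, unmapped read ids).
    """
    idx = ref if isinstance(ref, SeedIndex) else SeedIndex(ref, seed_len)
    k = idx.seed_len
    alignments: list[Alignment] = []
    unmapped: list[str] = []
    for r in reads:
        L = len(r.seq)
        if L < k:
            unmapped.append(f"{r.id}/{r.mate}")
            continue
        best: tuple[int, str, int, str] | None = None  # (mm, contig, start, strand)
        best_count = 0
        second = None
        seen: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", r.seq), ("-", revcomp(r.seq))):
            arr = _to_arr(seq)
            offsets = sorted({0, L // 3, (2 * L) // 3, L - k})
            n_cand = 0
            for off in offsets:
                for contig, pos in idx.index.get(seq[off : off + k], ()):
                    start = pos - off
                    key = (contig, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    if start < 0 or start + L > idx.lengths[contig]:
                        continue
                    n_cand += 1
                    if n_cand > max_candidates:
                        break
                    mm = int(np.count_nonzero(idx.arrs[contig][start : start + L] != arr))
                    if best is None or mm < best[0]:
                        second = best[0] if best else None
                        best = (mm, contig, start, strand)
                        best_count = 1
                    elif mm == best[0]:
                        best_count += 1
                        second = mm
                    elif second is None or mm < second:
                        second = mm
                if n_cand > max_candidates:
                    break
        if best is None or best[0] > max_mismatch:
            unmapped.append(f"{r.id}/{r.mate}")
            continue
        mm, contig, start, strand = best
        if best_count > 1:
            mapq = 0
        elif second is None:
            mapq = 60
        else:
            mapq = min(60, 6 * (second - mm))
        oriented = r.seq if strand == "+" else revcomp(r.seq)
        qual = r.qual if strand == "+" else tuple(reversed(r.qual))
        alignments.append(
            Alignment(
                read_id=r.id,
                mate=r.mate,
                contig=contig,
                start=start,
                strand=strand,
                mapq=mapq,
                cigar=f"{L}M",
                nm=mm,
                seq=oriented,
                qual=qual,
            )
        )
    return alignments, unmapped


# ---------------------------------------------------------------------------
# SAM io (pysam-backed; M/I/D/S CIGARs)
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Iterable[Alignment],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> int:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contig_lengths.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"{a.read_id}/{a.mate}"
            seg.query_sequence = a.seq or None
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = out.header.get_tid(a.contig)
            seg.reference_start = a.start
            seg.mapping_quality = a.mapq
            seg.cigarstring = a.cigar
            if a.qual is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in a.qual)
                )
            seg.set_tag("NM", a.nm)
            out.write(seg)
            n += 1
    return n


def read_sam(path: str | Path) -> list[Alignment]:
    """Import alignments from SAM/BAM; unmapped and secondary records skipped."""
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            name = seg.query_name
            mate = 1
            if name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            elif seg.is_paired:
                mate = 2 if seg.is_read2 else 1
            out.append(
                Alignment(
                    read_id=name,
                    mate=mate,
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    cigar=seg.cigarstring or "",
                    nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    seq=seg.query_sequence or "",
                    qual=tuple(seg.query_qualities) if seg.query_qualities is not None else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Anchor-region read subsetting (the depth-anomaly workaround)
# ---------------------------------------------------------------------------


def subset_reads_by_anchor_regions(
    alignments: Iterable[Alignment],
    anchor_intervals: list[tuple[str, int, int]],
    reads: ReadSet | None = None,
) -> tuple[set[str], ReadSet]:
    """Read ids whose alignment overlaps >= 1 bp of any anchor interval.

    The returned ids identify fragments; when ``reads`` is given, both
    mates of any selected fragment are returned for re-mapping to the
    draft assembly. Intervals on contigs absent from the alignments are
    skipped with a warning.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in anchor_intervals:
        by_contig.setdefault(c, []).append((s, e))
    starts_ends = {
        c: (
            np.array([s for s, _ in sorted(iv)]),
            np.array([e for _, e in sorted(iv)]),
        )
        for c, iv in by_contig.items()
    }
    seen_contigs: set[str] = set()
    ids: set[str] = set()
    for a in alignments:
        seen_contigs.add(a.contig)
        iv = starts_ends.get(a.contig)
        if iv is None:
            continue
        starts, ends = iv
        j = int(np.searchsorted(starts, a.end))
        if np.any(ends[:j] > a.start):
            ids.add(a.read_id)
    missing = set(by_contig) - seen_contigs
    if missing:
        warnings.warn(f"anchor intervals on contigs with no alignments: {sorted(missing)[:5]}")
    subset = ReadSet([r for r in reads if r.id in ids]) if reads is not None else ReadSet([])
    return ids, subset


def depth_profiles(
    alignments: Iterable[Alignment], contig_lengths: dict[str, int]
) -> dict[str, DepthProfile]:
    depth = {c: np.zeros(ln, dtype=np.int32) for c, ln in contig_lengths.items()}
    for a in alignments:
        d = depth.get(a.contig)
        if d is not None:
            d[a.start : min(a.end, len(d))] += 1
    return {c: DepthProfile(c, d) for c, d in depth.items()}


def max_depth_mask(profile: DepthProfile) -> list[tuple[str, int, int]]:
    """BED intervals where depth exceeds d + 4*sqrt(d) (d = mean depth)."""
    if len(profile.depth) == 0:
        raise ValueError("empty depth profile")
    thr = profile.max_depth_threshold
    mask = profile.depth > thr
    out: list[tuple[str, int, int]] = []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    for s, e in zip(starts, ends):
        out.append((profile.contig, int(s), int(e)))
    return out


# ---------------------------------------------------------------------------
# Pileup calling
# ---------------------------------------------------------------------------

_GQ_SCALE = 4  # phred-like proxy: GQ = min(60, 4 * (best - second-best support))


def pileup_call(
    alignments_by_sample: dict[str, list[Alignment]],
    ref: dict[str, str],
    min_base_q: int = 13,
    method: str = "silver",
) -> VariantSet:
    """Consensus-call each haploid sample from its pileup.

    Per sample and site the consensus base is the majority base; its
    genotype quality is min(60, 4 * (best - second-best support)). A site
    is emitted when at least one called sample differs from the reference
    base. Site MQ is the RMS mapping quality of all reads covering the
    site. Bases with quality below ``min_base_q`` are excluded from the
    pileup when base qualities are available.
    """
    samples = list(alignments_by_sample)
    if len(samples) < 2:
        raise ConfigError("pileup calling requires >= 2 haploid samples")
    grouped: dict[str, dict[str, list[Alignment]]] = {s: {} for s in samples}
    for sample, alns in alignments_by_sample.items():
        for a in alns:
            grouped[sample].setdefault(a.contig, []).append(a)
    records: list[VariantRecord] = []
    for contig, seq in ref.items():
        L = len(seq)
        ref_arr = _to_arr(seq)
        counts = np.zeros((len(samples), 4, L), dtype=np.int32)
        mq_sq = np.zeros(L, dtype=np.float64)
        mq_n = np.zeros(L, dtype=np.int32)
        for si, sample in enumerate(samples):
            for a in grouped[sample].get(contig, ()):
                codes = _to_arr(a.seq)
                pos = np.arange(a.start, a.start + len(codes))
                ok = (pos >= 0) & (pos < L) & (codes < 4)
                if a.qual is not None:
                    ok &= np.asarray(a.qual) >= min_base_q
                np.add.at(counts[si], (codes[ok], pos[ok]), 1)
                mq_sq[pos[ok]] += a.mapq**2
                mq_n[pos[ok]] += 1
        depth = counts.sum(axis=1)  # (samples, L)
        order = np.argsort(counts, axis=1)
        best_code = order[:, 3, :]
        best_n = np.take_along_axis(counts, best_code[:, None, :], axis=1)[:, 0, :]
        second_n = np.take_along_axis(counts, order[:, 2, :][:, None, :], axis=1)[:, 0, :]
        gq = np.minimum(60, _GQ_SCALE * (best_n - second_n))
        called = depth > 0
        differs = called & (best_code != ref_arr[None, :])
        site_mask = differs.any(axis=0)
        for p in np.flatnonzero(site_mask):
            p = int(p)
            scalls: dict[str, SampleCall] = {}
            alt_order: list[str] = []
            for si, sample in enumerate(samples):
                if not called[si, p]:
                    scalls[sample] = SampleCall(None, 0, 0)
                    continue
                base = "ACGT"[best_code[si, p]]
                bc = {
                    "ACGT"[b]: int(counts[si, b, p])
                    for b in range(4)
                    if counts[si, b, p] > 0
                }
                scalls[sample] = SampleCall(base, int(depth[si, p]), int(gq[si, p]), bc)
                if base != seq[p] and base not in alt_order:
                    alt_order.append(base)
            mq = math.sqrt(mq_sq[p] / mq_n[p]) if mq_n[p] else 0.0
            records.append(
                VariantRecord(
                    contig=contig,
                    pos=p,
                    ref=seq[p],
                    alts=tuple(alt_order),
                    samples=scalls,
                    mq=mq,
                    method=method,
                )
            )
    return VariantSet(records, tuple(samples), method)


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

HET_MINOR_FRAC = 0.20  # minor base >= 20% of a haploid's reads flags collapsed paralogs
HET_MINOR_MIN_READS = 2


class FilterResult(NamedTuple):
    variants: VariantSet
    attrition: dict[str, int]
    annotated: VariantSet  # all input records with FILTER set


def _first_failure(rec: VariantRecord, cfg: PipelineConfig) -> str | None:
    if not rec.is_biallelic_snp():
        return "biallelic"
    called = [s for s in rec.samples.values() if s.base is not None]
    if any(s.depth < cfg.min_depth for s in called):
        return "depth"
    if any(s.gq < cfg.min_gq for s in called):
        return "gq"
    if rec.mq < cfg.min_mq:
        return "mq"
    for s in called:
        if len(s.base_counts) >= 2:
            top = sorted(s.base_counts.values(), reverse=True)
            minor = top[1]
            if minor >= HET_MINOR_MIN_READS and minor >= HET_MINOR_FRAC * s.depth:
                return "het"
    if rec.af < cfg.min_af:
        return "af"
    return None


def filter_variants(raw: VariantSet, cfg: PipelineConfig) -> FilterResult:
    """Apply the fixed cascade: biallelic -> depth/GQ/MQ -> het -> AF.

    Each record's FILTER is set to the first failing rule (or PASS);
    removal counts per rule are returned and conserve:
    len(raw) = len(kept) + sum(attrition).
    """
    attrition = {k: 0 for k in ("biallelic", "depth", "gq", "mq", "het", "af")}
    kept: list[VariantRecord] = []
    for rec in raw:
        fail = _first_failure(rec, cfg)
        rec.filter = fail or "PASS"
        if fail is None:
            kept.append(rec)
        else:
            attrition[fail] += 1
    return FilterResult(
        VariantSet(kept, raw.sample_names, raw.method),
        attrition,
        raw,
    )


def spacing_filter(vs: VariantSet, min_spacing: int) -> VariantSet:
    """Greedy left-to-right spacing filter per contig.

    Keeps a record iff it lies >= ``min_spacing`` bp from the last kept
    record on the same contig. Input must be sorted by (contig, pos).
    """
    last: tuple[str, int] | None = None
    prev_key: tuple[str, int] | None = None
    kept: list[VariantRecord] = []
    for rec in vs:
        key = (rec.contig, rec.pos)
        if prev_key is not None and key < prev_key:
            raise ValueError("spacing_filter requires input sorted by (contig, pos)")
        prev_key = key
        if last is None or rec.contig != last[0] or rec.pos - last[1] >= min_spacing:
            kept.append(rec)
            last = key
    return VariantSet(kept, vs.sample_names, vs.method)
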