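"""Variant containers and VCFv4.2 io.

Internally positions are 0-based; the pysam-backed reader/writer converts
at the boundary (VCF is 1-based). Each record carries per-haploid-sample
calls (base, depth, genotype quality) plus site mapping quality, the
alternative-allele frequency among called haploids, and a method tag
identifying the calling branch (``mas``, ``silver`` or ``ebwt``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

VALID_BASES = frozenset("ACGT")
METHOD_TAGS = ("mas", "silver", "ebwt")


@dataclass
class SampleCall:
    """One haploid sample's call at a site.

    ``base`` is None when the sample is uncalled (no/ambiguous coverage).
    ``base_counts`` keeps the raw pileup support per base, used by the
    within-individual heterozygosity filter.
    """

    base: str | None
    depth: int
    gq: int
    base_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    samples: dict[str, SampleCall] = field(default_factory=dict)
    mq: float = 60.0
    method: str = "silver"
    filter: str = "PASS"

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def af(self) -> float:
        """Alternative-allele frequency among called haploid samples."""
        called = [s for s in self.samples.values() if s.base is not None]
        if not called:
            return 0.0
        alt = sum(1 for s in called if s.base != self.ref)
        return alt / len(called)

    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and self.ref in VALID_BASES
            and all(a in VALID_BASES for a in self.alts)
        )


@dataclass
class VariantSet:
    records: list[VariantRecord] = field(default_factory=list)
    sample_names: tuple[str, ...] = ()
    method: str = "silver"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def sorted(self) -> "VariantSet":
        recs = sorted(self.records, key=lambda r: (r.contig, r.pos))
        return VariantSet(recs, self.sample_names, self.method)


# ---------------------------------------------------------------------------
# VCF io (pysam/htslib-backed)
# ---------------------------------------------------------------------------


def _build_header(vs: VariantSet, contig_lengths: dict[str, int] | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in vs.records:
        contigs.setdefault(rec.contig, 0)
        if contigs[rec.contig] < rec.pos + 1:
            contigs[rec.contig] = rec.pos + 1
    for name, length in contigs.items():
        header.contigs.add(name, length=max(length, 1))
    header.info.add("MQ", 1, "Float", "RMS mapping quality of contributing reads")
    header.info.add("AF", "A", "Float", "Alternative allele frequency among called haploids")
    header.info.add("MT", 1, "String", "Calling method tag (mas/silver/ebwt)")
    header.formats.add("GT", 1, "String", "Haploid genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for name in ("biallelic", "depth", "gq", "mq", "het", "af", "spacing"):
        header.filters.add(name, None, None, f"Failed the {name} rule")
    for s in vs.sample_names:
        header.add_sample(s)
    return header


def write_vcf(vs: VariantSet, path: str | Path, contig_lengths: dict[str, int] | None = None) -> int:
    """Write a VariantSet as VCFv4.2 (uncompressed text)."""
    header = _build_header(vs, contig_lengths)
    n = 0
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in vs.records:
            v = out.new_record(
                contig=rec.contig,
                start=rec.pos,
                stop=rec.pos + len(rec.ref),
                alleles=rec.alleles,
            )
            v.info["MQ"] = float(rec.mq)
            v.info["AF"] = float(rec.af)
            v.info["MT"] = rec.method
            if rec.filter != "PASS":
                v.filter.add(rec.filter)
            allele_index = {a: i for i, a in enumerate(rec.alleles)}
            for name in vs.sample_names:
                call = rec.samples.get(name)
                fmt = v.samples[name]
                if call is None or call.base is None:
                    fmt["GT"] = (None,)
                else:
                    fmt["GT"] = (allele_index.get(call.base),)
                    fmt["DP"] = call.depth
                    fmt["GQ"] = call.gq
            out.write(v)
            n += 1
    return n


def read_vcf(path: str | Path, method: str | None = None) -> VariantSet:
    """Read a VCF into a VariantSet (positions converted to 0-based)."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = tuple(vcf.header.samples)
        for v in vcf:
            alleles = tuple(a.upper() for a in v.alleles)
            samples: dict[str, SampleCall] = {}
            for name in sample_names:
                fmt = v.samples[name]
                gt = fmt.get("GT", (None,))
                idx = gt[0] if gt else None
                base = alleles[idx] if idx is not None else None
                samples[name] = SampleCall(
                    base=base,
                    depth=int(fmt.get("DP") or 0),
                    gq=int(fmt.get("GQ") or 0),
                )
            filt = next(iter(v.filter.keys()), "PASS")
            records.append(
                VariantRecord(
                    contig=v.chrom,
                    pos=v.start,
                    ref=alleles[0],
                    alts=alleles[1:],
                    samples=samples,
                    mq=float(v.info.get("MQ", 60.0)),
                    method=method or str(v.info.get("MT", "silver")),
                    filter=filt,
                )
            )
    mt = method or (records[0].method if records else "silver")
    return VariantSet(records, sample_names, mt)


# ---------------------------------------------------------------------------
# Genotype matrix TSV (individuals x loci, cells 0/1/2/NA)
# ---------------------------------------------------------------------------


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    gm = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return gm.astype("float64")


def write_genotype_tsv(gm: pd.DataFrame, path: str | Path) -> None:
    out = gm.copy()
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
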