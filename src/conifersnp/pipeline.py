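"""Stage orchestration for the toy end-to-end run.

Stages mirror the discovery workflow: simulate -> kmerfilter -> map ->
call -> ebwt -> intersect -> genotype -> clones. Each stage reads its
inputs from the run directory, writes standard-format outputs plus record
counts into ``manifest.json``, and fails with a pointer to the missing
upstream stage when run out of order. The three calling branches (mas,
silver, ebwt) are independent and meet in ``intersect``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import crossref, ebwtfree, genoclone, kmer_lowcopy, mapcall, simgen
from .config import PipelineConfig
from .seqio import (
    ReadSet,
    read_bed,
    read_fasta,
    read_fastq,
    trim_reads,
    write_bed,
    write_fasta,
    write_fastq,
)
from .variants import VariantSet, read_vcf, write_genotype_tsv, write_vcf

STAGES = (
    "simulate",
    "kmerfilter",
    "map",
    "call",
    "ebwt",
    "intersect",
    "genotype",
    "clones",
)

HAPLOID_SAMPLES = ("hap1", "hap2", "hap3", "hap4")


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{stage}' stage first"
        )
    return path


@dataclass
class Pipeline:
    """One run directory plus its configuration and manifest."""

    config: PipelineConfig
    run_dir: Path
    sim_size: int = 200_000
    repeat_fraction: float = 0.75
    divergence: float = 0.02
    coverage: float = 5.0
    read_err: float = 0.002
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.run_dir = Path(self.run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        (self.run_dir / "truth").mkdir(exist_ok=True)
        mf = self.run_dir / "manifest.json"
        if mf.exists():
            self.manifest = json.loads(mf.read_text())
        self.manifest.setdefault("config", self.config.to_dict())
        self.manifest.setdefault("config_hash", self.config.digest())
        self.manifest.setdefault("stages", {})

    def _record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = {"time": round(time.time(), 2), **counts}
        (self.run_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )

    # ------------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        genome = simgen.generate_genome(
            self.sim_size,
            repeat_fraction=self.repeat_fraction,
            divergence=self.divergence,
            seed=cfg.seed,
        )
        haploids, truth = simgen.sample_haploids(genome, seed=cfg.seed + 1)
        write_fasta({"truth": genome.truth}, self.run_dir / "truth.fasta")
        write_fasta({"silver": genome.silver_ref}, self.run_dir / "silver.fasta")
        write_fasta(genome.draft_contigs, self.run_dir / "contigs.fasta")
        write_bed(
            [("truth", s, e) for s, e in genome.lowcopy_intervals],
            self.run_dir / "truth" / "lowcopy.bed",
        )
        truth.to_csv(self.run_dir / "truth" / "snps.tsv", sep="\t", index=False)
        origin_lines = ["#contig\tstart\tend\tstrand"]
        for name, (s, e, st) in genome.contig_origin.items():
            origin_lines.append(f"{name}\t{s}\t{e}\t{st}")
        (self.run_dir / "truth" / "contig_origin.tsv").write_text(
            "\n".join(origin_lines) + "\n"
        )
        n_reads = 0
        for i, (name, seq) in enumerate(haploids.items()):
            reads = simgen.simulate_reads(
                seq,
                coverage=self.coverage,
                err=self.read_err,
                seed=cfg.seed + 10 + i,
                sample=name,
            )
            reads = trim_reads(reads, cfg.trim_q)
            n_reads += len(reads)
            write_fastq(reads, self.run_dir / f"{name}.fastq")
        self._record(
            "simulate",
            genome_bp=len(genome.truth),
            contigs=len(genome.draft_contigs),
            truth_snps=len(truth),
            reads=n_reads,
        )

    # ------------------------------------------------------------------
    def kmerfilter(self) -> None:
        cfg = self.config
        merged: list = []
        per_sample: dict[str, ReadSet] = {}
        for name in HAPLOID_SAMPLES:
            rs = read_fastq(_require(self.run_dir / f"{name}.fastq", "simulate"))
            per_sample[name] = rs
            merged.extend(rs.reads)
        table = kmer_lowcopy.count_kmers(ReadSet(merged), cfg.k)
        hist = kmer_lowcopy.kmer_histogram(table)
        kmer_lowcopy.write_histogram_tsv(hist, self.run_dir / "kmer_histogram.tsv")
        n_kept = 0
        for name, rs in per_sample.items():
            kept, _rej = kmer_lowcopy.filter_low_copy_reads(
                rs, table, cfg.cov_band, cfg.min_kmer_frac
            )
            paired, singles = kmer_lowcopy.repair_pairs(kept)
            n_kept += len(kept)
            write_fastq(paired, self.run_dir / f"{name}.lowcopy.fastq")
            write_fastq(singles, self.run_dir / f"{name}.singletons.fastq")
        self._record(
            "kmerfilter",
            distinct_kmers=len(table),
            reads_in=len(merged),
            reads_kept=n_kept,
        )

    # ------------------------------------------------------------------
    def map(self) -> None:
        silver = read_fasta(_require(self.run_dir / "silver.fasta", "simulate"))
        contigs = read_fasta(_require(self.run_dir / "contigs.fasta", "simulate"))
        silver_idx = mapcall.SeedIndex(silver)
        contig_idx = mapcall.SeedIndex(contigs)
        anchor_map = crossref.anchor_contigs(contigs, silver)
        anchor_map.write_tsv(self.run_dir / "anchors.tsv")
        anchor_bed = anchor_map.anchored_bed()
        write_bed(anchor_bed, self.run_dir / "anchored_regions.bed")
        counts = {}
        for name in HAPLOID_SAMPLES:
            reads = read_fastq(
                _require(self.run_dir / f"{name}.fastq", "simulate")
            )
            alns, unmapped = mapcall.seed_map(reads, silver_idx)
            mapcall.write_sam(
                alns,
                {c: len(s) for c, s in silver.items()},
                self.run_dir / f"{name}.silver.sam",
            )
            ids, subset = mapcall.subset_reads_by_anchor_regions(
                alns, anchor_bed, reads
            )
            sub_alns, _ = mapcall.seed_map(subset, contig_idx)
            mapcall.write_sam(
                sub_alns,
                {c: len(s) for c, s in contigs.items()},
                self.run_dir / f"{name}.mas.sam",
            )
            counts[name] = {
                "mapped_silver": len(alns),
                "unmapped_silver": len(unmapped),
                "subset_reads": len(subset),
                "mapped_mas": len(sub_alns),
            }
        self._record("map", anchors=len(anchor_map.anchors), **counts)

    # ------------------------------------------------------------------
    def call(self) -> None:
        cfg = self.config
        for branch, ref_file in (("silver", "silver.fasta"), ("mas", "contigs.fasta")):
            ref = read_fasta(self.run_dir / ref_file)
            alns = {
                name: mapcall.read_sam(
                    _require(self.run_dir / f"{name}.{branch}.sam", "map")
                )
                for name in HAPLOID_SAMPLES
            }
            raw = mapcall.pileup_call(alns, ref, method=branch)
            result = mapcall.filter_variants(raw, cfg)
            spaced = mapcall.spacing_filter(result.variants.sorted(), cfg.min_spacing)
            lengths = {c: len(s) for c, s in ref.items()}
            write_vcf(result.variants.sorted(), self.run_dir / f"{branch}.vcf", lengths)
            write_vcf(spaced, self.run_dir / f"{branch}.spaced.vcf", lengths)
            attr_lines = ["rule\tremoved"] + [
                f"{k}\t{v}" for k, v in result.attrition.items()
            ]
            (self.run_dir / f"{branch}.attrition.tsv").write_text(
                "\n".join(attr_lines) + "\n"
            )
            self.manifest["stages"][f"call_{branch}"] = {
                "raw": len(raw),
                "filtered": len(result.variants),
                "spaced": len(spaced),
                **{f"removed_{k}": v for k, v in result.attrition.items()},
            }
        self._record("call")

    # ------------------------------------------------------------------
    def ebwt(self, max_reads: int = 8000) -> None:
        cfg = self.config
        merged: list = []
        for name in HAPLOID_SAMPLES:
            rs = read_fastq(
                _require(self.run_dir / f"{name}.lowcopy.fastq", "kmerfilter")
            )
            merged.extend(rs.reads)
            singles = self.run_dir / f"{name}.singletons.fastq"
            if singles.exists():
                merged.extend(read_fastq(singles).reads)
        rng = np.random.default_rng(cfg.seed + 99)
        if len(merged) > max_reads:
            pick = rng.choice(len(merged), size=max_reads, replace=False)
            merged = [merged[i] for i in sorted(pick)]
        index = ebwtfree.build_ebwt(ReadSet(merged))
        clusters = ebwtfree.detect_clusters(index)
        candidates = ebwtfree.call_snps_from_clusters(index, clusters)
        ebwtfree.write_candidates_fasta(candidates, self.run_dir / "ebwt_calls.fasta")
        for branch, ref_file in (("mas", "contigs.fasta"), ("silver", "silver.fasta")):
            ref = read_fasta(self.run_dir / ref_file)
            vs = ebwtfree.anchor_to_reference(candidates, ref)
            write_vcf(vs, self.run_dir / f"ebwt.{branch}.vcf", {c: len(s) for c, s in ref.items()})
        self._record(
            "ebwt",
            reads=len(merged),
            clusters=len(clusters),
            candidates=len(candidates),
        )

    # ------------------------------------------------------------------
    def intersect(self) -> None:
        anchor_map = crossref.AnchorMap.read_tsv(
            _require(self.run_dir / "anchors.tsv", "map")
        )
        silver_vs = read_vcf(_require(self.run_dir / "silver.vcf", "call"), "silver")
        mas_vs = read_vcf(_require(self.run_dir / "mas.vcf", "call"), "mas")
        ebwt_vs = read_vcf(_require(self.run_dir / "ebwt.silver.vcf", "ebwt"), "ebwt")
        bed = read_bed(self.run_dir / "anchored_regions.bed")
        silver_restricted = crossref.restrict_to_regions(silver_vs, bed)
        mas_lifted = crossref.lift_variant_set(mas_vs, anchor_map)
        shared, a_only, b_only = crossref.intersect_variant_sets(
            silver_restricted, mas_lifted, mode="position"
        )
        venn = crossref.three_way_intersection(
            {"silver": silver_restricted, "mas": mas_lifted, "ebwt": ebwt_vs},
            mode="position",
        )
        spectrum = crossref.tstv(shared)
        silver = read_fasta(self.run_dir / "silver.fasta")
        lengths = {c: len(s) for c, s in silver.items()}
        write_vcf(shared.sorted(), self.run_dir / "shared.vcf", lengths)
        write_vcf(a_only.sorted(), self.run_dir / "silver_only.vcf", lengths)
        write_vcf(b_only.sorted(), self.run_dir / "mas_only.vcf", lengths)
        summary = {
            "venn": venn,
            "shared_silver_mas": len(shared),
            "tstv": spectrum.ratio if spectrum.tv else None,
            "spectrum": spectrum.counts,
        }
        (self.run_dir / "intersection.json").write_text(json.dumps(summary, indent=2))
        self._record("intersect", **{k: v for k, v in summary.items() if k != "spectrum"})

    # ------------------------------------------------------------------
    def genotype(
        self,
        n_trio: int = 88,
        n_duo: int = 26,
        n_single: int = 26,
        n_mislabels: int = 5,
        n_unrelated: int = 1,
        n_loci: int = 200,
    ) -> None:
        cfg = self.config
        pop = simgen.build_clone_population(
            n_trio, n_duo, n_single, n_mislabels,
            seed=cfg.seed + 7, n_unrelated=n_unrelated, n_loci=n_loci,
        )
        ref_c, alt_c = simgen.simulate_amplicons(pop, seed=cfg.seed + 8)
        gm = genoclone.call_amplicon_genotypes(ref_c, alt_c)
        keep = genoclone.flag_nonvariable_loci(ref_c, alt_c)
        gm = gm[keep[keep].index]
        panel = genoclone.filter_panel(gm)
        kept_loci, excluded = genoclone.het_ci_filter(panel.gm)
        write_genotype_tsv(panel.gm, self.run_dir / "genotypes.tsv")
        write_genotype_tsv(panel.gm[kept_loci], self.run_dir / "genotypes.het_filtered.tsv")
        pop.labels.to_csv(self.run_dir / "truth" / "labels.tsv", sep="\t")
        pop.true_genet.to_csv(self.run_dir / "truth" / "true_genets.tsv", sep="\t")
        mis_lines = ["#individual\ttrue_genet\tlabelled\tkind"] + [
            "\t".join(m) for m in pop.mislabels
        ]
        (self.run_dir / "truth" / "mislabels.tsv").write_text("\n".join(mis_lines) + "\n")
        self._record(
            "genotype",
            individuals=panel.gm.shape[0],
            loci_called=gm.shape[1],
            loci_panel=panel.gm.shape[1],
            loci_het_filtered=len(kept_loci),
            het_excluded=len(excluded),
            **{f"removed_{k}": v for k, v in panel.attrition.items()},
        )

    # ------------------------------------------------------------------
    def clones(self, n_groups: int = 83) -> None:
        cfg = self.config
        import pandas as pd

        gm = pd.read_csv(
            _require(self.run_dir / "genotypes.tsv", "genotype"),
            sep="\t", index_col=0, na_values=["NA"],
        )
        labels = pd.read_csv(
            self.run_dir / "truth" / "labels.tsv", sep="\t", index_col=0
        ).iloc[:, 0]
        identity = genoclone.identity_analysis(gm, labels)
        # mismatch profile on corrected labels: mislabelled ramets are
        # reassigned to their inferred genet before profiling
        profile = genoclone.mismatch_profile(
            gm, identity.assignments, n_groups, seed=cfg.seed + 9
        )
        profile.table.to_csv(self.run_dir / "mismatch_profile.tsv", sep="\t", index=False)
        identity.mislabels.to_csv(self.run_dir / "mislabels.tsv", sep="\t", index=False)
        het_gm = pd.read_csv(
            self.run_dir / "genotypes.het_filtered.tsv",
            sep="\t", index_col=0, na_values=["NA"],
        )
        rel = genoclone.grm(het_gm)
        rel.G.round(4).to_csv(self.run_dir / "grm.tsv", sep="\t")
        self._record(
            "clones",
            mislabels_found=len(identity.mislabels),
            conflicts=len(identity.conflicts),
            **{k: round(v, 2) for k, v in profile.summary.items()},
        )

    # ------------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage)()
        return self.manifest
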