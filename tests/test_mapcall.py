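"""Seed mapping, pileup calling, the filter cascade and depth tools."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conifersnp import simgen
from conifersnp.config import PipelineConfig
from conifersnp.mapcall import (
    Alignment,
    DepthProfile,
    SeedIndex,
    depth_profiles,
    filter_variants,
    max_depth_mask,
    pileup_call,
    read_sam,
    seed_map,
    spacing_filter,
    subset_reads_by_anchor_regions,
    write_sam,
)
from conifersnp.seqio import Read, ReadSet
from conifersnp.variants import SampleCall, VariantRecord, VariantSet


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSeedMap:
    def test_error_free_reads_map_to_true_positions(self):
        rng = np.random.default_rng(1)
        ref = {"c": _rand_seq(rng, 20_000)}
        reads = simgen.simulate_reads(ref["c"], coverage=3, err=0.0, seed=2)
        alns, unmapped = seed_map(reads, ref)
        assert not unmapped
        by_key = {(a.read_id, a.mate): a for a in alns}
        for r in reads:
            s, e = simgen.read_span(r)
            a = by_key[(r.id, r.mate)]
            assert a.start == s and a.nm == 0

    def test_repeat_read_gets_mapq_zero(self):
        rng = np.random.default_rng(3)
        unit = _rand_seq(rng, 500)
        ref = {"c": unit + _rand_seq(rng, 300) + unit}
        read = ReadSet([Read("r", 1, unit[100:250], (40,) * 150)])
        alns, _ = seed_map(read, ref)
        assert alns[0].mapq == 0

    def test_noisy_reads_map_within_5bp(self):
        """10k reads at the default error rate place >= 99% within 5 bp."""
        rng = np.random.default_rng(4)
        ref = {"c": _rand_seq(rng, 50_000)}
        reads = simgen.simulate_reads(ref["c"], coverage=30, err=0.002, seed=5)
        sub = ReadSet(reads.reads[:10_000])
        alns, _ = seed_map(sub, ref)
        ok = 0
        for a in alns:
            r = next(x for x in sub if x.id == a.read_id and x.mate == a.mate)
            s, _e = simgen.read_span(r)
            ok += abs(a.start - s) <= 5
        assert len(alns) >= 0.99 * len(sub)
        assert ok >= 0.99 * len(alns)

    def test_sam_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        ref = {"c": _rand_seq(rng, 5_000)}
        reads = simgen.simulate_reads(ref["c"], coverage=2, err=0.0, seed=7)
        alns, _ = seed_map(reads, ref)
        p = tmp_path / "x.sam"
        write_sam(alns, {"c": 5_000}, p)
        back = read_sam(p)
        assert [(a.read_id, a.mate, a.contig, a.start, a.strand, a.mapq) for a in alns] == [
            (a.read_id, a.mate, a.contig, a.start, a.strand, a.mapq) for a in back
        ]


class TestSubsetByAnchors:
    def test_overlap_rules(self):
        alns = [
            Alignment("in", 1, "c", 100, "+", 60, "50M", 0),
            Alignment("edge", 1, "c", 149, "+", 60, "50M", 0),
            Alignment("out", 1, "c", 300, "+", 60, "50M", 0),
        ]
        ids, _ = subset_reads_by_anchor_regions(alns, [("c", 90, 150)])
        assert ids == {"in", "edge"}

    def test_missing_contig_warns(self):
        alns = [Alignment("r", 1, "c", 0, "+", 60, "50M", 0)]
        with pytest.warns(UserWarning, match="no alignments"):
            subset_reads_by_anchor_regions(alns, [("other", 0, 10)])

    def test_subsetting_reduces_inflated_depth(self):
        """Mapping all reads onto the draft contigs stacks paralogous repeat
        reads; restricting to reads anchored on the related-species
        reference reduces the fraction of positions above twice the
        expected depth."""
        g = simgen.generate_genome(80_000, seed=21)
        haps, _ = simgen.sample_haploids(g, seed=22)
        name, seq = next(iter(haps.items()))
        reads = simgen.simulate_reads(seq, coverage=5, err=0.002, seed=23, sample=name)
        cidx = SeedIndex(g.draft_contigs)
        clens = {c: len(s) for c, s in g.draft_contigs.items()}
        all_alns, _ = seed_map(reads, cidx)
        from conifersnp.crossref import anchor_contigs

        silver = {"silver": g.silver_ref}
        bed = anchor_contigs(g.draft_contigs, silver).anchored_bed()
        s_alns, _ = seed_map(reads, SeedIndex(silver))
        _, subset = subset_reads_by_anchor_regions(s_alns, bed, reads)
        sub_alns, _ = seed_map(subset, cidx)
        d_all = np.concatenate([p.depth for p in depth_profiles(all_alns, clens).values()])
        d_sub = np.concatenate([p.depth for p in depth_profiles(sub_alns, clens).values()])
        frac_all = (d_all > 10).mean()  # 2x the 5x expected depth
        frac_sub = (d_sub > 10).mean()
        assert frac_sub < frac_all


class TestPileupCall:
    def _aligned_reads(self, seqs, contig="c"):
        out = {}
        for sample, seq_reads in seqs.items():
            out[sample] = [
                Alignment(f"{sample}r{i}", 1, contig, start, "+", 60, f"{len(s)}M", 0, s)
                for i, (start, s) in enumerate(seq_reads)
            ]
        return out

    def test_all_matching_reads_give_empty_set(self):
        ref = {"c": "ACGTACGTACGTACGTACGT"}
        alns = self._aligned_reads(
            {
                "s1": [(0, ref["c"][:15]), (5, ref["c"][5:])],
                "s2": [(0, ref["c"][:15])],
            }
        )
        assert len(pileup_call(alns, ref)) == 0

    def test_planted_snp_af_half(self):
        ref = {"c": "ACGTACGTACGTACGTACGT"}
        alt = ref["c"][:10] + "A" + ref["c"][11:]  # G->A at pos 10
        assert ref["c"][10] == "G"
        alns = self._aligned_reads(
            {
                "s1": [(0, alt)] * 10,
                "s2": [(0, ref["c"])] * 10,
                "s3": [(0, alt)] * 10,
                "s4": [(0, ref["c"])] * 10,
            }
        )
        vs = pileup_call(alns, ref)
        assert len(vs) == 1
        rec = vs.records[0]
        assert (rec.pos, rec.ref, rec.alts) == (10, "G", ("A",))
        assert rec.af == 0.5
        assert rec.samples["s1"].depth == 10

    def test_single_sample_rejected(self):
        with pytest.raises(Exception):
            pileup_call({"s1": []}, {"c": "ACGT"})

    def test_planted_snp_recall_on_clean_data(self, clean_callset):
        """>= 95% of planted low-copy SNPs covered >= 5x in every haploid
        survive raw calling plus the filter cascade."""
        genome, truth, alignments, _raw, result = clean_callset
        depth = {}
        for n, alist in alignments.items():
            d = {c: np.zeros(len(s), dtype=int) for c, s in genome.draft_contigs.items()}
            for a in alist:
                d[a.contig][a.start : a.end] += 1
            depth[n] = d

        def to_contig(pos):
            for name, (s, e, strand) in genome.contig_origin.items():
                if s <= pos < e:
                    return name, (pos - s if strand == "+" else e - 1 - pos)
            return None

        called = {(r.contig, r.pos) for r in result.variants}
        poly = truth[(truth.alt_count > 0) & (truth.alt_count < 4)]
        tot = rec = 0
        for _, row in poly.iterrows():
            tc = to_contig(row.pos)
            if tc is None:
                continue
            c, cp = tc
            if all(depth[n][c][cp] >= 5 for n in alignments):
                tot += 1
                rec += (c, cp) in called
        assert tot > 20
        assert rec / tot >= 0.95


class TestFilterCascade:
    def _rec(self, samples, mq=60.0, ref="A", alts=("G",), pos=100):
        return VariantRecord("c", pos, ref, alts, samples, mq=mq)

    def _call(self, base, depth=10, gq=40, counts=None):
        return SampleCall(base, depth, gq, counts or {base: depth})

    def test_low_depth_removed_by_depth_rule(self):
        rec = self._rec({"s1": self._call("G", depth=4), "s2": self._call("A")})
        result = filter_variants(VariantSet([rec], ("s1", "s2")), PipelineConfig())
        assert len(result.variants) == 0
        assert result.attrition["depth"] == 1
        assert rec.filter == "depth"

    def test_within_individual_heterozygosity_removed(self):
        rec = self._rec(
            {
                "s1": self._call("G", depth=12, counts={"G": 6, "A": 6}),
                "s2": self._call("A"),
            }
        )
        result = filter_variants(VariantSet([rec], ("s1", "s2")), PipelineConfig())
        assert result.attrition["het"] == 1

    def test_multiallelic_removed_first(self):
        rec = self._rec(
            {"s1": self._call("G", depth=4), "s2": self._call("T", depth=4)},
            alts=("G", "T"),
        )
        result = filter_variants(VariantSet([rec], ("s1", "s2")), PipelineConfig())
        assert result.attrition["biallelic"] == 1  # precedes the depth rule

    def test_af_rule_vacuous_with_four_called_haploids(self, clean_callset):
        """With all four haploids called, AF is forced into
        {0.25, 0.5, 0.75, 1.0}, so the AF >= 0.25 rule removes nothing."""
        _g, _t, _a, _raw, result = clean_callset
        assert result.attrition["af"] == 0
        full = [r for r in result.variants if all(s.base for s in r.samples.values())]
        assert {round(r.af, 4) for r in full} <= {0.25, 0.5, 0.75, 1.0}

    def test_idempotent_and_conserving(self, clean_callset):
        _g, _t, _a, raw, result = clean_callset
        assert len(raw) == len(result.variants) + sum(result.attrition.values())
        again = filter_variants(result.variants, PipelineConfig())
        assert len(again.variants) == len(result.variants)
        assert sum(again.attrition.values()) == 0


class TestSpacingFilter:
    def _vs(self, positions, contig="c"):
        recs = [VariantRecord(contig, p, "A", ("G",)) for p in positions]
        return VariantSet(recs, ())

    def test_greedy_scan(self):
        out = spacing_filter(self._vs([100, 120, 180]), 50)
        assert [r.pos for r in out] == [100, 180]

    def test_single_record_kept(self):
        assert len(spacing_filter(self._vs([7]), 50)) == 1

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            spacing_filter(self._vs([100, 50]), 50)

    @given(st.lists(st.integers(0, 3000), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_scan(self, positions):
        positions = sorted(set(positions))
        out = spacing_filter(self._vs(positions), 50)
        kept, last = [], None
        for p in positions:
            if last is None or p - last >= 50:
                kept.append(p)
                last = p
        assert [r.pos for r in out] == kept


class TestMaxDepthMask:
    def test_uniform_depth_below_threshold(self):
        prof = DepthProfile("c", np.full(100, 7))
        assert max_depth_mask(prof) == []  # 7 < 7 + 4*sqrt(7)

    def test_spike_masked(self):
        depth = np.full(100, 7)
        depth[40:45] = 100
        prof = DepthProfile("c", depth)
        mask = max_depth_mask(prof)
        assert mask == [("c", 40, 45)]

    def test_matches_per_position_comparison(self):
        rng = np.random.default_rng(8)
        depth = rng.poisson(7, 500)
        depth[rng.integers(0, 500, 20)] += 100
        prof = DepthProfile("c", depth)
        mask = max_depth_mask(prof)
        masked = set()
        for _c, s, e in mask:
            masked.update(range(s, e))
        thr = depth.mean() + 4 * np.sqrt(depth.mean())
        assert masked == set(np.flatnonzero(depth > thr))

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            max_depth_mask(DepthProfile("c", np.array([])))
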