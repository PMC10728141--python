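"""Synthetic data emulating low-coverage haploid conifer sequencing.

The generator produces, with full truth provenance:

* a repeat-rich genome (default 75% high-copy repeats planted as tandem and
  dispersed copies of a few unit sequences with 1% inter-copy divergence,
  plus a couple of single-copy paralog segments that recreate the
  pileup-inflation pathology of collapsed paralogous mapping);
* a diverged related-species reference (substitutions plus short indels)
  standing in for a congener draft genome;
* a fragmented, lightly noisy draft assembly of the low-copy regions;
* four haploid megagametophyte samples from two gene pools, one allele per
  individual, with Balding–Nichols-style pool allele frequencies;
* paired-end 2x150 bp reads with substitution errors;
* a clonal population (genets with 1–3 ramets each, planted mislabels) and
  amplicon read counts for a SNP panel.

Every read id encodes its generating coordinates and every SNP and
individual is traceable through the truth tables, so downstream stages can
be scored against ground truth. Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError
from .seqio import Read, ReadSet, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _to_arr(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate_subs(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given per-site rate (always to a different base)."""
    out = arr.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


@dataclass
class SyntheticGenome:
    """Truth genome plus derived references and provenance tables."""

    truth: str
    repeat_fraction: float
    repeat_families: list[tuple[str, int]]
    lowcopy_intervals: list[tuple[int, int]]  # 0-based half-open, on truth
    silver_ref: str
    draft_contigs: dict[str, str]
    contig_origin: dict[str, tuple[int, int, str]]  # contig -> (start, end, strand) on truth
    silver_coords: np.ndarray  # truth position -> silver position (-1 where deleted)
    truth_snps: pd.DataFrame | None = None
    paralog_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.truth)

    def realized_repeat_fraction(self) -> float:
        low = sum(e - s for s, e in self.lowcopy_intervals)
        return 1.0 - low / len(self.truth)

    def in_lowcopy(self, start: int, end: int, min_overlap_frac: float = 0.5) -> bool:
        """Whether [start, end) overlaps low-copy intervals by >= the fraction."""
        need = (end - start) * min_overlap_frac
        got = 0
        for s, e in self.lowcopy_intervals:
            got += max(0, min(end, e) - max(start, s))
            if got >= need:
                return True
        return False


def generate_genome(
    size: int,
    repeat_fraction: float = 0.75,
    n_repeat_families: int = 3,
    divergence: float = 0.02,
    frag_n50: int = 600,
    seed: int = 0,
    n_paralogs: int = 2,
    contig_noise: float = 0.002,
) -> SyntheticGenome:
    """Generate the truth genome, related-species reference and draft contigs.

    The genome alternates unique (low-copy) segments with repeat blocks
    built from ``n_repeat_families`` unit sequences (300-2000 bp) copied
    with 1% inter-copy divergence, steering the realized repeat fraction to
    ``repeat_fraction``. ``n_paralogs`` extra near-copies (3% diverged) of
    repeat units are embedded inside low-copy segments: single-copy in the
    truth, they attract reads from the high-copy family when mapped naively.

    The related-species reference diverges by ``divergence`` substitutions
    per site plus short indels at 5% of that rate. Draft contigs tile the
    low-copy intervals with ~``frag_n50`` fragments, ``contig_noise``
    substitution noise and random strand.
    """
    if size < 50_000:
        raise ConfigError("size must be >= 50 kb")
    if repeat_fraction >= 1:
        raise ConfigError("repeat_fraction must be < 1")
    if not 0 <= divergence <= 0.1:
        raise ConfigError("divergence must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)

    units = [_random_seq(rng, int(rng.integers(300, 2001))) for _ in range(n_repeat_families)]
    copy_counts = [0] * n_repeat_families
    parts: list[np.ndarray] = []
    lowcopy: list[tuple[int, int]] = []
    paralogs: list[tuple[int, int]] = []
    pos = 0
    repeat_bases = 0
    paralogs_left = n_paralogs
    while pos < size:
        make_repeat = pos > 0 and repeat_bases < repeat_fraction * pos
        if make_repeat:
            f = int(rng.integers(0, n_repeat_families))
            tandem = int(rng.integers(1, 6))
            block = np.concatenate(
                [_mutate_subs(units[f], 0.01, rng) for _ in range(tandem)]
            )
            copy_counts[f] += tandem
            parts.append(block)
            repeat_bases += len(block)
            pos += len(block)
        else:
            seg_len = int(rng.integers(1500, 4001))
            seg = _random_seq(rng, seg_len)
            if paralogs_left > 0 and pos > 0:
                f = int(rng.integers(0, n_repeat_families))
                para = _mutate_subs(units[f], 0.03, rng)
                if len(para) < seg_len - 200:
                    off = int(rng.integers(100, seg_len - len(para) - 100))
                    seg[off : off + len(para)] = para
                    paralogs.append((pos + off, pos + off + len(para)))
                    paralogs_left -= 1
            parts.append(seg)
            lowcopy.append((pos, pos + seg_len))
            pos += seg_len
    truth_arr = np.concatenate(parts)

    # related-species reference: substitutions + short indels, with coord map
    silver_parts: list[np.ndarray] = []
    coords = np.full(len(truth_arr), -1, dtype=np.int64)
    indel_rate = divergence * 0.05
    sub_arr = _mutate_subs(truth_arr, divergence, rng)
    indel_sites = (
        np.flatnonzero(rng.random(len(truth_arr)) < indel_rate)
        if indel_rate > 0
        else np.array([], dtype=np.int64)
    )
    spos = 0
    prev = 0
    for site in indel_sites:
        if site <= prev:
            continue
        chunk = sub_arr[prev:site]
        coords[prev:site] = np.arange(spos, spos + len(chunk))
        silver_parts.append(chunk)
        spos += len(chunk)
        ilen = int(rng.integers(1, 6))
        if rng.random() < 0.5:  # insertion into the reference
            silver_parts.append(_random_seq(rng, ilen))
            spos += ilen
            prev = site
        else:  # deletion from the reference
            prev = min(site + ilen, len(truth_arr))
    chunk = sub_arr[prev:]
    coords[prev:] = np.arange(spos, spos + len(chunk))
    silver_parts.append(chunk)
    silver_arr = np.concatenate(silver_parts)

    # draft contigs over low-copy intervals
    contigs: dict[str, str] = {}
    origin: dict[str, tuple[int, int, str]] = {}
    idx = 0
    min_ctg = 200
    for s, e in lowcopy:
        p = s
        while e - p >= min_ctg:
            clen = int(np.clip(rng.normal(frag_n50, 0.3 * frag_n50), min_ctg, 2 * frag_n50))
            clen = min(clen, e - p)
            frag = _mutate_subs(truth_arr[p : p + clen], contig_noise, rng)
            strand = "-" if rng.random() < 0.25 else "+"
            seq = _to_seq(frag)
            if strand == "-":
                seq = revcomp(seq)
            name = f"ctg{idx:05d}"
            contigs[name] = seq
            origin[name] = (p, p + clen, strand)
            idx += 1
            p += clen + int(rng.integers(0, 80))

    return SyntheticGenome(
        truth=_to_seq(truth_arr),
        repeat_fraction=repeat_fraction,
        repeat_families=[(_to_seq(u), c) for u, c in zip(units, copy_counts)],
        lowcopy_intervals=lowcopy,
        silver_ref=_to_seq(silver_arr),
        draft_contigs=contigs,
        contig_origin=origin,
        silver_coords=coords,
        paralog_intervals=paralogs,
    )


def sample_haploids(
    genome: SyntheticGenome,
    n: int = 4,
    pool_assignment: tuple[str, ...] = ("A", "A", "B", "B"),
    snp_density: float = 1 / 200,
    seed: int = 0,
    fst: float = 0.15,
    tstv_odds: float = 1.84,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw haploid megagametophyte genomes carrying one allele per truth SNP.

    Truth SNPs are planted uniformly at ``snp_density``; each gets pool
    allele frequencies from a Balding–Nichols split (differentiation
    ``fst``) around a uniform ancestral frequency, and each haploid draws
    its single allele from its pool's frequency. Transition alternatives
    are chosen with odds ``tstv_odds`` : 1 against transversions.
    """
    if n < 2:
        raise ConfigError("need at least two haploids")
    if len(pool_assignment) != n:
        raise ConfigError("pool_assignment length must equal n")
    rng = np.random.default_rng(seed)
    truth_arr = _to_arr(genome.truth)
    L = len(truth_arr)
    n_snps = int(rng.binomial(L, snp_density))
    positions = np.sort(rng.choice(L, size=n_snps, replace=False))

    # transitions: A<->G (0<->2), C<->T (1<->3); i.e. code ^ 2
    ref_codes = truth_arr[positions]
    is_ts = rng.random(n_snps) < tstv_odds / (1.0 + tstv_odds)
    tv_shift = rng.choice([1, 3], size=n_snps)
    alt_codes = np.where(is_ts, ref_codes ^ 2, (ref_codes + tv_shift) % 4)

    anc = rng.uniform(0.05, 0.95, size=n_snps)
    pools = sorted(set(pool_assignment))
    pool_freq = {}
    for pool in pools:
        if fst > 0:
            a = anc * (1 - fst) / fst
            b = (1 - anc) * (1 - fst) / fst
            pool_freq[pool] = rng.beta(a, b)
        else:
            pool_freq[pool] = anc.copy()

    sample_names = [f"hap{i+1}" for i in range(n)]
    alleles = {}
    haploids = {}
    for name, pool in zip(sample_names, pool_assignment):
        has_alt = rng.random(n_snps) < pool_freq[pool]
        alleles[name] = has_alt
        arr = truth_arr.copy()
        arr[positions[has_alt]] = alt_codes[has_alt]
        haploids[name] = _to_seq(arr)

    bases = "ACGT"
    table = pd.DataFrame(
        {
            "pos": positions,
            "ref": [bases[c] for c in ref_codes],
            "alt": [bases[c] for c in alt_codes],
            "is_transition": is_ts,
            "lowcopy": [
                genome.in_lowcopy(int(p), int(p) + 1) for p in positions
            ],
        }
    )
    for pool in pools:
        table[f"freq_{pool}"] = pool_freq[pool]
    for name in sample_names:
        table[name] = np.where(alleles[name], table["alt"], table["ref"])
    table["alt_count"] = sum(alleles[name].astype(int) for name in sample_names)
    genome.truth_snps = table
    return haploids, table


def simulate_reads(
    seq: str | dict[str, str],
    coverage: float,
    read_len: int = 150,
    insert_mean: int = 300,
    insert_sd: int = 30,
    err: float = 0.002,
    seed: int = 0,
    sample: str = "S",
    three_prime_ramp: int = 0,
) -> ReadSet:
    """Simulate paired-end reads by uniform fragment sampling.

    Read ids encode provenance as ``sample|index|contig|fragstart|insert``
    (see :func:`parse_read_origin`). With ``err=0`` every read is an exact
    substring of its template (reverse complement for mate 2).
    ``three_prime_ramp`` marks that many 3' bases with quality 2 to emulate
    a terminal quality drop; all other bases get quality 37.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be > 0")
    seqs = {"genome": seq} if isinstance(seq, str) else dict(seq)
    for name, s in seqs.items():
        if read_len > len(s):
            raise ConfigError(f"read_len {read_len} exceeds length of {name}")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    base_q = 37
    for contig, s in seqs.items():
        arr = _to_arr(s)
        L = len(arr)
        n_pairs = max(1, round(coverage * L / (2 * read_len)))
        inserts = np.clip(
            rng.normal(insert_mean, insert_sd, size=n_pairs).round().astype(int),
            read_len,
            L,
        )
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
        for i in range(n_pairs):
            st, ins = int(starts[i]), int(inserts[i])
            frag = arr[st : st + ins]
            r1 = _mutate_subs(frag[:read_len], err, rng)
            r2 = _mutate_subs(frag[-read_len:][::-1] ^ 3, err, rng)  # revcomp
            qual = [base_q] * read_len
            if three_prime_ramp > 0:
                qual[-three_prime_ramp:] = [2] * min(three_prime_ramp, read_len)
            rid = f"{sample}|{i}|{contig}|{st}|{ins}"
            reads.append(Read(rid, 1, _to_seq(r1), tuple(qual)))
            reads.append(Read(rid, 2, _to_seq(r2), tuple(qual)))
    return ReadSet(reads)


def parse_read_origin(read_id: str) -> dict:
    """Decode the provenance encoded in a simulated read id."""
    sample, index, contig, start, insert = read_id.split("|")
    return {
        "sample": sample,
        "index": int(index),
        "contig": contig,
        "start": int(start),
        "insert": int(insert),
    }


def read_span(read: Read) -> tuple[int, int]:
    """Template interval covered by one simulated read (truth coordinates)."""
    o = parse_read_origin(read.id)
    if read.mate == 1:
        return o["start"], o["start"] + len(read.seq)
    end = o["start"] + o["insert"]
    return end - len(read.seq), end


# ---------------------------------------------------------------------------
# Clonal population and amplicon counts
# ---------------------------------------------------------------------------


@dataclass
class ClonePopulation:
    """Genets with 1-3 ramets each, plus planted mislabels.

    ``genotypes`` holds the true diploid dosages (individuals x loci);
    ``labels`` the (possibly wrong) genet label per individual;
    ``true_genet`` the generating genet ("unrelated:<id>" for injected
    unrelated genotypes). ``mislabels`` lists
    (individual, true genet, labelled genet, kind).
    """

    genotypes: pd.DataFrame
    labels: pd.Series
    true_genet: pd.Series
    ramet_structure: dict[str, int]
    mislabels: list[tuple[str, str, str, str]]
    allele_freqs: pd.Series
    gene_pool: dict[str, str]

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)


def build_clone_population(
    n_trio: int,
    n_duo: int,
    n_single: int,
    n_mislabels: int,
    seed: int = 0,
    n_unrelated: int = 0,
    n_loci: int = 200,
    allele_freqs: np.ndarray | None = None,
) -> ClonePopulation:
    """Build a clonal population with planted label errors.

    Genets get Hardy-Weinberg diploid genotypes at ``n_loci`` biallelic
    loci (frequencies uniform on [0.05, 0.95] unless given); ramets copy
    their genet's genotype exactly. Of the ``n_mislabels`` planted errors,
    the last ``n_unrelated`` replace the individual's genotype with an
    unrelated one (label retained); the rest relabel a trio ramet to a
    different genet.
    """
    for v in (n_trio, n_duo, n_single, n_mislabels, n_unrelated):
        if v < 0:
            raise ConfigError("counts must be >= 0")
    if n_unrelated > n_mislabels:
        raise ConfigError("n_unrelated cannot exceed n_mislabels")
    n_ind = 3 * n_trio + 2 * n_duo + n_single
    if n_mislabels > n_ind:
        raise ConfigError("more mislabels than individuals")
    rng = np.random.default_rng(seed)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.05, 0.95, size=n_loci)
    loci = [f"L{i+1:03d}" for i in range(len(allele_freqs))]

    n_genets = n_trio + n_duo + n_single
    genet_ids = [f"G{i+1:03d}" for i in range(n_genets)]
    genet_geno = {
        g: (rng.random((2, len(loci))) < allele_freqs).sum(axis=0)
        for g in genet_ids
    }
    ramet_counts = [3] * n_trio + [2] * n_duo + [1] * n_single

    rows, labels, true_genet, ind_ids = [], [], [], []
    k = 0
    for g, count in zip(genet_ids, ramet_counts):
        for _ in range(count):
            k += 1
            ind_ids.append(f"I{k:04d}")
            rows.append(genet_geno[g])
            labels.append(g)
            true_genet.append(g)
    genotypes = pd.DataFrame(np.array(rows), index=ind_ids, columns=loci, dtype=float)
    labels = pd.Series(labels, index=ind_ids, name="labelled_genet")
    true_genet = pd.Series(true_genet, index=ind_ids, name="true_genet")

    mislabels: list[tuple[str, str, str, str]] = []
    trio_inds = [i for i in ind_ids if true_genet[i] in genet_ids[:n_trio]]
    victims = list(rng.choice(trio_inds, size=min(n_mislabels, len(trio_inds)), replace=False))
    n_swap = n_mislabels - n_unrelated
    multi = genet_ids[: n_trio + n_duo]  # swap targets keep a matching ramet
    for j, ind in enumerate(victims):
        if j < n_swap:
            others = [g for g in multi if g != true_genet[ind]] or [
                g for g in genet_ids if g != true_genet[ind]
            ]
            target = str(rng.choice(others))
            labels[ind] = target
            mislabels.append((ind, str(true_genet[ind]), target, "reassigned"))
        else:
            genotypes.loc[ind] = (rng.random((2, len(loci))) < allele_freqs).sum(axis=0)
            mislabels.append((ind, f"unrelated:{ind}", str(labels[ind]), "unrelated"))
            true_genet[ind] = f"unrelated:{ind}"

    return ClonePopulation(
        genotypes=genotypes,
        labels=labels,
        true_genet=true_genet,
        ramet_structure=dict(zip(genet_ids, ramet_counts)),
        mislabels=mislabels,
        allele_freqs=pd.Series(allele_freqs, index=loci),
        gene_pool={g: "Ambrolauri" for g in genet_ids},
    )


def simulate_amplicons(
    population: ClonePopulation,
    loci: list[str] | None = None,
    mean_depth: float = 21.0,
    err: float = 0.01,
    dropout: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-individual, per-locus (ref, alt) amplicon read counts.

    Depth is gamma-dispersed Poisson around ``mean_depth``; alt counts are
    binomial around the genotype dosage with base error ``err``; a
    ``dropout`` fraction of cells gets zero depth.
    """
    rng = np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(population.genotypes.columns)
    geno = population.genotypes[loci].to_numpy()
    n_ind, n_loc = geno.shape
    lam = rng.gamma(shape=10.0, scale=mean_depth / 10.0, size=(n_ind, n_loc))
    depth = rng.poisson(lam)
    depth[rng.random((n_ind, n_loc)) < dropout] = 0
    p_alt = np.choose(geno.astype(int), [err, 0.5, 1.0 - err])
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    idx, cols = population.genotypes.index, loci
    return (
        pd.DataFrame(ref, index=idx, columns=cols),
        pd.DataFrame(alt, index=idx, columns=cols),
    )
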