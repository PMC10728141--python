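# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic data does and does not emulate, and
the known limits of the desk-scale setting.

## Study system and scale

The workflow targets SNP discovery in a conifer with a ~17.3 Gb haploid
genome, ~75% high-copy repeats, no species reference, and four haploid
megagametophyte samples sequenced at ~5x each (2×150 bp). None of the
genome-scale quantities (tens of millions of SNPs from billions of reads)
are reproducible on a workstation; the package instead runs every stage
on truth-labelled synthetic data at 50–200 kb scale and verifies the
*properties* the genome-scale workflow relies on: filter purity, forced
AF classes, recall of planted variants, spectrum estimation, clone
discrimination. Printed worked-example arithmetic (coverage, SNP
spacing, panel bookkeeping, the mismatch gap) is recomputed exactly from
its published inputs. Problem sizes used by the test suite and the
acceptance script (60–200 kb genomes, 4 haploids at 5–8x, 342-ramet
clone panels at ~21x amplicon depth) were chosen as the smallest sizes at
which each property is statistically meaningful.

## Synthetic data generator

**Genome.** Unique ("low-copy") segments of 1.5–4 kb alternate with
repeat blocks — tandem arrays of 1–5 copies drawn from 3 unit sequences
(300–2000 bp) mutated 1% per copy — steering the realized repeat
fraction to the target (default 0.75, realized within ±0.02). This
creates the k-mer coverage pathology of real conifer data (repeat k-mers
orders of magnitude above the unique peak) without modelling transposon
biology. Two *paralog* segments — near-copies of repeat units at 3%
divergence embedded in low-copy regions — are single-copy in the truth
yet attract reads from the whole repeat family when mapped naively;
they exist to reproduce the pileup-inflation pathology that the
anchor-region read-subsetting workaround corrects.

**References.** The related-species reference applies substitutions at
the configured divergence (default 0.02/site, giving ~0.96–0.99 contig
anchoring identity) plus short (1–5 bp) indels at 5% of that rate. The
draft assembly tiles low-copy intervals with ~N50-600 bp fragments,
0.2% substitution noise and random strand, emulating a fragmented
short-read assembly restricted to low-copy reads.

**Haploids and SNPs.** Truth SNPs are planted uniformly at density
1/200 bp. Transition alternatives are drawn at odds 1.84:1 against
transversions — the spectrum reported for the shared SNP set — so the
Ts/Tv estimator can be validated against a planted value. Pool allele
frequencies follow a Balding–Nichols split (default Fst 0.15 around a
uniform ancestral frequency); the two-pool differentiation of the real
gene pools is unreported, so this default is a placeholder flagged in
config, and nothing downstream depends on its exact value. Each haploid
draws one allele per SNP from its pool's frequency.

**Reads.** Uniform fragment sampling (insert 300±30 bp), substitution
errors only (default 0.002/base; no indel errors), constant quality 37
with an optional 3' low-quality ramp for trim testing. Read ids encode
sample, fragment coordinates and insert so that every alignment and
k-mer decision can be scored against truth. What this misses relative
to real data: GC and coverage bias, quality-dependent error profiles,
PCR duplicates and chimeras, adapter read-through. Tests passing on
this generator therefore demonstrate algorithmic correctness, not
robustness to every bench artifact.

**Clones and amplicons.** Genets receive Hardy–Weinberg genotypes at
~200 loci (frequencies uniform on [0.05, 0.95]); ramets copy them
exactly (no somatic mutation). Mislabels are planted either by
relabelling a trio ramet to another multi-ramet genet ("reassigned") or
by replacing an individual's genotype with an unrelated draw
("unrelated"). Amplicon depth is gamma-dispersed Poisson around 21x
(the reported average minimum coverage), alt counts binomial with base
error 1%, and 5% dropout.

## Stage-specific decisions

**Trimming** applies adapter-suffix, 3'-poly-G (runs ≥ 10, the
two-channel-chemistry artifact) and 3' quality (< 10) rules to a
fixpoint, which makes trimming exactly idempotent; a single pass can
re-expose an adapter-prefix suffix by chance. Adapter matches require
≥ 6 bp overlap. Pairs are discarded together when either mate falls
below 30 bp.

**K-mer filter.** k defaults to 25 — the assembly-graph k of 99 applies
to contig construction, not read screening, and 25 keeps per-read k-mer
counts high enough that the 90% in-band fraction is meaningful for 150 bp
reads. Counting is exact (hash map, no sketch) so the filter is
auditable against a naive recount; this caps practical input size at
desk scale, which is the intended regime. The table is built from the
merged four-sample pool, matching the ~20x merged-coverage design.

**Seed mapper.** Exact 21-mer seeds at four read offsets, ungapped
extension, one best placement per read. MAPQ is 0 on placement ties,
otherwise 6x the mismatch gap to the runner-up (capped at 60).
Reporting a single best hit is deliberate: it reproduces the
paralog-pileup pathology on the draft assembly that the subsetting
workaround must fix. The mapper handles no indels (reads crossing a
reference indel go unmapped); real alignments can be imported from
SAM/BAM instead.

**Pileup calling.** Per haploid sample the consensus base is called
with GQ = min(60, 4·(best − second-best support)) — a deliberately
simple phred-like proxy for a genotype-likelihood model, documented as
such; depth ≥ 5 with this proxy implies GQ ≥ 20, comfortably above the
GQ ≥ 15 threshold on clean data. Site MQ is the RMS mapping quality of
covering reads. Within-individual heterozygosity (impossible in clean
haploid tissue, diagnostic of collapsed paralogs) is flagged when a
sample's minor base reaches 20% of its reads with at least 2 reads.
The AF denominator counts samples with a call, so missingness does not
bias the frequency. Filter order is fixed (biallelic → depth/GQ/MQ →
het → AF) and each record's FILTER names the first failing rule. Sites
where all four haploids share a non-reference base (AF = 1) represent
reference divergence rather than polymorphism; they pass the cascade by
design and are distinguishable by AF.

**eBWT calling.** Suffix sorting is prefix doubling over the
integer-coded, terminator-augmented text (terminators unique per read
and smaller than every base, so the transform is stable and independent
of input order); LCP by Kasai's algorithm. Reverse complements are
indexed alongside the forward reads, doubling the text but making
clustering strand-agnostic. Clusters are maximal SA intervals with
interior LCP ≥ 20 and size ≥ 4. A candidate needs exactly two preceding
bases with support ≥ 2 each: with four ~5x haploids only ~17x of reads
carry the required ≥ 20 bp right context, so a singleton allele
contributes ~4 such reads *split across the two strand-mirror clusters*;
demanding 4–5 reads per cluster (a quarter of pooled coverage) costs
20–30 points of recall, while 2 concordant reads already exclude
singleton sequencing errors. For noisier inputs the threshold should be
raised toward pooled coverage / 4; the pipeline leaves the default.
Left contexts are reconstructed by direct suffix-array lookup of a
representative occurrence (equivalent to LF-stepping on an in-memory
index). Indel-like clusters are not interpreted; candidates anchor to a
reference only when their right context matches exactly once
genome-wide (both strands; reverse matches complement the alleles),
which silently discards repeat-context candidates — the intended
repeat-safety behaviour.

**Anchoring and intersection.** Contigs place by seed–chain–extend with
edlib infix alignment scoring candidate windows; near-tied placements at
distinct loci are dropped as ambiguous rather than assigned. Anchors
below 100 bp or 90% identity are discarded. Coordinate lift interpolates
linearly inside an anchor (exact for indel-free anchors; within the
±indel slack otherwise). The cross-reference intersection defaults to
the indirect, region-restriction semantics (restrict the
related-species-based set to the anchored-region BED, lift the
draft-based set, intersect on position); a stricter
position-plus-strand-normalized-allele mode is available. Three-way
Venn counts are computed as a pairwise chain.

**Genotyping and panel filters.** Dosage likelihoods are
Binomial(alt | depth, p_g) with p_g ∈ {err, 0.5, 1−err}; the prior is
Hardy–Weinberg at a first-pass frequency pooled over read fractions,
and calls need posterior > 0.95. The polymorphism screen is a
likelihood-ratio test of the Hardy–Weinberg mixture (free frequency,
optimized numerically) against the best monomorphic-with-error model,
referred to χ²(df = 1); loci with p ≥ 0.001 are flagged non-variable.
Panel boundaries follow the stated rules exactly: locus missingness
≥ 15% inclusive, MAF ≤ 0.05 inclusive, individual missingness > 20%
exclusive. The heterozygosity filter uses the Wilson score interval
(two-sided 95%) and excludes a locus when the lower bound of its
heterozygote fraction exceeds 0.5, the Hardy–Weinberg maximum for the
population mean at a biallelic locus — the signature of collapsed
paralogs genotyped as permanent heterozygotes. Its type-I error under
Hardy–Weinberg is ≤ α by construction and verified by simulation.

**Clone analysis.** Trio mismatch is the fraction of jointly non-missing
loci at which the three genotypes are not all identical — this makes
trio mismatch ≥ the maximum pairwise mismatch within the trio, matching
the observed ordering of trio over pair ranges. Unrelated control
groups are drawn without replacement across genets, seeded, with the
group count matching the ramet-group count (83). Mismatch profiles are
computed after mislabelled ramets are reassigned to their inferred
genet, mirroring the published procedure. Fuzzy identity is
single-linkage grouping at pairwise mismatch ≤ 0.10, a threshold chosen
inside the empirical gap between within-clone (≤ ~9%) and unrelated
(≥ ~30%) mismatch regimes and exposed in config; a chain merging two
labelled genets with > 2 ramets each is reported as a conflict, never
silently merged. The relatedness matrix is VanRaden's
G = ZZ′ / (2 Σ pᵢ(1−pᵢ)) on per-locus mean-imputed dosages with allele
frequencies computed over all individuals including ramets (as in the
validation study); clonal replication biases those frequencies, so a
one-genotype-per-genet frequency vector can be supplied instead via the
`freqs` argument.

## Degenerate inputs and tie-breaks

Empty read sets, all-monomorphic panels, unanchored contigs, zero-depth
cells and unsorted variant streams raise typed errors naming the rule or
stage; pileup base ties resolve deterministically (highest base code)
with GQ 0, which the GQ filter then removes. All randomness flows from
explicit integer seeds; fixed seeds give byte-identical outputs, and
eBWT calls are invariant to read input order.

## Known limitations

No indel calling or indel-aware alignment (substitution SNPs only, as in
the validated panel); exact k-mer counting and in-memory suffix sorting
bound inputs to tens of megabases; the GQ proxy is not a calibrated
genotype-likelihood model; identity analysis is threshold-based matching,
not a likelihood model of genotyping error; GRM allele frequencies from
clonal data are biased toward large clones unless deduplicated.
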