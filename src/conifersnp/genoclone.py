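"""Amplicon genotype calling, panel filtering and clone validation.

Genotypes are called from per-locus (ref, alt) amplicon read counts with a
binomial likelihood over dosages {0, 1, 2} and an allele-frequency prior;
cells below the posterior threshold are missing. The panel is then
filtered (locus missingness, minor allele frequency, individual
missingness, and a Wilson-interval test against heterozygosity above the
0.5 theoretical maximum) before clone validation: within-clone versus
randomized unrelated mismatch profiles and the gap statistic, fuzzy
identity grouping with mislabel classification, and the VanRaden genomic
relatedness matrix G = ZZ' / (2 * sum p_i (1-p_i)) over centered dosages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom, chi2
from statsmodels.stats.proportion import proportion_confint

DOSAGES = (0, 1, 2)


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------


def call_amplicon_genotypes(
    ref_counts: pd.DataFrame,
    alt_counts: pd.DataFrame,
    err: float = 0.01,
    min_posterior: float = 0.95,
) -> pd.DataFrame:
    """Posterior genotype calls from amplicon read counts.

    Dosage likelihoods are Binomial(alt | depth, p_g) with p_g in
    {err, 0.5, 1-err}; the prior is Hardy-Weinberg at a first-pass
    per-locus frequency estimated from pooled read fractions. Cells whose
    MAP posterior is <= ``min_posterior`` (or with zero depth) are NaN.
    """
    if not 0 < err <= 0.05:
        raise ValueError("err must lie in (0, 0.05]")
    if (ref_counts.values < 0).any() or (alt_counts.values < 0).any():
        raise ValueError("negative read counts")
    alt = alt_counts.to_numpy(dtype=float)
    depth = alt + ref_counts.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.clip(alt.sum(axis=0) / np.maximum(depth.sum(axis=0), 1), 0.01, 0.99)
    prior = np.stack(
        [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
    )  # (3, n_loci)
    p_g = np.array([err, 0.5, 1 - err])
    lik = np.stack(
        [binom.pmf(alt, depth, p) for p in p_g]
    )  # (3, n_ind, n_loci)
    post = lik * prior[:, None, :]
    norm = post.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = post / norm
    best = np.argmax(post, axis=0).astype(float)
    best_post = np.max(post, axis=0)
    best[(depth == 0) | ~(best_post > min_posterior)] = np.nan
    return pd.DataFrame(best, index=ref_counts.index, columns=ref_counts.columns)


def polymorphism_test(
    ref_col: np.ndarray, alt_col: np.ndarray, err: float = 0.01
) -> float:
    """Likelihood-ratio p-value against a monomorphic read-level model.

    Null: every individual is homozygous for the same allele (alt counts
    are sequencing error at rate ``err``). Alternative: Hardy-Weinberg
    genotype mixture at a free allele frequency. Returns the chi-square
    (df=1) tail probability; NaN when the locus is untestable (fewer than
    10 covered individuals).
    """
    alt = np.asarray(alt_col, dtype=float)
    depth = alt + np.asarray(ref_col, dtype=float)
    ok = depth > 0
    alt, depth = alt[ok], depth[ok]
    if len(alt) < 10:
        return float("nan")
    ll_mono = max(
        binom.logpmf(alt, depth, err).sum(),
        binom.logpmf(alt, depth, 1 - err).sum(),
    )
    p_g = np.array([err, 0.5, 1 - err])
    lik_g = np.stack([binom.pmf(alt, depth, p) for p in p_g])  # (3, n)

    def neg_ll(p: float) -> float:
        w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        mix = w @ lik_g
        return -np.log(np.maximum(mix, 1e-300)).sum()

    res = minimize_scalar(neg_ll, bounds=(1e-3, 1 - 1e-3), method="bounded")
    lr = max(0.0, 2 * (-res.fun - ll_mono))
    return float(chi2.sf(lr, df=1))


def flag_nonvariable_loci(
    ref_counts: pd.DataFrame,
    alt_counts: pd.DataFrame,
    err: float = 0.01,
    alpha: float = 0.001,
) -> pd.Series:
    """Per-locus polymorphism p-values; loci with p >= alpha (or NaN) are
    flagged non-variable. Returns the boolean 'keep' mask as a Series."""
    pvals = {
        locus: polymorphism_test(ref_counts[locus].to_numpy(), alt_counts[locus].to_numpy(), err)
        for locus in ref_counts.columns
    }
    s = pd.Series(pvals)
    return s < alpha


# ---------------------------------------------------------------------------
# Panel filtering
# ---------------------------------------------------------------------------


class PanelFilterResult(NamedTuple):
    gm: pd.DataFrame
    attrition: dict[str, int]


class EmptyPanelError(ValueError):
    pass


def allele_freq(gm: pd.DataFrame) -> pd.Series:
    """Per-locus alternative allele frequency from non-missing dosages."""
    return gm.mean(axis=0, skipna=True) / 2.0


def filter_panel(
    gm: pd.DataFrame,
    max_locus_missing: float = 0.15,
    min_maf: float = 0.05,
    max_indiv_missing: float = 0.20,
) -> PanelFilterResult:
    """Fixed-order panel filter: locus missingness -> MAF -> individual
    missingness.

    Boundaries follow the stated rules: loci with missing fraction
    >= ``max_locus_missing`` are dropped (inclusive), loci with
    MAF <= ``min_maf`` are dropped (inclusive), individuals with missing
    fraction > ``max_indiv_missing`` are dropped (exclusive).
    """
    attrition: dict[str, int] = {}
    out = gm
    miss = out.isna().mean(axis=0)
    keep = miss[miss < max_locus_missing].index
    attrition["locus_missing"] = out.shape[1] - len(keep)
    out = out[keep]
    if out.shape[1] == 0:
        raise EmptyPanelError("locus_missing rule removed every locus")
    p = allele_freq(out)
    maf = np.minimum(p, 1 - p)
    keep = maf[maf > min_maf].index
    attrition["maf"] = out.shape[1] - len(keep)
    out = out[keep]
    if out.shape[1] == 0:
        raise EmptyPanelError("maf rule removed every locus")
    imiss = out.isna().mean(axis=1)
    keep_i = imiss[imiss <= max_indiv_missing].index
    attrition["indiv_missing"] = out.shape[0] - len(keep_i)
    out = out.loc[keep_i]
    if out.shape[0] == 0:
        raise EmptyPanelError("indiv_missing rule removed every individual")
    return PanelFilterResult(out, attrition)


def het_ci_filter(gm: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Exclude loci whose heterozygote fraction is significantly above 0.5.

    0.5 is the theoretical maximum for the expected heterozygosity of a
    biallelic locus under Hardy-Weinberg; a Wilson score interval whose
    lower bound exceeds it marks paralog-collapse artifacts. Returns
    (kept, excluded) locus lists.
    """
    kept, excluded = [], []
    for locus in gm.columns:
        col = gm[locus].dropna()
        n = len(col)
        if n == 0:
            kept.append(locus)
            continue
        het = int((col == 1).sum())
        lower, _ = proportion_confint(het, n, alpha=alpha, method="wilson")
        (excluded if lower > 0.5 else kept).append(locus)
    return kept, excluded


# ---------------------------------------------------------------------------
# Clone validation
# ---------------------------------------------------------------------------


def mismatch_percent(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    c: pd.Series | np.ndarray | None = None,
) -> float:
    """Fraction of jointly non-missing loci where genotypes disagree.

    For a trio, a locus counts as a mismatch unless all three genotypes
    are identical (hence trio mismatch >= max pairwise mismatch).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if c is None:
        ok = ~np.isnan(a) & ~np.isnan(b)
        if not ok.any():
            raise ValueError("no jointly non-missing locus")
        return float((a[ok] != b[ok]).mean())
    c = np.asarray(c, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b) & ~np.isnan(c)
    if not ok.any():
        raise ValueError("no jointly non-missing locus")
    same = (a[ok] == b[ok]) & (b[ok] == c[ok])
    return float((~same).mean())


def mismatch_gap(max_ramet_pct: float, min_unrelated_pct: float) -> float:
    """Gap statistic: minimum unrelated mismatch minus maximum ramet
    mismatch, on the percent scale."""
    return min_unrelated_pct - max_ramet_pct


class MismatchProfile(NamedTuple):
    table: pd.DataFrame  # columns: kind, size, members, mismatch_pct
    summary: dict[str, float]  # min/max per (kind, size) and gaps


def mismatch_profile(
    gm: pd.DataFrame,
    clone_map: pd.Series,
    n_groups: int = 83,
    seed: int = 0,
) -> MismatchProfile:
    """Within-clone versus randomized unrelated mismatch distributions.

    Every within-clone pair and trio is scored, plus ``n_groups`` seeded
    random unrelated pairs and trios (members drawn from distinct
    genets). The summary reports min/max per group and the gap statistic
    (min unrelated - max ramet) for pairs and trios separately.
    """
    rng = np.random.default_rng(seed)
    clone_map = clone_map.loc[gm.index]
    genets = clone_map.groupby(clone_map).groups
    genet_ids = list(genets)
    if n_groups > 0 and len(genet_ids) < 3:
        raise ValueError("need at least 3 genets for unrelated groups")
    rows = []
    for g, members in genets.items():
        members = list(members)
        if len(members) >= 2:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pct = 100 * mismatch_percent(gm.loc[members[i]], gm.loc[members[j]])
                    rows.append(("ramet", 2, f"{members[i]},{members[j]}", pct))
        if len(members) >= 3:
            pct = 100 * mismatch_percent(*(gm.loc[m] for m in members[:3]))
            rows.append(("ramet", 3, ",".join(members[:3]), pct))
    for size in (2, 3):
        for _ in range(n_groups):
            gs = rng.choice(genet_ids, size=size, replace=False)
            members = [str(rng.choice(list(genets[g]))) for g in gs]
            pct = 100 * mismatch_percent(*(gm.loc[m] for m in members))
            rows.append(("unrelated", size, ",".join(members), pct))
    table = pd.DataFrame(rows, columns=["kind", "size", "members", "mismatch_pct"])
    summary: dict[str, float] = {}
    for kind in ("ramet", "unrelated"):
        for size in (2, 3):
            sel = table[(table["kind"] == kind) & (table["size"] == size)]["mismatch_pct"]
            if len(sel):
                summary[f"{kind}_{'pair' if size == 2 else 'trio'}_min"] = float(sel.min())
                summary[f"{kind}_{'pair' if size == 2 else 'trio'}_max"] = float(sel.max())
    for grp in ("pair", "trio"):
        if f"ramet_{grp}_max" in summary and f"unrelated_{grp}_min" in summary:
            summary[f"{grp}_gap"] = mismatch_gap(
                summary[f"ramet_{grp}_max"], summary[f"unrelated_{grp}_min"]
            )
    return MismatchProfile(table, summary)


class IdentityResult(NamedTuple):
    assignments: pd.Series  # individual -> inferred genet label
    mislabels: pd.DataFrame  # individual, labelled_genet, inferred_genet, class
    conflicts: list[str]


def identity_analysis(
    gm: pd.DataFrame,
    labels: pd.Series,
    max_mismatch: float = 0.10,
) -> IdentityResult:
    """Fuzzy identity: single-linkage grouping at a mismatch threshold.

    Individuals whose pairwise mismatch is <= ``max_mismatch`` join the
    same inferred genet. Each group is named after its majority label;
    individuals whose label disagrees are reported as mislabels —
    "reassigned" when their group carries another label, "unrelated" when
    they end up alone while their labelled genet has other members. A
    group merging two labelled genets that both contribute more than two
    ramets is reported as a conflict rather than silently merged.
    """
    labels = labels.loc[gm.index]
    inds = list(gm.index)
    parent = {i: i for i in inds}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mat = gm.to_numpy(dtype=float)
    ok = ~np.isnan(mat)
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            both = ok[i] & ok[j]
            if not both.any():
                continue
            mm = float((mat[i, both] != mat[j, both]).mean())
            if mm <= max_mismatch:
                parent[find(inds[i])] = find(inds[j])

    groups: dict[str, list[str]] = {}
    for i in inds:
        groups.setdefault(find(i), []).append(i)

    label_counts = labels.value_counts()
    assignments = {}
    mis_rows = []
    conflicts: list[str] = []
    for members in groups.values():
        mem_labels = labels.loc[members]
        counts = mem_labels.value_counts()
        consensus = counts.index[0]
        heavy = [lab for lab, c in counts.items() if c > 2]
        if len(heavy) > 1:
            conflicts.append(
                f"groups {sorted(heavy)} merged by a linkage chain ({len(members)} members)"
            )
        for m in members:
            assignments[m] = consensus
            if labels[m] == consensus:
                continue
            if len(members) == 1:
                if label_counts.get(labels[m], 0) > 1:
                    mis_rows.append((m, labels[m], consensus, "unrelated"))
            else:
                mis_rows.append((m, labels[m], consensus, "reassigned"))
    # a singleton whose labelled genet has other members is unrelated even
    # if it is its own group's (trivial) majority
    for members in groups.values():
        if len(members) == 1:
            m = members[0]
            if label_counts.get(labels[m], 0) > 1:
                if not any(r[0] == m for r in mis_rows):
                    mis_rows.append((m, labels[m], f"unrelated:{m}", "unrelated"))
                assignments[m] = f"unrelated:{m}"
    mislabels = pd.DataFrame(
        mis_rows, columns=["individual", "labelled_genet", "inferred_genet", "class"]
    )
    return IdentityResult(pd.Series(assignments).loc[gm.index], mislabels, conflicts)


# ---------------------------------------------------------------------------
# Genomic relatedness (VanRaden)
# ---------------------------------------------------------------------------


@dataclass
class RelatednessMatrix:
    G: pd.DataFrame
    freqs: pd.Series
    loci: list[str]


def grm(gm: pd.DataFrame, freqs: pd.Series | None = None) -> RelatednessMatrix:
    """VanRaden genomic relatedness matrix from SNP dosages.

    Missing cells are mean-imputed per locus; Z is the dosage matrix with
    column i centered by 2 p_i; G = Z Z' / (2 * sum_i p_i (1 - p_i)).
    """
    if freqs is None:
        freqs = allele_freq(gm)
    freqs = freqs.loc[gm.columns]
    denom = 2.0 * float((freqs * (1 - freqs)).sum())
    if denom == 0:
        raise ValueError("all loci monomorphic; relatedness undefined")
    mat = gm.to_numpy(dtype=float)
    col_mean = np.nanmean(mat, axis=0)
    nan_mask = np.isnan(mat)
    mat = np.where(nan_mask, col_mean[None, :], mat)
    Z = mat - 2.0 * freqs.to_numpy()[None, :]
    G = Z @ Z.T / denom
    return RelatednessMatrix(
        G=pd.DataFrame(G, index=gm.index, columns=gm.index),
        freqs=freqs,
        loci=list(gm.columns),
    )
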