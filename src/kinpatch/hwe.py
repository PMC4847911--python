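"""Hardy-Weinberg diagnostics for site x locus genotype samples.

Both randomization tests condition on the observed allele counts: the null
distribution is generated by shuffling the multiset of gene copies and
re-pairing them into diploid genotypes, which samples genotype tables
uniformly from the conditional distribution given allele counts.  The exact
test ranks tables by their conditional probability

    P(table | allele counts) = n! * prod_a m_a! * 2^h / ((2n)! * prod_g n_g!)

(h = heterozygote count, m_a = allele copy counts, n_g = genotype counts);
the homozygote-excess test uses the total homozygote count as a one-tailed
upper statistic, which is the direction produced by inbreeding or null
alleles.  A per-allele weighted variant of the excess statistic,
sum_a (Obs_aa - E[Obs_aa]) / p_a, is available behind ``weighted=True``.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .genotype import (
    GenotypeTable,
    GenotypeTableError,
    allele_frequencies,
    expected_heterozygosity,
    locus_summary,
)
from .results import RegressionResult, TestResult

__all__ = [
    "genotype_counts",
    "hwe_exact_test",
    "homozygote_excess_test",
    "inbreeding_coefficient",
    "fis_permutation_test",
    "missingness_heterozygosity_regression",
    "hwe_grid",
]

LN2 = float(np.log(2.0))


def genotype_counts(table: GenotypeTable, site: str, locus: str) -> dict[tuple[int, int], int]:
    """Counts of each (sorted) genotype pair at a locus within a site."""
    sub = table.site_table(site)
    j = sub.locus_index(locus)
    ok = ~sub.missing_mask()[:, j]
    return dict(Counter(map(tuple, sub.alleles[ok, j, :].tolist())))


def _counts_to_copies(counts: Mapping[tuple[int, int], int]) -> np.ndarray:
    copies: list[int] = []
    for (a, b), c in counts.items():
        copies.extend([a, b] * c)
    return np.asarray(copies, dtype=np.int64)


def _log_conditional_prob(counts: Mapping[tuple[int, int], int]) -> float:
    """log P(genotype table | its own allele counts)."""
    n = sum(counts.values())
    copies = _counts_to_copies(counts)
    m = np.asarray(list(Counter(copies.tolist()).values()), float)
    h = sum(c for (a, b), c in counts.items() if a != b)
    ng = np.asarray(list(counts.values()), float)
    return float(
        gammaln(n + 1) + gammaln(m + 1).sum() + h * LN2
        - gammaln(2 * n + 1) - gammaln(ng + 1).sum()
    )


def _simulate_tables(copies: np.ndarray, n_mc: int, rng: np.random.Generator):
    """Vectorized conditional-null tables.

    Returns per-replicate genotype-count log-score components: the
    -sum log(n_g!) + h*log2 part of the conditional log-probability (terms
    fixed by the allele counts are constant across tables) and the
    homozygote count per replicate.
    """
    n2 = copies.size
    n = n2 // 2
    # relabel alleles 0..K-1 for compact genotype codes
    uniq, relab = np.unique(copies, return_inverse=True)
    k = uniq.size
    tiled = np.tile(relab.astype(np.int32), (n_mc, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    a = tiled[:, 0::2]
    b = tiled[:, 1::2]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    hom = (lo == hi).sum(axis=1)
    code = lo.astype(np.int64) * k + hi
    offset = (np.arange(n_mc, dtype=np.int64) * (k * k))[:, None]
    flat = (code + offset).ravel()
    table_counts = np.bincount(flat, minlength=n_mc * k * k).reshape(n_mc, k * k)
    log_score = -gammaln(table_counts + 1.0).sum(axis=1) + (n - hom) * LN2
    return log_score, hom


def _validate(counts: Mapping[tuple[int, int], int], n_mc: int):
    n = sum(counts.values())
    if n < 2:
        raise GenotypeTableError("need >= 2 non-missing genotypes for an HWE test")
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    copies = _counts_to_copies(counts)
    return copies, np.unique(copies).size


def hwe_exact_test(
    counts: Mapping[tuple[int, int], int],
    n_mc: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Monte Carlo exact test of Hardy-Weinberg proportions.

    p estimates the probability, under the conditional null, of a table
    whose conditional probability is <= that of the observed table
    (two-sided in the usual exact-test sense), with the add-one correction.
    """
    copies, k = _validate(counts, n_mc)
    if k == 1:
        return TestResult(1.0, 1.0, 0, "lower", seed, degenerate=True,
                          flags=["monomorphic"])
    rng = np.random.default_rng(seed)
    n = copies.size // 2
    ng = np.asarray(list(counts.values()), float)
    h = sum(c for (a, b), c in counts.items() if a != b)
    obs_score = -gammaln(ng + 1.0).sum() + h * LN2
    sim_score, _ = _simulate_tables(copies, n_mc, rng)
    hits = int((sim_score <= obs_score + 1e-9).sum())
    p = (hits + 1) / (n_mc + 1)
    return TestResult(float(np.exp(_log_conditional_prob(counts))), p, n_mc,
                      "lower", seed)


def homozygote_excess_test(
    counts: Mapping[tuple[int, int], int],
    n_mc: int = 100_000,
    seed: int | None = None,
    weighted: bool = False,
) -> TestResult:
    """One-tailed Monte Carlo test for homozygote excess.

    Default statistic: total homozygote count U; ``weighted=True`` uses the
    per-allele excess score sum_a (Obs_aa - E[Obs_aa]) / p_a, with E under
    the conditional (without-replacement) null.
    """
    copies, k = _validate(counts, n_mc)
    if k == 1:
        return TestResult(float(sum(counts.values())), 1.0, 0, "upper", seed,
                          degenerate=True, flags=["monomorphic"])
    rng = np.random.default_rng(seed)
    n = copies.size // 2
    allele_counts = Counter(copies.tolist())
    if not weighted:
        u_obs = sum(c for (a, b), c in counts.items() if a == b)
        _, hom_sim = _simulate_tables(copies, n_mc, rng)
        hits = int((hom_sim >= u_obs).sum())
        return TestResult(float(u_obs), (hits + 1) / (n_mc + 1), n_mc, "upper", seed)
    # weighted variant: needs per-allele homozygote counts per replicate
    uniq = np.asarray(sorted(allele_counts))
    m = np.asarray([allele_counts[a] for a in uniq], float)
    p_a = m / (2.0 * n)
    e_aa = n * m * (m - 1) / ((2.0 * n) * (2.0 * n - 1.0))
    w = 1.0 / p_a

    def weighted_u(gcounts: Mapping[tuple[int, int], int]) -> float:
        obs = np.zeros(uniq.size)
        lookup = {int(a): i for i, a in enumerate(uniq)}
        for (a, b), c in gcounts.items():
            if a == b:
                obs[lookup[a]] += c
        return float(((obs - e_aa) * w).sum())

    u_obs = weighted_u(counts)
    relab = {int(a): i for i, a in enumerate(uniq)}
    arr = np.asarray([relab[int(c)] for c in copies], dtype=np.int32)
    tiled = np.tile(arr, (n_mc, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    a_sim = tiled[:, 0::2]
    b_sim = tiled[:, 1::2]
    hom_mask = a_sim == b_sim
    u_sim = np.zeros(n_mc)
    for i_a in range(uniq.size):
        u_sim += ((hom_mask & (a_sim == i_a)).sum(axis=1) - e_aa[i_a]) * w[i_a]
    hits = int((u_sim >= u_obs - 1e-9).sum())
    return TestResult(u_obs, (hits + 1) / (n_mc + 1), n_mc, "upper", seed)


def inbreeding_coefficient(table: GenotypeTable, site: str, locus: str) -> float:
    """F_IS = 1 - Ho/He from within-site allele frequencies.

    Returns NaN when He = 0 (monomorphic or empty sample), matching the
    convention that the coefficient is undefined there.
    """
    summ = locus_summary(table.site_table(site), locus)
    if summ.he == 0.0:
        return float("nan")
    return 1.0 - summ.ho / summ.he


def fis_permutation_test(
    table: GenotypeTable,
    site: str,
    locus: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """One-tailed allele-permutation significance for F_IS > 0.

    Gene copies are shuffled within the site x locus sample and re-paired;
    because re-pairing conserves allele counts (hence He), F_IS_perm >=
    F_IS_obs reduces to Ho_perm <= Ho_obs.
    """
    counts = genotype_counts(table, site, locus)
    fis = inbreeding_coefficient(table, site, locus)
    if not np.isfinite(fis):
        return TestResult(0.0, 1.0, 0, "upper", seed, degenerate=True,
                          flags=["He=0"])
    copies = _counts_to_copies(counts)
    rng = np.random.default_rng(seed)
    h_obs = sum(c for (a, b), c in counts.items() if a != b)
    tiled = np.tile(copies.astype(np.int32), (n_perm, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    het_sim = (tiled[:, 0::2] != tiled[:, 1::2]).sum(axis=1)
    hits = int((het_sim <= h_obs).sum())
    return TestResult(fis, (hits + 1) / (n_perm + 1), n_perm, "upper", seed)


def missingness_heterozygosity_regression(table: GenotypeTable) -> tuple[RegressionResult, pd.DataFrame]:
    """OLS of |He - Ho| on missingness over all site x locus samples.

    Null alleles make apparent homozygotes and missing genotypes together,
    so a positive slope is the diagnostic signature; a flat fit argues
    against null alleles.  Returns the fit plus the per-point scatter
    (site, locus, missing, |He - Ho|) for plotting.
    """
    records = []
    for site in table.site_labels:
        sub = table.site_table(site)
        for locus in table.loci:
            s = locus_summary(sub, locus)
            if s.richness == 0 or s.he == 0.0:
                continue
            records.append((site, locus, s.missing, abs(s.he - s.ho)))
    pts = pd.DataFrame(records, columns=["site", "locus", "missing", "abs_he_ho"])
    if len(pts) < 3:
        raise GenotypeTableError("need >= 3 site x locus points with defined He")
    if np.ptp(pts["missing"].to_numpy()) == 0:
        raise GenotypeTableError("no variance in missingness predictor")
    x = sm.add_constant(pts["missing"].to_numpy())
    fit = sm.OLS(pts["abs_he_ho"].to_numpy(), x).fit()
    f_stat = float(fit.fvalue)
    p_val = float(fit.f_pvalue)
    if not np.isfinite(f_stat) or f_stat < 0:  # degenerate zero-variance fit
        f_stat, p_val = 0.0, 1.0
    result = RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_statistic=f_stat,
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=p_val,
        n=len(pts),
    )
    return result, pts


def hwe_grid(
    table: GenotypeTable,
    n_mc: int = 100_000,
    seed: int | None = None,
    test: str = "exact",
) -> pd.DataFrame:
    """Site x locus p-value grid for the exact or homozygote-excess test."""
    if test not in ("exact", "excess"):
        raise ValueError("test must be 'exact' or 'excess'")
    ss = np.random.SeedSequence(seed)
    rows = {}
    for site in table.site_labels:
        rows[site] = {}
        for locus in table.loci:
            counts = genotype_counts(table, site, locus)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            if sum(counts.values()) < 2:
                rows[site][locus] = np.nan
                continue
            fn = hwe_exact_test if test == "exact" else homozygote_excess_test
            rows[site][locus] = fn(counts, n_mc=n_mc, seed=sub_seed).p_value
    return pd.DataFrame(rows).T.loc[table.site_labels, table.loci]
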