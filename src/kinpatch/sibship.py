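"""Pairwise-likelihood sibship classification and marker-panel power.

Each dyad is scored under the three canonical non-inbred relationship
hypotheses -- full sib k = (1/4, 1/2, 1/4), half sib (1/2, 1/2, 0), and
unrelated (1, 0, 0) -- by multiplying the error-aware per-locus genotype
pair probabilities across loci; posteriors are prior x likelihood,
normalized.  A dyad is labeled only when its maximum posterior reaches the
confidence threshold (default 0.95), otherwise UNASSIGNED.  This is a
deliberate pairwise replacement for full-pedigree sibship reconstruction:
it classifies dyads independently and cannot use sibship-group
constraints; avuncular and grandparent-grandchild dyads share the half-sib
k-vector and are indistinguishable from half sibs.

The exclusion-probability power analysis asks: for a group of (by default)
three unrelated individuals drawn from the population frequencies, what is
the probability that at least one locus proves they cannot all be full
sibs?  A locus excludes the group when no ordered pair of parental
genotypes could have produced every member as offspring.  It suffices to
enumerate candidate parents over the alleles observed in the group: any
parental allele never transmitted to a group member can be replaced by an
observed one without breaking compatibility, so restricting parents to
observed alleles never misses a compatible pair.  Per-locus exclusion
probabilities E_l combine as 1 - prod_l (1 - E_l).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotype import FrequencyTable, GenotypeTable, GenotypeTableError, allele_frequencies
from .relatedness import FULL_SIB_K, HALF_SIB_K, UNRELATED_K, dyad_mode_likelihoods

__all__ = [
    "DyadClassification",
    "ExclusionResult",
    "classify_dyads",
    "sib_count_permutation",
    "exclusion_probability",
]

CATEGORIES = ("FS", "HS", "U")
_K_VECTORS = np.array([FULL_SIB_K, HALF_SIB_K, UNRELATED_K])


@dataclass
class DyadClassification:
    """Posterior FS/HS/U classification of every dyad."""

    table: pd.DataFrame  # columns id1, id2, pFS, pHS, pU, label
    error_rate: float
    prior: tuple[float, float, float]
    threshold: float

    def sib_pairs(self) -> set[tuple[str, str]]:
        """Unordered id pairs labeled FS or HS."""
        sib = self.table[self.table["label"].isin(("FS", "HS"))]
        return {tuple(sorted((a, b))) for a, b in zip(sib["id1"], sib["id2"])}

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


@dataclass
class ExclusionResult:
    """Probability of excluding a group of unrelated individuals from a
    single full sibship, for a locus subset."""

    probability: float
    loci: list[str]
    group_size: int
    n_mc: int
    per_locus: dict[str, float] = field(default_factory=dict)
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.probability <= 1.0


def classify_dyads(
    table: GenotypeTable,
    freqs: FrequencyTable | None = None,
    error_rate: float = 0.01,
    prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    threshold: float = 0.95,
    min_loci: int = 3,
) -> DyadClassification:
    """Posterior relationship category per dyad.

    Dyads with fewer than ``min_loci`` overlapping scored loci are
    UNASSIGNED and flagged with NaN posteriors.
    """
    if freqs is None:
        freqs = allele_frequencies(table, "global")
    prior_arr = np.asarray(prior, float)
    if prior_arr.shape != (3,) or abs(prior_arr.sum() - 1) > 1e-9 or (prior_arr < 0).any():
        raise ValueError("prior must be a probability vector over (FS, HS, U)")
    p, valid = dyad_mode_likelihoods(table, freqs, error_rate)
    # log-likelihood per hypothesis: sum_l log(k . P_l)
    mix = np.einsum("mlc,hc->mlh", p, _K_VECTORS)
    logl = np.where(valid[:, :, None], np.log(np.maximum(mix, 1e-300)), 0.0).sum(axis=1)
    logpost = logl + np.log(np.maximum(prior_arr, 1e-300))[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    n_overlap = valid.sum(axis=1)
    i_idx, j_idx = np.triu_indices(table.n_individuals, k=1)
    labels = []
    for row, nov in zip(post, n_overlap):
        if nov < min_loci:
            labels.append("UNASSIGNED")
        elif row.max() >= threshold:
            labels.append(CATEGORIES[int(row.argmax())])
        else:
            labels.append("UNASSIGNED")
    post = post.copy()
    post[n_overlap < min_loci] = np.nan
    df = pd.DataFrame({
        "id1": [table.ids[i] for i in i_idx],
        "id2": [table.ids[j] for j in j_idx],
        "pFS": post[:, 0],
        "pHS": post[:, 1],
        "pU": post[:, 2],
        "n_loci": n_overlap,
        "label": labels,
    })
    return DyadClassification(df, error_rate, tuple(prior_arr), threshold)


def sib_count_permutation(
    dyads: DyadClassification,
    clusters: dict[str, object],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-tailed permutation test of within-cluster sib-dyad counts.

    Statistic per cluster: number of FS+HS dyads whose two members both lie
    in the cluster.  The null permutes individuals among clusters keeping
    cluster sizes; p doubles the smaller add-one tail (capped at 1).
    """
    ids = sorted({i for pair in zip(dyads.table["id1"], dyads.table["id2"]) for i in pair})
    labels = np.asarray([clusters[i] for i in ids], object)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise GenotypeTableError("need >= 2 clusters to permute among")
    index = {i: k for k, i in enumerate(ids)}
    sib = dyads.table[dyads.table["label"].isin(("FS", "HS"))]
    e1 = np.asarray([index[i] for i in sib["id1"]], int)
    e2 = np.asarray([index[i] for i in sib["id2"]], int)
    rng = np.random.default_rng(seed)

    def counts(lab: np.ndarray) -> dict:
        same = lab[e1] == lab[e2]
        return {g: int(((lab[e1] == g) & same).sum()) for g in uniq}

    obs = counts(labels)
    null = {g: np.empty(n_perm, int) for g in uniq}
    for b in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        c = counts(perm)
        for g in uniq:
            null[g][b] = c[g]
    rows = []
    for g in uniq:
        upper = (int((null[g] >= obs[g]).sum()) + 1) / (n_perm + 1)
        lower = (int((null[g] <= obs[g]).sum()) + 1) / (n_perm + 1)
        rows.append((g, obs[g], min(1.0, 2.0 * min(upper, lower))))
    return pd.DataFrame(rows, columns=["cluster", "sib_dyads", "p_value"]).set_index("cluster")


@lru_cache(maxsize=None)
def _compatible_pattern(pattern: tuple[tuple[int, int], ...]) -> bool:
    """Can some ordered parental genotype pair produce all these offspring?

    Parents are enumerated over the offspring's observed alleles only
    (sufficient; see module docstring).
    """
    alleles = sorted({a for g in pattern for a in g})
    genos = list(itertools.combinations_with_replacement(alleles, 2))
    for p1 in genos:
        for p2 in genos:
            if all((a in p1 and b in p2) or (b in p1 and a in p2)
                   for a, b in pattern):
                return True
    return False


def _canonical(genos: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Relabel alleles by order of appearance so equivalent trios share a key."""
    relab: dict[int, int] = {}
    out = []
    for a, b in genos:
        for x in (a, b):
            if x not in relab:
                relab[x] = len(relab)
        out.append(tuple(sorted((relab[a], relab[b]))))
    return tuple(sorted(out))


def exclusion_probability(
    freqs: FrequencyTable,
    loci_subset: list[str] | None = None,
    group_size: int = 3,
    n_mc: int = 100_000,
    seed: int | None = None,
    n_subsets: int | None = None,
    subset_size: int | None = None,
) -> ExclusionResult:
    """Monte Carlo full-sibship exclusion probability for a marker panel.

    Draws ``n_mc`` groups of ``group_size`` unrelated genotypes per locus
    from the (pooled) frequencies, error-free, and counts groups no
    parental pair can explain.  When ``n_subsets``/``subset_size`` are
    given, the combined probability is instead evaluated over random locus
    subsets, reporting the mean and 2.5/97.5 percentile interval.
    """
    loci = list(loci_subset) if loci_subset is not None else list(freqs.loci)
    if not loci:
        raise GenotypeTableError("empty locus subset")
    rng = np.random.default_rng(seed)
    per_locus: dict[str, float] = {}
    for locus in loci:
        p = freqs.pooled(locus)
        if not p:
            raise GenotypeTableError(f"no frequencies for locus {locus!r}")
        alleles = np.asarray(sorted(p))
        probs = np.asarray([p[a] for a in alleles])
        probs = probs / probs.sum()
        if len(alleles) == 1:
            per_locus[locus] = 0.0
            continue
        draws = rng.choice(alleles, size=(n_mc, group_size, 2), p=probs)
        draws = np.sort(draws, axis=2)
        excluded = 0
        for trio in draws:
            if not _compatible_pattern(_canonical(trio)):
                excluded += 1
        per_locus[locus] = excluded / n_mc
    if n_subsets is None:
        combined = 1.0 - float(np.prod([1.0 - per_locus[l] for l in loci]))
        return ExclusionResult(combined, loci, group_size, n_mc, per_locus)
    size = subset_size if subset_size is not None else len(loci)
    if size > len(loci):
        raise GenotypeTableError("subset_size exceeds available loci")
    vals = []
    for _ in range(n_subsets):
        pick = rng.choice(len(loci), size=size, replace=False)
        vals.append(1.0 - float(np.prod([1.0 - per_locus[loci[i]] for i in pick])))
    vals_arr = np.asarray(vals)
    lo, hi = np.percentile(vals_arr, [2.5, 97.5])
    return ExclusionResult(float(vals_arr.mean()), loci, group_size, n_mc,
                           per_locus, ci=(float(lo), float(hi)))
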