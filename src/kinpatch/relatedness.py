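"""Likelihood estimation of pairwise relatedness from codominant genotypes.

The relationship between two non-inbred individuals is summarized by the
IBD-mode coefficients k = (k0, k1, k2): the probabilities that the dyad
shares 0, 1 or 2 alleles identical by descent at a locus.  Relatedness is
r = k2 + k1/2 (full sibs (1/4, 1/2, 1/4) -> 0.5, half sibs (1/2, 1/2, 0)
-> 0.25, unrelated (1, 0, 0) -> 0).

Genotyping error uses the class-II model: each *observed* allele is,
independently with probability e, a random draw from the locus allele
frequency distribution instead of the true allele.  Under this model the
per-locus probability of an observed genotype pair given the IBD mode has
a closed form built from

    S(x, y) = (1-e)^2 p_x [x == y] + e (2-e) p_x p_y

(the joint emission of two observed copies descending from one shared true
allele), and the marginal observed-allele distribution stays p.  The
likelihood is linear in k, so the log-likelihood is concave on the simplex
and the maximizer is found by EM (mixture weights) from multiple starts.

The default estimator maximizes the triad likelihood -- the joint
probability of the focal pair's and a random reference individual's
genotypes -- over the dyad's (k0, k1, k2) simplex.  With the reference
unrelated to the pair, its genotype term does not involve k, so the triad
likelihood factorizes and the maximizer coincides with the dyadic ML
estimate; the computation therefore runs on the dyad emissions directly
(the reference-policy arguments are honored for the joint variant below).
Because the likelihood is linear in k, the log-likelihood is concave on
the simplex and EM from multiple starts finds the global maximum.

``estimator="joint-trio"`` relaxes the unrelated-reference assumption and
maximizes over all 16 IBD configurations of the trio's six genes,
reporting the dyad's fitted marginal r = E[shared gene pairs]/2.  Both
variants are boundary-constrained maximum likelihood and share its known
small-panel behavior: estimates for truly unrelated pairs pile up at
r = 0 but cannot go negative, leaving a positive mean bias of a few
hundredths at ten-locus panels (see docs/methods.md for measurements).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import FrequencyTable, GenotypeTable, GenotypeTableError, allele_frequencies

__all__ = [
    "IBDModel",
    "RelatednessMatrix",
    "FULL_SIB_K",
    "HALF_SIB_K",
    "UNRELATED_K",
    "dyad_mode_likelihoods",
    "pairwise_relatedness",
    "mean_group_relatedness",
    "relatedness_permutation_test",
]

FULL_SIB_K = (0.25, 0.5, 0.25)
HALF_SIB_K = (0.5, 0.5, 0.0)
UNRELATED_K = (1.0, 0.0, 0.0)


@dataclass
class IBDModel:
    """IBD-mode coefficients for a dyad plus the genotyping error rate."""

    k0: float
    k1: float
    k2: float
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        k = np.array([self.k0, self.k1, self.k2])
        assert np.all(k >= -1e-9) and abs(k.sum() - 1.0) < 1e-6
        assert 0.0 <= self.error_rate < 1.0

    @property
    def r(self) -> float:
        return self.k2 + 0.5 * self.k1


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise r-hat matrix (diagonal NaN, values in [0, 1])."""

    ids: list[str]
    values: np.ndarray
    estimator: str
    error_rate: float
    n_reference: int
    seed: int | None

    def to_long(self) -> pd.DataFrame:
        n = len(self.ids)
        i, j = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "id1": [self.ids[a] for a in i],
            "id2": [self.ids[b] for b in j],
            "r": self.values[i, j],
        })

    def pair_values(self, idx: np.ndarray) -> np.ndarray:
        """Within-group pairwise values for the given individual indices."""
        sub = self.values[np.ix_(idx, idx)]
        return sub[np.triu_indices(len(idx), k=1)]


def _freq_lookup(freqs: FrequencyTable, loci: list[str]) -> list[dict[int, float]]:
    return [freqs.pooled(locus) for locus in loci]


def dyad_mode_likelihoods(
    table: GenotypeTable,
    freqs: FrequencyTable | None = None,
    error_rate: float = 0.01,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dyad, per-locus probabilities of the observed genotype pair
    conditional on sharing 0/1/2 alleles IBD.

    Returns ``(P, valid)``: P has shape (n_dyads, L, 3) and ``valid`` marks
    dyad x locus cells where both genotypes are scored.  ``pairs`` defaults
    to all unordered pairs i < j.
    """
    if freqs is None:
        freqs = allele_frequencies(table, "global")
    lookups = _freq_lookup(freqs, table.loci)
    n, n_loci = table.n_individuals, len(table.loci)
    if pairs is None:
        pairs = np.triu_indices(n, k=1)
    i_idx, j_idx = pairs
    m = len(i_idx)
    e = float(error_rate)
    miss = table.missing_mask()
    p_out = np.zeros((m, n_loci, 3))
    valid = np.zeros((m, n_loci), dtype=bool)
    c_same = (1.0 - e) ** 2
    c_err = e * (2.0 - e)
    for l in range(n_loci):
        lut = lookups[l]
        if not lut:
            continue
        max_allele = max(max(lut), int(table.alleles[:, l, :].max()))
        pvec = np.zeros(max_allele + 1)
        for a, f in lut.items():
            pvec[a] = f
        g = table.alleles[:, l, :]
        observed = np.unique(g[~miss[:, l]])
        uncovered = [int(a) for a in observed if pvec[a] == 0.0]
        if uncovered:
            raise GenotypeTableError(
                f"frequencies at locus {table.loci[l]!r} do not cover alleles {uncovered}"
            )
        ok = ~miss[:, l]
        cell_ok = ok[i_idx] & ok[j_idx]
        valid[:, l] = cell_ok
        x1, x2 = g[i_idx, 0], g[i_idx, 1]
        y1, y2 = g[j_idx, 0], g[j_idx, 1]
        px1, px2, py1, py2 = pvec[x1], pvec[x2], pvec[y1], pvec[y2]
        mult = ((x1 != x2).astype(float) + 1.0) * ((y1 != y2).astype(float) + 1.0)

        def s_fn(u, v, pu, pv):
            return c_same * pu * (u == v) + c_err * pu * pv

        p0 = p1 = p2 = 0.0
        for (u, pu, u2, pu2) in (((x1, px1, x2, px2)), ((x2, px2, x1, px1))):
            for (v, pv, v2, pv2) in (((y1, py1, y2, py2)), ((y2, py2, y1, py1))):
                s_uv = s_fn(u, v, pu, pv)
                p2 = p2 + s_uv * s_fn(u2, v2, pu2, pv2)
                p1 = p1 + s_uv * pu2 * pv2
                p0 = p0 + pu * pu2 * pv * pv2
        scale = mult / 4.0
        p_out[:, l, 0] = p0 * scale
        p_out[:, l, 1] = p1 * scale
        p_out[:, l, 2] = p2 * scale
    p_out[~valid] = 1.0  # neutral cells drop out of the product
    return p_out, valid


def _enumerate_trio_states() -> list[tuple[tuple[tuple[int, ...], ...], int]]:
    """IBD configurations of a non-inbred trio's six genes.

    Gene slots 0,1 belong to the first dyad member, 2,3 to the second and
    4,5 to the reference.  A configuration is a partition of the slots
    into IBD classes with at most one gene per individual per class (no
    inbreeding).  Configurations equivalent under exchanging the two genes
    within an individual are collapsed to one representative (16 states).
    Each state carries the dyad's marginal IBD-shared pair count
    m in {0, 1, 2}; relatedness is E[m]/2 under the fitted state weights.
    """
    owner = (0, 0, 1, 1, 2, 2)

    def parts(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for p in parts(rest):
            for i, b in enumerate(p):
                yield p[:i] + [b + [first]] + p[i + 1:]
            yield [[first]] + p

    valid = set()
    for p in parts(list(range(6))):
        if all(len({owner[g] for g in b}) == len(b) for b in p):
            valid.add(frozenset(frozenset(b) for b in p))

    def image(p, sw):
        m = {}
        for ind, (g1, g2) in enumerate(((0, 1), (2, 3), (4, 5))):
            m[g1], m[g2] = (g2, g1) if sw[ind] else (g1, g2)
        return frozenset(frozenset(m[g] for g in b) for b in p)

    canon_set = set()
    for p in valid:
        canon_set.add(min((image(p, s) for s in itertools.product((0, 1), repeat=3)),
                          key=lambda q: sorted(tuple(sorted(b)) for b in q)))
    states = []
    for rep in sorted(canon_set, key=lambda q: sorted(tuple(sorted(b)) for b in q)):
        blocks = tuple(sorted((tuple(sorted(b)) for b in rep)))
        m_ab = sum(1 for b in blocks
                   if any(g < 2 for g in b) and any(2 <= g < 4 for g in b))
        states.append((blocks, m_ab))
    return states


TRIO_STATES = _enumerate_trio_states()
TRIO_M_AB = np.asarray([m for _, m in TRIO_STATES], float)


def trio_mode_likelihoods(
    table: GenotypeTable,
    freqs: FrequencyTable,
    error_rate: float,
    pairs: tuple[np.ndarray, np.ndarray],
    refs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dyad, per-locus emission probability of the trio's observed
    genotypes under each of the 16 trio IBD states.

    ``refs`` gives the reference individual index per dyad.  Cells where a
    dyad member is unscored are invalid; cells where only the reference is
    unscored fall back to the dyadic emission of the state's marginal IBD
    mode (marginalizing an unobserved gene just drops its factor).
    """
    lookups = _freq_lookup(freqs, table.loci)
    i_idx, j_idx = pairs
    m = len(i_idx)
    n_loci = len(table.loci)
    e = float(error_rate)
    miss = table.missing_mask()
    p_dyad, _ = dyad_mode_likelihoods(table, freqs, error_rate, pairs=pairs)
    s_count = len(TRIO_STATES)
    out = np.zeros((m, n_loci, s_count))
    valid = np.zeros((m, n_loci), dtype=bool)
    c2_same = (1.0 - e) ** 2
    c2_err = e * (2.0 - e)
    c3_err = e * e * (3.0 - 2.0 * e)
    c3_two = (1.0 - e) ** 2 * e
    c3_all = (1.0 - e) ** 3
    for l in range(n_loci):
        lut = lookups[l]
        if not lut:
            continue
        max_allele = max(max(lut), int(table.alleles[:, l, :].max()))
        pvec = np.zeros(max_allele + 1)
        for a, f in lut.items():
            pvec[a] = f
        g = table.alleles[:, l, :]
        ok = ~miss[:, l]
        cell_ok = ok[i_idx] & ok[j_idx]
        valid[:, l] = cell_ok
        ref_ok = ok[refs]
        base = np.stack([g[i_idx, 0], g[i_idx, 1],
                         g[j_idx, 0], g[j_idx, 1],
                         g[refs, 0], g[refs, 1]])
        mult = ((base[0] != base[1]).astype(float) + 1.0) \
            * ((base[2] != base[3]) + 1.0) * ((base[4] != base[5]) + 1.0)
        acc = np.zeros((m, s_count))
        for oa, ob, oc in itertools.product((0, 1), repeat=3):
            sl = [base[0 + oa], base[1 - oa], base[2 + ob], base[3 - ob],
                  base[4 + oc], base[5 - oc]]
            sp = [pvec[v] for v in sl]
            pair_e: dict[tuple[int, int], np.ndarray] = {}
            for i in (0, 1):
                for j in (2, 3, 4, 5):
                    pair_e[(i, j)] = (c2_same * sp[i] * (sl[i] == sl[j])
                                      + c2_err * sp[i] * sp[j])
            for i in (2, 3):
                for j in (4, 5):
                    pair_e[(i, j)] = (c2_same * sp[i] * (sl[i] == sl[j])
                                      + c2_err * sp[i] * sp[j])
            trip_e: dict[tuple[int, int, int], np.ndarray] = {}
            for i in (0, 1):
                for j in (2, 3):
                    for k in (4, 5):
                        dij = sl[i] == sl[j]
                        dik = sl[i] == sl[k]
                        djk = sl[j] == sl[k]
                        trip_e[(i, j, k)] = (
                            c3_err * sp[i] * sp[j] * sp[k]
                            + c3_two * (dij * sp[i] * sp[k]
                                        + dik * sp[i] * sp[j]
                                        + djk * sp[j] * sp[i])
                            + c3_all * sp[i] * (dij & dik))
            for s, (blocks, _) in enumerate(TRIO_STATES):
                term = np.ones(m)
                for b in blocks:
                    if len(b) == 1:
                        term = term * sp[b[0]]
                    elif len(b) == 2:
                        term = term * pair_e[b]
                    else:
                        term = term * trip_e[b]
                acc[:, s] += term
        acc *= (mult / 8.0)[:, None]
        # reference unscored: marginal dyadic emission of the state's mode
        fb = ~ref_ok & cell_ok
        if fb.any():
            for s, (_, m_ab) in enumerate(TRIO_STATES):
                acc[fb, s] = p_dyad[fb, l, m_ab]
        out[:, l, :] = acc
    out[~valid] = 1.0
    return out, valid


def _em_simplex(p: np.ndarray, valid: np.ndarray, starts: np.ndarray,
                tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Maximize prod_l (k . P_l) over the simplex per dyad; returns k (m, 3).

    The log-likelihood is concave in k, so EM from any interior start
    converges to the global maximum; multiple starts guard the boundary.
    """
    m = p.shape[0]
    n_valid = np.maximum(valid.sum(axis=1), 1)[:, None]
    best_k = np.zeros((m, p.shape[2]))
    best_ll = np.full(m, -np.inf)
    for start in starts:
        k = np.tile(start, (m, 1)).astype(float)
        active = np.arange(m)
        for _ in range(max_iter):
            ka = k[active]
            pa = p[active]
            mix = np.maximum(np.einsum("mlc,mc->ml", pa, ka), 1e-300)
            resp = pa * ka[:, None, :] / mix[:, :, None]
            resp[~valid[active]] = 0.0
            k_new = resp.sum(axis=1) / n_valid[active]
            tot = k_new.sum(axis=1, keepdims=True)
            k_new = np.where(tot > 0, k_new / np.where(tot > 0, tot, 1.0), ka)
            delta = np.abs(k_new - ka).max(axis=1)
            k[active] = k_new
            active = active[delta >= tol]
            if active.size == 0:
                break
        ll = np.where(valid, np.log(np.maximum(
            np.einsum("mlc,mc->ml", p, k), 1e-300)), 0.0).sum(axis=1)
        better = ll > best_ll + 1e-12
        best_k[better] = k[better]
        best_ll[better] = ll[better]
    return best_k


def _simplex_starts(dim: int) -> np.ndarray:
    """Three deterministic EM starts: uniform plus the two extremes."""
    uniform = np.full(dim, 1.0 / dim)
    lo = np.full(dim, 0.1 / (dim - 1))
    lo[0] = 0.9  # all-singleton (unrelated) state is listed first
    hi = np.full(dim, 0.1 / (dim - 1))
    hi[-1] = 0.9
    return np.vstack([uniform, lo, hi])


def pairwise_relatedness(
    table: GenotypeTable,
    freqs: FrequencyTable | None = None,
    error_rate: float = 0.01,
    n_reference: int = 1,
    seed: int | None = None,
    estimator: str = "triadic",
    chunk_size: int = 20_000,
) -> RelatednessMatrix:
    """Maximum-likelihood pairwise relatedness for all dyads.

    ``"triadic"`` (default) and ``"dyadic"`` both compute the factorized
    triad maximum-likelihood estimate on the (k0, k1, k2) simplex (see
    module docstring); ``"joint-trio"`` maximizes over the full 16-state
    trio IBD space with ``n_reference`` reference individuals per dyad
    drawn uniformly at random (excluding the dyad, seeded), averaging the
    per-reference estimates.  Allele frequencies default to the full
    pooled sample (within-site frequencies are inflated by the very kin
    structure being estimated).  Dyads with zero overlapping scored loci
    get NaN.
    """
    n = table.n_individuals
    if n < 3:
        raise GenotypeTableError("need >= 3 individuals (a reference is needed)")
    if estimator not in ("triadic", "dyadic", "joint-trio"):
        raise ValueError("estimator must be 'triadic', 'dyadic' or 'joint-trio'")
    if freqs is None:
        freqs = allele_frequencies(table, "global")
    i_all, j_all = np.triu_indices(n, k=1)
    m_all = len(i_all)
    rng = np.random.default_rng(seed)
    r = np.full(m_all, np.nan)
    for lo in range(0, m_all, chunk_size):
        sl = slice(lo, min(lo + chunk_size, m_all))
        pairs = (i_all[sl], j_all[sl])
        m = len(pairs[0])
        if estimator == "joint-trio":
            r_acc = np.zeros(m)
            for _ in range(max(n_reference, 1)):
                # uniform reference excluding the dyad
                draw = rng.integers(0, n - 2, size=m)
                draw = draw + (draw >= np.minimum(pairs[0], pairs[1]))
                draw = draw + (draw >= np.maximum(pairs[0], pairs[1]))
                p, valid = trio_mode_likelihoods(table, freqs, error_rate,
                                                 pairs, draw.astype(np.int64))
                k = _em_simplex(p, valid, _simplex_starts(len(TRIO_STATES)))
                r_acc += k @ (TRIO_M_AB / 2.0)
            r_chunk = r_acc / max(n_reference, 1)
        else:
            p, valid = dyad_mode_likelihoods(table, freqs, error_rate, pairs=pairs)
            k = _em_simplex(p, valid, _simplex_starts(3))
            r_chunk = k[:, 2] + 0.5 * k[:, 1]
        overlap_chunk = valid.sum(axis=1) > 0
        r[sl] = np.where(overlap_chunk, r_chunk, np.nan)
    mat = np.full((n, n), np.nan)
    mat[i_all, j_all] = r
    mat[j_all, i_all] = r
    return RelatednessMatrix(
        ids=list(table.ids), values=mat,
        estimator="ml-triad" if estimator != "joint-trio" else "ml-joint-trio",
        error_rate=error_rate, n_reference=n_reference, seed=seed,
    )


def mean_group_relatedness(matrix: RelatednessMatrix, groups) -> pd.DataFrame:
    """Arithmetic mean r-bar and SE over within-group pairs, per group.

    ``groups`` maps ids to labels (dict or per-individual array).  Singleton
    groups get NaN.
    """
    labels = _group_labels(matrix.ids, groups)
    rows = []
    for g in dict.fromkeys(labels):
        idx = np.flatnonzero(np.asarray(labels, object) == g)
        if len(idx) < 2:
            rows.append((g, len(idx), np.nan, np.nan))
            continue
        vals = matrix.pair_values(idx)
        vals = vals[np.isfinite(vals)]
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append((g, len(idx), float(np.mean(vals)), se))
    return pd.DataFrame(rows, columns=["group", "n", "r_mean", "se"]).set_index("group")


def _group_labels(ids: list[str], groups) -> list:
    if isinstance(groups, dict):
        missing = [i for i in ids if i not in groups]
        if missing:
            raise GenotypeTableError(f"no group for individuals {missing}")
        return [groups[i] for i in ids]
    labels = list(groups)
    if len(labels) != len(ids):
        raise GenotypeTableError("group labels must match the number of individuals")
    return labels


def relatedness_permutation_test(
    matrix: RelatednessMatrix,
    groups,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-tailed permutation test of elevated within-group mean relatedness.

    Individuals (whole genotype rows) are permuted among groups preserving
    group sizes; since a permutation only relabels group membership, the
    precomputed pairwise matrix is reused and group means are recomputed
    per replicate.  Returns, per group: observed r-bar, add-one upper-tail
    p, and the 2.5/97.5 percentile null envelope.
    """
    labels = np.asarray(_group_labels(matrix.ids, groups), object)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise GenotypeTableError("need >= 2 groups to permute among")
    rng = np.random.default_rng(seed)
    obs = {g: _group_mean(matrix, labels, g) for g in uniq}
    null = {g: np.empty(n_perm) for g in uniq}
    for b in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        for g in uniq:
            null[g][b] = _group_mean(matrix, perm, g)
    rows = []
    for g in uniq:
        sims = null[g][np.isfinite(null[g])]
        if np.isnan(obs[g]) or len(sims) == 0:
            rows.append((g, obs[g], np.nan, np.nan, np.nan))
            continue
        p = (int((sims >= obs[g] - 1e-12).sum()) + 1) / (len(sims) + 1)
        lo, hi = np.percentile(sims, [2.5, 97.5])
        rows.append((g, obs[g], p, lo, hi))
    return pd.DataFrame(
        rows, columns=["group", "r_mean", "p_value", "null_lo", "null_hi"]
    ).set_index("group")


def _group_mean(matrix: RelatednessMatrix, labels: np.ndarray, g) -> float:
    idx = np.flatnonzero(labels == g)
    if len(idx) < 2:
        return np.nan
    vals = matrix.pair_values(idx)
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if len(vals) else np.nan
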