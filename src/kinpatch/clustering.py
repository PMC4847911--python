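"""Within-site genetic clustering in the DAPC framework.

Genotypes are one-hot encoded as allele dosage counts (0/1/2 per observed
allele per locus), missing genotypes imputed by the per-locus mean dosage,
the centered matrix projected onto principal components, and k-means run
over a range of candidate k.  The number of clusters is chosen by minimum

    BIC(k) = n * ln(W_k / n) + k * ln(n)

with W_k the total within-cluster sum of squares.  Discriminant axes for
plotting come from an LDA of the retained PCs on the selected labels
(at most k - 1 axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotype import GenotypeTable, GenotypeTableError

__all__ = ["ClusterAssignment", "allele_dosage_matrix", "find_clusters",
           "discriminant_projection"]


@dataclass
class ClusterAssignment:
    """K-means/BIC clustering solution for one site."""

    site: str
    ids: list[str]
    labels: np.ndarray            # cluster id per individual, 0-based
    bic: dict[int, float]         # candidate k -> BIC
    selected_k: int
    n_pcs: int
    wss: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.selected_k == min(self.bic, key=self.bic.get)
        assert len(np.unique(self.labels)) == self.selected_k

    def cluster_members(self) -> dict[int, list[str]]:
        return {int(c): [self.ids[i] for i in np.flatnonzero(self.labels == c)]
                for c in np.unique(self.labels)}


def allele_dosage_matrix(table: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Centered allele-dosage matrix with mean imputation for missing cells.

    Columns are (locus, allele) pairs; a scored genotype contributes dosage
    0/1/2 per allele, a missing genotype the locus mean dosage.
    """
    miss = table.missing_mask()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for j, locus in enumerate(table.loci):
        ok = ~miss[:, j]
        if not ok.any():
            continue
        alleles = np.unique(table.alleles[ok, j, :])
        for a in alleles:
            d = (table.alleles[:, j, :] == a).sum(axis=1).astype(float)
            mean = d[ok].mean()
            d[~ok] = mean
            cols.append(d)
            names.append(f"{locus}.{int(a)}")
    x = np.column_stack(cols)
    return x - x.mean(axis=0), names


def find_clusters(
    site_table: GenotypeTable,
    max_k: int = 10,
    n_pcs: int | None = None,
    n_starts: int = 50,
    seed: int | None = None,
    scale: bool = False,
    site: str | None = None,
) -> ClusterAssignment:
    """K-means over k = 1..max_k on the PCA-projected dosage matrix,
    selecting k by minimum BIC.

    ``n_pcs`` defaults to all components with positive variance; k-means
    uses ``n_starts`` restarts per k.  ``max_k`` is lowered to the number
    of individuals when the site is small.
    """
    n = site_table.n_individuals
    if n < 2:
        raise GenotypeTableError("need >= 2 individuals to cluster")
    x, _ = allele_dosage_matrix(site_table)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    pca = PCA(random_state=seed)
    scores = pca.fit_transform(x)
    positive = pca.explained_variance_ > 1e-12
    keep = int(positive.sum()) if n_pcs is None else min(n_pcs, int(positive.sum()))
    keep = max(keep, 1)
    scores = scores[:, :keep]
    max_k = min(max_k, n)
    bic: dict[int, float] = {}
    wss: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for k in range(1, max_k + 1):
        if k == 1:
            w = float(((scores - scores.mean(axis=0)) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts,
                        random_state=int(rng.integers(2**31)))
            lab = km.fit_predict(scores)
            w = float(km.inertia_)
        w = max(w, 1e-12)
        bic[k] = n * np.log(w / n) + k * np.log(n)
        wss[k] = w
        labels_by_k[k] = lab
    k_sel = min(bic, key=bic.get)
    return ClusterAssignment(
        site=site if site is not None else (site_table.site_labels[0] if site_table.site_labels else ""),
        ids=list(site_table.ids),
        labels=labels_by_k[k_sel],
        bic=bic,
        selected_k=k_sel,
        n_pcs=keep,
        wss=wss,
    )


def discriminant_projection(
    site_table: GenotypeTable,
    assignment: ClusterAssignment,
    n_pcs: int | None = None,
    seed: int | None = None,
) -> dict:
    """LDA projection of the retained PCs onto <= k-1 discriminant axes.

    Returns per-individual coordinates plus 67%-inertia ellipse parameters
    per cluster (center, axis half-lengths, orientation) for the first two
    axes; with k = 2 there is a single axis and the ellipse degenerates to
    a 1-D interval (density-plot data).
    """
    k = assignment.selected_k
    if k < 2:
        raise GenotypeTableError("discriminant axes undefined for k = 1")
    x, _ = allele_dosage_matrix(site_table)
    pca = PCA(random_state=seed)
    scores = pca.fit_transform(x)
    positive = pca.explained_variance_ > 1e-12
    keep = int(positive.sum()) if n_pcs is None else min(n_pcs, int(positive.sum()))
    scores = scores[:, :max(keep, 1)]
    lda = LinearDiscriminantAnalysis(n_components=min(k - 1, scores.shape[1]))
    coords = lda.fit_transform(scores, assignment.labels)
    ellipses = {}
    # chi-square quantile scales the covariance ellipse to 67% inertia
    q = chi2.ppf(0.67, df=min(2, coords.shape[1]))
    for c in np.unique(assignment.labels):
        pts = coords[assignment.labels == c][:, :2]
        center = pts.mean(axis=0)
        if pts.shape[0] > 1 and pts.shape[1] == 2:
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
            half = np.sqrt(np.maximum(evals, 0) * q)
            angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        else:
            sd = pts.std(ddof=1) if pts.shape[0] > 1 else 0.0
            half = np.array([np.sqrt(max(sd, 0) ** 2 * q)])
            angle = 0.0
        ellipses[int(c)] = {"center": center, "half_axes": half, "angle_deg": angle}
    return {
        "ids": list(site_table.ids),
        "labels": assignment.labels.copy(),
        "coordinates": coords,
        "n_axes": coords.shape[1],
        "ellipses": ellipses,
    }
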