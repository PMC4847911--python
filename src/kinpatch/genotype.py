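"""Data model and I/O for multilocus codominant genotype tables.

Genotypes are unordered pairs of positive-integer allele sizes (microsatellite
fragment lengths).  A missing genotype is whole-locus: both alleles absent,
stored as (0, 0).  Allele pairs are stored canonically sorted so genotype
equality is independent of the order alleles appear in the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeTable",
    "FrequencyTable",
    "LocusSummary",
    "GenotypeTableError",
    "read_genotype_table",
    "write_genotype_table",
    "read_coordinates",
    "allele_frequencies",
    "locus_summary",
]


class GenotypeTableError(ValueError):
    """Raised on malformed genotype input (bad rows, odd columns, codes)."""


@dataclass
class GenotypeTable:
    """Individuals x loci table of unordered diploid allele pairs.

    Attributes
    ----------
    ids : list of str
        Unique individual identifiers.
    sites : ndarray of str, shape (n,)
        Site label per individual.
    loci : list of str
        Ordered locus names.
    alleles : ndarray of int, shape (n, L, 2)
        Allele sizes, pair sorted ascending; (0, 0) marks a missing genotype.
    coords : dict, optional
        site -> (lat, lon) in decimal degrees (WGS84).
    """

    ids: list[str]
    sites: np.ndarray
    loci: list[str]
    alleles: np.ndarray
    coords: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, loc, two = self.alleles.shape
        if two != 2 or n != len(self.ids) or loc != len(self.loci):
            raise GenotypeTableError("allele array shape inconsistent with ids/loci")
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids)
            raise GenotypeTableError(
                f"duplicate individual ids: {sorted(dupes[dupes.duplicated()])}"
            )
        if (self.alleles < 0).any():
            raise GenotypeTableError("allele sizes must be positive (0 = missing)")
        # half-missing genotypes (one allele scored) are not supported: demote
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-missing genotype(s) treated as missing",
                stacklevel=2,
            )
            self.alleles[half] = MISSING
        self.alleles = np.sort(self.alleles, axis=2)
        if n and (~self.missing_mask()).sum(axis=1).min() < 1:
            bad = [self.ids[i] for i in np.flatnonzero((~self.missing_mask()).sum(axis=1) < 1)]
            raise GenotypeTableError(f"individuals with no scored loci: {bad}")

    # -- basic queries -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def site_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the genotype is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise GenotypeTableError(f"unknown locus {locus!r}") from None

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        """Sub-table for a boolean mask or integer index array."""
        arr = np.asarray(mask)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return GenotypeTable(
            ids=[self.ids[i] for i in idx],
            sites=self.sites[idx],
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
            coords=self.coords,
        )

    def site_table(self, site: str) -> "GenotypeTable":
        if site not in set(self.sites):
            raise GenotypeTableError(f"unknown site {site!r}")
        return self.subset(self.sites == site)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"id": self.ids, "site": list(self.sites)}
        for j, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.alleles[:, j, 0]
            data[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(data)


@dataclass
class FrequencyTable:
    """Per group x locus allele frequencies from non-missing genotypes.

    ``freqs[(group, locus)]`` maps allele -> frequency (zero-frequency
    alleles absent); ``n[(group, locus)]`` is the count of non-missing
    genotypes (gene copies = 2n).  Group ``"__all__"`` denotes the pooled
    sample under global grouping.
    """

    grouping: str
    groups: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n: dict[tuple[str, str], int]
    empty: list[tuple[str, str]] = field(default_factory=list)

    GLOBAL = "__all__"

    def group_freqs(self, group: str, locus: str) -> dict[int, float]:
        return self.freqs[(group, locus)]

    def pooled(self, locus: str) -> dict[int, float]:
        """Frequencies for a locus pooled over all groups (gene-copy weighted)."""
        counts: dict[int, float] = {}
        total = 0.0
        for g in self.groups:
            key = (g, locus)
            if key not in self.freqs:
                continue
            w = 2.0 * self.n[key]
            total += w
            for a, f in self.freqs[key].items():
                counts[a] = counts.get(a, 0.0) + f * w
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}


@dataclass
class LocusSummary:
    """Summary statistics for one locus (richness, Ho, He, missingness)."""

    locus: str
    richness: int
    ho: float
    he: float
    missing: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.ho <= 1.0 and 0.0 <= self.he <= 1.0
        assert 0.0 <= self.missing <= 1.0 and self.richness >= 0


# -- readers / writers -----------------------------------------------------

def _parse_allele(token: str, missing_codes: frozenset) -> int:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "NAN"}:
        return MISSING
    try:
        value = int(float(token))
    except ValueError:
        raise GenotypeTableError(f"unparseable allele code {token!r}") from None
    if value in missing_codes:
        return MISSING
    if value <= 0:
        raise GenotypeTableError(f"unknown missing code {value} (declare it in missing_codes)")
    return value


def read_genotype_table(
    path: str | Path,
    dialect: str = "csv",
    missing_codes: Iterable[int] = (0,),
    coordinates: str | Path | None = None,
    min_loci: int = 1,
) -> GenotypeTable:
    """Read a genotype table from CSV or Genepop.

    CSV layout: header with ``id``, ``site``, then either two columns per
    locus (``<locus>_1``, ``<locus>_2``) or one ``a/b`` column per locus.
    Genepop layout: title line, locus names, POP blocks with 3-digit allele
    codes ("000" = missing).

    Individuals with fewer than ``min_loci`` scored loci are rejected with a
    warning listing their ids.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeTableError(f"no such file: {path}")
    codes = frozenset(int(c) for c in missing_codes) | {MISSING}
    if dialect == "csv":
        table = _read_csv(path, codes, min_loci)
    elif dialect == "genepop":
        table = _read_genepop(path, min_loci)
    else:
        raise GenotypeTableError(f"unknown dialect {dialect!r}")
    if coordinates is not None:
        table.coords = read_coordinates(coordinates)
        missing_sites = set(table.sites) - set(table.coords)
        if missing_sites:
            raise GenotypeTableError(f"no coordinates for sites: {sorted(missing_sites)}")
    return table


def _finalize(ids, sites, loci, rows, min_loci) -> GenotypeTable:
    alleles = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    scored = ((alleles != MISSING).any(axis=2)).sum(axis=1)
    keep = scored >= max(min_loci, 1)
    if not keep.all():
        rejected = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"rejected {len(rejected)} individual(s) with < {min_loci} scored loci: "
            f"{rejected}",
            stacklevel=3,
        )
    if not keep.any():
        raise GenotypeTableError("no individuals with sufficient scored loci")
    idx = np.flatnonzero(keep)
    return GenotypeTable(
        ids=[ids[i] for i in idx],
        sites=np.asarray(sites, dtype=object)[idx],
        loci=loci,
        alleles=alleles[idx],
    )


def _read_csv(path: Path, codes: frozenset, min_loci: int) -> GenotypeTable:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GenotypeTableError(f"empty file: {path}") from None
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    lower = [c.lower() for c in cols]
    if "id" not in lower or "site" not in lower:
        raise GenotypeTableError("CSV header must name 'id' and 'site' columns")
    id_col = cols[lower.index("id")]
    site_col = cols[lower.index("site")]
    locus_cols = [c for c in cols if c not in (id_col, site_col)]
    paired = all(c.endswith(("_1", "_2")) for c in locus_cols)
    loci: list[str] = []
    rows: list[list[int]] = []
    if paired:
        stems: dict[str, None] = {}
        for c in locus_cols:
            stems.setdefault(c[:-2], None)
        loci = list(stems)
        for locus in loci:
            if f"{locus}_1" not in cols or f"{locus}_2" not in cols:
                raise GenotypeTableError(f"odd allele column count for locus {locus!r}")
        bad_rows: list[int] = []
        for i, row in df.iterrows():
            vals: list[int] = []
            try:
                for locus in loci:
                    vals.append(_parse_allele(row[f"{locus}_1"], codes))
                    vals.append(_parse_allele(row[f"{locus}_2"], codes))
            except GenotypeTableError:
                bad_rows.append(i + 2)  # 1-based, plus header
                vals = []
            rows.append(vals or [MISSING] * (2 * len(loci)))
        if bad_rows:
            raise GenotypeTableError(f"unparseable rows (1-based line numbers): {bad_rows}")
    else:
        loci = locus_cols
        bad_rows = []
        for i, row in df.iterrows():
            vals = []
            try:
                for locus in loci:
                    parts = str(row[locus]).split("/")
                    if len(parts) != 2:
                        raise GenotypeTableError("expected 'a/b' genotype")
                    vals.extend(_parse_allele(p, codes) for p in parts)
            except GenotypeTableError:
                bad_rows.append(i + 2)
                vals = []
            rows.append(vals or [MISSING] * (2 * len(loci)))
        if bad_rows:
            raise GenotypeTableError(f"unparseable rows (1-based line numbers): {bad_rows}")
    ids = [str(v) for v in df[id_col]]
    sites = [str(v) for v in df[site_col]]
    return _finalize(ids, sites, loci, rows, min_loci)


def _read_genepop(path: Path, min_loci: int) -> GenotypeTable:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise GenotypeTableError(f"truncated Genepop file: {path}")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if i == len(body):
        raise GenotypeTableError("no POP block found")
    ids: list[str] = []
    sites: list[str] = []
    rows: list[list[int]] = []
    pop = 0
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            pop += 1
            continue
        if "," not in ln:
            raise GenotypeTableError(f"malformed Genepop line: {ln!r}")
        name, geno = ln.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeTableError(
                f"{name.strip()!r}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        vals: list[int] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeTableError(f"bad Genepop genotype code {tok!r}")
            w = len(tok) // 2
            vals.extend((int(tok[:w]), int(tok[w:])))
        ids.append(name.strip())
        sites.append(f"POP{pop}")
        rows.append(vals)
    return _finalize(ids, sites, loci, rows, min_loci)


def write_genotype_table(table: GenotypeTable, path: str | Path, dialect: str = "csv") -> None:
    """Canonical writer; inverse of :func:`read_genotype_table` for both dialects."""
    path = Path(path)
    if dialect == "csv":
        table.to_frame().to_csv(path, index=False)
    elif dialect == "genepop":
        out = ["kinpatch export"]
        out.extend(table.loci)
        for site in table.site_labels:
            out.append("POP")
            sub = table.site_table(site)
            for i, ind in enumerate(sub.ids):
                codes = "".join(
                    f" {a:03d}{b:03d}" for a, b in sub.alleles[i]
                )
                out.append(f"{ind},{codes}")
        path.write_text("\n".join(out) + "\n")
    else:
        raise GenotypeTableError(f"unknown dialect {dialect!r}")


def read_coordinates(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a site coordinates CSV (columns site, lat, lon; decimal degrees)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("site", "lat", "lon"):
        if col not in df.columns:
            raise GenotypeTableError(f"coordinates file missing column {col!r}")
    coords = {}
    for _, row in df.iterrows():
        lat, lon = float(row["lat"]), float(row["lon"])
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise GenotypeTableError(f"coordinates out of range for site {row['site']!r}")
        coords[str(row["site"])] = (lat, lon)
    return coords


# -- summary statistics ----------------------------------------------------

def _resolve_groups(table: GenotypeTable, grouping) -> tuple[str, np.ndarray]:
    """Return (grouping name, per-individual group label array)."""
    if isinstance(grouping, str):
        if grouping == "global":
            return "global", np.asarray([FrequencyTable.GLOBAL] * table.n_individuals, dtype=object)
        if grouping == "site":
            return "site", table.sites
        raise GenotypeTableError(f"unknown grouping {grouping!r}")
    labels = np.asarray(grouping, dtype=object)
    if labels.shape != (table.n_individuals,):
        raise GenotypeTableError("grouping labels must match the number of individuals")
    return "custom", labels


def allele_frequencies(table: GenotypeTable, grouping="global") -> FrequencyTable:
    """Allele frequencies per group x locus from non-missing genotypes.

    ``grouping`` is ``"global"``, ``"site"``, or an explicit per-individual
    label array (e.g. cluster ids).  Gene copies counted = 2 x non-missing
    genotypes.  Group x locus cells with zero scored genotypes are recorded
    in ``FrequencyTable.empty``.
    """
    if table.n_individuals == 0:
        raise GenotypeTableError("empty genotype table")
    name, labels = _resolve_groups(table, grouping)
    groups: list[str] = []
    for g in labels:
        if g not in groups:
            groups.append(g)
    missing = table.missing_mask()
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    ns: dict[tuple[str, str], int] = {}
    empty: list[tuple[str, str]] = []
    for g in groups:
        sel = labels == g
        for j, locus in enumerate(table.loci):
            ok = sel & ~missing[:, j]
            n = int(ok.sum())
            if n == 0:
                empty.append((g, locus))
                continue
            copies = table.alleles[ok, j, :].ravel()
            values, counts = np.unique(copies, return_counts=True)
            freqs[(g, locus)] = {int(a): c / (2.0 * n) for a, c in zip(values, counts)}
            ns[(g, locus)] = n
    return FrequencyTable(grouping=name, groups=groups, loci=list(table.loci),
                          freqs=freqs, n=ns, empty=empty)


def expected_heterozygosity(freqs: Mapping[int, float], n: int | None = None,
                            unbiased: bool = False) -> float:
    """Gene diversity He = 1 - sum p^2; optional small-sample correction.

    The unbiased form multiplies by 2n/(2n-1) (n = genotype count) and
    requires ``n``.
    """
    he = 1.0 - sum(f * f for f in freqs.values())
    if unbiased:
        if n is None or n < 1:
            raise GenotypeTableError("unbiased He needs the genotype sample size")
        if 2 * n > 1:
            he *= (2.0 * n) / (2.0 * n - 1.0)
    return min(max(he, 0.0), 1.0)


def locus_summary(
    table: GenotypeTable,
    locus: str,
    grouping: str = "global",
    unbiased_he: bool = False,
) -> LocusSummary | dict[str, LocusSummary]:
    """Richness, Ho, He and missingness for one locus.

    Under ``grouping="global"`` (the default, matching a one-row-per-locus
    summary table pooled across sites) a single :class:`LocusSummary` is
    returned; under ``"site"`` a dict keyed by site.
    """
    j = table.locus_index(locus)
    name, labels = _resolve_groups(table, grouping)
    out: dict[str, LocusSummary] = {}
    groups = [FrequencyTable.GLOBAL] if name == "global" else list(dict.fromkeys(labels))
    missing = table.missing_mask()[:, j]
    for g in groups:
        sel = np.ones(table.n_individuals, bool) if name == "global" else labels == g
        ok = sel & ~missing
        n = int(ok.sum())
        if n == 0:
            out[g] = LocusSummary(locus, 0, 0.0, 0.0, 1.0)
            continue
        pairs = table.alleles[ok, j, :]
        values = np.unique(pairs)
        ho = float((pairs[:, 0] != pairs[:, 1]).mean())
        p = {int(a): c / (2.0 * n) for a, c in
             zip(*np.unique(pairs.ravel(), return_counts=True))}
        he = expected_heterozygosity(p, n=n, unbiased=unbiased_he)
        out[g] = LocusSummary(
            locus=locus,
            richness=int(len(values)),
            ho=ho,
            he=he,
            missing=float((sel & missing).sum() / sel.sum()),
        )
    return out[FrequencyTable.GLOBAL] if name == "global" else out
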