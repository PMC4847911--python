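"""End-to-end orchestration of the kin-aggregation analysis.

Stages run in the analysis order HWE -> differentiation -> relatedness ->
clustering -> sibship -> networks, each with its own sub-seed derived from
the global seed by a fixed counter scheme (``SeedSequence(seed).spawn``
consumed in stage order), so any stage can be rerun independently and
deterministically.  All tabular outputs are plain CSV prefixed with a
schema-version comment line; the machine-readable summary is versioned
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clu
from . import differentiation as diff
from . import hwe as hwe_mod
from . import networks as net
from . import relatedness as rel
from . import sibship as sib
from .genotype import allele_frequencies, locus_summary, read_genotype_table
from .simulate import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineStageError", "run_full_analysis", "make_report"]

SCHEMA_VERSION = 1
STAGES = ("input", "hwe", "differentiation", "clustering", "relatedness",
          "sibship", "networks")

log = logging.getLogger("kinpatch")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, per-stage parameters and toggles for a full run."""

    seed: int
    out_dir: str | Path = "kinpatch_out"
    input_path: str | Path | None = None
    coords_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    stages: tuple[str, ...] = STAGES[1:]
    n_mc_hwe: int = 100_000
    n_perm_diff: int = 10_000
    n_perm_rel: int = 1000
    n_perm_sib: int = 10_000
    n_perm_fis: int = 10_000
    n_sim_net: int = 10_000
    n_mc_exclusion: int = 100_000
    error_rate: float = 0.01
    sib_threshold: float = 0.95
    max_k: int = 10
    kmeans_starts: int = 50
    fst_estimator: str = "weir_cockerham"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31))
            for stage, c in zip(STAGES, children)}


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kinpatch schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index)


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every enabled stage and write the report bundle to ``out_dir``.

    Returns the in-memory bundle: per-stage result objects plus the
    summary dict that is also written as ``summary.json``.  A stage
    failure aborts with the stage name; outputs written so far stay on
    disk next to an ``INCOMPLETE`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    seeds = _stage_seeds(config.seed)
    bundle: dict = {"config": config, "seeds": seeds}
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                     "stage_seeds": seeds}
    run_log = [f"kinpatch run, global seed {config.seed}"]
    try:
        table = _stage_input(config, seeds, bundle, summary, out, run_log)
        groups_cluster = None
        if "hwe" in config.stages:
            _stage_hwe(config, seeds, table, bundle, summary, out, run_log)
        if "differentiation" in config.stages:
            _stage_diff(config, seeds, table, bundle, summary, out, run_log)
        if "clustering" in config.stages:
            groups_cluster = _stage_cluster(config, seeds, table, bundle, summary, out, run_log)
        if "relatedness" in config.stages:
            _stage_rel(config, seeds, table, groups_cluster, bundle, summary, out, run_log)
        if "sibship" in config.stages:
            _stage_sib(config, seeds, table, groups_cluster, bundle, summary, out, run_log)
        if "networks" in config.stages:
            _stage_net(config, seeds, bundle, summary, out, run_log)
    except PipelineStageError:
        (out / "run.log").write_text("\n".join(run_log) + "\n")
        raise
    except Exception as exc:  # pragma: no cover - defensive
        (out / "run.log").write_text("\n".join(run_log) + "\n")
        raise PipelineStageError("unknown", exc) from exc
    bundle["summary"] = summary
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    (out / "run.log").write_text("\n".join(run_log) + "\n")
    marker.unlink(missing_ok=True)
    return bundle


def _guard(stage):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
        return wrapped
    return deco


@_guard("input")
def _stage_input(config, seeds, bundle, summary, out, run_log):
    if config.input_path is not None:
        table = read_genotype_table(config.input_path, dialect="csv",
                                    coordinates=config.coords_path)
        run_log.append(f"input: read {config.input_path}")
    else:
        sim = config.simulation or SimulationConfig(seed=seeds["input"])
        table, truth = simulate_study(sim)
        bundle["truth"] = truth
        run_log.append(f"input: simulated with seed {sim.seed}")
    bundle["table"] = table
    summary["n_individuals"] = table.n_individuals
    summary["n_sites"] = len(table.site_labels)
    summary["n_loci"] = len(table.loci)
    rows = []
    for locus in table.loci:
        s = locus_summary(table, locus)
        rows.append((locus, s.richness, s.ho, s.he, s.missing))
    t1 = pd.DataFrame(rows, columns=["locus", "richness", "Ho", "He", "missing"])
    _write_csv(t1, out / "locus_summary.csv", index=False)
    bundle["locus_summary"] = t1
    return table


@_guard("hwe")
def _stage_hwe(config, seeds, table, bundle, summary, out, run_log):
    seed = seeds["hwe"]
    grid_exact = hwe_mod.hwe_grid(table, n_mc=config.n_mc_hwe, seed=seed, test="exact")
    grid_excess = hwe_mod.hwe_grid(table, n_mc=config.n_mc_hwe, seed=seed + 1,
                                   test="excess")
    _write_csv(grid_exact, out / "hwe_exact_grid.csv")
    _write_csv(grid_excess, out / "homozygote_excess_grid.csv")
    fis_rows = {}
    ss = np.random.SeedSequence(seed + 2)
    for site in table.site_labels:
        fis_rows[site] = {}
        for locus in table.loci:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            fis = hwe_mod.inbreeding_coefficient(table, site, locus)
            if np.isfinite(fis):
                t = hwe_mod.fis_permutation_test(table, site, locus,
                                                n_perm=config.n_perm_fis, seed=sub_seed)
                fis_rows[site][locus] = fis
                fis_rows[site][f"{locus}_p"] = t.p_value
            else:
                fis_rows[site][locus] = np.nan
                fis_rows[site][f"{locus}_p"] = np.nan
    t2 = pd.DataFrame(fis_rows).T
    _write_csv(t2, out / "fis_by_site.csv")
    reg, pts = hwe_mod.missingness_heterozygosity_regression(table)
    _write_csv(pts, out / "missingness_regression_points.csv", index=False)
    bundle["hwe"] = {"exact": grid_exact, "excess": grid_excess, "fis": t2,
                     "regression": reg}
    summary["hwe_exact_significant_frac"] = float((grid_exact < 0.05).to_numpy().mean())
    summary["homozygote_excess_significant_frac"] = float((grid_excess < 0.05).to_numpy().mean())
    summary["missingness_regression"] = {
        "F": reg.f_statistic, "df": [reg.df_num, reg.df_den], "p": reg.p_value,
        "slope": reg.slope,
    }
    run_log.append(f"hwe: seed {seed}, n_mc {config.n_mc_hwe}")


@_guard("differentiation")
def _stage_diff(config, seeds, table, bundle, summary, out, run_log):
    seed = seeds["differentiation"]
    pd_m = diff.pairwise_pd(table)
    fst_m = diff.pairwise_fst(table, estimator=config.fst_estimator)
    sig_fst = diff.differentiation_significance(
        table, "fst", estimator=config.fst_estimator,
        n_perm=config.n_perm_diff, seed=seed)
    sig_pd = diff.differentiation_significance(
        table, "pd", n_perm=config.n_perm_diff, seed=seed + 1)
    # combined matrix: P_D above the diagonal, F_ST below
    sites = pd_m.index
    t3 = pd.DataFrame(np.nan, index=sites, columns=sites)
    for i, a in enumerate(sites):
        for j, b in enumerate(sites):
            if i < j:
                t3.loc[a, b] = pd_m.loc[a, b]
            elif i > j:
                t3.loc[a, b] = fst_m.loc[a, b]
    _write_csv(t3, out / "pd_fst_matrix.csv")
    _write_csv(sig_fst["p_adjusted"], out / "fst_p_adjusted.csv")
    _write_csv(sig_pd["p_adjusted"], out / "pd_p_adjusted.csv")
    bundle["differentiation"] = {"pd": pd_m, "fst": fst_m,
                                 "sig_fst": sig_fst, "sig_pd": sig_pd}
    tri = np.triu_indices(len(sites), k=1)
    summary["fst_significant_frac"] = float(
        (sig_fst["p_adjusted"].to_numpy()[tri] < 0.05).mean())
    summary["pd_significant_frac"] = float(
        (sig_pd["p_adjusted"].to_numpy()[tri] < 0.05).mean())
    if table.coords and len(sites) >= 3:
        geo = diff.great_circle_distances(
            {s: table.coords[s] for s in sites})
        mantel_pd = diff.mantel_test(pd_m, geo, n_perm=config.n_perm_diff, seed=seed + 2)
        mantel_fst = diff.mantel_test(fst_m, geo, n_perm=config.n_perm_diff, seed=seed + 3)
        _write_csv(geo, out / "geographic_km.csv")
        bundle["differentiation"]["geo"] = geo
        bundle["differentiation"]["mantel"] = {"pd": mantel_pd, "fst": mantel_fst}
        summary["mantel"] = {
            "pd": {"r": mantel_pd.statistic, "p": mantel_pd.p_value},
            "fst": {"r": mantel_fst.statistic, "p": mantel_fst.p_value},
        }
    run_log.append(f"differentiation: seed {seed}, n_perm {config.n_perm_diff}")


@_guard("clustering")
def _stage_cluster(config, seeds, table, bundle, summary, out, run_log):
    seed = seeds["clustering"]
    assignments = {}
    bic_rows = []
    member_rows = []
    ss = np.random.SeedSequence(seed)
    for site in table.site_labels:
        sub = table.site_table(site)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        a = clu.find_clusters(sub, max_k=config.max_k,
                              n_starts=config.kmeans_starts, seed=sub_seed,
                              site=site)
        assignments[site] = a
        for k, b in a.bic.items():
            bic_rows.append((site, k, b, k == a.selected_k))
        for ind, lab in zip(a.ids, a.labels):
            member_rows.append((ind, site, f"{site}-G{lab + 1}"))
    bic_df = pd.DataFrame(bic_rows, columns=["site", "k", "bic", "selected"])
    members = pd.DataFrame(member_rows, columns=["id", "site", "cluster"])
    _write_csv(bic_df, out / "bic_curves.csv", index=False)
    _write_csv(members, out / "cluster_assignments.csv", index=False)
    bundle["clustering"] = {"assignments": assignments, "members": members}
    summary["selected_k"] = {s: a.selected_k for s, a in assignments.items()}
    summary["cluster_sizes"] = {
        s: np.bincount(a.labels).tolist() for s, a in assignments.items()}
    run_log.append(f"clustering: seed {seed}, max_k {config.max_k}")
    return dict(zip(members["id"], members["cluster"]))


@_guard("relatedness")
def _stage_rel(config, seeds, table, groups_cluster, bundle, summary, out, run_log):
    seed = seeds["relatedness"]
    freqs = allele_frequencies(table, "global")
    matrix = rel.pairwise_relatedness(table, freqs, error_rate=config.error_rate,
                                      seed=seed)
    _write_csv(matrix.to_long(), out / "relatedness_long.csv", index=False)
    site_groups = {i: s for i, s in zip(table.ids, table.sites)}
    site_means = rel.mean_group_relatedness(matrix, site_groups)
    site_perm = rel.relatedness_permutation_test(matrix, site_groups,
                                                n_perm=config.n_perm_rel, seed=seed + 1)
    out_frames = {"site": site_perm.join(site_means[["n", "se"]])}
    if groups_cluster is not None:
        cl_means = rel.mean_group_relatedness(matrix, groups_cluster)
        cl_perm = rel.relatedness_permutation_test(matrix, groups_cluster,
                                                   n_perm=config.n_perm_rel,
                                                   seed=seed + 2)
        out_frames["cluster"] = cl_perm.join(cl_means[["n", "se"]])
    for level, frame in out_frames.items():
        _write_csv(frame, out / f"group_relatedness_{level}.csv")
    bundle["relatedness"] = {"matrix": matrix, **out_frames}
    summary["site_r"] = {
        g: {"r": row["r_mean"], "p": row["p_value"]}
        for g, row in out_frames["site"].iterrows()}
    if "cluster" in out_frames:
        cl = out_frames["cluster"]
        summary["cluster_r_significant_frac"] = float((cl["p_value"] < 0.05).mean())
    run_log.append(f"relatedness: seed {seed}, n_perm {config.n_perm_rel}")


@_guard("sibship")
def _stage_sib(config, seeds, table, groups_cluster, bundle, summary, out, run_log):
    seed = seeds["sibship"]
    freqs = allele_frequencies(table, "global")
    dyads = sib.classify_dyads(table, freqs, error_rate=config.error_rate,
                               threshold=config.sib_threshold)
    _write_csv(dyads.table, out / "sib_dyads.csv", index=False)
    excl = sib.exclusion_probability(freqs, n_mc=config.n_mc_exclusion, seed=seed)
    summary["exclusion_probability_all_loci"] = excl.probability
    bundle["sibship"] = {"dyads": dyads, "exclusion": excl}
    if groups_cluster is not None:
        perm = sib.sib_count_permutation(dyads, groups_cluster,
                                         n_perm=config.n_perm_sib, seed=seed + 1)
        _write_csv(perm, out / "sib_counts_per_cluster.csv")
        bundle["sibship"]["cluster_counts"] = perm
        # proportion of sib dyads among within-cluster dyads
        props = []
        members = pd.Series(groups_cluster)
        for g, row in perm.iterrows():
            n_g = int((members == g).sum())
            possible = n_g * (n_g - 1) // 2
            if possible:
                props.append(row["sib_dyads"] / possible)
        if props:
            summary["sib_proportion_mean"] = float(np.mean(props))
            summary["sib_proportion_sd"] = float(np.std(props, ddof=1)) if len(props) > 1 else 0.0
    run_log.append(f"sibship: seed {seed}, threshold {config.sib_threshold}")


@_guard("networks")
def _stage_net(config, seeds, bundle, summary, out, run_log):
    seed = seeds["networks"]
    if "sibship" not in bundle or "clustering" not in bundle:
        raise RuntimeError("networks stage needs sibship and clustering outputs")
    dyads = bundle["sibship"]["dyads"]
    members = bundle["clustering"]["members"]
    rows = []
    ss = np.random.SeedSequence(seed)
    trans_values = []
    for cluster, grp in members.groupby("cluster", sort=True):
        ids = list(grp["id"])
        g = net.build_sib_graph(ids, dyads)
        if g.number_of_nodes() < 3:
            continue
        t_mean, t_sd = net.mean_local_transitivity(g)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        res = net.er_transitivity_test(g, n_sim=config.n_sim_net, seed=sub_seed)
        rows.append((cluster, g.number_of_nodes(), g.number_of_edges(),
                     t_mean, t_sd, res.p_value, res.degenerate))
        trans_values.append(t_mean)
    t4 = pd.DataFrame(rows, columns=["cluster", "n", "sib_edges", "transitivity",
                                     "transitivity_sd", "er_p", "degenerate"])
    _write_csv(t4, out / "cluster_networks.csv", index=False)
    bundle["networks"] = t4
    if trans_values:
        summary["mean_transitivity"] = float(np.mean(trans_values))
        summary["transitivity_significant_frac"] = float(
            (t4.loc[~t4["degenerate"], "er_p"] < 0.05).mean()) if (~t4["degenerate"]).any() else 0.0
    run_log.append(f"networks: seed {seed}, n_sim {config.n_sim_net}")


def make_report(bundle: dict, path: str | Path | None = None) -> str:
    """Render a human-readable markdown summary, one section per stage.

    Missing stages are flagged as absent rather than failing.
    """
    lines = ["# kinpatch analysis report", ""]
    summary = bundle.get("summary", {})
    lines.append(f"Global seed: {summary.get('seed', 'n/a')}; "
                 f"{summary.get('n_individuals', '?')} individuals, "
                 f"{summary.get('n_sites', '?')} sites, "
                 f"{summary.get('n_loci', '?')} loci.")
    lines.append("")

    def section(title: str, key: str, render) -> None:
        lines.append(f"## {title}")
        if key not in bundle:
            lines.append("*stage output absent*")
        else:
            render()
        lines.append("")

    def _hwe():
        reg = bundle["hwe"]["regression"]
        lines.append(
            f"- exact-test deviations in "
            f"{100 * summary.get('hwe_exact_significant_frac', float('nan')):.0f}% "
            f"of site x locus samples; homozygote excess in "
            f"{100 * summary.get('homozygote_excess_significant_frac', float('nan')):.0f}%")
        lines.append(
            f"- missingness regression: F({reg.df_num},{reg.df_den}) = "
            f"{reg.f_statistic:.4g}, p = {reg.p_value:.2g}")

    def _diff():
        lines.append(
            f"- significant pairs after correction: F_ST "
            f"{100 * summary.get('fst_significant_frac', float('nan')):.0f}%, P_D "
            f"{100 * summary.get('pd_significant_frac', float('nan')):.0f}%")
        if "mantel" in summary:
            m = summary["mantel"]
            lines.append(
                f"- Mantel IBD: P_D r = {m['pd']['r']:.2f} (p = {m['pd']['p']:.2f}); "
                f"F_ST r = {m['fst']['r']:.2f} (p = {m['fst']['p']:.2f})")

    def _clu():
        ks = summary.get("selected_k", {})
        lines.append(f"- clusters per site: {ks}")
        two = [s for s, a in bundle["clustering"]["assignments"].items()
               if a.selected_k == 2]
        if two:
            lines.append(f"- sites with k = 2 (density-plot projection): {two}")

    def _rel():
        frame = bundle["relatedness"]["site"]
        for g, row in frame.iterrows():
            star = "*" if row["p_value"] < 0.05 else ""
            lines.append(f"- {g}: r = {row['r_mean']:.3f} +/- {row['se']:.3f}"
                         f" (p = {row['p_value']:.3f}){star}")

    def _sib():
        excl = bundle["sibship"]["exclusion"]
        lines.append(f"- exclusion probability (all loci): {excl.probability:.3f}")
        if "sib_proportion_mean" in summary:
            lines.append(f"- mean within-cluster sib proportion: "
                         f"{100 * summary['sib_proportion_mean']:.1f}%")

    def _net():
        if "mean_transitivity" in summary:
            lines.append(f"- mean cluster transitivity: "
                         f"{summary['mean_transitivity']:.3f}")

    section("Hardy-Weinberg diagnostics", "hwe", _hwe)
    section("Differentiation", "differentiation", _diff)
    section("Within-site clustering", "clustering", _clu)
    section("Relatedness", "relatedness", _rel)
    section("Sibship", "sibship", _sib)
    section("Sibship networks", "networks", _net)
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
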