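"""End-to-end study pipeline: strengths -> global MTCP -> nodal MTCP ->
clinical association, driven by a single config with a master seed.

Every stage writes plain CSV/JSON so that runs can be diffed; a manifest
records the config, derived seeds and package version.  All randomness
derives from the master seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlate_with_score, fit_and_compare
from .connectome import (
    Connectome,
    extract_hemisphere,
    read_cohort_table,
    read_matrix,
)
from .graph_measures import global_efficiency
from .group_stats import (
    REGION_SETS,
    group_averaged_distribution,
    ks_two_sample,
    quartile_table,
    rm_anova_2xk,
    simple_effects,
    tmax_permutation_test,
)
from .mtcp import (
    GLOBAL_KAPPA_GRID,
    NODAL_KAPPA_GRID,
    measure_curve,
    mtcp_test,
    nodal_mtcp_screen,
)
from .parcellation import read_region_table
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "load_cohort", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``matrix_dir`` + ``region_table`` + ``cohort_table`` point to
    delimited-text inputs (one ``<subject_id>.csv`` matrix per subject),
    or ``simulate`` holds a :class:`SimulationConfig` dict for a
    self-generated cohort.
    """

    out_dir: str = "connectopy_run"
    matrix_dir: str | None = None
    region_table: str | None = None
    cohort_table: str | None = None
    simulate: dict | None = None
    global_kappas: list[float] = field(
        default_factory=lambda: [float(k) for k in GLOBAL_KAPPA_GRID]
    )
    nodal_kappas: list[float] = field(
        default_factory=lambda: [float(k) for k in NODAL_KAPPA_GRID]
    )
    n_perm_tmax: int = 10_000
    n_perm_mtcp: int = 1000
    ensemble_size: int = 150
    normalize_global: bool = False
    global_measures: list[str] = field(
        default_factory=lambda: ["efficiency", "clustering", "modularity"]
    )
    nodal_measures: list[str] = field(
        default_factory=lambda: ["strength", "local_efficiency", "local_clustering"]
    )
    nodal_scope: str = "right"
    control_label: str = "control"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_cohort(cfg: RunConfig):
    """Load or simulate the cohort specified by the config."""
    if cfg.simulate is not None:
        sim = SimulationConfig(**cfg.simulate)
        if sim.seed is None:
            sim.seed = cfg.master_seed
        connectomes, table, truth = simulate_cohort(sim)
        return connectomes, table, truth
    if not (cfg.matrix_dir and cfg.region_table and cfg.cohort_table):
        raise ValueError(
            "config must provide either 'simulate' or matrix_dir, "
            "region_table and cohort_table"
        )
    parcellation = read_region_table(cfg.region_table)
    table = read_cohort_table(cfg.cohort_table)
    connectomes = []
    for sid in table["subject_id"]:
        w = read_matrix(Path(cfg.matrix_dir) / f"{sid}.csv", parcellation.size)
        connectomes.append(
            Connectome(weights=w, parcellation=parcellation, subject_id=sid)
        )
    return connectomes, table, None


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a summary dict, writes files.

    Stages, in order: overall connectivity (quartiles, t_max permutation
    family test, KS tests, mixed ANOVA with simple effects), global graph
    parameters (MTCP per scope and measure), localisation (nodal MTCP
    screen), and correlation with the clinical score.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = {k: int(s.generate_state(1)[0]) % (2**31)
             for k, s in zip(
                 ["tmax", "global_mtcp", "nodal_mtcp", "association", "curves"],
                 ss.spawn(5))}

    cohort, table, truth = load_cohort(cfg)
    groups = table["group"].to_numpy()
    control = cfg.control_label
    summary: dict = {"stages": {}}

    # ---- stage 1: overall connectivity -------------------------------
    try:
        qt = quartile_table(cohort)
        qt.to_csv(out / "strength_quartiles.csv")
        cmp_res = tmax_permutation_test(
            qt, groups, n_perm=cfg.n_perm_tmax, seed=seeds["tmax"], control=control
        )
        cmp_res.to_csv(out / "strength_comparison.csv")
        ks_rows = []
        for rs in REGION_SETS:
            dists = group_averaged_distribution(cohort, groups, rs)
            (a, b) = (dists[k] for k in sorted(dists))
            d, p = ks_two_sample(a, b)
            ks_rows.append({"region_set": rs, "D": d, "p": p})
        pd.DataFrame(ks_rows).to_csv(out / "ks_tests.csv", index=False)

        long = qt.reset_index().melt(
            id_vars="subject_id",
            value_vars=[f"{rs}_q50" for rs in REGION_SETS],
            var_name="region_set", value_name="value",
        )
        long["region_set"] = long["region_set"].str.replace("_q50", "", regex=False)
        long = long.merge(table[["subject_id", "group"]], on="subject_id")
        anova = rm_anova_2xk(long)
        anova.to_csv(out / "anova_median_strength.csv")
        simple = simple_effects(long, control=control)
        simple.to_csv(out / "simple_effects.csv")
        summary["stages"]["overall_connectivity"] = {
            "tmax_p_adjusted": cmp_res["p_adjusted"].to_dict(),
            "anova_p": anova["p"].to_dict(),
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'overall_connectivity' failed: {exc}") from exc

    # ---- stage 2: global graph parameters ----------------------------
    try:
        rows = []
        for scope in ("whole", "left", "right"):
            for measure in cfg.global_measures:
                curve = measure_curve(
                    cohort, scope=scope, measure=measure,
                    normalize=cfg.normalize_global and measure != "modularity",
                    kappas=np.asarray(cfg.global_kappas),
                    ensemble_size=cfg.ensemble_size, seed=seeds["curves"],
                )
                res = mtcp_test(
                    curve, groups, n_perm=cfg.n_perm_mtcp,
                    seed=seeds["global_mtcp"], control=control,
                )
                rows.append({
                    "scope": scope, "measure": measure,
                    "kappa_mtcp": res.kappa_mtcp, "t_mtcp": res.t_mtcp,
                    "t_max": res.t_max, "t_crit": res.t_crit,
                    "A": res.A, "A_crit": res.A_crit, "p": res.p,
                    "significant": res.significant,
                })
        global_df = pd.DataFrame(rows)
        global_df.to_csv(out / "global_mtcp.csv", index=False)
        summary["stages"]["global_graph_parameters"] = {
            "significant": global_df.loc[
                global_df["significant"], ["scope", "measure"]
            ].to_dict("records")
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'global_graph_parameters' failed: {exc}") from exc

    # ---- stage 3: localisation (nodal MTCP screen) -------------------
    try:
        nodal_frames = []
        for measure in cfg.nodal_measures:
            screen = nodal_mtcp_screen(
                cohort, groups, scope=cfg.nodal_scope, measure=measure,
                kappas=np.asarray(cfg.nodal_kappas),
                n_perm=cfg.n_perm_mtcp, seed=seeds["nodal_mtcp"], control=control,
            )
            nodal_frames.append(screen)
        nodal_df = pd.concat(nodal_frames, ignore_index=True)
        nodal_df.to_csv(out / "nodal_mtcp.csv", index=False)
        flagged = nodal_df[(nodal_df["t_ratio"] > 1) & (nodal_df["A_ratio"] > 1)]
        summary["stages"]["localisation"] = {
            "flagged_regions": flagged[["measure", "region"]].to_dict("records")
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'localisation' failed: {exc}") from exc

    # ---- stage 4: correlation with clinical score --------------------
    try:
        pat = table["group"] != control
        scores = table.loc[pat, "score"].to_numpy(dtype=float)
        ages = table.loc[pat, "age"].to_numpy(dtype=float)
        eff = np.array([
            global_efficiency(extract_hemisphere(c, "right"))
            for c, is_pat in zip(cohort, pat) if is_pat
        ])
        assoc_summary: dict = {}
        if np.isfinite(scores).sum() >= 5:
            assoc = correlate_with_score(eff, scores, age=ages)
            comparison = fit_and_compare(
                eff[np.isfinite(scores)], scores[np.isfinite(scores)],
                seed=seeds["association"],
            )
            assoc_summary = {
                "R": assoc.r, "p": assoc.p,
                "R_partial": assoc.r_partial, "p_partial": assoc.p_partial,
                "R_rank": assoc.r_rank, "p_rank": assoc.p_rank,
                "preferred_model": comparison.preferred,
                "relative_likelihood": comparison.relative_likelihood,
                "aicc_linear": comparison.linear.aicc,
                "aicc_exponential": comparison.exponential.aicc,
            }
        else:
            warnings.warn("too few scored patients; association stage skipped")
        with open(out / "association.json", "w") as fh:
            json.dump(assoc_summary, fh, indent=2)
        summary["stages"]["clinical_association"] = assoc_summary
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'clinical_association' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "derived_seeds": seeds,
        "ground_truth": truth,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    summary["out_dir"] = str(out)
    return summary
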