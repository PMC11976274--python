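"""End-to-end orchestration: simulate -> align -> matrices -> rates ->
subspace comparison -> branch alignment -> allometry -> fitness.

``run_pipeline`` executes the toggled stages on either simulated or
user-supplied inputs and writes one JSON summary (keyed by stage, every
stage recording its seed) plus CSV tables. The ``morphodiverge`` click
CLI is a thin wrapper over the same function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .allometry import alignment_null, fit_allometry, remove_allometry, vector_correlation
from .covariance import (
    CovMatrix,
    ReferenceBasis,
    estimate_D,
    estimate_G,
    estimate_P,
    effective_rank,
    resample_comparison,
    subspace_regression,
    write_matrix_csv,
)
from .fitness import (
    FITNESS_TRAITS,
    quality_pca,
    shape_fitness_pls,
    stabilizing_test,
    survival_blups,
    variance_components,
)
from .morphometrics import cva_loo, gpa, procrustes_anova, write_landmark_csv
from .phylo import (
    Phylogeny,
    drift_expectation,
    divergence_profile,
    estimate_R,
    rate_alignment_test,
    write_newick,
)
from .synthetic import (
    SynthConfig,
    gen_fitness,
    gen_lines,
    gen_macro_shapes,
    gen_tree,
    table_from_shapes,
    tangent_basis,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs", "cli"]


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results"
    k: int = 10  # subspace dimensions compared
    n_perm: int = 999
    n_sim: int = 500
    n_resamples: int = 500
    stages: tuple[str, ...] = (
        "align", "matrices", "rates", "compare", "branches", "allometry", "fitness",
    )
    synth: SynthConfig | None = None
    generations_per_myr: float = 1e6  # one generation per year


def simulate_inputs(cfg: RunConfig) -> dict:
    """Generate the full synthetic input bundle for one pipeline run."""
    synth = cfg.synth or SynthConfig(seed=cfg.seed)
    phy = gen_tree(synth)
    macro = gen_macro_shapes(synth, phy)
    configs, line_effects = gen_lines(synth)
    fitness = gen_fitness(synth, line_effects)
    return {"synth": synth, "phylogeny": phy, "macro": macro,
            "configs": configs, "line_effects": line_effects,
            "fitness": fitness}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig, inputs: dict | None = None) -> dict:
    """Run the analysis graph; returns the JSON-serializable summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed}
    inputs = inputs or simulate_inputs(cfg)
    phy: Phylogeny = inputs["phylogeny"]
    macro: pd.DataFrame = inputs["macro"]
    shape_cols = [c for c in macro.columns if c.startswith("s") and c[1:].isdigit()]

    try:
        # Common coordinate frame: all superimpositions are aligned to the
        # macroevolutionary mean shape so matrices estimated from different
        # datasets are comparable along one basis.
        ref_consensus = macro[shape_cols].mean().to_numpy()

        # --- align: GPA of the raw line-level configurations -------------
        table = None
        if "align" in cfg.stages:
            table = gpa(inputs["configs"], reference=ref_consensus)
            write_landmark_csv(out / "aligned_lines.csv", inputs["configs"])
            macro_table = table_from_shapes(
                macro[shape_cols].to_numpy(),
                macro[["family", "species"]].assign(
                    population="all", line="", side="unknown"),
            )
            anova = procrustes_anova(macro_table, "family",
                                     n_perm=min(cfg.n_perm, 499), seed=cfg.seed)
            cva = cva_loo(macro_table, "family")
            summary["align"] = {
                "seed": cfg.seed,
                "n_configs": len(inputs["configs"]),
                "anova_family": {k: anova[k] for k in ("F", "R2", "Z", "p")},
                "cva_classification_rate": cva["classification_rate"],
            }

        # --- matrices: D, G, P from the line-level data -------------------
        D = G = P = None
        if "matrices" in cfg.stages:
            if table is None:
                table = gpa(inputs["configs"], reference=ref_consensus)
            D = estimate_D(inputs["configs"], reference=ref_consensus)
            G = estimate_G(table)
            P = estimate_P(table)
            for name, C in (("D", D), ("G", G), ("P", P)):
                write_matrix_csv(out / f"matrix_{name}.csv", C)
            summary["matrices"] = {
                "seed": cfg.seed,
                **{f"trace_{n}": C.trace for n, C in (("D", D), ("G", G), ("P", P))},
                "rank_D": effective_rank(D),
            }

        # --- rates: R and phylogenetic heritability -----------------------
        rate_model = None
        if "rates" in cfg.stages:
            rate_model = estimate_R(phy)
            write_matrix_csv(out / "matrix_R.csv", rate_model.R)
            summary["rates"] = {
                "seed": cfg.seed,
                "trace_R": rate_model.R.trace,
                "h2_weighted": rate_model.h2_weighted,
                "n_families": len(phy.filter_families().tip_data),
            }

        # --- compare: common-subspace regression of R on D (and G) --------
        if "compare" in cfg.stages and rate_model is not None and D is not None:
            basis = ReferenceBasis.from_matrix(P if P is not None else D)
            comp = resample_comparison(D, rate_model.R, basis, k=cfg.k,
                                       n_resamples=cfg.n_resamples, seed=cfg.seed)
            summary["compare"] = {
                "seed": cfg.seed,
                "R_on_D": {"slope": comp.slope_beta, "r": comp.pearson_r,
                           "ci_slope": comp.ci_slope, "ci_r": comp.ci_r},
            }
            if G is not None:
                comp_g = subspace_regression(G, rate_model.R, basis, k=cfg.k)
                summary["compare"]["R_on_G"] = {
                    "slope": comp_g.slope_beta, "r": comp_g.pearson_r}

        # --- branches: e_beta / rate alignment with BM null ---------------
        if "branches" in cfg.stages and D is not None:
            res = rate_alignment_test(
                phy, D, rate_model=rate_model, n_sim=cfg.n_sim, seed=cfg.seed)
            summary["branches"] = {
                "seed": cfg.seed, "r_obs": res["r_obs"],
                "P_RAND": res["P_RAND"], "n_edges": res["n_edges"],
            }
            prof = divergence_profile(phy)
            prof.to_csv(out / "divergence_profile.csv", index=False)

        # --- allometry -----------------------------------------------------
        if "allometry" in cfg.stages:
            shapes = macro[shape_cols].to_numpy()
            sizes = np.exp(macro["log_size"].to_numpy())
            fit = fit_allometry(shapes, sizes, n_perm=min(cfg.n_perm, 499),
                                seed=cfg.seed)
            summary["allometry"] = {
                "seed": cfg.seed, "R2": fit.R2, "F": fit.F, "p": fit.p_perm,
            }
            if D is not None:
                al_D = alignment_null(fit.unit_vector, D, n_rand=1000,
                                      seed=cfg.seed, subspace=tangent_basis())
                summary["allometry"]["alignment_D"] = {
                    "captured": al_D["captured_fraction"], "P_RAND": al_D["P_RAND"]}
            if rate_model is not None:
                al_R = alignment_null(fit.unit_vector, rate_model.R, n_rand=1000,
                                      seed=cfg.seed, subspace=tangent_basis())
                summary["allometry"]["alignment_R"] = {
                    "captured": al_R["captured_fraction"], "P_RAND": al_R["P_RAND"]}

        # --- fitness battery -----------------------------------------------
        if "fitness" in cfg.stages:
            fit_df = inputs["fitness"]
            blups = {}
            tests = {}
            for trait in FITNESS_TRAITS:
                if trait == "longevity":
                    sb = survival_blups(fit_df, seed=cfg.seed,
                                        n_perm=min(cfg.n_perm, 499))
                    blups[trait] = sb["scores"]
                    tests[trait] = {"p": sb["p_perm"], "engine": "rank-censored"}
                else:
                    vc = variance_components(fit_df, trait)
                    blups[trait] = vc.blups
                    tests[trait] = {"chi2": vc.chi2_LRT, "p": vc.p_boundary,
                                    "V_line": vc.V_line}
            blup_df = pd.DataFrame(blups)
            blup_df.to_csv(out / "line_blups.csv")
            qp = quality_pca(blup_df, n_rand=1000, seed=cfg.seed)
            # line mean shapes for the PLS block
            if table is None:
                table = gpa(inputs["configs"], reference=ref_consensus)
            md = table.metadata
            lm = pd.DataFrame(table.shapes).assign(
                _line=md["line"].to_numpy(), _pop=md["population"].to_numpy())
            agg = lm.groupby("_line", observed=True)
            line_shapes_df = agg.mean(numeric_only=True)
            line_pops = agg["_pop"].first()
            line_sizes = pd.Series(table.centroid_sizes,
                                   index=md["line"]).groupby(level=0).mean()
            order = [l for l in blup_df.index if l in line_shapes_df.index]
            ls = line_shapes_df.loc[order].to_numpy()
            pops_arr = line_pops.loc[order].to_numpy()
            sz = line_sizes.loc[order].to_numpy()
            pls_pc1 = shape_fitness_pls(
                ls, qp["scores"].loc[order], sizes=sz, populations=pops_arr,
                n_perm=min(cfg.n_perm, 999), seed=cfg.seed)
            pls_all = shape_fitness_pls(
                ls, blup_df.loc[order], sizes=sz, populations=pops_arr,
                n_perm=min(cfg.n_perm, 999), seed=cfg.seed)
            stab = stabilizing_test(
                ls, blup_df.loc[order].assign(PC1=qp["scores"].loc[order]),
                sizes=sz, populations=pops_arr)
            summary["fitness"] = {
                "seed": cfg.seed,
                "line_tests": tests,
                "pc1_pct_var": qp["pct_var"] * 100,
                "pc1_p_rand_matrix": qp["p_rand_matrix"],
                "pc1_p_rand_perm": qp["p_rand_perm"],
                "pls_shape_pc1": {"r_pls": pls_pc1.r_pls, "Z": pls_pc1.Z,
                                  "p": pls_pc1.p_perm},
                "pls_shape_5traits": {"r_pls": pls_all.r_pls, "Z": pls_all.Z,
                                      "p": pls_all.p_perm},
                "stabilizing_max_abs_r":
                    float(stab["correlations"]["r"].abs().max()),
                "stabilizing_min_p": float(stab["correlations"]["p"].min()),
            }
    except Exception as exc:  # preserve partial outputs, name the stage
        done = [k for k in summary if k not in ("version", "seed")]
        (out / "summary_partial.json").write_text(
            json.dumps(_jsonable(summary), indent=2))
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    return summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """Developmental variability vs macroevolutionary divergence pipeline."""


@cli.command()
@click.option("--preset", default="paper", show_default=True,
              type=click.Choice(["paper", "small"]))
@click.option("--seed", default=1, show_default=True, type=int)
@click.option("--out", "out_dir", default="simulated", show_default=True)
def simulate(preset, seed, out_dir):
    """Write a synthetic input bundle (TPS/CSV/Newick) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kwargs = {} if preset == "paper" else {
        "n_families": 12, "species_per_family": 6, "n_lines": 20,
        "n_populations": 4, "inds_per_line": 4}
    synth = SynthConfig(seed=seed, **kwargs)
    phy = gen_tree(synth)
    macro = gen_macro_shapes(synth, phy)
    configs, line_effects = gen_lines(synth)
    fitness = gen_fitness(synth, line_effects)
    write_newick(out / "tree.nwk", phy)
    macro.to_csv(out / "macro_shapes.csv", index=False)
    write_landmark_csv(out / "line_landmarks.csv", configs)
    from .morphometrics import write_tps
    write_tps(out / "line_landmarks.tps", configs)
    fitness.to_csv(out / "fitness.csv", index=False)
    line_effects.to_csv(out / "line_effects_truth.csv", index=False)
    click.echo(f"wrote synthetic inputs (seed={seed}) to {out}")


@cli.command("all")
@click.option("--seed", default=1, show_default=True, type=int)
@click.option("--out", "out_dir", default="results", show_default=True)
@click.option("--k", default=10, show_default=True, type=int)
@click.option("--nsim", default=500, show_default=True, type=int)
@click.option("--skip", multiple=True, help="stages to skip")
def run_all(seed, out_dir, k, nsim, skip):
    """Simulate then run every analysis stage."""
    stages = tuple(s for s in RunConfig.__dataclass_fields__["stages"].default
                   if s not in skip)
    cfg = RunConfig(seed=seed, out_dir=out_dir, k=k, n_sim=nsim, stages=stages)
    summary = run_pipeline(cfg)
    click.echo(json.dumps(_jsonable(summary), indent=2))


if __name__ == "__main__":
    cli()
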