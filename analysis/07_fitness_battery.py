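"""Deleterious-pleiotropy battery: heritable line variation in five
fitness traits, genetic-quality PC1 against two randomization nulls, the
shape-fitness two-block PLS, and the stabilizing-selection distance
test."""

from pathlib import Path

import json
import numpy as np
import pandas as pd

from morphodiverge.fitness import (
    FITNESS_TRAITS, quality_pca, shape_fitness_pls, stabilizing_test,
    survival_blups, variance_components,
)

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")
SEED = 1


def main():
    fit_df = pd.read_csv(IN / "fitness.csv")
    blups, tests = {}, {}
    for trait in FITNESS_TRAITS:
        if trait == "longevity":
            sb = survival_blups(fit_df, seed=SEED, n_perm=999)
            blups[trait] = sb["scores"]
            tests[trait] = {"p": sb["p_perm"]}
            print(f"{trait:20s}: censored rank model, line effect "
                  f"P = {sb['p_perm']:.4f} ({sb['censor_rate']:.0%} censored)")
        else:
            vc = variance_components(fit_df, trait)
            blups[trait] = vc.blups
            tests[trait] = {"chi2": vc.chi2_LRT, "p": vc.p_boundary}
            print(f"{trait:20s}: V_line = {vc.V_line:.3g}, "
                  f"chi2_1 = {vc.chi2_LRT:.2f}, P = {vc.p_boundary:.4f}")
    blup_df = pd.DataFrame(blups)
    blup_df.to_csv(OUT / "line_blups.csv")

    qp = quality_pca(blup_df, n_rand=10_000, seed=SEED)
    print(f"genetic-quality PC1 explains {qp['pct_var']:.1%} of BLUP "
          f"variance (random-matrix null P = {qp['p_rand_matrix']:.4f}, "
          f"permutation null P = {qp['p_rand_perm']:.4f})")

    aligned = pd.read_csv(OUT / "aligned_line_shapes.csv")
    shape_cols = [c for c in aligned.columns
                  if c.startswith("s") and c[1:].isdigit()]
    agg = aligned.groupby("line")
    line_shapes = agg[shape_cols].mean()
    order = [l for l in blup_df.index if l in line_shapes.index]
    ls = line_shapes.loc[order].to_numpy()
    pops = agg["population"].first().loc[order].to_numpy()
    sz = agg["centroid_size"].mean().loc[order].to_numpy()

    pls1 = shape_fitness_pls(ls, qp["scores"].loc[order], sizes=sz,
                             populations=pops, n_perm=9999, seed=SEED)
    pls5 = shape_fitness_pls(ls, blup_df.loc[order], sizes=sz,
                             populations=pops, n_perm=9999, seed=SEED)
    print(f"shape ~ PC1:      r_PLS = {pls1.r_pls:.2f}, Z = {pls1.Z:.2f}, "
          f"P = {pls1.p_perm:.3f}")
    print(f"shape ~ 5 traits: r_PLS = {pls5.r_pls:.2f}, Z = {pls5.Z:.2f}, "
          f"P = {pls5.p_perm:.3f}")

    stab = stabilizing_test(ls, blup_df.loc[order].assign(
        PC1=qp["scores"].loc[order]), sizes=sz, populations=pops)
    mx = stab["correlations"]["r"].abs().max()
    mn = stab["correlations"]["p"].min()
    print(f"stabilizing-selection test: |r| <= {mx:.2f}, min P = {mn:.3f} "
          f"(outlier-excluded rerun written alongside)")
    stab["correlations"].to_csv(OUT / "stabilizing_correlations.csv")
    stab["correlations_no_outlier"].to_csv(
        OUT / "stabilizing_correlations_no_outlier.csv")
    (OUT / "fitness_tests.json").write_text(json.dumps(
        {"line_tests": tests, "pc1_pct_var": qp["pct_var"] * 100,
         "pc1_p_matrix": qp["p_rand_matrix"], "pc1_p_perm": qp["p_rand_perm"],
         "pls_pc1": {"r": pls1.r_pls, "Z": pls1.Z, "p": pls1.p_perm},
         "pls_5traits": {"r": pls5.r_pls, "Z": pls5.Z, "p": pls5.p_perm}},
        indent=2))


if __name__ == "__main__":
    main()
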