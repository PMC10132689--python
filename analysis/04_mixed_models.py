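#!/usr/bin/env python
"""Mixed-model battery: predictors of the five grooming network metrics.

For each metric: Rosner outlier screen, VIF check, full linear mixed model
(sex, centered age + its square, rearing, group size, sex ratio, sex
interactions; random intercepts for individual and group), backward AIC
reduction, REML refit, Tukey contrasts where a sex-by-rearing interaction
survives, and residual diagnostics.  A second pass re-fits the group-size-
standardized responses without group size as a predictor (the robustness
check).  Outputs land in results/models/.
"""

import argparse
from pathlib import Path

import pandas as pd

from groomnet.mixed_models import (FULL_TERMS, STANDARDIZED_TERMS,
                                   aic_backward_reduction, prepare_design,
                                   residual_diagnostics, tukey_contrasts,
                                   vif_check)

RESPONSES = ["out_strength", "in_strength", "disparity", "affinity",
             "eigenvector"]
STD_RESPONSES = ["out_strength_std", "in_strength_std", "disparity_dev",
                 "affinity_scaled", "eigenvector_scaled"]


def run_battery(metrics, responses, terms, outdir):
    outdir.mkdir(parents=True, exist_ok=True)
    for response in responses:
        design = prepare_design(metrics, response)
        vifs = vif_check(design)
        final, path = aic_backward_reduction(design, terms)
        diag = residual_diagnostics(final, outdir)
        final.summary_frame().to_csv(outdir / f"{response}_coefficients.csv")
        pd.Series(vifs).to_csv(outdir / f"{response}_vif.csv")
        print(f"\n== {response} (n = {final.n_obs}, "
              f"{len(design.removed_outliers)} outlier(s) removed, "
              f"Shapiro-Wilk p = {diag['shapiro_p']:.2f}) ==")
        print("retained terms:", ", ".join(final.terms) or "(intercept)")
        print(final.summary_frame().round(4).to_string())
        if "male:atypical" in final.terms:
            contrasts = tukey_contrasts(final, design)
            contrasts.to_csv(outdir / f"{response}_tukey.csv", index=False)
            print("Tukey sex-by-rearing contrasts:")
            print(contrasts.round(4).to_string(index=False))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--metrics", type=Path,
                        default=Path("results/metrics/node_metrics.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/models"))
    args = parser.parse_args()

    metrics = pd.read_csv(args.metrics)
    run_battery(metrics, RESPONSES, FULL_TERMS, args.out / "raw")
    # robustness pass on group-size-standardized responses
    run_battery(metrics, STD_RESPONSES, STANDARDIZED_TERMS,
                args.out / "standardized")


if __name__ == "__main__":
    main()
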