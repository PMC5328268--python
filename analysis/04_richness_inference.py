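"""Inference along the richness gradient.

Fits (i) the mixed model of log rarefied CV on species richness + climate
with a forest-type random intercept, (ii) square-root OLS of each overlap
summary on richness for every trait x method, and (iii) the paired
signed-rank comparison of the two overlap estimators' per-forest medians.
Writes a coefficient table shaped like a mixed-model summary and a
regression table (response x method x trait: slope, r^2, p).
"""

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from itvoverlap import compare_methods, fit_itv_model, read_metadata, regress_summary
from itvoverlap.pipeline import SUMMARY_RESPONSES, itv_fit_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_metadata(BASE / "synthetic" / "trait_packing_metadata.csv")
    summaries = pd.read_csv(BASE / "overlap_summaries.csv", dtype={"forest_id": str})

    fits = {}
    for trait in ("leaf_size", "sla"):
        stats = pd.read_csv(BASE / f"rarefied_{trait}.csv", dtype={"forest_id": str})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = fit_itv_model(stats, meta, trait=trait)
        note = "fixed-effects fallback" if fit.fixed_effects_only else "mixed model"
        sr = fit.coefficients.set_index("term").loc["species_richness"]
        print(
            f"{trait} ITV ~ richness ({note}, n={fit.n_obs}): slope {sr.estimate:+.4f} "
            f"(p={sr.p:.2f}), R2m={fit.r2_marginal:.3f}, R2c={fit.r2_conditional:.3f}"
        )
        fits[trait] = fit
    itv_fit_table(fits).to_csv(BASE / "itv_model.csv", index=False)

    rows = []
    for (trait, method), sub in summaries.groupby(["trait", "method"]):
        for response in SUMMARY_RESPONSES:
            fit = regress_summary(sub, meta, response=response)
            rows.append(dataclasses.asdict(fit))
            star = "*" if fit.p_value < 0.05 else " "
            print(
                f"sqrt({response}) ~ richness [{trait}/{method}]: "
                f"slope {fit.slope:+.5f}{star} r2={fit.r2:.2f} p={fit.p_value:.4f}"
            )
    pd.DataFrame(rows).to_csv(BASE / "summary_regressions.csv", index=False)

    comps = []
    for trait, sub in summaries.groupby("trait"):
        med = sub.pivot(index="forest_id", columns="method", values="median_overlap")
        comp = compare_methods(med["normal"], med["kernel"])
        direction = "below" if comp.z < 0 else "above"
        print(
            f"{trait}: normal-method medians sit {direction} kernel medians "
            f"(n={comp.n}, |Z|={comp.abs_z:.2f}, p={comp.p_value:.4f})"
        )
        comps.append({"trait": trait, "n": comp.n, "z": comp.z,
                      "abs_z": comp.abs_z, "p_value": comp.p_value})
    pd.DataFrame(comps).to_csv(BASE / "method_comparison.csv", index=False)


if __name__ == "__main__":
    main()
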