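"""Model subgroup membership from covariates by multinomial regression.

Chooses the subgroup most similar to the whole cohort as the reference,
fits the softmax regression, and reports odds ratios with Bonferroni
correction plus AIC / pseudo-R2 / likelihood-ratio fit statistics.
"""

from pathlib import Path

import pandas as pd

from symptomnet import io
from symptomnet.subgroup_stats import fit_multinomial, select_reference_group

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    covariates = pd.read_csv(RESULTS / "cohort" / "covariates.csv", index_col=0)
    labels = pd.read_csv(RESULTS / "subgroups" / "patient_subgroups.csv", index_col=0)["subgroup"]
    out = RESULTS / "regression"
    out.mkdir(parents=True, exist_ok=True)

    reference = select_reference_group(covariates, labels)
    model = fit_multinomial(covariates, labels, reference=reference)
    model.coefficients.to_csv(out / "regression_table.csv", index=False, float_format="%.10g")
    io.write_json(
        {
            "reference_group": model.reference_group,
            "aic": model.aic,
            "null_aic": -2 * model.null_log_likelihood + 2 * (labels.nunique() - 1),
            "pseudo_r2_cragg_uhler": model.pseudo_r2_cragg_uhler,
            "lr_chi2": model.lr_chi2,
            "lr_p": model.lr_p,
            "n": model.n,
        },
        out / "fit.json",
    )
    sig = model.coefficients.query("term != 'intercept' and p_bonferroni < 0.05")
    print(
        f"reference subgroup {reference}; AIC {model.aic:.0f}, "
        f"Cragg-Uhler pseudo-R2 {model.pseudo_r2_cragg_uhler:.3f}, "
        f"LR chi2 {model.lr_chi2:.1f} (p = {model.lr_p:.2g})"
    )
    for _, row in sig.iterrows():
        print(
            f"  subgroup {row['subgroup']}: {row['term']} OR {row['odds_ratio']:.2f} "
            f"(corrected p = {row['p_bonferroni']:.3g})"
        )


if __name__ == "__main__":
    main()
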