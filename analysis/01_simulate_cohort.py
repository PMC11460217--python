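"""Generate the demonstration cohort used throughout the analysis.

1000 synthetic patients x 31 ordinal symptoms: a general burden factor
(latent correlation 0.15 between all symptoms), three equal patient
subgroups each elevating an interleaved third of the symptoms by 1 sigma
(the symptom clusters thus emerge from co-elevation, as severity clusters
do in real cohorts), covariates whose planted log-odds drive subgroup
membership, and one near-duplicate symptom planted for the redundancy
stage. Writes severity/covariate CSVs plus the ground-truth labels.
"""

from pathlib import Path

from symptomnet import io
from symptomnet.experiments import demo_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    severity, covariates, truth = demo_cohort(seed=SEED)
    io.write_severity_csv(severity, OUT / "severity.csv")
    covariates.to_csv(OUT / "covariates.csv", index_label="patient_id")
    io.write_json({**truth, "seed": SEED}, OUT / "truth.json")
    zeros = (severity.to_numpy() == 0).mean()
    print(
        f"wrote {severity.shape[0]} patients x {severity.shape[1]} symptoms "
        f"({zeros:.0%} zero cells) to {OUT}"
    )


if __name__ == "__main__":
    main()
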