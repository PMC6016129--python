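#!/usr/bin/env python
"""Asset-based SES scoring: national tertiles and cohort projection.

Scores the survey's ten asset indicators by multiple correspondence
analysis, splits the score into weighted tertiles (the national SES
groups), then projects the national cutoffs onto the cohort's score
distribution through their percentile ranks in the rural survey subset
— mirroring the correction needed because the surveillance cohort is
predominantly rural and poorer than the nation.
"""

import argparse
from pathlib import Path

import pandas as pd

from sescra import asset_score as ascore
from sescra.synthetic import ASSET_COLUMNS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    survey = pd.read_csv(data / "survey.csv")
    cohort = pd.read_csv(data / "cohort.csv")

    scores = ascore.mca_score(survey[ASSET_COLUMNS])
    national = ascore.tertile_split(scores, survey["weight"].to_numpy(float))
    survey["score"], survey["ses"] = national.score, national.label

    cohort_scores = ascore.mca_score(cohort[ASSET_COLUMNS])
    rural = (survey["region"] == "rural").to_numpy()
    projected = ascore.project_cutoffs(
        scores[rural], survey.loc[rural, "weight"].to_numpy(float),
        national.cutoffs, cohort_scores,
    )
    plain = ascore.tertile_split(cohort_scores)
    cohort["score"] = cohort_scores
    cohort["ses_projected"] = ascore.labels_from_cutoffs(cohort_scores, projected)
    cohort["ses_unprojected"] = plain.label

    survey[["score", "ses"]].to_csv(out / "survey_ses.csv", index_label="id")
    cohort[["id", "score", "ses_projected", "ses_unprojected"]].to_csv(
        out / "cohort_ses.csv", index=False
    )

    print(f"national tertile cutoffs: {national.cutoffs[0]:+.4f}, "
          f"{national.cutoffs[1]:+.4f}")
    print(f"projected cohort cutoffs: {projected[0]:+.4f}, {projected[1]:+.4f} "
          f"(unprojected: {plain.cutoffs[0]:+.4f}, {plain.cutoffs[1]:+.4f})")
    for col in ("ses_projected", "ses_unprojected"):
        shares = cohort[col].value_counts(normalize=True)
        print(f"cohort {col} shares: "
              + ", ".join(f"{s}={shares.get(s, 0):.2f}" for s in ("low", "middle", "high")))


if __name__ == "__main__":
    main()
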