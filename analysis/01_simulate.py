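#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces the three data sets every later step consumes, calibrated to
the published South Africa 2015 population statistics: a national
drinking/asset survey (default 22,741 respondents, matching the real
survey's complete-case size), a rural open cohort (default 87,029
subjects, 15 years of follow-up), and the deterministic national death
table (~529,400 deaths across 19 causes).
"""

import argparse
from pathlib import Path

from sescra.synthetic import (
    SyntheticScenario,
    generate_cohort,
    generate_death_table,
    generate_survey,
    write_cohort_csv,
    write_deaths_csv,
    write_survey_csv,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2015)
    ap.add_argument("--n-survey", type=int, default=22_741)
    ap.add_argument("--n-cohort", type=int, default=87_029)
    ap.add_argument("--followup", type=float, default=15.0)
    ap.add_argument("--out", type=str, default="results/data")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    sc = SyntheticScenario(seed=args.seed)

    survey = generate_survey(sc, args.n_survey)
    write_survey_csv(survey, out / "survey.csv")
    cohort = generate_cohort(sc, args.n_cohort, args.followup)
    write_cohort_csv(cohort, out / "cohort.csv")
    deaths = generate_death_table(sc)
    write_deaths_csv(deaths, out / "deaths.csv")

    py = (cohort["exit"] - cohort["entry"]).sum()
    print(f"survey: {len(survey):,} respondents "
          f"({(survey.drink_status == 'current').mean():.1%} current drinkers)")
    print(f"cohort: {len(cohort):,} subjects, {py:,.0f} person-years, "
          f"{cohort['event'].sum():,} deaths")
    print(f"national deaths table: {deaths['count'].sum():,.0f} deaths, "
          f"{deaths['cause'].nunique()} causes")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
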