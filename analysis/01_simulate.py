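"""Generate the synthetic study inputs with known ground truth.

Writes the three calibration inputs (survey respondents + raking margins,
population mortality table, hazard-ratio prior summary) and the truth file
used for scoring, under results/inputs/.
"""

import argparse
import dataclasses
import pathlib

from smoketrends.surveys import write_margins, write_survey_table
from smoketrends.synthetic import Scenario, make_hr_study, make_mortality, make_surveys, make_truth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", default="small",
                    choices=["small", "paper_like"])
    ap.add_argument("--seed", type=int, default=None,
                    help="override the scenario's default seed")
    ap.add_argument("--out", default="results/inputs")
    args = ap.parse_args()

    sc = getattr(Scenario, args.scenario)()
    if args.seed is not None:
        sc = dataclasses.replace(sc, seed=args.seed)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    truth = make_truth(sc)
    mort = make_mortality(truth)
    hr = make_hr_study(truth)
    table, margins = make_surveys(truth, mort)

    mort.write(out / "mortality.tsv")
    hr.write(out / "hr_prior.tsv")
    write_survey_table(table, out / "surveys.tsv")
    write_margins(margins, out / "margins.tsv")
    truth.to_frame().to_csv(out / "truth_parameters.tsv", sep="\t",
                            index=False)
    print(f"scenario {sc.name!r} (seed {sc.seed}): "
          f"{len(table)} respondents over {len(sc.survey_years)} surveys; "
          f"inputs written to {out}/")


if __name__ == "__main__":
    main()
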