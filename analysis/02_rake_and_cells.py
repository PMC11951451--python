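"""Rake survey weights to the population margins and build likelihood cells.

Reads results/inputs/, applies iterative proportional fitting per survey,
and writes the adjusted weights plus the (survey x sex x age-band) cell
table with weighted proportions and Kish effective sample sizes.
"""

import argparse
import pathlib

import numpy as np

from smoketrends.surveys import (
    CellConfig,
    add_age_bands,
    build_cells,
    rake_weights,
    read_margins,
    read_survey_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/inputs")
    ap.add_argument("--out", default="results")
    ap.add_argument("--age-width", type=int, default=5,
                    help="age-band width for cells (1 = single-year)")
    ap.add_argument("--unweighted", action="store_true",
                    help="sensitivity: ignore survey weights")
    args = ap.parse_args()

    inp = pathlib.Path(args.inputs)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    table = read_survey_table(inp / "surveys.tsv")
    margins = read_margins(inp / "margins.tsv")
    banded = add_age_bands(table)
    weights = np.empty(len(banded))
    for sid, group in banded.groupby("survey_id", sort=False):
        weights[group.index] = rake_weights(group, margins)
        print(f"{sid}: raked {len(group)} respondents")

    table.assign(raked_weight=weights).to_csv(
        out / "raked_weights.tsv", sep="\t", index=False)
    cells = build_cells(table, weights,
                        CellConfig(age_group_width=args.age_width,
                                   use_weights=not args.unweighted))
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    print(f"{len(cells)} cells written; mean effective n "
          f"{cells['eff_n'].mean():.1f} (raw {cells['raw_n'].mean():.1f})")


if __name__ == "__main__":
    main()
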