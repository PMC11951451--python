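"""Survey ingestion, weight raking and reduction to likelihood-ready cells.

Respondent-level tables carry one row per participant: survey id, calendar
year, sex, single-year age, observed smoking category, design weight and the
raking strata (region, capital-city flag).  Weights are calibrated to
population margins by iterative proportional fitting (raking), and each
(survey, sex, age) cell is reduced to weighted category proportions with a
Kish effective sample size — the unit of data the likelihood consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import SEXES

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "GALLUP_CATEGORIES",
    "read_survey_table",
    "write_survey_table",
    "read_margins",
    "write_margins",
    "rake_weights",
    "effective_sample_size",
    "build_cells",
]

#: Observation categories of the full survey dialect.  ``former_unknown``
#: holds quitters whose age-at-quit is missing.
CATEGORIES = ["current", "former_lt30", "former_3039", "former_ge40",
              "former_unknown", "never"]
#: Early opinion-poll dialect: current vs not-current only.
GALLUP_CATEGORIES = ["current", "not_current"]

_SURVEY_COLS = ["survey_id", "year", "sex", "age", "category", "weight",
                "region", "capital_city"]


def write_survey_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_SURVEY_COLS].to_csv(path, sep="\t", index=False)


def read_survey_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"survey_id": str, "region": str,
                            "capital_city": str})
    _validate_survey_table(df)
    return df


def _validate_survey_table(df: pd.DataFrame) -> None:
    missing = set(_SURVEY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"survey table missing columns {sorted(missing)}")
    if not df["age"].between(20, 99).all():
        raise ValueError("ages must be within 20-99")
    if not (df["weight"] > 0).all():
        raise ValueError("weights must be positive")
    bad = set(df["category"]) - set(CATEGORIES) - set(GALLUP_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    if not df["sex"].isin(SEXES).all():
        raise ValueError("sex must be coded F/M")


def write_margins(margins: dict[str, pd.Series], path: str | Path) -> None:
    rows = [(dim, str(level), float(target))
            for dim, ser in margins.items() for level, target in ser.items()]
    pd.DataFrame(rows, columns=["dimension", "level", "target"]).to_csv(
        path, sep="\t", index=False)


def read_margins(path: str | Path) -> dict[str, pd.Series]:
    df = pd.read_csv(path, sep="\t", dtype={"level": str})
    return {dim: sub.set_index("level")["target"]
            for dim, sub in df.groupby("dimension")}


def add_age_bands(table: pd.DataFrame, lo: int = 20,
                  width: int = 10) -> pd.DataFrame:
    """Add the ``age_band`` raking stratum (band index from ``lo``, as str)."""
    out = table.copy()
    out["age_band"] = ((out["age"] - lo) // width).astype(str)
    return out


def rake_weights(table: pd.DataFrame, margins: dict[str, pd.Series],
                 dims: list[str] | None = None, tol: float = 1e-8,
                 max_iter: int = 200) -> np.ndarray:
    """Iterative proportional fitting of the design weights.

    Cyclically scales weights so the weighted respondent counts match each
    one-way population margin.  Base weights are multiplied, never replaced.
    Margins with no matching respondents but a nonzero target are an error.

    Returns the adjusted weights (aligned to ``table`` rows).
    """
    dims = dims if dims is not None else list(margins)
    w = table["weight"].to_numpy(dtype=float).copy()
    levels = {}
    for dim in dims:
        vals = table[dim].astype(str).to_numpy()
        target = margins[dim]
        present = pd.unique(vals)
        absent = [lv for lv in target.index if lv not in set(present)
                  and target[lv] > 0]
        if absent:
            raise ValueError(
                f"margin {dim!r} has nonzero target for empty levels {absent}")
        extra = set(present) - set(target.index.astype(str))
        if extra:
            raise ValueError(f"respondent levels {sorted(extra)} missing "
                             f"from margin {dim!r}")
        levels[dim] = vals
    for it in range(max_iter):
        max_rel = 0.0
        for dim in dims:
            vals = levels[dim]
            target = margins[dim]
            cur = pd.Series(w).groupby(vals).sum()
            for lv, t in target.items():
                mask = vals == str(lv)
                c = cur.get(str(lv), 0.0)
                if c > 0 and t > 0:
                    max_rel = max(max_rel, abs(c - t) / t)
                    w[mask] *= t / c
        # converged when, before any adjustment this sweep, all margins match
        if max_rel <= tol:
            return w
    warnings.warn(f"raking did not converge to {tol} in {max_iter} iterations "
                  f"(last max relative error {max_rel:.3g})")
    return w


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2.

    Scale-invariant; equals n iff all weights are equal.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(w.sum() ** 2 / (w * w).sum())


@dataclass(frozen=True)
class CellConfig:
    """Cell-building options."""

    age_group_width: int = 1   # >1 pools ages into bands (label = band centre)
    use_weights: bool = True   # False: the unweighted sensitivity variant


_FORMER_CATS = ["former_lt30", "former_3039", "former_ge40"]


def _survey_dialect(categories: pd.Series, mask_frac: float) -> list[str]:
    """Observation categories of one survey.

    Chosen so the model's probabilities over them always sum to 1: the
    per-group former categories appear unless every former respondent has
    missing age-at-quit, and ``former_unknown`` appears only when some do.
    """
    cats = set(categories)
    if cats <= set(GALLUP_CATEGORIES):
        return GALLUP_CATEGORIES
    dialect = ["current"]
    if mask_frac < 1.0:
        dialect += _FORMER_CATS
    if mask_frac > 0.0:
        dialect.append("former_unknown")
    return dialect + ["never"]


def build_cells(table: pd.DataFrame, weights: np.ndarray | None = None,
                config: CellConfig = CellConfig()) -> pd.DataFrame:
    """Cross-tabulate each survey by sex and age into likelihood cells.

    One row per (survey, sex, age[-band]); columns ``p_<category>`` hold the
    weighted proportions over that survey's dialect (NaN for categories not
    in the dialect), plus ``raw_n``, ``eff_n`` (Kish) and ``mask_frac`` — the
    survey-level weighted share of former respondents whose age-at-quit is
    missing, used to split the model's former probabilities.
    """
    _validate_survey_table(table)
    df = table.copy()
    if weights is not None:
        df["weight"] = np.asarray(weights, dtype=float)
    if not config.use_weights:
        df["weight"] = 1.0
    if config.age_group_width > 1:
        wdt = config.age_group_width
        band = ((df["age"] - 20) // wdt)
        df["age"] = (20 + band * wdt + wdt // 2).astype(int)

    rows = []
    for sid, sv in df.groupby("survey_id", sort=False):
        former_w = sv.loc[sv["category"].isin(_FORMER_CATS + ["former_unknown"]),
                          ["category", "weight"]]
        tot_former = former_w["weight"].sum()
        mask_frac = 0.0
        if tot_former > 0:
            mask_frac = float(
                former_w.loc[former_w["category"] == "former_unknown",
                             "weight"].sum() / tot_former)
        dialect = _survey_dialect(sv["category"], mask_frac)
        year = int(sv["year"].iloc[0])
        for (sex, age), cell in sv.groupby(["sex", "age"], sort=True):
            n = len(cell)
            if n == 0:  # pragma: no cover - groupby never yields empty
                continue
            w = cell["weight"].to_numpy(dtype=float)
            props = {c: 0.0 for c in dialect}
            wsum = w.sum()
            for cat, cw in cell.groupby("category")["weight"].sum().items():
                props[cat] += cw / wsum
            row = {
                "survey_id": sid, "year": year, "sex": sex, "age": int(age),
                "birth_year": year - int(age), "raw_n": n,
                "eff_n": min(effective_sample_size(w), float(n)),
                "mask_frac": mask_frac,
                "dialect": "gallup" if dialect == GALLUP_CATEGORIES else "full",
            }
            for c in CATEGORIES + ["not_current"]:
                row[f"p_{c}"] = props.get(c, np.nan) if c in dialect else np.nan
            rows.append(row)
    cells = pd.DataFrame(rows)
    if cells.empty:
        log.info("no non-empty cells built")
    return cells
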