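"""Clinical cohort table: loading, validation, and descriptive summary.

The packaged fixture describes a 27-patient temporal-lobe-epilepsy (TLE)
cohort started on levetiracetam (LEV) monotherapy: demographics, seizure
semiology, aetiology, EEG focus, 3-month clinical outcome and LEV
maintenance dose. :func:`summarize_cohort` reproduces the descriptive
statistics a clinical paper would print from such a table (counts,
percentages to one decimal, means and n-1 sample SDs).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed 3-month outcome categories: seizure-free, non-seizure-free with
#: seizure reduction above / below 50%.
OUTCOMES = ("SF", "NSF>50", "NSF<50")

_REQUIRED_COLUMNS = (
    "id", "sex", "age", "seizure_frequency", "semiology", "aetiology",
    "eeg_focus", "outcome", "lev_dose_mg", "adverse_events",
)


def packaged_cohort_path() -> Path:
    """Path of the cohort fixture shipped with the package."""
    return Path(str(resources.files("microstates").joinpath("data/cohort.tsv")))


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate a cohort table.

    Parameters
    ----------
    path
        Delimited file with the fixture schema; defaults to the packaged
        27-patient table.

    Raises
    ------
    ValueError
        On empty tables, missing columns, unknown outcome codes, or
        non-numeric ages / doses.
    """
    path = Path(path) if path is not None else packaged_cohort_path()
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"cohort file {path} is empty") from None
    if df.empty:
        raise ValueError(f"cohort file {path} has no rows")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    bad = sorted(set(df["outcome"]) - set(OUTCOMES))
    if bad:
        raise ValueError(f"unknown outcome code(s) {bad}; allowed: {OUTCOMES}")
    bad_sex = sorted(set(df["sex"]) - {"F", "M"})
    if bad_sex:
        raise ValueError(f"unknown sex code(s) {bad_sex}")
    df = df.copy()
    df["age"] = pd.to_numeric(df["age"])
    df["lev_dose_mg"] = pd.to_numeric(df["lev_dose_mg"])
    df["structural"] = df["aetiology"].str.startswith("Structural")
    df["side"] = np.where(
        df["eeg_focus"].str.startswith("Right"), "r-TLE", "l-TLE"
    )
    df["adverse_event_flag"] = df["adverse_events"].str.strip().str.lower() != "no"
    return df


def _round1(x: float) -> float:
    """Half-up rounding to 1 decimal, matching printed clinical style."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _mean_sd(values: pd.Series) -> tuple[float, float | None]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return mean, sd


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Descriptive summary of a cohort table.

    Returns a dict with count/percentage breakdowns (outcome, side, sex,
    structural aetiology, adverse events) and mean +/- sample SD of age and
    LEV dose. Percentages are ``100 * count / n`` rounded half-up to one
    decimal; SDs use the n-1 divisor and are ``None`` for single-row tables.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table has no rows")
    n = len(cohort)

    def breakdown(mask_or_col, categories=None) -> dict:
        if categories is None:
            count = int(mask_or_col.sum())
            return {"count": count, "pct": _round1(100.0 * count / n)}
        out = {}
        for cat in categories:
            count = int((mask_or_col == cat).sum())
            out[cat] = {"count": count, "pct": _round1(100.0 * count / n)}
        return out

    age_mean, age_sd = _mean_sd(cohort["age"])
    dose_mean, dose_sd = _mean_sd(cohort["lev_dose_mg"])
    return {
        "n": n,
        "outcome": breakdown(cohort["outcome"], OUTCOMES),
        "side": breakdown(cohort["side"], ("r-TLE", "l-TLE")),
        "sex": breakdown(cohort["sex"], ("F", "M")),
        "structural_aetiology": breakdown(cohort["structural"]),
        "adverse_events": breakdown(cohort["adverse_event_flag"]),
        "age": {
            "mean": _round1(age_mean),
            "sd": _round1(age_sd) if age_sd is not None else None,
            "min": float(cohort["age"].min()),
            "max": float(cohort["age"].max()),
        },
        "lev_dose_mg": {
            "mean": _round1(dose_mean),
            "sd": round(dose_sd, 2) if dose_sd is not None else None,
            "min": float(cohort["lev_dose_mg"].min()),
            "max": float(cohort["lev_dose_mg"].max()),
        },
    }
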