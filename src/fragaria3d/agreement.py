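"""Method-agreement statistics for estimated-vs-reference trait vectors.

Lin's concordance correlation coefficient (CCC) measures agreement with
the identity line, penalising location and scale shifts as well as poor
correlation:

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with 1/n moment estimators, as in Lin's original estimator. r^2 is the
squared Pearson correlation, RMSE is measured against the identity line
y = x (not the fitted line), and the linear fit is ordinary least squares
of y on x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAITS = [
    "height_mm",
    "length_mm",
    "width_mm",
    "volume_ml",
    "calyx_size_mm",
    "achene_count",
    "mean_hue_deg",
]


@dataclass
class AgreementStats:
    trait: str
    ccc: float
    r_squared: float
    rmse: float
    slope: float
    intercept: float
    n: int


def _check_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} paired values")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (1/n moment estimators)."""
    x, y = _check_pair(x, y)
    sx2 = np.mean((x - x.mean()) ** 2)
    sy2 = np.mean((y - y.mean()) ** 2)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("both variances zero and means equal: CCC undefined")
    return float(2.0 * sxy / denom)


def r_squared(x, y) -> float:
    """Squared Pearson correlation."""
    x, y = _check_pair(x, y)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("r^2 undefined for a constant vector")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r**2)


def rmse(x, y) -> float:
    """Root mean square deviation from the identity line y = x."""
    x, y = _check_pair(x, y, min_n=1)
    return float(np.sqrt(np.mean((y - x) ** 2)))


def linfit(x, y) -> tuple[float, float]:
    """Ordinary least squares of y on x: returns (slope, intercept)."""
    x, y = _check_pair(x, y)
    if x.std() == 0:
        raise ValueError("linear fit undefined for constant x")
    slope = np.mean((x - x.mean()) * (y - y.mean())) / np.mean(
        (x - x.mean()) ** 2
    )
    return float(slope), float(y.mean() - slope * x.mean())


def agreement(x, y, trait: str = "") -> AgreementStats:
    """All agreement statistics for one trait (x = reference, y = estimate)."""
    x, y = _check_pair(x, y)
    slope, intercept = linfit(x, y)
    return AgreementStats(
        trait=trait,
        ccc=ccc(x, y),
        r_squared=r_squared(x, y),
        rmse=rmse(x, y),
        slope=slope,
        intercept=intercept,
        n=len(x),
    )


def validate_batch(
    estimates: pd.DataFrame, truth: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Join estimate and reference tables on sample_id and score each trait.

    The estimate (automated) values are regressed on the reference (manual
    or ground-truth) values. Samples with a missing value for a trait are
    dropped for that trait with a logged count.
    """
    traits = traits or TRAITS
    for df, name in ((estimates, "estimates"), (truth, "truth")):
        if "sample_id" not in df.columns:
            raise ValueError(f"{name} table lacks a sample_id column")
    missing = [t for t in traits if t not in estimates.columns or t not in truth.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")
    merged = estimates.merge(truth, on="sample_id", suffixes=("_est", "_ref"))
    if merged.empty:
        raise ValueError("no overlapping sample_ids between the two tables")
    rows = []
    for trait in traits:
        pair = merged[[f"{trait}_ref", f"{trait}_est"]].apply(
            pd.to_numeric, errors="coerce"
        ).dropna()
        dropped = len(merged) - len(pair)
        if dropped:
            log.info("%s: dropped %d samples with missing values", trait, dropped)
        stats = agreement(
            pair[f"{trait}_ref"].to_numpy(), pair[f"{trait}_est"].to_numpy(), trait
        )
        rows.append(stats.__dict__)
    return pd.DataFrame(rows)
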