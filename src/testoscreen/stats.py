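"""Validation statistics: partial correlation, 2x2 carrier comparison,
count reconstruction from printed proportions, and Wilks normalization.

The carrier comparison builds a 2x2 table (rows = case/control group,
columns = carrier/non-carrier of >= threshold effect alleles) and reports a
Woolf-interval odds ratio plus a Pearson chi-square with Yates continuity
correction (on by default for 2x2 tables).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoByTwoTable",
    "CorrelationResult",
    "WilksParams",
    "WILKS_MALE",
    "WILKS_FEMALE",
    "partial_correlation",
    "reconstruct_counts",
    "odds_ratio",
    "chi_square_2x2",
    "wilks_coefficient",
    "wilks_points",
    "carrier_case_control",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b) = group 1 carrier / non-carrier, (c, d) = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    covariates_used: tuple[str, ...] = ()


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> CorrelationResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    With no covariates this is exactly the plain Pearson correlation.  The
    two-sided P value comes from t = r * sqrt(df / (1 - r^2)) on
    df = n - 2 - k degrees of freedom, k = number of covariates.  Rows with
    any missing value are dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None and len(covariates.columns) > 0:
        cov = pd.DataFrame(covariates).astype(float)
        mask = ~np.isnan(x) & ~np.isnan(y) & ~cov.isna().any(axis=1).to_numpy()
        names = tuple(cov.columns)
        Z = np.column_stack([np.ones(int(mask.sum())), cov.to_numpy()[mask]])
        k = Z.shape[1] - 1
    else:
        mask = ~np.isnan(x) & ~np.isnan(y)
        names = ()
        Z = None
        k = 0
    n = int(mask.sum())
    if n < 4 + k:
        raise ValueError(f"need at least {4 + k} complete cases, have {n}")
    xr, yr = x[mask], y[mask]
    if Z is not None:
        xr = _residualize(xr, Z)
        yr = _residualize(yr, Z)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("constant vector after residualization")
    r = float(np.corrcoef(xr, yr)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p_value=p, n=n, covariates_used=names)


def reconstruct_counts(n: int, proportion: float) -> tuple[int, int]:
    """Recover (count, complement) from a group size and a printed percentage.

    Rounds n * proportion/100 to the nearest integer, half away from zero --
    the convention under which a published proportion and group size imply
    integer counts.
    """
    if not (0.0 <= proportion <= 100.0):
        raise ValueError("proportion must be a percentage in [0, 100]")
    if n < 0:
        raise ValueError("group size must be non-negative")
    count = math.floor(n * proportion / 100.0 + 0.5)
    return count, n - count


def odds_ratio(table: TwoByTwoTable) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Woolf (log-scale) 95% CI.

    If any single cell is zero the Haldane-Anscombe correction (+0.5 to each
    cell) is applied and logged; a zero row or column margin raises.
    """
    if 0 in table.margins:
        raise ValueError("odds ratio undefined for a table with a zero margin")
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        logger.info("zero cell: applying Haldane-Anscombe 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.975)
    lo, hi = math.exp(math.log(oratio) - z * se), math.exp(math.log(oratio) + z * se)
    return oratio, (lo, hi)


def chi_square_2x2(table: TwoByTwoTable, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default.

    Closed form: chi2 = N * (|ad - bc| - [N/2])^2 / (r1 r2 c1 c2), with the
    N/2 continuity term only when ``yates`` (and never overshooting past
    zero).  P from the chi-square distribution with 1 df.
    """
    r1, r2, c1, c2 = table.margins
    if 0 in table.margins:
        raise ValueError("chi-square undefined for a table with a zero margin")
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


@dataclass(frozen=True)
class WilksParams:
    """Fifth-order bodyweight polynomial for one sex; coefficient = scale /
    (a + b x + c x^2 + d x^3 + e x^4 + f x^5), x = bodyweight in kg."""

    sex: str
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    scale: float = 500.0
    bw_range: tuple[float, float] = (40.0, 200.0)


# Published 1994 coefficient tables.
WILKS_MALE = WilksParams(
    "male", -216.0475144, 16.2606339, -0.002388645, -0.00113732, 7.01863e-06, -1.291e-08
)
WILKS_FEMALE = WilksParams(
    "female", 594.31747775582, -27.23842536447, 0.82112226871, -0.00930733913,
    4.731582e-05, -9.054e-08,
)


def wilks_coefficient(bodyweight_kg: float, sex: str, params: WilksParams | None = None) -> float:
    if params is None:
        params = WILKS_MALE if sex == "male" else WILKS_FEMALE
    lo, hi = params.bw_range
    if not (lo <= bodyweight_kg <= hi):
        raise ValueError(f"bodyweight {bodyweight_kg} kg outside validity range [{lo}, {hi}]")
    x = bodyweight_kg
    denom = params.a + params.b * x + params.c * x**2 + params.d * x**3 + params.e * x**4 + params.f * x**5
    return params.scale / denom


def wilks_points(
    total_kg: float, bodyweight_kg: float, sex: str, params: WilksParams | None = None
) -> float:
    """Bodyweight-normalized strength: total lifted (kg) x Wilks coefficient."""
    if total_kg < 0:
        raise ValueError("total lifted must be non-negative")
    return total_kg * wilks_coefficient(bodyweight_kg, sex, params)


def carrier_case_control(
    groups: Sequence[str],
    scores: pd.DataFrame,
    threshold: int = 2,
    yates: bool = True,
) -> dict:
    """Carrier (score >= threshold) enrichment of group 1 versus group 2.

    ``groups`` holds exactly two labels aligned with ``scores`` rows (a
    score table with a ``score`` column, as from the scorer).  Individuals
    with missing scores are dropped.  Returns the 2x2 table, per-group
    carrier proportions, odds ratio with CI, and the chi-square report.
    """
    g = np.asarray(groups)
    s = scores["score"].to_numpy(dtype=float)
    if len(g) != len(s):
        raise ValueError("groups and scores have different lengths")
    keep = ~np.isnan(s)
    g, s = g[keep], s[keep]
    labels = list(dict.fromkeys(g))
    if len(labels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {labels}")
    carrier = s >= threshold
    g1, g2 = labels
    table = TwoByTwoTable(
        a=int((carrier & (g == g1)).sum()),
        b=int((~carrier & (g == g1)).sum()),
        c=int((carrier & (g == g2)).sum()),
        d=int((~carrier & (g == g2)).sum()),
    )
    oratio, ci = odds_ratio(table)
    stat, p = chi_square_2x2(table, yates=yates)
    report = {
        "table": table,
        "groups": (g1, g2),
        "proportion_carrier": {
            g1: table.a / (table.a + table.b),
            g2: table.c / (table.c + table.d),
        },
        "odds_ratio": oratio,
        "odds_ratio_ci95": ci,
        "chi2": stat,
        "p_value": p,
        "threshold": threshold,
    }
    logger.info(
        "carrier comparison %s vs %s: %.1f%% vs %.1f%% carriers, OR=%.2f, p=%.4g",
        g1, g2, 100 * report["proportion_carrier"][g1],
        100 * report["proportion_carrier"][g2], oratio, p,
    )
    return report
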