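"""The four-stage variant selection cascade.

Stage 1 drops variants whose male and female discovery effects disagree in
direction (sex-concordance filter).  Stage 2 runs a per-variant
covariate-adjusted association of the trait on effect-allele dosage and keeps
variants that are nominally significant (P < alpha, strict) with the required
effect direction.  Stage 3 keeps autosomal variants only.  Stage 4 looks the
survivors up in external summary statistics for additional traits and keeps
those nominally significant, in the required direction, for every trait.

The association model defaults to ordinary least squares on the continuous
trait, which reports effects in trait units per allele copy; a logistic model
on the median-dichotomized trait is available via ``ScreenConfig.model``.
A Bonferroni family-wise threshold (alpha / (variants x traits)) is computed
for reporting; selection itself is at the nominal alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .genio import GenotypeTable
from .panel import VariantSpec, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "AssociationVariantSelector",
    "sex_concordance_filter",
    "per_variant_association",
    "nominal_direction_filter",
    "autosome_filter",
    "lookup_filter",
    "bonferroni_threshold",
]

MIN_COMPLETE_CASES = 10


@dataclass
class ScreenConfig:
    """Tuning knobs of the cascade.

    ``require_direction`` is the sign (+1/-1) the trait effect must share
    with the discovery (testosterone-increasing) orientation; a zero beta
    fails the direction rule.  ``model`` is 'linear' (OLS on the continuous
    trait) or 'logistic' (median-split then logistic regression).
    """

    alpha: float = 0.05
    require_direction: int = 1
    autosomes_only: bool = True
    model: str = "linear"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.require_direction not in (-1, 1):
            raise ValueError("require_direction must be +1 or -1")
        if self.model not in ("linear", "logistic"):
            raise ValueError("model must be 'linear' or 'logistic'")


def sex_concordance_filter(stats: pd.DataFrame) -> list[str]:
    """Retain variants whose male and female betas share a sign.

    ``stats`` is long-format with columns rsid, sex ('male'/'female'), beta;
    each rsid must carry exactly one record per stratum.  A zero beta in
    either stratum is treated as direction-failing (conservative), matching
    the rule that an effect allele must be "increasing" in both sexes.
    Input order is preserved.
    """
    pivot = stats.pivot_table(index="rsid", columns="sex", values="beta", aggfunc="count")
    for stratum in ("male", "female"):
        if stratum not in pivot.columns:
            raise ValueError(f"no {stratum} records in summary statistics")
        bad = pivot.index[pivot[stratum].fillna(0) != 1].tolist()
        if bad:
            raise ValueError(
                f"rsids without exactly one {stratum} record: {bad[:5]}"
                + ("..." if len(bad) > 5 else "")
            )
    beta = stats.pivot(index="rsid", columns="sex", values="beta")
    concordant = set(beta.index[(beta["male"] * beta["female"]) > 0])
    ordered = list(dict.fromkeys(stats["rsid"]))
    retained = [r for r in ordered if r in concordant]
    logger.info("sex-concordance filter: %d -> %d variants", len(ordered), len(retained))
    return retained


class AssociationVariantSelector(TransformerMixin, BaseEstimator):
    """Per-variant association screen as a scikit-learn feature selector.

    Fits one regression per variant -- trait on effect-allele dosage plus
    covariates -- and selects variants with Wald P < ``alpha`` (strict) and
    effect sign equal to ``direction``.  Complete cases are used per variant
    (listwise deletion); a variant with constant dosage or fewer than
    ``min_complete_cases`` complete rows is flagged untestable and never
    selected, but does not raise.

    Parameters
    ----------
    alpha : nominal significance level (strict inequality).
    direction : required sign of the dosage effect, +1 or -1.
    model : 'linear' for OLS on the continuous trait; 'logistic' for a
        median-split of the trait followed by logistic regression.
    min_complete_cases : minimum complete rows per variant.

    Attributes
    ----------
    results_ : DataFrame with one row per variant (rsid, beta, se, p, n_used,
        testable, passed).
    support_ : boolean mask over input variants.
    selected_rsids_ : selected variant ids, in input order.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        direction: int = 1,
        model: str = "linear",
        min_complete_cases: int = MIN_COMPLETE_CASES,
    ):
        self.alpha = alpha
        self.direction = direction
        self.model = model
        self.min_complete_cases = min_complete_cases

    def fit(self, X, y, covariates: pd.DataFrame | None = None):
        """Run the per-variant regressions.

        X : DataFrame (or array) of dosages, one column per variant.
        y : trait vector aligned with X's rows.
        covariates : optional DataFrame of adjustment columns aligned with X.
        """
        cfg = ScreenConfig(alpha=self.alpha, require_direction=self.direction,
                           model=self.model)
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        cov_arr = None
        if covariates is not None:
            cov = pd.DataFrame(covariates).astype(float)
            if len(cov) != len(X):
                raise ValueError("covariates and X have different lengths")
            _check_collinearity(cov)
            cov_arr = cov.to_numpy(dtype=float)

        rows = []
        for col in X.columns:
            dosage = X[col].to_numpy(dtype=float)
            mask = ~np.isnan(dosage) & ~np.isnan(y)
            if cov_arr is not None:
                mask &= ~np.isnan(cov_arr).any(axis=1)
            n_used = int(mask.sum())
            d, t = dosage[mask], y[mask]
            testable = n_used >= self.min_complete_cases and np.unique(d).size > 1
            if not testable:
                rows.append((col, np.nan, np.nan, np.nan, n_used, False))
                continue
            design = [np.ones(n_used), d]
            if cov_arr is not None:
                design.extend(cov_arr[mask, k] for k in range(cov_arr.shape[1]))
            A = np.column_stack(design)
            beta, se, p = _fit_dosage_term(A, t, cfg.model)
            rows.append((col, beta, se, p, n_used, True))

        res = pd.DataFrame(
            rows, columns=["rsid", "beta", "se", "p", "n_used", "testable"]
        )
        res["passed"] = (
            res["testable"]
            & (res["p"] < cfg.alpha)
            & (np.sign(res["beta"]) == cfg.require_direction)
        )
        self.results_ = res
        self.support_ = res["passed"].to_numpy()
        self.selected_rsids_ = res.loc[res["passed"], "rsid"].tolist()
        self.n_features_in_ = X.shape[1]
        logger.info(
            "association screen: %d variants tested, %d passed (alpha=%g, direction=%+d)",
            len(res), len(self.selected_rsids_), cfg.alpha, cfg.require_direction,
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of variants than at fit")
        return X.loc[:, self.support_]


def _check_collinearity(cov: pd.DataFrame) -> None:
    M = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    M = M[~np.isnan(M).any(axis=1)]
    if M.size and np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(
            f"singular covariate matrix; collinear columns among: {list(cov.columns)}"
        )


def _fit_dosage_term(A: np.ndarray, y: np.ndarray, model: str):
    """(beta, se, p) for the dosage column (index 1) of design matrix A."""
    if model == "linear":
        fit = sm.OLS(y, A).fit()
    else:
        y = (y > np.median(y)).astype(float)
        fit = sm.Logit(y, A).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def per_variant_association(
    genotypes: GenotypeTable,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted association of a trait with each variant's dosage.

    Thin wrapper over :class:`AssociationVariantSelector`; returns its
    ``results_`` table in the genotype table's variant order.
    """
    config = config or ScreenConfig()
    sel = AssociationVariantSelector(
        alpha=config.alpha, direction=config.require_direction, model=config.model
    )
    X = genotypes.to_frame()
    if isinstance(trait, pd.Series):
        trait = trait.reindex(X.index).to_numpy(dtype=float)
    if covariates is not None:
        covariates = covariates.reindex(X.index)
    sel.fit(X, trait, covariates=covariates)
    return sel.results_


def nominal_direction_filter(
    results: pd.DataFrame, config: ScreenConfig | None = None
) -> list[str]:
    """Variants with P strictly below alpha and the required effect sign."""
    config = config or ScreenConfig()
    ok = (
        (results["p"] < config.alpha)
        & (np.sign(results["beta"].fillna(0)) == config.require_direction)
    )
    retained = results.loc[ok, "rsid"].tolist()
    logger.info("nominal+direction filter: %d -> %d", len(results), len(retained))
    return retained


def autosome_filter(variants: Sequence[VariantSpec] | pd.DataFrame) -> list[str]:
    """Retain variants on chromosomes 1-22; X/Y/MT are dropped.

    Accepts either VariantSpec records or a DataFrame with rsid and chrom
    columns.  Unrecognized chromosome labels raise.
    """
    if isinstance(variants, pd.DataFrame):
        pairs = list(zip(variants["rsid"], variants["chrom"]))
    else:
        pairs = [(v.rsid, v.chrom) for v in variants]
    retained = [r for r, c in pairs if normalize_chrom(c).isdigit()]
    logger.info("autosome filter: %d -> %d", len(pairs), len(retained))
    return retained


def lookup_filter(
    rsids: Sequence[str],
    stats: pd.DataFrame,
    traits: Sequence[str],
    config: ScreenConfig | None = None,
) -> list[str]:
    """Keep variants nominally significant, in the required direction, for
    EVERY requested trait in an external summary-statistics table.

    A variant absent from any trait's statistics is excluded (and logged),
    never silently passed.  A trait entirely absent from the table raises.
    """
    config = config or ScreenConfig()
    for trait in traits:
        if not (stats["trait"] == trait).any():
            raise ValueError(f"trait {trait!r} absent from summary statistics")
    retained = []
    for rsid in rsids:
        ok = True
        for trait in traits:
            rec = stats[(stats["rsid"] == rsid) & (stats["trait"] == trait)]
            if rec.empty:
                logger.warning("%s: no %s summary statistics; excluded", rsid, trait)
                ok = False
                break
            row = rec.iloc[0]
            if not (row["p"] < config.alpha and np.sign(row["beta"]) == config.require_direction):
                ok = False
                break
        if ok:
            retained.append(rsid)
    logger.info("summary-stat lookup filter: %d -> %d", len(rsids), len(retained))
    return retained


def bonferroni_threshold(alpha: float, n_variants: int, n_traits: int) -> float:
    """Family-wise threshold alpha / (n_variants * n_traits)."""
    if n_variants <= 0 or n_traits <= 0:
        raise ValueError("variant and trait counts must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_variants * n_traits)
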