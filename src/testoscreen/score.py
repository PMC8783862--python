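"""Unweighted allele-count polygenic score and its exact HWE distribution.

The score is the raw number of effect-allele copies an individual carries
over a fixed variant set: a heterozygote contributes 1, an effect-allele
homozygote 2, so the score ranges 0..2m for m variants.  No beta weighting
is applied -- the score is a count, and individuals are dichotomized into
"high" carriers (score >= threshold, default 2) versus "low" (0-1).

Under Hardy-Weinberg and linkage equilibrium the score is Poisson-binomial:
the sum of m independent Binomial(2, p_i) variables.  Its exact probability
vector is obtained by sequentially convolving the per-locus genotype triples
(q_i^2, 2 p_i q_i, p_i^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genio import GenotypeTable

__all__ = [
    "ScoreConfig",
    "AlleleCountScorer",
    "allele_count_score",
    "dichotomize",
    "score_distribution_hwe",
]


@dataclass
class ScoreConfig:
    """Variant set, carrier threshold and missing-dosage policy."""

    variant_set: list[str] | None = None  # None = every variant in the table
    carrier_threshold: int = 2
    missing_policy: str = "exclude"  # or "maf_impute"
    mafs: dict[str, float] = field(default_factory=dict)  # for maf_impute

    def __post_init__(self) -> None:
        if self.carrier_threshold < 0:
            raise ValueError("carrier_threshold must be non-negative")
        if self.missing_policy not in ("exclude", "maf_impute"):
            raise ValueError("missing_policy must be 'exclude' or 'maf_impute'")


class AlleleCountScorer(TransformerMixin, BaseEstimator):
    """Allele-count polygenic score as a scikit-learn transformer.

    ``transform`` maps an individuals x variants dosage matrix to a single
    score column (sum of effect-allele dosages over ``variant_set``).
    Individuals with any missing dosage get a NaN score under the default
    ``missing_policy='exclude'``; under ``'maf_impute'`` a missing dosage is
    replaced by its expected value 2*maf (requires ``mafs``).

    Attributes
    ----------
    variant_set_ : the rsids actually scored, in input-column order.
    max_score_ : 2 * len(variant_set_).
    """

    def __init__(
        self,
        variant_set: Sequence[str] | None = None,
        carrier_threshold: int = 2,
        missing_policy: str = "exclude",
        mafs: dict[str, float] | None = None,
    ):
        self.variant_set = variant_set
        self.carrier_threshold = carrier_threshold
        self.missing_policy = missing_policy
        self.mafs = mafs

    def fit(self, X, y=None):
        ScoreConfig(
            variant_set=list(self.variant_set) if self.variant_set else None,
            carrier_threshold=self.carrier_threshold,
            missing_policy=self.missing_policy,
        )
        X = pd.DataFrame(X)
        if self.variant_set is None:
            self.variant_set_ = list(X.columns)
        else:
            absent = [r for r in self.variant_set if r not in X.columns]
            if absent:
                raise KeyError(f"variant(s) absent from genotypes: {absent}")
            self.variant_set_ = [c for c in X.columns if c in set(self.variant_set)]
        if self.missing_policy == "maf_impute":
            missing = [r for r in self.variant_set_ if r not in (self.mafs or {})]
            if missing:
                raise ValueError(f"maf_impute needs a maf for: {missing}")
        self.max_score_ = 2 * len(self.variant_set_)
        return self

    def transform(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        D = X[self.variant_set_].to_numpy(dtype=float)
        if self.missing_policy == "maf_impute":
            for j, rsid in enumerate(self.variant_set_):
                col = D[:, j]
                col[np.isnan(col)] = 2.0 * self.mafs[rsid]
        score = D.sum(axis=1)  # NaN propagates under 'exclude'
        return score.reshape(-1, 1)

    def score_frame(self, genotypes: GenotypeTable | pd.DataFrame) -> pd.DataFrame:
        """Per-individual table: id, score, carrier flag.

        Individuals dropped by the missing policy keep a row with a missing
        score and carrier flag.
        """
        X = genotypes.to_frame() if isinstance(genotypes, GenotypeTable) else genotypes
        self.fit(X)
        s = self.transform(X)[:, 0]
        carrier = np.where(np.isnan(s), np.nan, (s >= self.carrier_threshold))
        out = pd.DataFrame({"id": X.index, "score": s, "carrier": carrier})
        return out.reset_index(drop=True)


def allele_count_score(
    genotypes: GenotypeTable | pd.DataFrame, config: ScoreConfig | None = None
) -> pd.DataFrame:
    """Per-individual allele-count score; see :class:`AlleleCountScorer`."""
    config = config or ScoreConfig()
    scorer = AlleleCountScorer(
        variant_set=config.variant_set,
        carrier_threshold=config.carrier_threshold,
        missing_policy=config.missing_policy,
        mafs=config.mafs or None,
    )
    return scorer.score_frame(genotypes)


def dichotomize(scores: pd.DataFrame | np.ndarray, threshold: int = 2) -> np.ndarray:
    """Carrier flag: score >= threshold (NaN scores stay NaN)."""
    s = scores["score"].to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    return np.where(np.isnan(s), np.nan, s >= threshold)


def score_distribution_hwe(mafs: Sequence[float]) -> np.ndarray:
    """Exact score distribution under HWE and linkage equilibrium.

    Returns the probability vector over scores 0..2m for effect-allele
    frequencies ``mafs``, by sequential convolution of the per-locus genotype
    triples ((1-p)^2, 2p(1-p), p^2).  Probabilities sum to 1 to within 1e-12.
    """
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size and (np.isnan(mafs).any() or (mafs < 0).any() or (mafs > 1).any()):
        raise ValueError("every maf must lie in [0, 1]")
    dist = np.array([1.0])
    for p in mafs:
        q = 1.0 - p
        dist = np.convolve(dist, [q * q, 2.0 * p * q, p * p])
    return dist
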