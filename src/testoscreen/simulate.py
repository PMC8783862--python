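"""Synthetic genotype/phenotype cohorts with the structure the analysis assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium and linkage equilibrium:
each variant's effect-allele dosage is an independent Binomial(2, maf) draw.
Quantitative traits are additive-linear in dosage with Gaussian noise:

    trait = intercept + sum_j beta_j * dosage_j + sum_c beta_c * covariate_c
            + Normal(0, residual_sd)

One global seed is split into per-variant / per-operation substreams
(numpy ``SeedSequence.spawn``), so extending a panel does not perturb draws
for variants already present.  The generator deliberately omits linkage
disequilibrium, genotyping error, imputation uncertainty and population
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import GenotypeTable
from .panel import DEFAULT_PANEL, ATHLETE_MAF, VariantSpec, panel_with_mafs

__all__ = [
    "TraitModel",
    "CohortSpec",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_discovery_panel",
    "simulate_case_control",
    "simulate_cohort",
    "default_csa_model",
]

# Sex-specific baseline CSA of fast-twitch fibers (um^2) used by the default
# trait model, matching physically active female/male cohort means.
FEMALE_CSA_MEAN = 4305.0
MALE_CSA_MEAN = 5925.0


@dataclass
class TraitModel:
    """Additive-linear generating model for one quantitative trait.

    ``per_variant_beta`` maps rsid -> effect (trait units per effect-allele
    copy); ``covariate_betas`` maps covariate column -> effect.  ``residual_sd``
    is the SD of the Gaussian noise term, in trait units.
    """

    trait_name: str
    intercept: float = 0.0
    per_variant_beta: dict[str, float] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``covariate_distributions`` maps a covariate name either to
    ``{"mean": m, "sd": s}`` (Gaussian) or to ``{"levels": [...], "weights":
    [...]}`` (categorical, label-encoded as integer codes in level order).
    Sex is generated as the binary column ``sex`` (1 = male) with
    P(male) = ``sex_ratio``.
    """

    n: int
    panel: list[VariantSpec] = field(default_factory=lambda: list(DEFAULT_PANEL))
    trait_models: list[TraitModel] = field(default_factory=list)
    sex_ratio: float = 0.5
    covariate_distributions: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be a fraction in [0, 1]")
        for m in self.trait_models:
            unknown = set(m.per_variant_beta) - {v.rsid for v in self.panel}
            if unknown:
                raise ValueError(
                    f"trait {m.trait_name!r} references variants not in the panel: "
                    f"{sorted(unknown)}"
                )


def _substreams(seed: int, n: int, salt: int) -> list[np.random.Generator]:
    """Deterministic child generators; child i is invariant to n."""
    children = np.random.SeedSequence(entropy=seed, spawn_key=(salt,)).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_genotypes(spec: CohortSpec) -> GenotypeTable:
    """Draw HWE genotypes: dosage_ij ~ Binomial(2, maf_j), independent loci."""
    streams = _substreams(spec.seed, len(spec.panel), salt=1)
    cols = [
        rng.binomial(2, v.maf, size=spec.n).astype(float)
        for v, rng in zip(spec.panel, streams)
    ]
    ids = [f"S{i + 1:06d}" for i in range(spec.n)]
    dosages = np.column_stack(cols) if cols else np.empty((spec.n, 0))
    return GenotypeTable(ids, list(spec.panel), dosages)


def simulate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Draw the covariate table (always includes binary ``sex``, 1 = male)."""
    rng_sex, *_ = _substreams(spec.seed, 1, salt=2)
    df = pd.DataFrame(index=[f"S{i + 1:06d}" for i in range(spec.n)])
    df.index.name = "id"
    df["sex"] = rng_sex.binomial(1, spec.sex_ratio, size=spec.n)
    names = sorted(spec.covariate_distributions)
    streams = _substreams(spec.seed, len(names), salt=3)
    for name, rng in zip(names, streams):
        dist = spec.covariate_distributions[name]
        if "levels" in dist:
            w = np.asarray(dist["weights"], dtype=float)
            df[name] = rng.choice(len(dist["levels"]), size=spec.n, p=w / w.sum())
        else:
            df[name] = rng.normal(dist["mean"], dist["sd"], size=spec.n)
    return df


def simulate_phenotypes(
    genotypes: GenotypeTable,
    model: TraitModel,
    covariates: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Generate one trait column from the additive-linear model.

    Returns a single-column DataFrame indexed like the genotypes.  Missing
    dosages propagate to a missing trait value (listwise handling downstream).
    """
    dosage = genotypes.to_frame()
    absent = [r for r in model.per_variant_beta if r not in dosage.columns]
    if absent:
        raise KeyError(f"trait {model.trait_name!r}: variant(s) not in genotypes: {absent}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(4, _stable_hash(model.trait_name)))
    )
    y = np.full(len(dosage), float(model.intercept))
    for rsid, beta in model.per_variant_beta.items():
        y = y + beta * dosage[rsid].to_numpy()
    for cov, beta in model.covariate_betas.items():
        if cov not in covariates.columns:
            raise KeyError(f"covariate {cov!r} not in covariate table")
        y = y + beta * covariates.loc[dosage.index, cov].to_numpy(dtype=float)
    if model.residual_sd > 0:
        y = y + rng.normal(0.0, model.residual_sd, size=len(y))
    return pd.DataFrame({model.trait_name: y}, index=dosage.index)


def _stable_hash(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def default_csa_model(
    panel: Sequence[VariantSpec] | None = None,
    betas: Mapping[str, float] | None = None,
    residual_sd: float = 800.0,
) -> TraitModel:
    """Default fast-twitch-fiber CSA model with sex-specific baselines.

    The intercept is the female baseline minus the expected dosage
    contribution at the panel's allele frequencies, and the ``sex`` covariate
    carries the male-female difference, so cohort means land near the
    female/male reference values (~4305 / ~5925 um^2) regardless of the
    genetic contribution.
    """
    panel = list(panel) if panel is not None else list(DEFAULT_PANEL)
    if betas is None:
        betas = {
            "rs190930099": 2123.1,
            "rs34706136": 361.1,
            "rs62260729": 407.8,
            "rs77031559": 939.5,
            "rs850294": 824.8,
        }
        betas = {r: b for r, b in betas.items() if r in {v.rsid for v in panel}}
    expected = sum(2.0 * v.maf * betas.get(v.rsid, 0.0) for v in panel)
    return TraitModel(
        trait_name="csa_fast_twitch",
        intercept=FEMALE_CSA_MEAN - expected,
        per_variant_beta=dict(betas),
        covariate_betas={"sex": MALE_CSA_MEAN - FEMALE_CSA_MEAN},
        residual_sd=residual_sd,
    )


def simulate_discovery_panel(
    n_total: int, n_discordant: int, seed: int
) -> pd.DataFrame:
    """Sex-stratified summary statistics with a known number of
    direction-discordant variants.

    Returns a long-format table (two rows per variant: sex = male / female)
    where exactly ``n_discordant`` variants have opposite-signed male and
    female betas and the rest share a sign.  Effect-size magnitudes are
    log-normal on the scale typical of hormone GWAS hits (median |beta|
    ~ 0.02 SD per allele).
    """
    if n_total < 0 or n_discordant < 0 or n_discordant > n_total:
        raise ValueError("need 0 <= n_discordant <= n_total")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    rsids = [f"rs{90000000 + i}" for i in range(n_total)]
    chroms = rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n_total)
    mag_m = np.exp(rng.normal(np.log(0.02), 0.5, size=n_total))
    mag_f = np.exp(rng.normal(np.log(0.02), 0.5, size=n_total))
    base_sign = rng.choice([-1.0, 1.0], size=n_total)
    discordant = np.zeros(n_total, dtype=bool)
    discordant[rng.choice(n_total, size=n_discordant, replace=False)] = True
    sign_f = np.where(discordant, -base_sign, base_sign)
    rows = []
    for i, rsid in enumerate(rsids):
        for sex, beta in (("male", base_sign[i] * mag_m[i]), ("female", sign_f[i] * mag_f[i])):
            rows.append(
                {
                    "rsid": rsid,
                    "chrom": chroms[i],
                    "trait": "testosterone",
                    "effect_allele": "A",
                    "sex": sex,
                    "beta": beta,
                    "p": 1e-9,
                }
            )
    return pd.DataFrame(rows)


def simulate_case_control(
    panel_cases: Sequence[VariantSpec],
    panel_controls: Sequence[VariantSpec],
    n_cases: int,
    n_controls: int,
    seed: int,
) -> tuple[GenotypeTable, np.ndarray]:
    """Two-group HWE genotypes at group-specific allele frequencies.

    Returns a stacked genotype table (cases first) and an array of group
    labels ('case' / 'control').  Both panels must list the same rsids in the
    same order.
    """
    if [v.rsid for v in panel_cases] != [v.rsid for v in panel_controls]:
        raise ValueError("case and control panels must cover the same rsids in order")
    gt_cases = simulate_genotypes(
        CohortSpec(n=n_cases, panel=list(panel_cases), seed=seed)
    )
    gt_controls = simulate_genotypes(
        CohortSpec(n=n_controls, panel=list(panel_controls), seed=seed + 1)
    )
    ids = [f"case_{i}" for i in gt_cases.individual_ids] + [
        f"ctrl_{i}" for i in gt_controls.individual_ids
    ]
    dosages = np.vstack([gt_cases.dosages, gt_controls.dosages])
    labels = np.array(["case"] * n_cases + ["control"] * n_controls)
    return GenotypeTable(ids, list(panel_cases), dosages), labels


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeTable, pd.DataFrame]:
    """Genotypes plus a phenotype table (covariates + every trait model)."""
    genotypes = simulate_genotypes(spec)
    pheno = simulate_covariates(spec)
    for model in spec.trait_models:
        pheno[model.trait_name] = simulate_phenotypes(
            genotypes, model, pheno, spec.seed
        )[model.trait_name]
    return genotypes, pheno
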