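"""End-to-end orchestration: simulate -> screen -> score -> validate.

``run_all`` executes the full cascade on synthetic cohorts built at the
bundled panel's allele frequencies and effect sizes, writes per-stage TSV
outputs, and returns a summary report with the cascade counts
(total -> sex-concordant -> nominally associated -> autosomal -> lookup
survivors) and the final carrier case-control statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genio, screen, score, simulate, stats
from .panel import (
    ATHLETE_MAF,
    CONTROL_MAF,
    DEFAULT_PANEL,
    VariantSpec,
    panel_with_mafs,
    reported_associations,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "make_fixtures"]


@dataclass
class PipelineConfig:
    """All knobs of the demo pipeline, serializable as YAML."""

    seed: int = 0
    out_dir: str = "testoscreen_out"
    # discovery-stage panel
    discovery_total: int = 855
    discovery_discordant: int = 33
    # association cohort
    n_cohort: int = 2000
    n_null_variants: int = 20
    n_null_on_x: int = 3
    csa_residual_sd: float = 800.0
    # case-control validation cohorts
    n_cases: int = 5000
    n_controls: int = 5000
    # analysis settings
    alpha: float = 0.05
    model: str = "linear"
    carrier_threshold: int = 2
    # per-allele testosterone effect (nmol/l) used for the validation trait
    testosterone_beta: float = 1.1
    testosterone_sd: float = 4.6
    testosterone_mean: float = 22.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _null_variants(cfg: PipelineConfig, rng: np.random.Generator) -> list[VariantSpec]:
    """Effect-free filler variants, a few on X to exercise the autosome stage."""
    out = []
    for i in range(cfg.n_null_variants):
        chrom = "X" if i < cfg.n_null_on_x else str(rng.integers(1, 23))
        out.append(
            VariantSpec(
                rsid=f"rs{70000000 + i}",
                chrom=chrom,
                pos=int(rng.integers(10_000, 50_000_000)),
                effect_allele="A",
                other_allele="G",
                maf=float(rng.uniform(0.05, 0.5)),
            )
        )
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes TSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(99,)))
    report: dict = {"seed": config.seed}

    # --- stage 1: discovery panel and sex-concordance filter -----------------
    discovery = simulate.simulate_discovery_panel(
        config.discovery_total, config.discovery_discordant, config.seed
    )
    concordant = screen.sex_concordance_filter(discovery)
    report["n_discovery"] = config.discovery_total
    report["n_concordant"] = len(concordant)

    # --- stage 2: per-variant association in a synthetic cohort --------------
    panel = panel_with_mafs(ATHLETE_MAF) + _null_variants(config, rng)
    csa_model = simulate.default_csa_model(panel, residual_sd=config.csa_residual_sd)
    spec = simulate.CohortSpec(
        n=config.n_cohort,
        panel=panel,
        trait_models=[csa_model],
        covariate_distributions={"age": {"mean": 28.0, "sd": 6.0}},
        seed=config.seed,
    )
    genotypes, pheno = simulate.simulate_cohort(spec)
    cfg = screen.ScreenConfig(alpha=config.alpha, model=config.model)
    assoc = screen.per_variant_association(
        genotypes, pheno["csa_fast_twitch"], pheno[["sex", "age"]], cfg
    )
    nominal = screen.nominal_direction_filter(assoc, cfg)
    report["n_tested"] = len(assoc)
    report["n_nominal"] = len(nominal)

    # --- stage 3: autosomes only ---------------------------------------------
    by_rsid = {v.rsid: v for v in panel}
    autosomal = screen.autosome_filter([by_rsid[r] for r in nominal])
    report["n_autosomal"] = len(autosomal)

    # --- stage 4: lookup in external summary statistics ----------------------
    sumstats = reported_associations()
    selected = screen.lookup_filter(
        autosomal, sumstats, ("handgrip", "fat_free_mass"), cfg
    )
    report["n_selected"] = len(selected)
    report["selected"] = selected
    report["bonferroni_threshold"] = screen.bonferroni_threshold(
        config.alpha, len(concordant), 3
    )

    # --- scoring and case-control validation ---------------------------------
    sel_specs_case = [by_rsid[r] for r in selected]
    sel_specs_ctrl = [
        v.with_maf(CONTROL_MAF.get(v.rsid, v.maf)) for v in sel_specs_case
    ]
    cc_genotypes, labels = simulate.simulate_case_control(
        sel_specs_case, sel_specs_ctrl, config.n_cases, config.n_controls,
        seed=config.seed + 7,
    )
    scores = score.allele_count_score(
        cc_genotypes, score.ScoreConfig(carrier_threshold=config.carrier_threshold)
    )
    cc = stats.carrier_case_control(labels, scores, threshold=config.carrier_threshold)
    report["carrier_proportions"] = cc["proportion_carrier"]
    report["odds_ratio"] = cc["odds_ratio"]
    report["odds_ratio_ci95"] = cc["odds_ratio_ci95"]
    report["chi2"] = cc["chi2"]
    report["chi2_p"] = cc["p_value"]

    # score-testosterone correlation in the case group
    testo_model = simulate.TraitModel(
        trait_name="testosterone",
        intercept=config.testosterone_mean
        - 2 * config.testosterone_beta * sum(v.maf for v in sel_specs_case),
        per_variant_beta={v.rsid: config.testosterone_beta for v in sel_specs_case},
        residual_sd=config.testosterone_sd,
    )
    case_mask = labels == "case"
    case_gt = genio.GenotypeTable(
        [cc_genotypes.individual_ids[i] for i in np.nonzero(case_mask)[0]],
        cc_genotypes.variants,
        cc_genotypes.dosages[case_mask],
    )
    testo = simulate.simulate_phenotypes(
        case_gt, testo_model, pd.DataFrame(index=case_gt.individual_ids),
        seed=config.seed + 11,
    )
    corr = stats.partial_correlation(
        scores.loc[case_mask.nonzero()[0], "score"], testo["testosterone"]
    )
    report["testosterone_correlation_r"] = corr.r
    report["testosterone_correlation_p"] = corr.p_value

    # --- outputs --------------------------------------------------------------
    hist = np.bincount(
        scores["score"].dropna().astype(int), minlength=2 * len(selected) + 1
    )
    genio.write_results(
        {
            "associations": assoc,
            "scores": scores.assign(group=labels),
            "score_histogram": pd.DataFrame(
                {"score": np.arange(hist.size), "count": hist}
            ),
            "cascade_counts": pd.DataFrame(
                {
                    "stage": [
                        "discovery", "sex_concordant", "nominal_direction",
                        "autosomal", "lookup_selected",
                    ],
                    "n": [
                        report["n_discovery"], report["n_concordant"],
                        report["n_nominal"], report["n_autosomal"],
                        report["n_selected"],
                    ],
                }
            ),
        },
        out_dir,
    )
    with open(out_dir / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=True)
    logger.info("pipeline report: %s", report)
    return report


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the bundled reference tables and a small synthetic cohort.

    Emits the five-variant published association table as a summary-stats
    TSV, the athlete/control allele-frequency panels, a variant list for the
    scorer, and a 60-individual synthetic cohort (VCF + phenotype TSV).
    Byte-identical across reruns with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sumstats = reported_associations()
    p = out_dir / "summary_stats.tsv"
    sumstats.to_csv(p, sep="\t", index=False)
    written.append(p)

    for name, mafs in (("athlete", ATHLETE_MAF), ("control", CONTROL_MAF)):
        rows = [
            {
                "rsid": v.rsid, "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
                "effect_allele": v.effect_allele, "other_allele": v.other_allele,
                "maf": mafs[v.rsid],
            }
            for v in DEFAULT_PANEL
        ]
        p = out_dir / f"panel_{name}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out_dir / "variants.tsv"
    pd.DataFrame(
        [{"rsid": v.rsid, "effect_allele": v.effect_allele} for v in DEFAULT_PANEL]
    ).to_csv(p, sep="\t", index=False)
    written.append(p)

    spec = simulate.CohortSpec(
        n=60,
        panel=panel_with_mafs(ATHLETE_MAF),
        trait_models=[simulate.default_csa_model(panel_with_mafs(ATHLETE_MAF))],
        covariate_distributions={"age": {"mean": 28.0, "sd": 6.0}},
        seed=seed,
    )
    genotypes, pheno = simulate.simulate_cohort(spec)
    p = out_dir / "cohort.vcf"
    genio.write_vcf(genotypes, p)
    written.append(p)
    p = out_dir / "cohort_phenotypes.tsv"
    pheno.reset_index().to_csv(p, sep="\t", index=False, float_format="%.6f")
    written.append(p)
    for path in written:
        logger.info("fixture written: %s", path)
    return written
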