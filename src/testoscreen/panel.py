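"""The five-variant testosterone panel and its published statistics.

Five SNPs whose testosterone-increasing alleles were reported as nominally
associated (P < 0.05) with cross-sectional area (CSA) of fast-twitch muscle
fibers, handgrip strength and fat-free mass.  Their per-trait effect sizes,
and the effect-allele frequencies observed in elite power athletes and
non-athlete controls, are bundled here so the whole pipeline can run without
external downloads.  GLIS3 rs34706136 is an insertion polymorphism: the
effect allele is a two-base (TG) insertion relative to the other allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd

__all__ = [
    "VariantSpec",
    "DEFAULT_PANEL",
    "ATHLETE_MAF",
    "CONTROL_MAF",
    "TRAITS",
    "reported_associations",
    "panel_with_mafs",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}
_ALLOWED_CHROMS = _AUTOSOMES | {"X"}


def normalize_chrom(label: str) -> str:
    """Map 'chr1', '1', 'chrX', 'x' ... onto canonical '1'..'22', 'X'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s not in _ALLOWED_CHROMS and s not in {"Y", "MT", "M"}:
        raise ValueError(f"unrecognized chromosome label: {label!r}")
    return s


@dataclass(frozen=True)
class VariantSpec:
    """A biallelic variant with a designated effect allele.

    ``maf`` is the effect-allele frequency as a fraction.  It is usually the
    minor allele (<= 0.5) but may exceed 0.5 when the effect allele happens
    to be major in a given population.  Alleles may be multi-base strings
    (indels); for an insertion the effect allele can be written either as the
    full VCF ALT sequence or as the inserted bases alone.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float = 0.0
    gene: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.rsid}: maf must be in [0, 1], got {self.maf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.effect_allele or not self.other_allele:
            raise ValueError(f"{self.rsid}: alleles must be non-empty")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be 1-based positive")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def with_maf(self, maf: float) -> "VariantSpec":
        d = asdict(self)
        d["maf"] = maf
        return VariantSpec(**d)


# Positions are GRCh37 dbSNP coordinates; the pipeline matches on rsid and is
# genome-build agnostic.
DEFAULT_PANEL: tuple[VariantSpec, ...] = (
    VariantSpec("rs77031559", "3", 51283523, "G", "A", 0.06, gene="DOCK3"),
    VariantSpec("rs190930099", "6", 152061247, "G", "A", 0.016, gene="ESR1"),
    VariantSpec("rs34706136", "9", 4286116, "TTG", "T", 0.45, gene="GLIS3"),
    VariantSpec("rs850294", "11", 123394507, "T", "C", 0.107, gene="GRAMD1B"),
    VariantSpec("rs62260729", "3", 49869051, "C", "T", 0.396, gene="TRAIP"),
)

#: Effect-allele frequencies in the elite power-athlete group (fractions).
ATHLETE_MAF: dict[str, float] = {
    "rs77031559": 0.060,
    "rs190930099": 0.016,
    "rs34706136": 0.450,
    "rs850294": 0.107,
    "rs62260729": 0.396,
}

#: Effect-allele frequencies in the non-athlete control group (fractions).
#: ESR1 rs190930099 G was absent from controls; a zero frequency is legal
#: everywhere in the pipeline.
CONTROL_MAF: dict[str, float] = {
    "rs77031559": 0.063,
    "rs190930099": 0.000,
    "rs34706136": 0.430,
    "rs850294": 0.093,
    "rs62260729": 0.351,
}

TRAITS = ("testosterone", "csa_fast_twitch", "handgrip", "fat_free_mass")

# Per-variant published association results: (testosterone beta, P),
# (CSA um^2 beta, P), (handgrip beta, P), (fat-free mass beta, P).
_REPORTED = {
    "rs190930099": ((0.135, 8.1e-11), (2123.1, 0.028), (0.367, 0.0024), (0.485, 0.0000013)),
    "rs34706136": ((0.012, 2.7e-8), (361.1, 0.044), (0.09, 0.0000015), (0.02, 0.011)),
    "rs62260729": ((0.014, 3.0e-10), (407.8, 0.033), (0.048, 0.011), (0.054, 0.00067)),
    "rs77031559": ((0.027, 9.2e-9), (939.5, 0.016), (0.072, 0.045), (0.101, 0.0007)),
    "rs850294": ((0.034, 5.2e-18), (824.8, 0.011), (0.055, 0.0499), (0.025, 0.038)),
}


def reported_associations() -> pd.DataFrame:
    """Published per-trait association results for the five-variant panel.

    Returns a long-format summary-statistics table with one row per
    (variant, trait): columns ``rsid``, ``gene``, ``trait``, ``effect_allele``,
    ``beta``, ``p``.  Betas are in trait units per effect-allele copy
    (CSA in um^2).
    """
    by_rsid = {v.rsid: v for v in DEFAULT_PANEL}
    rows = []
    for rsid, stats in _REPORTED.items():
        v = by_rsid[rsid]
        for trait, (beta, p) in zip(TRAITS, stats):
            rows.append(
                {
                    "rsid": rsid,
                    "gene": v.gene,
                    "trait": trait,
                    "effect_allele": v.effect_allele,
                    "beta": beta,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def panel_with_mafs(mafs: dict[str, float]) -> list[VariantSpec]:
    """Return the default panel with effect-allele frequencies replaced."""
    missing = [v.rsid for v in DEFAULT_PANEL if v.rsid not in mafs]
    if missing:
        raise KeyError(f"no frequency given for: {', '.join(missing)}")
    return [v.with_maf(mafs[v.rsid]) for v in DEFAULT_PANEL]
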