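"""Reading and writing the pipeline's file formats.

Genotypes travel as VCF (diploid GT field) or as a plain TSV dosage table
(individuals x variants, effect-allele dosage 0/1/2, '.' for missing);
summary statistics and phenotype/covariate tables are TSV with a header.
All TSV output is tab-separated UTF-8 with '.' for missing values and a
stable column order, so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import VariantSpec, normalize_chrom

logger = logging.getLogger(__name__)

MISSING = "."

__all__ = [
    "GenotypeTable",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_summary_stats",
    "read_phenotypes",
    "write_results",
]


@dataclass
class GenotypeTable:
    """Individuals x variants matrix of effect-allele dosages.

    ``dosages`` is a float array with values in {0, 1, 2} or NaN for missing.
    Row order follows ``individual_ids``, column order follows ``variants``.
    """

    individual_ids: list[str]
    variants: list[VariantSpec]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.individual_ids)} individuals and {len(self.variants)} variants"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != m:
            raise ValueError("duplicate rsids in panel")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame indexed by individual id, one column per rsid."""
        return pd.DataFrame(self.dosages, index=self.individual_ids, columns=self.rsids)

    def subset(self, rsids: Sequence[str]) -> "GenotypeTable":
        idx = {v.rsid: j for j, v in enumerate(self.variants)}
        missing = [r for r in rsids if r not in idx]
        if missing:
            raise KeyError(f"variants absent from genotypes: {', '.join(missing)}")
        cols = [idx[r] for r in rsids]
        return GenotypeTable(
            list(self.individual_ids),
            [self.variants[j] for j in cols],
            self.dosages[:, cols],
        )


def _match_effect_allele(ref: str, alts: Sequence[str], effect: str, rsid: str) -> int | None:
    """Index of the effect allele among [ref, *alts] (0 = ref), or None.

    An insertion effect allele may be written either as the full ALT string
    (e.g. 'TTG') or as the inserted bases alone (e.g. 'TG' against REF 'T').
    """
    alleles = [ref, *alts]
    if effect in alleles:
        return alleles.index(effect)
    for j, alt in enumerate(alts, start=1):
        if alt.startswith(ref) and alt[len(ref):] == effect:
            return j
    return None


def read_vcf(path: str | Path, effect_allele_map: Mapping[str, str]) -> GenotypeTable:
    """Read diploid genotypes from a VCF, counting copies of each effect allele.

    Only variants whose rsid appears in ``effect_allele_map`` are loaded.
    The effect allele may be REF or any ALT (multi-allelic records count only
    the named allele; everything else is non-effect).  './.' genotypes become
    missing dosages.  Mapped rsids absent from the file are reported in a
    warning and skipped.
    """
    from cyvcf2 import VCF

    ids: list[str] | None = None
    variants: list[VariantSpec] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    for rec in vcf:
        rsid = rec.ID
        if rsid is None or rsid not in effect_allele_map:
            continue
        seen.add(rsid)
        effect = effect_allele_map[rsid]
        eidx = _match_effect_allele(rec.REF, rec.ALT, effect, rsid)
        if eidx is None:
            raise ValueError(
                f"{rsid}: effect allele {effect!r} matches neither REF {rec.REF!r} "
                f"nor ALT {rec.ALT!r}"
            )
        col = np.full(len(ids), np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2:
                raise ValueError(f"{rsid}: non-diploid genotype for sample {ids[i]}")
            if any(a < 0 for a in alleles):
                continue
            col[i] = sum(1 for a in alleles if a == eidx)
        other = rec.REF if eidx != 0 else (rec.ALT[0] if rec.ALT else "N")
        variants.append(
            VariantSpec(rsid, rec.CHROM, rec.POS, [rec.REF, *rec.ALT][eidx], other)
        )
        columns.append(col)
    vcf.close()

    absent = sorted(set(effect_allele_map) - seen)
    if absent:
        logger.warning("variants absent from %s: %s", path, ", ".join(absent))
    dosages = np.column_stack(columns) if columns else np.empty((len(ids), 0))
    return GenotypeTable(ids, variants, dosages)


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write genotypes as a minimal VCF 4.2 with diploid GT fields.

    REF is each variant's other allele and ALT its effect allele, so a
    dosage d round-trips as the genotype carrying d ALT copies.
    """
    path = Path(path)
    order = sorted(
        range(len(table.variants)),
        key=lambda j: (
            (0, int(table.variants[j].chrom)) if table.variants[j].chrom.isdigit()
            else (1, 0),
            table.variants[j].pos,
        ),
    )
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(table.variants[j].chrom for j in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individual_ids)
            + "\n"
        )
        for j in order:
            v = table.variants[j]
            calls = [
                gt_of[d] if not np.isnan(d) else "./."
                for d in table.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.other_allele}\t{v.effect_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(table: GenotypeTable, path: str | Path) -> None:
    df = table.to_frame()
    out = df.map(lambda d: MISSING if np.isnan(d) else str(int(d)))
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path, variants: Sequence[VariantSpec] | None = None) -> GenotypeTable:
    """Read a TSV dosage table (rows = individuals, columns = rsids).

    If ``variants`` is omitted, placeholder variant records (chrom 1, unknown
    alleles) are synthesized from the column names.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""], dtype=str)
    dosages = df.apply(pd.to_numeric).to_numpy(dtype=float)
    if variants is None:
        variants = [
            VariantSpec(rsid, "1", j + 1, "E", "O") for j, rsid in enumerate(df.columns)
        ]
    else:
        by_rsid = {v.rsid: v for v in variants}
        missing = [c for c in df.columns if c not in by_rsid]
        if missing:
            raise KeyError(f"no VariantSpec for columns: {', '.join(missing)}")
        variants = [by_rsid[c] for c in df.columns]
    return GenotypeTable([str(i) for i in df.index], list(variants), dosages)


REQUIRED_SUMSTAT_COLUMNS = ("rsid", "trait", "effect_allele", "beta", "p")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a long-format summary-statistics TSV into typed records.

    Required columns: rsid, trait, effect_allele, beta, p.  Optional: sex
    (male/female stratum), se.  Rows with unparseable beta/p, or p outside
    (0, 1], are rejected with their line numbers in a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, ""])
    missing = [c for c in REQUIRED_SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file missing column(s): {', '.join(missing)}")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    p = pd.to_numeric(df["p"], errors="coerce")
    bad = beta.isna() | p.isna() | (p <= 0) | (p > 1) | df["effect_allele"].isna()
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        logger.warning(
            "rejected %d summary-statistic row(s) at line(s): %s",
            bad.sum(), ", ".join(lines),
        )
    out = df.loc[~bad].copy()
    out["beta"] = beta[~bad]
    out["p"] = p[~bad]
    if "se" in out.columns:
        out["se"] = pd.to_numeric(out["se"], errors="coerce")
    return out.reset_index(drop=True)


def read_phenotypes(
    path: str | Path,
    id_column: str = "id",
    categorical_levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Read a phenotype/covariate TSV indexed by individual id.

    Missing values ('.' or empty) are retained as NaN and handled listwise by
    each analysis.  ``categorical_levels`` maps a column to its allowed labels;
    such columns are label-encoded as integer codes in level order, and an
    unknown label raises with the allowed set.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING, ""])
    if id_column not in df.columns:
        raise ValueError(f"phenotype file has no {id_column!r} column")
    if df[id_column].duplicated().any():
        dups = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate individual ids: {dups}")
    df = df.set_index(id_column)
    for col, levels in (categorical_levels or {}).items():
        if col not in df.columns:
            raise ValueError(f"categorical column {col!r} not present")
        observed = df[col].dropna()
        unknown = sorted(set(observed) - set(levels))
        if unknown:
            raise ValueError(
                f"unknown {col!r} label(s) {unknown}; allowed: {list(levels)}"
            )
        df[col] = pd.Categorical(df[col], categories=levels).codes
        df.loc[df[col] == -1, col] = np.nan
    return df


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as <name>.tsv under out_dir; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep=MISSING)
        logger.info("wrote %s (%d rows)", p, len(df))
        paths.append(p)
    return paths
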