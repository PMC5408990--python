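"""Readers and writers for the pipeline's tabular formats.

All interchange is plain TSV with headers (SNP weight tables, carrier
cohort tables, incidence curves, genotype dosage matrices, result tables);
genotypes may alternatively come from a VCF, preferring the ``DS`` dosage
FORMAT field and falling back to ``GT`` allele counts.  Readers validate
invariants and raise :class:`FormatError` naming the offending row or
column; writers emit deterministic column order and six significant digits
so that read -> write -> read is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .incidence import IncidenceCurve

WEIGHT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_allele_freq",
    "weight",
    "phenotype_tag",
]
PHENOTYPE_TAGS = {"overall_bc", "er_pos_bc", "er_neg_bc", "oc", "custom"}

COHORT_COLUMNS = ["individual_id", "family_id", "study", "gene", "affected", "age_end"]
GENES = {"BRCA1", "BRCA2"}

RESULT_COLUMNS = [
    "term",
    "estimate",
    "se",
    "robust_se",
    "hr",
    "ci_low",
    "ci_high",
    "p_one_sided",
    "p_two_sided",
]


class FormatError(ValueError):
    """A file failed validation; the message names the offending row/column."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants, values in [0, 2], NaN = missing).

    ``counted_allele`` records, per variant, which allele the dosages count
    (the VCF ALT for VCF input); ``None`` means the file carries no allele
    labels and dosages are assumed to count the weight table's effect allele.
    """

    dosages: pd.DataFrame
    counted_allele: Optional[dict] = None

    @property
    def individual_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list:
        return list(self.dosages.columns)


def _require_columns(df: pd.DataFrame, required, path, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: {what} is missing column(s) {missing}")


def read_weight_table(path) -> pd.DataFrame:
    """Read and validate a SNP weight table (per-allele log risk ratios)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    _require_columns(df, WEIGHT_COLUMNS, path, "weight table")
    df = df[WEIGHT_COLUMNS].copy()

    dup = df["variant_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{path}: duplicate variant_id {df['variant_id'].iloc[row]!r} at row {row}"
        )
    for col, ok in [
        ("pos", lambda s: (s > 0) & (s == s.astype(int))),
        ("weight", lambda s: np.isfinite(s)),
        ("effect_allele_freq", lambda s: (s > 0) & (s < 1)),
    ]:
        vals = pd.to_numeric(df[col], errors="coerce")
        good = vals.notna() & ok(vals.astype(float))
        if not good.all():
            row = int(np.flatnonzero(~good.to_numpy())[0])
            raise FormatError(
                f"{path}: invalid {col} value {df[col].iloc[row]!r} at row {row}"
            )
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        row = int(np.flatnonzero(same.to_numpy())[0])
        raise FormatError(
            f"{path}: effect_allele equals other_allele at row {row} "
            f"({df['variant_id'].iloc[row]!r})"
        )
    bad_tag = ~df["phenotype_tag"].isin(PHENOTYPE_TAGS)
    if bad_tag.any():
        row = int(np.flatnonzero(bad_tag.to_numpy())[0])
        raise FormatError(
            f"{path}: unknown phenotype_tag {df['phenotype_tag'].iloc[row]!r} "
            f"at row {row} (expected one of {sorted(PHENOTYPE_TAGS)})"
        )
    df["pos"] = df["pos"].astype(int)
    df["effect_allele_freq"] = df["effect_allele_freq"].astype(float)
    df["weight"] = df["weight"].astype(float)
    return df


def write_weight_table(path, table: pd.DataFrame) -> None:
    _format_table(table[WEIGHT_COLUMNS]).to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype dosage matrix from TSV or VCF.

    dosage_tsv: individuals as rows (first column ``individual_id``),
    variant ids as columns.  vcf: ``DS`` preferred, else ``GT`` converted to
    the ALT allele count; missing genotypes become NaN, never zero.
    """
    if format == "dosage_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
        if "individual_id" not in df.columns:
            raise FormatError(f"{path}: dosage matrix is missing column 'individual_id'")
        df = df.set_index("individual_id")
        mat = df.apply(pd.to_numeric, errors="coerce").astype(float)
        notna = mat.notna().to_numpy()
        out_of_range = notna & (
            (mat.to_numpy() < -1e-6) | (mat.to_numpy() > 2 + 1e-6)
        )
        if out_of_range.any():
            i, j = map(int, np.argwhere(out_of_range)[0])
            raise FormatError(
                f"{path}: dosage {mat.iloc[i, j]!r} outside [0, 2] for individual "
                f"{mat.index[i]!r}, variant {mat.columns[j]!r}"
            )
        # raw text that failed numeric conversion (as opposed to empty cells)
        raw_missing = df.isna().to_numpy()
        silently_coerced = mat.isna().to_numpy() & ~raw_missing
        if silently_coerced.any():
            i, j = map(int, np.argwhere(silently_coerced)[0])
            raise FormatError(
                f"{path}: non-numeric dosage {df.iloc[i, j]!r} for individual "
                f"{df.index[i]!r}, variant {df.columns[j]!r}"
            )
        return GenotypeMatrix(mat.clip(0.0, 2.0))
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, alts, rows = [], {}, []
    for i, var in enumerate(vcf):
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise FormatError(
                f"{path}: variant {vid} (record {i}) is not biallelic"
            )
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
            dose = np.where((dose < -1) | (dose > 3), np.nan, dose)
            if np.nanmax(dose, initial=0.0) > 2 + 1e-6 or np.nanmin(dose, initial=0.0) < -1e-6:
                raise FormatError(f"{path}: DS outside [0, 2] for variant {vid}")
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            dose = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        ids.append(vid)
        alts[vid] = var.ALT[0]
        rows.append(dose)
    if not ids:
        raise FormatError(f"{path}: VCF contains no variant records")
    mat = pd.DataFrame(np.column_stack(rows), index=samples, columns=ids)
    mat.index.name = "individual_id"
    return GenotypeMatrix(mat, counted_allele=alts)


def write_genotypes(path, genotypes: GenotypeMatrix) -> None:
    out = genotypes.dosages.copy()
    out.index.name = "individual_id"
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a carrier phenotype table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"individual_id": str, "family_id": str, "study": str}
    )
    _require_columns(df, COHORT_COLUMNS, path, "cohort table")
    if "age_entry" not in df.columns:
        df["age_entry"] = 18.0
    df = df[COHORT_COLUMNS + ["age_entry"]].copy()

    dup = df["individual_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{path}: duplicate individual_id {df['individual_id'].iloc[row]!r} at row {row}"
        )
    bad_gene = ~df["gene"].isin(GENES)
    if bad_gene.any():
        row = int(np.flatnonzero(bad_gene.to_numpy())[0])
        raise FormatError(
            f"{path}: gene must be BRCA1 or BRCA2, got {df['gene'].iloc[row]!r} at row {row}"
        )
    if not df["affected"].isin([0, 1, True, False]).all():
        row = int(np.flatnonzero(~df["affected"].isin([0, 1, True, False]).to_numpy())[0])
        raise FormatError(
            f"{path}: affected must be 0/1, got {df['affected'].iloc[row]!r} at row {row}"
        )
    df["affected"] = df["affected"].astype(bool)
    for col in ("age_end", "age_entry"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    bad_end = ~((df["age_end"] > 18) & (df["age_end"] <= 100))
    if bad_end.any():
        row = int(np.flatnonzero(bad_end.to_numpy())[0])
        raise FormatError(
            f"{path}: age_end must lie in (18, 100], got {df['age_end'].iloc[row]!r} at row {row}"
        )
    bad_order = df["age_entry"] >= df["age_end"]
    if bad_order.any():
        row = int(np.flatnonzero(bad_order.to_numpy())[0])
        raise FormatError(
            f"{path}: age_entry >= age_end at row {row} "
            f"(individual {df['individual_id'].iloc[row]!r})"
        )
    if (df["age_entry"] < 18).any():
        row = int(np.flatnonzero((df["age_entry"] < 18).to_numpy())[0])
        raise FormatError(f"{path}: age_entry below 18 at row {row}")
    return df


def write_cohort(path, cohort: pd.DataFrame) -> None:
    out = cohort[COHORT_COLUMNS + ["age_entry"]].copy()
    out["affected"] = out["affected"].astype(int)
    _format_table(out).to_csv(path, sep="\t", index=False)


def read_incidence(path) -> IncidenceCurve:
    """Read an average-carrier incidence curve (columns: age, rate)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["age", "rate"], path, "incidence curve")
    age = pd.to_numeric(df["age"], errors="coerce")
    rate = pd.to_numeric(df["rate"], errors="coerce")
    bad = age.isna() | rate.isna() | (rate < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: invalid incidence row {row} "
            f"(age {df['age'].iloc[row]!r}, rate {df['rate'].iloc[row]!r})"
        )
    try:
        return IncidenceCurve(age.to_numpy(float), rate.to_numpy(float))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_incidence(path, curve: IncidenceCurve) -> None:
    pd.DataFrame({"age": curve.age, "rate": curve.hazard}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_results(path, records: pd.DataFrame) -> None:
    """Write a tidy one-row-per-estimate result table."""
    out = records.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    _format_table(out[RESULT_COLUMNS]).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["term", "estimate"], path, "result table")
    return df


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Round floats to 6 significant digits for deterministic round-trips."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda x: float(f"{x:.6g}") if np.isfinite(x) else x
            )
    return out
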