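"""Containers and file I/O for genotype, expression and phenotype data.

Genotypes are held as additive dosages (count of the VCF ALT allele, 0/1/2,
NaN for missing), expression as an individuals x probes real matrix, and
phenotypes as a long table with one record per (individual, visit, trait).
SNP-level quality control (minor-allele-frequency and missingness filters)
lives here too.

Formats: VCF v4.x (GT field only) via cyvcf2, and plain tab-separated text
for dosage, expression and phenotype tables. Missing cells are written "NA".
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "individual_id",
    "time_point",
    "trait",
    "value",
    "age",
    "sex",
    "medication",
    "smoking",
]


def _check_unique(ids: Sequence, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``dosages`` is float with entries in {0, 1, 2} or NaN (missing);
    ``snp_meta`` has columns ``id``, ``chrom``, ``pos``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("row count of dosages != number of sample_ids")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("column count of dosages != number of snp_meta records")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(list(self.snp_meta["id"]), "snp ids")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["id"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)

    def save(self, path: Union[str, Path], meta_path: Union[str, Path, None] = None) -> None:
        """Write the dosage TSV dialect (rows = individuals, header = SNP ids).

        SNP positions go to ``meta_path`` (default: ``<path>`` with suffix
        ``.meta.tsv``) so that save -> load is the identity.
        """
        path = Path(path)
        df = self.to_frame()
        df.index.name = "individual_id"
        df.to_csv(path, sep="\t", na_rep="NA")
        mp = Path(meta_path) if meta_path is not None else path.with_suffix(".meta.tsv")
        self.snp_meta.to_csv(mp, sep="\t", index=False)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency on non-missing entries, folded to <= 0.5."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_alt = np.nanmean(self.dosages, axis=0) / 2.0
        p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
        return np.minimum(p_alt, 1.0 - p_alt)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosages), axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, keep], self.snp_meta.iloc[np.where(keep)[0]], self.sample_ids
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(self.dosages[idx, :], self.snp_meta, list(ids))


@dataclasses.dataclass
class ExpressionMatrix:
    """Individuals x probes expression matrix; no missing values after loading."""

    values: np.ndarray
    probe_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count of values != number of sample_ids")
        if self.values.shape[1] != len(self.probe_meta):
            raise ValueError("column count of values != number of probe records")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(list(self.probe_meta["probe_id"]), "probe ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing values")
        self.probe_meta = self.probe_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probe_meta["probe_id"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    def save(self, path: Union[str, Path]) -> None:
        df = self.to_frame()
        df.index.name = "individual_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return ExpressionMatrix(self.values[idx, :], self.probe_meta, list(ids))

    def probe_vector(self, probe_id: str) -> np.ndarray:
        j = self.probe_ids.index(probe_id)
        return self.values[:, j]


@dataclasses.dataclass
class PhenotypeTable:
    """Long-format phenotype records with covariates.

    One row per (individual, time point, trait); covariate columns are
    age (years), sex (0/1), medication (0/1) and smoking (0/1). Sex must be
    constant within an individual; age may vary by visit.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        self.data = self.data[PHENOTYPE_COLUMNS].reset_index(drop=True)
        self.data["individual_id"] = self.data["individual_id"].astype(str)
        key = self.data[["individual_id", "time_point", "trait"]]
        if key.duplicated().any():
            raise ValueError("(individual, time_point, trait) keys must be unique")
        sex_n = self.data.groupby("individual_id")["sex"].nunique()
        if (sex_n > 1).any():
            raise ValueError("sex must be constant within individual")

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def individual_ids(self) -> list[str]:
        return list(pd.unique(self.data["individual_id"]))

    def sex_by_individual(self) -> pd.Series:
        return self.data.groupby("individual_id", sort=False)["sex"].first()

    def save(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_genotypes(path: Union[str, Path], format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from a VCF (``format="vcf"``) or dosage TSV.

    VCF GT calls 0/0, 0/1, 1/1 map to dosages 0, 1, 2 (ALT-allele count);
    missing calls map to NaN. Records that are not biallelic SNVs are skipped
    with a logged warning.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "dosage_tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "dosage_tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'vcf' or 'dosage_tsv')")


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta = [], []
    # cyvcf2 gt_types: 0 = hom-ref, 1 = het, 3 = hom-alt, 2 = unknown
    code = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            log.warning("skipping non-biallelic record %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
            continue
        cols.append([code[int(t)] for t in rec.gt_types])
        meta.append((rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS))
    if not cols:
        raise ValueError(f"no biallelic records parsed from {path}")
    dosages = np.array(cols, dtype=float).T
    snp_meta = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(dosages, snp_meta, samples)


def _load_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed dosage TSV {path}: {exc}") from exc
    meta_path = Path(path).with_suffix(".meta.tsv")
    if meta_path.exists():
        snp_meta = pd.read_csv(meta_path, sep="\t")
    else:
        snp_meta = pd.DataFrame({"id": df.columns, "chrom": "NA", "pos": 0})
    return GenotypeMatrix(df.to_numpy(dtype=float), snp_meta, [str(s) for s in df.index])


def load_expression(path: Union[str, Path], impute_missing: bool = False) -> ExpressionMatrix:
    """Load an individuals x probes expression TSV.

    Missing cells are rejected unless ``impute_missing`` is set, in which case
    each probe's missing entries are replaced by the probe mean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        if not impute_missing:
            raise ValueError(
                f"expression matrix {path} has missing values "
                "(pass impute_missing=True to mean-impute per probe)"
            )
        col_mean = np.nanmean(vals, axis=0)
        ind = np.where(~np.isfinite(vals))
        vals[ind] = col_mean[ind[1]]
    probe_meta = pd.DataFrame({"probe_id": df.columns})
    return ExpressionMatrix(vals, probe_meta, [str(s) for s in df.index])


def load_phenotypes(path: Union[str, Path]) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return PhenotypeTable(df)


def snp_qc(
    g: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.05
) -> tuple[GenotypeMatrix, dict]:
    """Remove SNPs with folded MAF < ``maf_min``, then missingness > ``miss_max``.

    Returns the filtered panel and a QC report with the count removed by each
    filter (applied in that order).
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= miss_max <= 1.0:
        raise ValueError("miss_max must be in [0, 1]")
    maf = g.maf()
    keep_maf = maf >= maf_min
    n_maf = int((~keep_maf).sum())
    g1 = g.subset_snps(keep_maf) if n_maf else g
    miss = g1.missing_fraction()
    keep_miss = miss <= miss_max
    n_miss = int((~keep_miss).sum())
    g2 = g1.subset_snps(keep_miss) if n_miss else g1
    if g2.n_snps == 0:
        raise ValueError("empty panel: all SNPs removed by QC")
    report = {
        "n_input": g.n_snps,
        "removed_maf": n_maf,
        "removed_missingness": n_miss,
        "n_retained": g2.n_snps,
        "maf_min": maf_min,
        "miss_max": miss_max,
    }
    return g2, report


def align_samples(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    p: Union[pd.Series, "object"],
) -> tuple[GenotypeMatrix, ExpressionMatrix, pd.Series]:
    """Restrict all inputs to the shared individuals, in genotype order.

    ``p`` may be a pandas Series indexed by individual id or any object with a
    ``.series`` attribute holding one (an adjusted phenotype).
    """
    series = p if isinstance(p, pd.Series) else p.series
    e_ids = set(e.sample_ids)
    p_ids = set(series.index.astype(str))
    shared = [s for s in g.sample_ids if s in e_ids and s in p_ids]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} individuals shared across inputs (need >= 3)")
    return g.subset_samples(shared), e.subset_samples(shared), series.loc[shared].astype(float)
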