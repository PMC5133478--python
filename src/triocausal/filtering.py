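"""Association-scan filtering: from all (SNP, probe) pairs to candidate trios.

Two OLS scans in sequence: probes against the adjusted phenotype, then — for
probes that pass — a genome-wide scan of every SNP against that probe's
expression. Pairs clearing the -log10 p threshold (strictly greater than,
default 5) at both stages become trios for causal modelling.

The scans are plain OLS slope t-tests on unrelated individuals; a
kinship-adjusted mixed model would replace them for family data (hook: any
scan producing the same result table slots in).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from ._regression import slope_test
from .data_io import ExpressionMatrix, GenotypeMatrix
from .phenotype import AdjustedPhenotype

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 5.0


@dataclasses.dataclass
class AssociationScanResult:
    """Per-unit association results, sorted by -log10 p descending."""

    table: pd.DataFrame  # id, beta, se, p, mlog10p, n
    kind: str  # "probe~phenotype" or "snp~probe"
    threshold: float | None = None

    def passing(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.threshold if threshold is None else threshold
        return self.table[self.table["mlog10p"] > thr]

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclasses.dataclass
class Trio:
    """One aligned (SNP dosage, expression, phenotype) triple."""

    snp_id: str
    dosage: np.ndarray
    expression_id: str
    expression: np.ndarray
    phenotype_name: str
    phenotype: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.dosage) == len(self.expression) == len(self.phenotype) == n):
            raise ValueError("trio vectors must share the aligned sample set")
        if n < 3:
            raise ValueError("trio needs at least 3 individuals")
        if not np.isin(self.dosage, (0.0, 1.0, 2.0)).all():
            raise ValueError("trio dosages must be complete and in {0, 1, 2}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _scan(X: np.ndarray, y: np.ndarray, ids: Sequence[str], kind: str) -> AssociationScanResult:
    beta, se, p, mlog10p, n_used = slope_test(X, y)
    n_degenerate = int(np.isnan(beta).sum())
    if n_degenerate:
        log.warning("%d degenerate (zero-variance) units in %s scan set to p=1", n_degenerate, kind)
    table = pd.DataFrame(
        {"id": list(ids), "beta": beta, "se": se, "p": p, "mlog10p": mlog10p, "n": n_used}
    )
    table = table.sort_values("mlog10p", ascending=False, kind="mergesort").reset_index(drop=True)
    return AssociationScanResult(table=table, kind=kind)


def probe_phenotype_scan(
    e: ExpressionMatrix, y: Union[AdjustedPhenotype, pd.Series, np.ndarray]
) -> AssociationScanResult:
    """OLS of the adjusted phenotype on each (sex-corrected) probe."""
    if isinstance(y, AdjustedPhenotype):
        yv = y.aligned(e.sample_ids)
    elif isinstance(y, pd.Series):
        yv = y.loc[e.sample_ids].to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if len(yv) != e.n_samples:
        raise ValueError("phenotype not aligned with expression samples")
    if len(yv) < 3:
        raise ValueError("need at least 3 individuals")
    return _scan(e.values, yv, e.probe_ids, "probe~phenotype")


def snp_probe_gwas(g: GenotypeMatrix, x: np.ndarray) -> AssociationScanResult:
    """OLS of an expression (or eigengene) vector on each SNP's dosage.

    Missing dosages are handled by pairwise-complete deletion per SNP;
    SNPs monomorphic in the analysed sample get p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != g.n_samples:
        raise ValueError("expression vector not aligned with genotype samples")
    return _scan(g.dosages, x, g.snp_ids, "snp~probe")


def select_trios(
    probe_scan: AssociationScanResult,
    gwas_scans: Mapping[str, AssociationScanResult],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    genotypes: GenotypeMatrix,
    expression_vectors: Mapping[str, np.ndarray],
    phenotype: np.ndarray,
    phenotype_name: str,
    sample_ids: Sequence[str],
) -> list[Trio]:
    """Form the deduplicated trio list from two passed scan stages.

    Probes with -log10 p strictly above ``threshold`` enter stage two; each
    of their SNPs above the same threshold yields one trio. Ordering is
    deterministic: probe rank, then SNP rank within probe. Individuals with
    a missing dosage for a trio's SNP are dropped from that trio.
    """
    if threshold <= 0 and threshold != 0.0:
        raise ValueError("threshold must be >= 0")
    phenotype = np.asarray(phenotype, dtype=float)
    sample_ids = [str(s) for s in sample_ids]
    trios: list[Trio] = []
    seen: set[tuple[str, str]] = set()
    dos = genotypes.to_frame()
    for probe_id in probe_scan.passing(threshold)["id"]:
        if probe_id not in gwas_scans:
            continue
        for snp_id in gwas_scans[probe_id].passing(threshold)["id"]:
            key = (snp_id, probe_id)
            if key in seen:
                continue
            seen.add(key)
            d = dos.loc[sample_ids, snp_id].to_numpy(dtype=float)
            keep = np.isfinite(d)
            trios.append(
                Trio(
                    snp_id=snp_id,
                    dosage=d[keep],
                    expression_id=probe_id,
                    expression=np.asarray(expression_vectors[probe_id], dtype=float)[keep],
                    phenotype_name=phenotype_name,
                    phenotype=phenotype[keep],
                    sample_ids=tuple(np.asarray(sample_ids)[keep]),
                )
            )
    if not trios:
        log.info("no (SNP, probe) pair passed the threshold %.3g; empty trio list", threshold)
    return trios
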