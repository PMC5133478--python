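"""End-to-end orchestration: QC -> adjustment -> filtering -> causal modelling.

``run_pipeline`` chains the stages in one of two modes:

* ``probe_filtering`` — probe~phenotype scan, then per-probe SNP scans, trios
  from pairs clearing the -log10 p threshold;
* ``wgcna`` — coexpression modules, Bonferroni-significant module eigengenes
  as the expression measure, SNP scan per significant eigengene.

Each retained trio is scored by both SEM/AIC and Bayes-factor partition
selection; the report has one row per trio with both labels, their agreement
flag, the BUF margin and the SEM tie set. A manifest records the full config,
seed and input checksums so a run is reproducible byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .buf import DEFAULT_SIGMA_GRID, select_buf
from .data_io import (
    align_samples,
    load_expression,
    load_genotypes,
    load_phenotypes,
    snp_qc,
)
from .filtering import (
    DEFAULT_THRESHOLD,
    AssociationScanResult,
    Trio,
    probe_phenotype_scan,
    select_trios,
    snp_probe_gwas,
)
from .phenotype import DEFAULT_COVARIATES, adjust_phenotype, correct_for_sex
from .sem import select_sem
from .wgcna import NetworkConfig, build_modules, module_trait_association

log = logging.getLogger(__name__)

MODES = ("probe_filtering", "wgcna")


@dataclasses.dataclass
class RunConfig:
    """Losslessly serialisable configuration of a pipeline run."""

    genotypes: str
    expression: str
    phenotypes: str
    outdir: str = "triocausal_out"
    genotype_format: str | None = None
    trait: str = "SBP"
    covariates: Sequence[str] = DEFAULT_COVARIATES
    pool_time_points: bool = False
    maf_min: float = 0.01
    miss_max: float = 0.05
    filter_threshold: float = DEFAULT_THRESHOLD
    soft_power: int = 6
    min_module_size: int = 10
    cut_height: float = 0.95
    module_alpha: float = 0.05
    model_set: str = "all"
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID
    seed: int = 0

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            soft_power=self.soft_power,
            min_module_size=self.min_module_size,
            cut_height=self.cut_height,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["sigma_grid"] = [float(s) for s in self.sigma_grid]
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def variance_explained(x: np.ndarray, y: Union[np.ndarray, "object"]) -> float:
    """R^2 of the OLS of y on intercept + x (equals squared Pearson r)."""
    x = np.asarray(x, dtype=float)
    yv = np.asarray(y.series if hasattr(y, "series") else y, dtype=float)
    if len(x) != len(yv) or len(x) < 3:
        raise ValueError("x and y must be aligned with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    xc = x - x.mean()
    yc = yv - yv.mean()
    syy = float(yc @ yc)
    if syy == 0:
        return 0.0
    beta = float(xc @ yc) / float(xc @ xc)
    rss = syy - beta * float(xc @ yc)
    return float(1.0 - rss / syy)


def score_trio(trio: Trio, model_set: str = "all",
               sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID) -> dict:
    """SEM + BUF selection for one trio, as a report-row dict."""
    sem = select_sem(trio, model_set)
    buf = select_buf(trio, sigma_grid)
    return {
        "snp": trio.snp_id,
        "expression_id": trio.expression_id,
        "phenotype": trio.phenotype_name,
        "n": trio.n,
        "sem_model": sem.selected,
        "buf_model": buf.model,
        "agree": sem.selected == buf.model,
        "buf_margin": buf.margin,
        "buf_near_tie": buf.near_tie,
        "sem_ties": "|".join(sem.tie_set),
        "sem_table": sem.table,
        "buf_table": buf.table,
    }


def _report_frame(rows: list[dict], snp_meta: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "snp", "chrom", "pos", "expression_id", "phenotype", "n",
        "sem_model", "buf_model", "agree", "buf_margin", "buf_near_tie", "sem_ties",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    meta = snp_meta.set_index("id")
    out = []
    for r in rows:
        rec = {k: r[k] for k in r if k not in ("sem_table", "buf_table")}
        rec["chrom"] = meta.loc[r["snp"], "chrom"] if r["snp"] in meta.index else "NA"
        rec["pos"] = meta.loc[r["snp"], "pos"] if r["snp"] in meta.index else 0
        out.append(rec)
    return pd.DataFrame(out)[cols]


def run_pipeline(cfg: RunConfig, mode: str = "probe_filtering") -> tuple[pd.DataFrame, dict]:
    """Execute the full pipeline; returns (report table, manifest dict).

    Writes ``report.tsv``, ``trios.json`` (full per-trio AIC/BF tables),
    scan tables and ``run_manifest.json`` under ``cfg.outdir``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("load")
        genotypes = load_genotypes(cfg.genotypes, cfg.genotype_format)
        expression = load_expression(cfg.expression)
        phenotypes = load_phenotypes(cfg.phenotypes)

        stage("snp_qc")
        genotypes, qc_report = snp_qc(genotypes, cfg.maf_min, cfg.miss_max)

        stage("adjust_phenotype")
        adjusted = adjust_phenotype(
            phenotypes, cfg.trait, cfg.covariates, pool_time_points=cfg.pool_time_points
        )

        stage("align")
        genotypes, expression, y = align_samples(genotypes, expression, adjusted)
        sex = phenotypes.sex_by_individual()
        expression = correct_for_sex(expression, sex)
        yv = y.to_numpy(dtype=float)

        stage(mode)
        if mode == "probe_filtering":
            probe_scan = probe_phenotype_scan(expression, yv)
            passing = list(probe_scan.passing(cfg.filter_threshold)["id"])
            gwas_scans = {
                pid: snp_probe_gwas(genotypes, expression.probe_vector(pid)) for pid in passing
            }
            vectors = {pid: expression.probe_vector(pid) for pid in passing}
            probe_scan.save(outdir / "probe_phenotype_scan.tsv")
        else:
            modules = build_modules(expression, cfg.network_config())
            assoc = (
                module_trait_association(
                    modules.eigengenes.set_axis(expression.sample_ids, axis=0),
                    {cfg.trait: y},
                    alpha=cfg.module_alpha,
                )
                if modules.labels
                else pd.DataFrame(columns=["module", "trait", "significant", "mlog10p"])
            )
            modules.assignment.rename_axis("probe_id").to_frame().to_csv(
                outdir / "modules.tsv", sep="\t"
            )
            if len(assoc):
                assoc.to_csv(outdir / "module_trait.tsv", sep="\t", index=False,
                             float_format="%.6g")
            sig = [m for m in assoc[assoc["significant"]]["module"]] if len(assoc) else []
            gwas_scans = {
                lab: snp_probe_gwas(genotypes, modules.eigengenes[lab].to_numpy())
                for lab in sig
            }
            vectors = {lab: modules.eigengenes[lab].to_numpy() for lab in sig}
            # every significant eigengene enters stage 2 unconditionally
            probe_scan = AssociationScanResult(
                table=pd.DataFrame(
                    {
                        "id": sig,
                        "beta": np.nan,
                        "se": np.nan,
                        "p": 0.0,
                        "mlog10p": np.inf,
                        "n": len(yv),
                    }
                ),
                kind="module~phenotype",
            )

        for pid, scan in gwas_scans.items():
            scan.save(outdir / f"gwas_{pid}.tsv")

        stage("select_trios")
        trios = select_trios(
            probe_scan,
            gwas_scans,
            cfg.filter_threshold,
            genotypes=genotypes,
            expression_vectors=vectors,
            phenotype=yv,
            phenotype_name=cfg.trait,
            sample_ids=genotypes.sample_ids,
        )

        stage("causal_modelling")
        rows = [score_trio(t, cfg.model_set, cfg.sigma_grid) for t in trios]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    report = _report_frame(rows, genotypes.snp_meta)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
    detail = [
        {
            "snp": r["snp"],
            "expression_id": r["expression_id"],
            "sem": r["sem_table"].drop(columns=["error"]).to_dict(orient="records"),
            "buf": r["buf_table"].to_dict(orient="records"),
        }
        for r in rows
    ]
    (outdir / "trios.json").write_text(json.dumps(detail, indent=1))

    manifest = {
        "version": __version__,
        "mode": mode,
        "config": cfg.to_dict(),
        "qc_report": qc_report,
        "n_trios": len(trios),
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("genotypes", cfg.genotypes),
                ("expression", cfg.expression),
                ("phenotypes", cfg.phenotypes),
            )
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
    return report, manifest


def concordance_summary(rows: pd.DataFrame) -> dict:
    """Cross-tabulate SEM and BUF labels over a report table.

    Returns agreement counts per label, the disagreement total, and counts
    of every (sem_model, buf_model) pair.
    """
    if rows.empty:
        raise ValueError("empty report table")
    pairs = Counter(zip(rows["sem_model"], rows["buf_model"]))
    agreement = {lab: c for (lab, buf), c in pairs.items() if lab == buf}
    n_disagree = sum(c for (s, b), c in pairs.items() if s != b)
    return {
        "n_trios": int(len(rows)),
        "agreement": dict(sorted(agreement.items())),
        "n_agree": int(len(rows)) - n_disagree,
        "n_disagree": int(n_disagree),
        "pairs": {f"{s}|{b}": int(c) for (s, b), c in sorted(pairs.items())},
    }
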