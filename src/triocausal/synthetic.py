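"""Synthetic trios and cohorts with the structure the causal analysis assumes.

Two generators:

* :func:`simulate_trio` draws one (dosage, expression, phenotype) triple under
  a named causal DAG with linear Gaussian effects — the unit for calibrating
  SEM/BUF model selection.
* :func:`simulate_cohort` builds a whole study: i.i.d. biallelic SNP dosages,
  an expression matrix with planted correlated modules (a one-factor model
  per module), and a longitudinal phenotype with covariates (age, sex,
  medication, smoking), optionally with one planted causal chain
  SNP -> module factor -> trait. The returned truth record carries every
  generative coefficient so downstream stages can be tested against it.

Unsimulated features of real cohorts (deliberately): family relatedness /
kinship, linkage disequilibrium between SNPs, and non-Gaussian expression
noise.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .sem import DAG_BY_LABEL, EDGE_GP, EDGE_PG, EDGE_SG, EDGE_SP


@dataclasses.dataclass
class TrioSpec:
    """Generative parameters for a single trio under one causal DAG.

    Effects are structural coefficients on the raw scale; the residual SDs
    ``sigma_g``/``sigma_p`` are the noise of the expression and phenotype
    equations. Effects on edges absent from ``dag_label`` must be zero.
    """

    dag_label: str = "null"
    n: int = 600
    maf: float = 0.3
    beta_sg: float = 0.0
    beta_sp: float = 0.0
    beta_gp: float = 0.0
    beta_pg: float = 0.0
    sigma_g: float = 1.0
    sigma_p: float = 1.0
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.dag_label not in DAG_BY_LABEL:
            raise ValueError(
                f"unknown dag_label {self.dag_label!r}; valid labels: "
                f"{sorted(DAG_BY_LABEL)}"
            )
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.sigma_g <= 0 or self.sigma_p <= 0:
            raise ValueError("sigma_g and sigma_p must be positive")
        edges = DAG_BY_LABEL[self.dag_label].edges
        for beta, edge in (
            (self.beta_sg, EDGE_SG),
            (self.beta_sp, EDGE_SP),
            (self.beta_gp, EDGE_GP),
            (self.beta_pg, EDGE_PG),
        ):
            if edge not in edges and beta != 0.0:
                raise ValueError(f"effect on absent edge {edge} must be zero")

    @classmethod
    def for_dag(cls, dag_label: str, effect: float = 0.5, **kwargs) -> "TrioSpec":
        """Spec with ``effect`` on every edge the DAG has, zero elsewhere."""
        edges = DAG_BY_LABEL[dag_label].edges
        return cls(
            dag_label=dag_label,
            beta_sg=effect if EDGE_SG in edges else 0.0,
            beta_sp=effect if EDGE_SP in edges else 0.0,
            beta_gp=effect if EDGE_GP in edges else 0.0,
            beta_pg=effect if EDGE_PG in edges else 0.0,
            **kwargs,
        )


def simulate_trio(spec: TrioSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (s, g, p) under the spec's DAG, in topological order.

    s ~ Binomial(2, maf) i.i.d.; g and p are linear in their parents plus
    independent Gaussian noise; parentless continuous nodes are pure noise
    around 0. Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    s = rng.binomial(2, spec.maf, spec.n).astype(float)
    eps_g = rng.normal(0.0, spec.sigma_g, spec.n)
    eps_p = rng.normal(0.0, spec.sigma_p, spec.n)
    edges = DAG_BY_LABEL[spec.dag_label].edges
    if EDGE_PG in edges:  # PHEN before GE
        p = spec.beta_sp * s + eps_p
        g = spec.beta_sg * s + spec.beta_pg * p + eps_g
    else:
        g = spec.beta_sg * s + eps_g
        p = spec.beta_sp * s + spec.beta_gp * g + eps_p
    if spec.standardize:
        g = (g - g.mean()) / g.std()
        p = (p - p.mean()) / p.std()
    return s, g, p


@dataclasses.dataclass
class CohortSpec:
    """Generative parameters for a full synthetic cohort.

    Expression follows a per-module one-factor model: probe j of module k is
    ``loading * factor_k + noise`` with noise SD sqrt(1 - loading^2), so the
    loading is the probe-factor correlation and probes have unit variance.
    Probes beyond ``sum(module_sizes)`` are unclustered standard-normal noise.
    When ``coupling`` is nonzero there is exactly one planted causal chain:
    SNP ``causal_snp`` -> factor of ``causal_module`` -> trait.

    The trait is observed at ``n_time_points`` visits: a covariate linear
    predictor (age in years, constant across visits; sex, medication and
    smoking as 0/1) plus the coupled factor plus i.i.d. per-visit noise of SD
    ``sigma_trait``. Trait units are arbitrary; effect sizes are chosen
    relative to ``sigma_trait`` = 1.
    """

    n: int = 600
    n_snps: int = 50
    maf: float | Sequence[float] = 0.3
    n_probes: int = 180
    module_sizes: Sequence[int] = (50, 50, 50)
    loadings: float | Sequence[float] = 0.8
    n_time_points: int = 3
    trait: str = "SBP"
    base_level: float = 120.0
    age_effect: float = 0.5
    sex_effect: float = 4.0
    medication_effect: float = -10.0
    smoking_effect: float = 3.0
    age2_effect: float = 0.0
    coupling: float = 0.3
    causal_module: int = 0
    causal_snp: int = 0
    snp_factor_effect: float = 0.5
    sigma_trait: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(m) for m in self.module_sizes)
        if any(m < 2 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_probes:
            raise ValueError("module sizes must sum to <= n_probes")
        k = len(self.module_sizes)
        self.loadings = (
            tuple(float(l) for l in self.loadings)
            if np.ndim(self.loadings)
            else (float(self.loadings),) * k
        )
        if len(self.loadings) != k:
            raise ValueError("need one loading per module")
        if any(not 0 < l < 1 for l in self.loadings):
            raise ValueError("loadings must lie in (0, 1)")
        self.maf = (
            tuple(float(m) for m in self.maf)
            if np.ndim(self.maf)
            else (float(self.maf),) * self.n_snps
        )
        if len(self.maf) != self.n_snps:
            raise ValueError("need one MAF per SNP")
        if self.coupling != 0 and not 0 <= self.causal_module < k:
            raise ValueError("causal_module out of range")
        if not 0 <= self.causal_snp < self.n_snps:
            raise ValueError("causal_snp out of range")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, ExpressionMatrix, PhenotypeTable, dict]:
    """Generate (genotypes, expression, phenotypes, truth) for a cohort spec."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n, len(spec.module_sizes)
    sample_ids = [f"ind{i:04d}" for i in range(n)]
    snp_ids = [f"rs{j + 1:05d}" for j in range(spec.n_snps)]

    dosages = np.column_stack(
        [rng.binomial(2, m, n).astype(float) for m in spec.maf]
    )
    snp_meta = pd.DataFrame(
        {"id": snp_ids, "chrom": "1", "pos": [10_000 * (j + 1) for j in range(spec.n_snps)]}
    )
    genotypes = GenotypeMatrix(dosages, snp_meta, sample_ids)

    factors = rng.normal(0.0, 1.0, (n, k))
    if spec.snp_factor_effect != 0.0:
        factors[:, spec.causal_module] += spec.snp_factor_effect * dosages[:, spec.causal_snp]

    probe_ids = [f"probe{j:04d}" for j in range(spec.n_probes)]
    assignment = np.full(spec.n_probes, -1, dtype=int)  # -1 = unclustered noise
    values = np.empty((n, spec.n_probes))
    j = 0
    for mod, (size, loading) in enumerate(zip(spec.module_sizes, spec.loadings)):
        noise_sd = np.sqrt(1.0 - loading * loading)
        for _ in range(size):
            values[:, j] = loading * factors[:, mod] + rng.normal(0.0, noise_sd, n)
            assignment[j] = mod
            j += 1
    values[:, j:] = rng.normal(0.0, 1.0, (n, spec.n_probes - j))
    expression = ExpressionMatrix(values, pd.DataFrame({"probe_id": probe_ids}), sample_ids)

    age = rng.uniform(20.0, 80.0, n)
    sex = rng.binomial(1, 0.5, n)
    medication = rng.binomial(1, 0.2, n)
    smoking = rng.binomial(1, 0.2, n)
    genetic = spec.coupling * factors[:, spec.causal_module] if spec.coupling else np.zeros(n)
    linpred = (
        spec.base_level
        + spec.age_effect * age
        + spec.age2_effect * (age - 50.0) ** 2
        + spec.sex_effect * sex
        + spec.medication_effect * medication
        + spec.smoking_effect * smoking
        + genetic
    )
    records = []
    for t in range(spec.n_time_points):
        value = linpred + rng.normal(0.0, spec.sigma_trait, n)
        for i in range(n):
            records.append(
                (sample_ids[i], t, spec.trait, value[i], age[i], sex[i], medication[i], smoking[i])
            )
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            records,
            columns=[
                "individual_id",
                "time_point",
                "trait",
                "value",
                "age",
                "sex",
                "medication",
                "smoking",
            ],
        )
    )

    truth = {
        "module_assignment": {pid: int(m) for pid, m in zip(probe_ids, assignment)},
        "module_sizes": list(spec.module_sizes),
        "loadings": list(spec.loadings),
        "causal_snp": snp_ids[spec.causal_snp],
        "causal_module": int(spec.causal_module) if spec.coupling else None,
        "snp_factor_effect": spec.snp_factor_effect,
        "coupling": spec.coupling,
        "trait": spec.trait,
        "covariate_effects": {
            "age": spec.age_effect,
            "age2": spec.age2_effect,
            "sex": spec.sex_effect,
            "medication": spec.medication_effect,
            "smoking": spec.smoking_effect,
        },
        "sigma_trait": spec.sigma_trait,
        "factors": factors.tolist(),
        "seed": spec.seed,
    }
    return genotypes, expression, phenotypes, truth
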