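"""Phenotype adjustment and sex correction of expression.

The working phenotype for causal analysis is a single number per individual:
at each visit the trait is regressed on the covariates by OLS, and the
residuals are averaged over an individual's observed visits. Expression is
residualised on sex before any association scan.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import ExpressionMatrix, PhenotypeTable

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "medication", "smoking")


@dataclasses.dataclass
class AdjustedPhenotype:
    """Per-individual covariate-adjusted trait (average of visit residuals)."""

    series: pd.Series
    trait: str
    covariates: tuple[str, ...]
    n_time_points: pd.Series

    def __post_init__(self) -> None:
        if self.series.index.duplicated().any():
            raise ValueError("one adjusted value per individual expected")
        if not np.isfinite(self.series.to_numpy(dtype=float)).all():
            raise ValueError("adjusted phenotype contains non-finite values")

    def aligned(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.series.loc[list(sample_ids)].to_numpy(dtype=float)

    def save(self, path) -> None:
        out = self.series.rename("adjusted_value").rename_axis("individual_id")
        out.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def _design(df: pd.DataFrame, covariates: Sequence[str], age_center: float,
            center_age: bool) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "age2":
            base = df["age"].to_numpy(dtype=float)
            cols.append((base - age_center) ** 2 if center_age else base ** 2)
        else:
            if cov not in df.columns:
                raise ValueError(f"covariate {cov!r} not present in phenotype table")
            cols.append(df[cov].to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return sm.add_constant(X, has_constant="add")


def adjust_phenotype(
    p: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    pool_time_points: bool = False,
    center_age: bool = True,
) -> AdjustedPhenotype:
    """Covariate-adjust one trait and average residuals within individual.

    By default each visit gets its own OLS fit (so covariate effects may
    differ by visit); ``pool_time_points`` fits one pooled regression across
    visits instead. ``"age2"`` in the covariate list is derived as squared
    (mean-centred, unless ``center_age=False``) age. A constant covariate
    column raises (singular design).
    """
    df = p.data[p.data["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    df = df.dropna(subset=["value"])
    age_center = float(df["age"].mean())

    def _fit(block: pd.DataFrame) -> pd.Series:
        X = _design(block, covariates, age_center, center_age)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design: a covariate column is constant")
        fit = sm.OLS(block["value"].to_numpy(dtype=float), X).fit()
        return pd.Series(fit.resid, index=block["individual_id"].to_numpy())

    if pool_time_points:
        resid = _fit(df)
    else:
        parts = [_fit(block) for _, block in df.groupby("time_point", sort=True)]
        resid = pd.concat(parts)
    adjusted = resid.groupby(level=0).mean().sort_index()
    n_tp = resid.groupby(level=0).size().sort_index()
    return AdjustedPhenotype(
        series=adjusted, trait=trait, covariates=tuple(covariates), n_time_points=n_tp
    )


def correct_for_sex(
    e: ExpressionMatrix, sex: Union[pd.Series, np.ndarray]
) -> ExpressionMatrix:
    """Replace each probe by its residuals from OLS on intercept + sex.

    In a single-sex cohort the sex coefficient is inestimable; probes are
    simply centred and a warning is logged.
    """
    if isinstance(sex, pd.Series):
        sex_v = sex.loc[e.sample_ids].to_numpy(dtype=float)
    else:
        sex_v = np.asarray(sex, dtype=float)
        if len(sex_v) != e.n_samples:
            raise ValueError("sex vector length does not match expression samples")
    if not np.isfinite(sex_v).all():
        raise ValueError("sex must be known for all individuals")
    vals = e.values
    if np.ptp(sex_v) == 0:
        log.warning("single-sex cohort: returning centred expression values")
        corrected = vals - vals.mean(axis=0)
    else:
        sc = sex_v - sex_v.mean()
        centred = vals - vals.mean(axis=0)
        slope = (sc @ centred) / (sc @ sc)
        corrected = centred - np.outer(sc, slope)
    return ExpressionMatrix(corrected, e.probe_meta.copy(), list(e.sample_ids))
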