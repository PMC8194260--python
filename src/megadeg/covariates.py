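"""Study-level covariate regression on per-study effect sizes.

For one gene, the per-study log2 fold-changes are regressed on study-level
covariates: total sample size, country of origin (categorical) and study age
in years. The default mode fits one simple regression per covariate and
reports its slope p-value (for country, the overall F-test across the
category contrasts) — with few contributing studies a joint three-predictor
fit has no residual degrees of freedom, so the univariate reading is the only
estimable one. Joint mode is available when enough studies contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effects import StudyEffect
from .io import DatasetMeta

__all__ = ["CovariateResult", "covariate_regression", "covariate_table"]

UNIVARIATE = "univariate"
JOINT = "joint"


@dataclass(frozen=True)
class CovariateResult:
    """Per-covariate p-values for one gene; NaN marks not-estimable."""

    gene: str
    p_nsample: float
    p_country: float
    p_study_age: float
    mode: str


def _align(effects: list[StudyEffect], metas: list[DatasetMeta]) -> pd.DataFrame:
    meta_by_id = {m.dataset_id: m for m in metas}
    rows = []
    for e in effects:
        if e.dataset_id not in meta_by_id:
            raise ValueError(f"no metadata for dataset {e.dataset_id!r}")
        m = meta_by_id[e.dataset_id]
        rows.append(
            {
                "lfc": e.lfc,
                "n_total": m.n_total,
                "country": m.country,
                "study_age": m.study_age,
            }
        )
    return pd.DataFrame(rows)


def _slope_p(y: np.ndarray, x: np.ndarray) -> float:
    if np.ptp(x) == 0:  # constant covariate: not estimable
        return math.nan
    X = sm.add_constant(x.astype(float))
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[1])


def _country_p(y: np.ndarray, country: pd.Series) -> float:
    if country.nunique() < 2:
        return math.nan
    dummies = pd.get_dummies(country, drop_first=True, dtype=float)
    if len(y) - dummies.shape[1] - 1 < 1:  # no residual df for the F test
        return math.nan
    X = sm.add_constant(dummies.to_numpy())
    fit = sm.OLS(y, X).fit()
    return float(fit.f_pvalue)


def covariate_regression(
    effects: list[StudyEffect],
    metas: list[DatasetMeta],
    mode: str = UNIVARIATE,
) -> CovariateResult:
    """Regress one gene's per-study LFCs on sample size, country, study age.

    Univariate mode (default) needs >=3 studies and reports each covariate's
    own regression p-value; a covariate constant across studies is marked
    not-estimable (NaN). Joint mode fits all covariates together and raises
    when residual degrees of freedom run out.
    """
    gene = effects[0].gene if effects else ""
    df = _align(effects, metas)
    y = df["lfc"].to_numpy(dtype=float)
    if mode == UNIVARIATE:
        if len(df) < 3:
            raise ValueError("univariate covariate regression needs >=3 studies")
        return CovariateResult(
            gene=gene,
            p_nsample=_slope_p(y, df["n_total"].to_numpy()),
            p_country=_country_p(y, df["country"]),
            p_study_age=_slope_p(y, df["study_age"].to_numpy()),
            mode=UNIVARIATE,
        )
    if mode == JOINT:
        parts = []
        names = []
        if np.ptp(df["n_total"].to_numpy()) > 0:
            parts.append(df[["n_total"]].astype(float))
            names.append("n_total")
        cdum = pd.get_dummies(df["country"], drop_first=True, dtype=float)
        country_cols = list(cdum.columns)
        if country_cols:
            parts.append(cdum)
        if np.ptp(df["study_age"].to_numpy()) > 0:
            parts.append(df[["study_age"]].astype(float))
            names.append("study_age")
        X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
        if len(df) - X.shape[1] - 1 < 1:
            raise ValueError(
                "insufficient residual degrees of freedom for a joint fit; "
                "use univariate mode"
            )
        fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        pv = dict(zip(["const", *X.columns], fit.pvalues))
        if country_cols:
            # overall F test on the country contrasts
            k = len(country_cols)
            idx = [1 + list(X.columns).index(c) for c in country_cols]
            R = np.zeros((k, X.shape[1] + 1))
            for r, j in enumerate(idx):
                R[r, j] = 1.0
            p_country = float(fit.f_test(R).pvalue)
        else:
            p_country = math.nan
        return CovariateResult(
            gene=gene,
            p_nsample=float(pv.get("n_total", math.nan)),
            p_country=p_country,
            p_study_age=float(pv.get("study_age", math.nan)),
            mode=JOINT,
        )
    raise ValueError(f"mode must be univariate or joint, got {mode!r}")


def covariate_table(
    effects_by_gene: dict[str, list[StudyEffect]],
    metas: list[DatasetMeta],
    mode: str = UNIVARIATE,
) -> pd.DataFrame:
    """Covariate p-values for a panel; genes sorted by id."""
    rows = []
    for gene in sorted(effects_by_gene):
        r = covariate_regression(effects_by_gene[gene], metas, mode=mode)
        rows.append(
            {
                "gene": gene,
                "p_nsample": r.p_nsample,
                "p_country": r.p_country,
                "p_study_age": r.p_study_age,
                "mode": r.mode,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "p_nsample", "p_country", "p_study_age", "mode"]
    )
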