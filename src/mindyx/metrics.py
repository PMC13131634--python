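"""Validation metrics and behavioral statistics.

Functional connectivity (Pearson, optionally Fisher z-transformed), excess
kurtosis, test-retest ICC, per-parcel GLM task effects, and ordinary
least-squares behavioral models over the dynamical feature table with
nested-model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "PRESET_SPECS",
    "OlsResult",
    "fc_matrix",
    "excess_kurtosis",
    "icc",
    "glm_task_betas",
    "fit_behavior_model",
    "nested_f_test",
]


def fc_matrix(states: np.ndarray, fisher_z: bool = False) -> np.ndarray:
    """Functional connectivity: pairwise Pearson correlations of parcels.

    With ``fisher_z`` the off-diagonal entries are atanh-transformed (the
    diagonal is left at 1).
    """
    states = np.asarray(states, dtype=np.float64)
    if states.shape[1] < 3:
        raise ValueError("need at least 3 volumes")
    if np.any(states.std(axis=1) < 1e-12):
        raise ValueError("constant parcel series has undefined correlation")
    fc = np.corrcoef(states)
    if fisher_z:
        off = ~np.eye(fc.shape[0], dtype=bool)
        fc = fc.copy()
        fc[off] = np.arctanh(np.clip(fc[off], -1 + 1e-15, 1 - 1e-15))
    return fc


def excess_kurtosis(values: np.ndarray) -> float:
    """Fourth standardized moment minus 3 (0 for a Gaussian)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 4:
        raise ValueError("need at least 4 values")
    if v.std() < 1e-15:
        raise ValueError("zero variance")
    return float(sps.kurtosis(v, fisher=True, bias=True))


def icc(visit1: np.ndarray, visit2: np.ndarray, kind: str = "ICC(2,1)") -> float:
    """Test-retest intraclass correlation across subjects.

    ``ICC(2,1)`` (default) is the two-way random-effects, absolute-agreement,
    single-measure coefficient: with MSR/MSC/MSE the subject, visit
    (column) and residual mean squares of the two-way ANOVA over the S x 2
    table,

        ICC = (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / S).

    ``ICC(3,1)`` (consistency; insensitive to a constant offset between
    visits) is also available.
    """
    y1 = np.asarray(visit1, dtype=np.float64)
    y2 = np.asarray(visit2, dtype=np.float64)
    if y1.shape != y2.shape or y1.ndim != 1 or y1.size < 3:
        raise ValueError("need two aligned vectors of >= 3 subjects")
    Y = np.column_stack([y1, y2])
    S, R = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = R * np.sum((row_means - grand) ** 2)
    ss_cols = S * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (S - 1)
    msc = ss_cols / (R - 1)
    mse = ss_err / ((S - 1) * (R - 1))
    if kind == "ICC(2,1)":
        denom = msr + (R - 1) * mse + R * (msc - mse) / S
    elif kind == "ICC(3,1)":
        denom = msr + (R - 1) * mse
    else:
        raise ValueError("kind must be 'ICC(2,1)' or 'ICC(3,1)'")
    if abs(denom) < 1e-30:
        raise ValueError("degenerate variance structure")
    return float((msr - mse) / denom)


def glm_task_betas(states: np.ndarray, design) -> tuple[np.ndarray, np.ndarray]:
    """Per-parcel OLS of the static model ``x_t = mu + beta u_t``.

    Returns ``(mu (n,), beta (n, m))`` for a design with m box-car
    regressors.
    """
    states = np.asarray(states, dtype=np.float64)
    U = design.u if hasattr(design, "u") else np.asarray(design, dtype=np.float64)
    Z = np.column_stack([np.ones(U.shape[1]), U.T])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear design")
    coef, *_ = np.linalg.lstsq(Z, states.T, rcond=None)
    return coef[0], coef[1:].T


@dataclass
class ModelSpec:
    """A named behavioral regression: response and right-hand-side terms.

    ``terms`` uses feature-table column names; ``a:b`` denotes an
    interaction and ``a*b`` expands to main effects plus interaction (patsy
    conventions).
    """

    name: str
    response: str
    terms: tuple[str, ...]

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"


def preset_specs(response: str = "accuracy",
                 motifs=("DMN", "FPN", "TPN"),
                 rest_motifs=("DMN", "VIS", "TPN", "SAL")) -> dict:
    """The standard battery of behavioral models over the feature table.

    Occupancy uses all but the first motif's time share (the shares sum to
    one); distance models use the task-condition motif distances; rest-only
    uses resting-condition distances; the joint model nests both.
    """
    occ = tuple(f"{m}_time" for m in motifs[1:])
    dist = tuple(f"d{m}" for m in motifs)
    dist_rest = tuple(f"d{m}_rest" for m in rest_motifs)
    inter = tuple(f"Bifurc:d{m}" for m in motifs)
    return {
        "bifurcation": ModelSpec("bifurcation", response, ("Bifurc",)),
        "occupancy": ModelSpec("occupancy", response, occ),
        "distance": ModelSpec("distance", response, dist),
        "additive": ModelSpec("additive", response, ("Bifurc",) + dist),
        "interaction": ModelSpec("interaction", response,
                                 ("Bifurc",) + dist + inter),
        "rest_only": ModelSpec("rest_only", response, dist_rest),
        "task_only": ModelSpec("task_only", response, dist),
        "joint": ModelSpec("joint", response, dist + dist_rest),
    }


PRESET_SPECS = preset_specs()


@dataclass
class OlsResult:
    """Summary of one behavioral OLS fit."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    std_params: pd.Series
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float
    aic: float
    bic: float
    _sm_result: object = field(repr=False, default=None)

    def nested_f(self, sub: "OlsResult"):
        """F-test of this model against a nested sub-model."""
        return nested_f_test(sub, self)


def fit_behavior_model(table: pd.DataFrame, spec: ModelSpec) -> OlsResult:
    """OLS with intercept for one behavioral model specification.

    Standardized coefficients (fit on z-scored response and numeric
    predictors) are reported alongside the raw ones.
    """
    missing = [t for term in spec.terms for t in term.replace("*", ":").split(":")
               if t not in table.columns]
    if spec.response not in table.columns:
        raise ValueError(f"response {spec.response!r} not in table")
    if missing:
        raise ValueError(f"predictors not in table: {sorted(set(missing))}")
    if table[spec.response].isna().any():
        raise ValueError("missing responses")
    res = smf.ols(spec.formula, data=table).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError("singular design matrix")
    ztable = table.copy()
    for c in ztable.columns:
        col = ztable[c]
        if np.issubdtype(col.dtype, np.number) and col.std() > 0:
            ztable[c] = (col - col.mean()) / col.std()
    zres = smf.ols(spec.formula, data=ztable).fit()
    return OlsResult(
        spec=spec, params=res.params, bse=res.bse, tvalues=res.tvalues,
        pvalues=res.pvalues, std_params=zres.params,
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        df_model=float(res.df_model), df_resid=float(res.df_resid),
        aic=float(res.aic), bic=float(res.bic), _sm_result=res,
    )


def nested_f_test(sub: OlsResult, full: OlsResult):
    """F-test for the extra terms of ``full`` over nested ``sub``.

    Returns ``(F, df_num, df_den, p)``.
    """
    f, p, df_num = full._sm_result.compare_f_test(sub._sm_result)
    return float(f), float(df_num), float(full.df_resid), float(p)
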