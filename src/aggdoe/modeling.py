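"""Interaction-model fitting with MODDE-style quality metrics.

Each response from the campaign is fitted by ordinary least squares to a
main-effect + two-factor-interaction model in coded (-1..+1) factor space, so
coefficient magnitudes are directly comparable across additives.  Four
quality metrics summarize each fit:

* R2          — corrected coefficient of determination,
* Q2          — leave-one-out predictive R2, 1 − PRESS/SS_tot (may be < 0),
* validity    — 1 + 0.57647·log10(p_lack-of-fit), capped at 1, so the
                conventional 0.25 floor corresponds to p_lof = 0.05,
* reproducibility — 1 − pooled replicate variance / total response variance.

Replicated center points provide the pure-error estimate behind the
lack-of-fit test and the replicate variance behind reproducibility, and
anchor the multiplicative between-batch normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, ModelSpec, model_matrix

__all__ = [
    "FittedModel",
    "build_model_matrix",
    "apply_transform",
    "invert_transform",
    "normalize_to_center_points",
    "fit_mlr",
    "q2_press",
    "model_validity",
    "reproducibility",
    "correlation_matrix",
    "replicate_groups_from_design",
    "fit_campaign",
]

NEGLOG_EPS = 1e-6


def build_model_matrix(design: DesignTable, model: ModelSpec) -> pd.DataFrame:
    """Model matrix X for a design: intercept, coded mains, term products."""
    if design.n_runs == 0:
        raise ValueError("design is empty")
    X = model_matrix(design.coded, model, design.factor_names)
    return pd.DataFrame(X, columns=model.term_names, index=design.run_ids)


def apply_transform(y, transform: str = "identity", eps: float = NEGLOG_EPS):
    """Apply a response transform; 'neglog' maps a percent y to −log10(y/100+eps).

    neglog is the normalizing transform used for skewed high-percentage flow
    responses; it is monotone decreasing, so model signs flip on that scale.
    """
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y.copy()
    if transform == "neglog":
        frac = y / 100.0 + eps
        if np.any(frac <= 0):
            bad = np.flatnonzero(frac <= 0)
            raise ValueError(f"neglog transform undefined at rows {bad.tolist()}")
        return -np.log10(frac)
    raise ValueError(f"unknown transform {transform!r}")


def invert_transform(z, transform: str = "identity", eps: float = NEGLOG_EPS):
    z = np.asarray(z, dtype=float)
    if transform == "identity":
        return z.copy()
    if transform == "neglog":
        return (np.power(10.0, -z) - eps) * 100.0
    raise ValueError(f"unknown transform {transform!r}")


def normalize_to_center_points(
    responses: pd.DataFrame,
    design: DesignTable,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Rescale each batch so its center-point mean matches the grand mean.

    Within each batch, every value of a response is multiplied by
    (grand center mean)/(batch center mean).  The grand center-point mean is
    preserved and the map is idempotent.  Only sensible for responses that
    are strictly positive at the center; signed near-zero responses (e.g.
    aggregate % error) should be excluded via ``columns``.
    """
    df = responses.copy()
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    batch = pd.Series(design.batch, index=design.run_ids)
    is_center = pd.Series(design.is_center, index=design.run_ids)
    missing = [r for r in df.index if r not in batch.index]
    if missing:
        raise ValueError(f"responses contain run_ids not in design: {missing}")
    for b in pd.unique(batch):
        runs_b = batch.index[(batch == b)]
        centers_b = batch.index[(batch == b) & is_center]
        if len(centers_b) == 0:
            raise ValueError(f"batch {b!r} has no center point; cannot normalize")
    for col in columns:
        center_vals = df.loc[df.index.intersection(batch.index[is_center]), col]
        grand = center_vals.mean()
        for b in pd.unique(batch):
            centers_b = [r for r in batch.index[(batch == b) & is_center] if r in df.index]
            if not centers_b:
                raise ValueError(f"batch {b!r} has no center point in responses")
            bmean = df.loc[centers_b, col].mean()
            if bmean == 0 or not np.isfinite(bmean):
                raise ValueError(f"batch {b!r} center mean of {col!r} is zero/non-finite")
            runs_b = [r for r in batch.index[batch == b] if r in df.index]
            df.loc[runs_b, col] = df.loc[runs_b, col] * (grand / bmean)
    return df


@dataclass
class FittedModel:
    """OLS fit of one response on the coded model matrix."""

    response: str
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    r2: float
    q2: float
    validity: float
    reproducibility: float
    lof_pvalue: float
    df_resid: int
    sigma2: float
    xtx_inv: np.ndarray
    transform: str = "identity"
    model: ModelSpec | None = None
    factor_names: list[str] = field(default_factory=list)

    def predict(self, coded: np.ndarray) -> np.ndarray:
        X = model_matrix(np.atleast_2d(coded), self.model, self.factor_names)
        return X @ self.coef

    def predict_sd(self, coded: np.ndarray, include_observation: bool = True) -> np.ndarray:
        """Prediction SD at new points: sqrt(sigma2·(1 + x'(X'X)^-1 x)).

        ``include_observation=False`` drops the irreducible-noise term and
        returns the SD of the fitted mean only (leverage term).
        """
        X = model_matrix(np.atleast_2d(coded), self.model, self.factor_names)
        lev = np.einsum("ij,jk,ik->i", X, self.xtx_inv, X)
        extra = 1.0 if include_observation else 0.0
        return np.sqrt(self.sigma2 * (extra + lev))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=self.terms,
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "transform": self.transform,
            "terms": list(self.terms),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "r2": self.r2,
            "q2": self.q2,
            "validity": self.validity,
            "reproducibility": self.reproducibility,
            "lof_pvalue": self.lof_pvalue,
            "df_resid": self.df_resid,
        }


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    terms: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int, float, np.ndarray]:
    """OLS fit returning (coef, se, ci_lo, ci_hi, R2, df_resid, sigma2, XtX_inv).

    R2 is the corrected (mean-centered) coefficient of determination; a
    constant response is reported as R2 = 0 rather than raising.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"n={n} rows < p={p} columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("model matrix is rank-deficient")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=alpha)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res.resid**2)) / ss_tot if ss_tot > 0 else 0.0
    df_resid = int(res.df_resid)
    sigma2 = float(res.mse_resid) if df_resid > 0 else math.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    return (
        np.asarray(res.params),
        np.asarray(res.bse),
        np.asarray(ci[:, 0]),
        np.asarray(ci[:, 1]),
        r2,
        df_resid,
        sigma2,
        xtx_inv,
    )


def q2_press(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out predictive R2 via the hat-matrix PRESS shortcut.

    PRESS = Σ (e_i / (1 − h_ii))²; Q2 = 1 − PRESS/SS_tot.  Negative values
    mean the model predicts worse than the response mean and are reported
    as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("Q2 requires n > p")
    H = X @ np.linalg.solve(X.T @ X, X.T)
    h = np.diag(H)
    resid = y - H @ y
    if np.any(1.0 - h < 1e-12):
        raise ValueError("a leverage of 1 makes leave-one-out undefined")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - press / ss_tot


def replicate_groups_from_design(design: DesignTable) -> list[np.ndarray]:
    """Replicate groups for pure error: identical coded settings (center points)."""
    seen: dict[tuple, list[int]] = {}
    for i in range(design.n_runs):
        key = tuple(np.round(design.coded[i], 12))
        seen.setdefault(key, []).append(i)
    return [np.array(v) for v in seen.values() if len(v) >= 2]


def _pure_error(y: np.ndarray, groups: list[np.ndarray]) -> tuple[float, int]:
    ss, df = 0.0, 0
    for g in groups:
        if len(g) >= 2:
            vals = y[g]
            ss += float(np.sum((vals - vals.mean()) ** 2))
            df += len(g) - 1
    return ss, df


def lack_of_fit_pvalue(
    X: np.ndarray, y: np.ndarray, replicate_groups: list[np.ndarray]
) -> float:
    """p-value of the lack-of-fit F-test against replicate pure error.

    Residual SS is partitioned into pure error (within replicate groups) and
    lack of fit; F = (SS_lof/df_lof)/(SS_pe/df_pe).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_res = float(np.sum((y - X @ beta) ** 2))
    ss_pe, df_pe = _pure_error(y, replicate_groups)
    if df_pe == 0:
        return math.nan
    df_lof = (n - p) - df_pe
    if df_lof <= 0:
        return math.nan
    ss_lof = max(ss_res - ss_pe, 0.0)
    if ss_pe == 0.0:
        return 0.0 if ss_lof > 0 else 1.0
    F = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(F, df_lof, df_pe))


def model_validity(
    X: np.ndarray, y: np.ndarray, replicate_groups: list[np.ndarray]
) -> float:
    """Validity = 1 + 0.57647·log10(p_lof), capped at 1.

    The scaling makes validity 0.25 exactly at p_lof = 0.05, the conventional
    floor below which the model form is suspect relative to replicate noise.
    nan when no replicate groups exist (pure error unavailable).
    """
    p_lof = lack_of_fit_pvalue(X, y, replicate_groups)
    if math.isnan(p_lof):
        return math.nan
    return validity_from_pvalue(p_lof)


def validity_from_pvalue(p_lof: float) -> float:
    if p_lof <= 0:
        return -math.inf
    return min(1.0, 1.0 + 0.57647 * math.log10(p_lof))


def reproducibility(y: np.ndarray, replicate_groups: list[np.ndarray]) -> float:
    """1 − (pooled within-replicate variance)/(total response variance)."""
    y = np.asarray(y, dtype=float)
    ss_pe, df_pe = _pure_error(y, replicate_groups)
    if df_pe == 0:
        return math.nan
    var_total = float(np.var(y, ddof=1))
    if var_total == 0:
        return math.nan
    var_rep = ss_pe / df_pe
    return 1.0 - var_rep / var_total


def correlation_matrix(
    responses: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between responses with two-sided t-test p-values.

    Returns (r, p) DataFrames; symmetric with unit diagonal.  Each cell uses
    the complete pairs of its two columns (>= 3 required).
    """
    cols = list(responses.columns)
    if pairs is not None:
        used = sorted({c for pr in pairs for c in pr}, key=cols.index)
    else:
        used = cols
    r = pd.DataFrame(np.eye(len(used)), index=used, columns=used)
    p = pd.DataFrame(np.zeros((len(used), len(used))), index=used, columns=used)
    for i, a in enumerate(used):
        for b in used[i + 1 :]:
            sub = responses[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            rr, pp = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


DEFAULT_TRANSFORMS = {
    # the normalizing transform is applied to the two skewed flow responses
    "OCT4_flow": "neglog",
    "TRA160_flow": "neglog",
}


def fit_campaign(
    design: DesignTable,
    responses: pd.DataFrame,
    model: ModelSpec,
    transforms: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> dict[str, FittedModel]:
    """Fit the interaction model to every numeric response column.

    Responses are aligned to the design by run_id; each is transformed per
    ``transforms`` (default: neglog for OCT4/TRA-1-60 flow), fitted by OLS,
    and scored with R2/Q2/validity/reproducibility.
    """
    transforms = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)
    Xdf = build_model_matrix(design, model)
    responses = responses.loc[Xdf.index]
    X = Xdf.to_numpy()
    groups = replicate_groups_from_design(design)
    fits: dict[str, FittedModel] = {}
    for col in responses.columns:
        if not pd.api.types.is_numeric_dtype(responses[col]):
            continue
        tf = transforms.get(col, "identity")
        y = apply_transform(responses[col].to_numpy(float), tf)
        coef, se, lo, hi, r2, df_resid, sigma2, xtx_inv = fit_mlr(
            X, y, model.term_names, alpha=alpha
        )
        fits[col] = FittedModel(
            response=col,
            terms=model.term_names,
            coef=coef,
            se=se,
            ci_lower=lo,
            ci_upper=hi,
            r2=r2,
            q2=q2_press(X, y) if X.shape[0] > X.shape[1] else math.nan,
            validity=model_validity(X, y, groups),
            reproducibility=reproducibility(y, groups),
            lof_pvalue=lack_of_fit_pvalue(X, y, groups),
            df_resid=df_resid,
            sigma2=sigma2,
            xtx_inv=xtx_inv,
            transform=tf,
            model=model,
            factor_names=design.factor_names,
        )
    return fits
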