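"""Statistical stages: hierarchical block regression, collinearity
diagnostics, the quadratic age model, leave-site-out cross-validation,
Levene's residual-variance test, and the impairment-rate summary.

The hierarchical regression fits ordinary-least-squares models with an
intercept for each nested predictor block and reports, per block, R^2,
adjusted R^2, the overall F test, and the increment tests

    dR^2_k = R^2_k - R^2_{k-1}
    dF_k   = (dR^2_k / q) / ((1 - R^2_k) / (n - p_k - 1))

with q new predictors and p_k total predictors in block k (block 1 is
compared against the intercept-only model, so its dF equals the overall
F).  Standardized coefficients are beta = b * sd(x) / sd(y).  All tests
are two-tailed at alpha = 0.05; no multiple-testing correction is
applied.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import ConfigError, FormatError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Block regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BlockSpec:
    """Outcome name plus an ordered list of predictor blocks."""

    outcome: str
    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        flat = [p for block in self.blocks for p in block]
        if len(set(flat)) != len(flat):
            raise ConfigError("predictor names must be unique across blocks")
        if not flat:
            raise ConfigError("at least one predictor block is required")

    @property
    def all_predictors(self) -> tuple[str, ...]:
        return tuple(p for block in self.blocks for p in block)


@dataclasses.dataclass
class BlockResult:
    predictors: tuple[str, ...]  # cumulative predictor set of this model
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    delta_r2: float
    delta_f: float
    delta_f_p: float
    coef: pd.DataFrame  # index predictor, columns b_raw, b_std, p_value


@dataclasses.dataclass
class BlockRegressionResult:
    spec: BlockSpec
    n: int
    blocks: list[BlockResult]

    @property
    def final(self) -> BlockResult:
        return self.blocks[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (block, row-kind)."""
        rows = []
        for k, blk in enumerate(self.blocks, start=1):
            for name in blk.coef.index:
                rows.append(
                    {
                        "block": k,
                        "row": name,
                        "B": blk.coef.loc[name, "b_raw"],
                        "beta": blk.coef.loc[name, "b_std"],
                        "p": blk.coef.loc[name, "p_value"],
                    }
                )
            for label, value in (
                ("R2", blk.r2),
                ("adj_R2", blk.adj_r2),
                ("F", blk.f_stat),
                ("F_p", blk.f_p),
                ("delta_R2", blk.delta_r2),
                ("delta_F", blk.delta_f),
                ("delta_F_p", blk.delta_f_p),
            ):
                rows.append({"block": k, "row": label, "B": value,
                             "beta": np.nan, "p": np.nan})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "outcome": self.spec.outcome,
            "n": self.n,
            "blocks": [
                {
                    "predictors": list(blk.predictors),
                    "r2": blk.r2,
                    "adj_r2": blk.adj_r2,
                    "f_stat": blk.f_stat,
                    "f_p": blk.f_p,
                    "delta_r2": blk.delta_r2,
                    "delta_f": blk.delta_f,
                    "delta_f_p": blk.delta_f_p,
                    "coef": {
                        name: {
                            "b_raw": blk.coef.loc[name, "b_raw"],
                            "b_std": blk.coef.loc[name, "b_std"],
                            "p_value": blk.coef.loc[name, "p_value"],
                        }
                        for name in blk.coef.index
                    },
                }
                for blk in self.blocks
            ],
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def _check_design(design: pd.DataFrame, spec: BlockSpec) -> None:
    needed = (spec.outcome,) + spec.all_predictors
    missing = [c for c in needed if c not in design.columns]
    if missing:
        raise FormatError(f"design table missing column(s) {missing}")
    n, p = len(design), len(spec.all_predictors)
    if n <= p + 1:
        raise ConfigError(f"n={n} too small for {p} predictors")
    for name in spec.all_predictors:
        if float(np.std(design[name].to_numpy(dtype=float))) == 0.0:
            raise ConfigError(f"predictor {name!r} is constant")
    x = design[list(spec.all_predictors)].to_numpy(dtype=float)
    xc = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        vif = collinearity_diagnostics(design[list(spec.all_predictors)])["vif"]
        bad = [name for name, v in vif.items() if not np.isfinite(v)]
        raise ConfigError(f"rank-deficient design; collinear predictor set: {bad}")


def hierarchical_regression(
    design: pd.DataFrame, spec: BlockSpec
) -> BlockRegressionResult:
    """Fit the nested OLS models of ``spec`` and all increment tests."""
    _check_design(design, spec)
    y = design[spec.outcome].to_numpy(dtype=float)
    n = len(y)
    sd_y = y.std(ddof=1)
    results: list[BlockResult] = []
    cumulative: list[str] = []
    r2_prev = 0.0
    for block in spec.blocks:
        cumulative = cumulative + list(block)
        x = sm.add_constant(design[cumulative].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        r2 = float(fit.rsquared)
        p_k = len(cumulative)
        df2 = n - p_k - 1
        q = len(block)
        denom = (1.0 - r2) / df2
        delta_r2 = r2 - r2_prev
        if denom <= 0:
            delta_f = np.inf if delta_r2 > 0 else 0.0
            delta_f_p = 0.0 if delta_r2 > 0 else 1.0
        else:
            delta_f = (delta_r2 / q) / denom
            delta_f_p = float(scipy.stats.f.sf(delta_f, q, df2))
        coef = pd.DataFrame(
            {
                "b_raw": fit.params[1:],
                "b_std": [
                    fit.params[1 + i]
                    * design[name].to_numpy(dtype=float).std(ddof=1)
                    / sd_y
                    for i, name in enumerate(cumulative)
                ],
                "p_value": fit.pvalues[1:],
            },
            index=list(cumulative),
        )
        results.append(
            BlockResult(
                predictors=tuple(cumulative),
                r2=r2,
                adj_r2=float(fit.rsquared_adj),
                f_stat=float(fit.fvalue),
                f_p=float(fit.f_pvalue),
                delta_r2=float(delta_r2),
                delta_f=float(delta_f),
                delta_f_p=float(delta_f_p),
                coef=coef,
            )
        )
        r2_prev = r2
    return BlockRegressionResult(spec=spec, n=n, blocks=results)


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------

def collinearity_diagnostics(design: pd.DataFrame) -> dict:
    """Per-predictor VIF plus the full bivariate correlation table.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from regressing
    predictor j on all the others (with intercept).  Perfect collinearity
    yields ``inf`` rather than an exception.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ConfigError("need at least 2 predictors for diagnostics")
    x = design.to_numpy(dtype=float)
    n = x.shape[0]
    vif: dict[str, float] = {}
    for j, name in enumerate(cols):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        yj = x[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        vif[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return {"vif": vif, "correlations": design.corr()}


# ---------------------------------------------------------------------------
# Quadratic age model
# ---------------------------------------------------------------------------

def quadratic_age_model(
    values: Sequence[float], ages: Sequence[float]
) -> BlockRegressionResult:
    """Two-block model: metric ~ age, then + age^2 (raw, uncentered)."""
    ages = np.asarray(ages, dtype=float)
    design = pd.DataFrame(
        {"metric": np.asarray(values, dtype=float), "age": ages, "age_sq": ages**2}
    )
    spec = BlockSpec(outcome="metric", blocks=(("age",), ("age_sq",)))
    return hierarchical_regression(design, spec)


# ---------------------------------------------------------------------------
# Leave-site-out cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVFold:
    held_out_site: str
    n_test: int
    test_r2: float  # NaN when undefined (single-subject site, SS_tot = 0)
    residuals: np.ndarray


@dataclasses.dataclass
class CVResult:
    folds: list[CVFold]
    mean_r2: float
    sd_r2: float
    levene_f: float
    levene_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "held_out_site": [f.held_out_site for f in self.folds],
                "n_test": [f.n_test for f in self.folds],
                "test_r2": [f.test_r2 for f in self.folds],
            }
        )


def leave_site_out_cv(
    design: pd.DataFrame,
    spec: BlockSpec,
    site_column: str = "site",
    r2_baseline: str = "test_mean",
) -> CVResult:
    """Train the full block model on all-but-one site, test on the rest.

    Out-of-sample R^2 for a fold is ``1 - SS_res / SS_tot``; by default
    SS_tot is taken about the held-out fold's own outcome mean (the
    stricter convention; negative values are expected and permitted).
    Set ``r2_baseline="train_mean"`` to center on the training mean
    instead.  Levene's test (mean-centered) is applied to the pooled
    residuals grouped by site.
    """
    if site_column not in design.columns:
        raise FormatError(f"design table has no {site_column!r} column")
    if r2_baseline not in ("test_mean", "train_mean"):
        raise ConfigError(f"unknown r2_baseline {r2_baseline!r}")
    sites = list(dict.fromkeys(design[site_column]))
    if len(sites) < 2:
        raise ConfigError("leave-site-out CV needs at least 2 sites")
    predictors = list(spec.all_predictors)
    y_all = design[spec.outcome].to_numpy(dtype=float)
    x_all = design[predictors].to_numpy(dtype=float)
    site_arr = design[site_column].to_numpy()
    folds: list[CVFold] = []
    for site in sites:
        test = site_arr == site
        train = ~test
        x_tr = sm.add_constant(x_all[train])
        fit = sm.OLS(y_all[train], x_tr).fit()
        x_te = np.column_stack([np.ones(test.sum()), x_all[test]])
        pred = x_te @ fit.params
        resid = y_all[test] - pred
        ss_res = float((resid**2).sum())
        center = y_all[test].mean() if r2_baseline == "test_mean" else y_all[train].mean()
        ss_tot = float(((y_all[test] - center) ** 2).sum())
        test_r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
        folds.append(CVFold(str(site), int(test.sum()), test_r2, resid))
    r2s = np.array([f.test_r2 for f in folds])
    valid = r2s[np.isfinite(r2s)]
    levene_f, levene_p = levene_test(
        np.concatenate([f.residuals for f in folds]),
        np.concatenate([[f.held_out_site] * f.n_test for f in folds]),
    )
    return CVResult(
        folds=folds,
        mean_r2=float(valid.mean()) if valid.size else np.nan,
        sd_r2=float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
        levene_f=levene_f,
        levene_p=levene_p,
    )


# ---------------------------------------------------------------------------
# Levene's test
# ---------------------------------------------------------------------------

def levene_test(
    values: Sequence[float], groups: Sequence, center: str = "mean"
) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test.

    One-way ANOVA F on ``|x_ij - center_j|`` with df (k-1, N-k); the
    classic mean-centered variant is the default, ``center="median"``
    gives the Brown-Forsythe variant.  Groups with fewer than 2
    observations are dropped with a warning.  A degenerate numerator
    (identical group spreads) returns F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if center not in ("mean", "median"):
        raise ConfigError(f"unknown center {center!r}")
    samples = []
    for g in dict.fromkeys(groups.tolist()):
        sample = values[groups == g]
        if sample.size < 2:
            warnings.warn(f"dropping group {g!r} with {sample.size} observation(s)")
            continue
        samples.append(sample)
    if len(samples) < 2:
        raise ConfigError("Levene's test needs >= 2 groups with >= 2 observations")
    centre = np.mean if center == "mean" else np.median
    z = [np.abs(s - centre(s)) for s in samples]
    k = len(z)
    n_total = sum(len(zj) for zj in z)
    zbar = np.concatenate(z).mean()
    between = sum(len(zj) * (zj.mean() - zbar) ** 2 for zj in z)
    within = sum(((zj - zj.mean()) ** 2).sum() for zj in z)
    if between == 0:
        return 0.0, 1.0
    if within == 0:
        return np.inf, 0.0
    f = ((n_total - k) / (k - 1)) * (between / within)
    p = float(scipy.stats.f.sf(f, k - 1, n_total - k))
    return float(f), p


# ---------------------------------------------------------------------------
# Impairment rate
# ---------------------------------------------------------------------------

def impairment_rate(
    sdmt_z: Sequence[float], threshold: float = -1.5
) -> tuple[int, float]:
    """Count and proportion of z-scores strictly below ``threshold``."""
    z = np.asarray(sdmt_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FormatError("non-finite z-score in impairment_rate input")
    count = int((z < threshold).sum())
    return count, count / z.size if z.size else 0.0
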