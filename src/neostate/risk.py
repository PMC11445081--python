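"""Risk-factor modelling for community-state acquisition.

Each community state is modelled one-vs-rest with fixed-effect logistic
regression. Confounding is handled with a hierarchical distal-to-proximal
framework: variables are grouped into ordered blocks (maternal, delivery,
postnatal, week 1, ...), and the adjusted model for an exposure contains all
variables from the exposure's own block and every earlier block. Effect
sizes are adjusted odds ratios (AOR) with Wald 95% confidence intervals;
p-values come from likelihood-ratio tests of the exposure's terms. Only
complete cases enter a model (listwise deletion of the explicit "missing"
level), and variables with more than 15% missingness are excluded from
multivariable models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationError",
    "LogisticFit",
    "HierarchicalModelSpec",
    "build_design",
    "fit_logistic",
    "lrt",
    "hierarchical_aor",
]

MISSING = "missing"
MAX_MISSING_FRACTION = 0.15
_SEPARATION_BETA = 15.0


class SeparationError(RuntimeError):
    """The likelihood diverges: an exposure perfectly separates the outcome."""


@dataclass
class LogisticFit:
    params: pd.Series  # log-odds coefficients, intercept included
    cov: pd.DataFrame
    loglik: float
    n_used: int
    converged: bool

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with Wald 95% confidence intervals."""
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)
        return pd.DataFrame({
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - 1.96 * se),
            "ci_high": np.exp(self.params + 1.96 * se),
        })


def fit_logistic(y, X: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    ``X`` must contain an intercept column. Perfect separation is reported as
    :class:`SeparationError` (any |beta| > 15 after fitting); rank-deficient
    designs are rejected with the offending columns named.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        offending = []
        for j in range(X.shape[1]):
            others = np.delete(Xv, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                offending.append(X.columns[j])
        raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")
    model = sm.Logit(y, Xv)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=False,
                            warn_convergence=False)
    except (np.linalg.LinAlgError, PerfectSeparationError) as err:
        # the design has full rank, so a singular Hessian means the
        # likelihood is diverging along a separating direction
        raise SeparationError(f"perfect separation suspected: {err}") from err
    params = pd.Series(res.params, index=X.columns)
    if np.any(np.abs(params) > _SEPARATION_BETA):
        bad = params.index[np.abs(params) > _SEPARATION_BETA].tolist()
        raise SeparationError(f"perfect separation suspected for: {bad}")
    score = model.score(res.params)
    converged = bool(res.mle_retvals.get("converged", False)) and np.max(np.abs(score)) < 1e-6
    return LogisticFit(
        params=params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        n_used=len(y),
        converged=converged,
    )


def lrt(full: LogisticFit, reduced: LogisticFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested logistic models.

    Returns (statistic, p) with stat = 2 (ll_full - ll_reduced) referred to a
    chi-square with df = the difference in parameter count (upper tail).
    """
    if full.n_used != reduced.n_used:
        raise ValueError("models must be fitted on the same observations")
    df = len(full.params) - len(reduced.params)
    if df < 0 or not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced model must be nested in the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return 0.0, 1.0
    return stat, float(stats.chi2.sf(stat, df))


@dataclass
class HierarchicalModelSpec:
    """Ordered distal-to-proximal variable blocks and the outcome definition.

    ``blocks`` maps block name to its variable list, in distal-to-proximal
    order (dicts preserve insertion order). ``reference_levels`` optionally
    pins the reference category per variable; otherwise the first level in
    sorted order is the reference.
    """

    blocks: dict
    outcome: str  # e.g. "EF" for the EF vs non-EF model
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for block, variables in self.blocks.items():
            for v in variables:
                if v in seen:
                    raise ValueError(f"variable {v!r} assigned to both "
                                     f"{seen[v]!r} and {block!r}")
                seen[v] = block

    def block_of(self, variable: str) -> str:
        for block, variables in self.blocks.items():
            if variable in variables:
                return block
        raise KeyError(f"variable {variable!r} is not in any block")

    def adjustment_set(self, exposure: str) -> list[str]:
        """All variables in the exposure's block and every earlier block."""
        target = self.block_of(exposure)
        out: list[str] = []
        for block, variables in self.blocks.items():
            out.extend(variables)
            if block == target:
                break
        return out


def build_design(data: pd.DataFrame, variables, spec: HierarchicalModelSpec | None = None
                 ) -> pd.DataFrame:
    """Dummy-coded design matrix with intercept for the given variables.

    Categorical variables are expanded against their reference level; numeric
    variables enter as-is. Rows containing the explicit "missing" level (or
    NaN) must be removed by the caller beforehand.
    """
    cols = {"intercept": np.ones(len(data))}
    for v in variables:
        col = data[v]
        if pd.api.types.is_numeric_dtype(col):
            cols[v] = col.to_numpy(dtype=float)
            continue
        levels = sorted(col.astype(str).unique())
        ref = spec.reference_levels.get(v, levels[0]) if spec else levels[0]
        for level in levels:
            if level == ref:
                continue
            cols[f"{v}[{level}]"] = (col.astype(str) == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def _complete_cases(data: pd.DataFrame, variables) -> pd.DataFrame:
    mask = np.ones(len(data), dtype=bool)
    for v in variables:
        col = data[v]
        mask &= col.notna().to_numpy()
        if not pd.api.types.is_numeric_dtype(col):
            mask &= (col.astype(str) != MISSING).to_numpy()
    return data.loc[mask]


def hierarchical_aor(data: pd.DataFrame, spec: HierarchicalModelSpec, exposure: str,
                     extra_adjust: list | None = None) -> dict:
    """Adjusted odds ratio for one exposure under the hierarchical framework.

    The model adjusts for every variable in the exposure's block and earlier
    blocks (optionally plus ``extra_adjust`` terms, e.g. the week-1 state for
    sensitivity analyses). The exposure's p-value is a likelihood-ratio test
    of all its levels jointly. Variables (other than the exposure) with more
    than 15% missingness are dropped from the adjustment set with a log note.
    """
    adjust = spec.adjustment_set(exposure)
    if extra_adjust:
        adjust = adjust + [v for v in extra_adjust if v not in adjust]
    kept = []
    for v in adjust:
        col = data[v]
        frac_missing = float(
            (col.isna() | (col.astype(str) == MISSING)).mean()
            if not pd.api.types.is_numeric_dtype(col) else col.isna().mean()
        )
        if v != exposure and frac_missing > MAX_MISSING_FRACTION:
            logger.info("dropping %r from adjustment set (%.0f%% missing)",
                        v, 100 * frac_missing)
            continue
        kept.append(v)
    if exposure not in kept:
        kept.append(exposure)

    outcome_col = spec.outcome + "_outcome"
    if outcome_col not in data.columns:
        raise KeyError(f"data must contain a binary column {outcome_col!r}")
    complete = _complete_cases(data, kept)
    y = complete[outcome_col].to_numpy(dtype=float)
    n_dropped = len(data) - len(complete)

    X_full = build_design(complete, kept, spec)
    exposure_cols = [c for c in X_full.columns if c == exposure or c.startswith(f"{exposure}[")]
    X_reduced = X_full.drop(columns=exposure_cols)
    try:
        full = fit_logistic(y, X_full)
        reduced = fit_logistic(y, X_reduced)
    except SeparationError as err:
        return {"exposure": exposure, "error": str(err), "n_used": len(complete),
                "n_dropped_missing": n_dropped}
    stat, p = lrt(full, reduced)
    ors = full.odds_ratios().loc[exposure_cols]
    return {
        "exposure": exposure,
        "aor": ors["or"].to_dict(),
        "ci_low": ors["ci_low"].to_dict(),
        "ci_high": ors["ci_high"].to_dict(),
        "p_lrt": p,
        "lrt_stat": stat,
        "n_used": full.n_used,
        "n_dropped_missing": n_dropped,
        "adjusted_for": [v for v in kept if v != exposure],
        "fit": full,
    }
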