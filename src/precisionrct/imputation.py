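"""Multiple imputation by chained equations (MICE) with predictive-mean
matching, producing an odd number of completed datasets (default 11) for
per-imputation treatment-rule estimation and a downstream plurality vote.

Only non-CGM baseline covariates are imputed; arm and outcomes are complete
by construction (participants missing outcomes are excluded upstream) and
enter every conditional model as predictors.  Continuous and count columns
use a linear model followed by a predictive-mean-matching draw from the k
nearest observed donors; binary/categorical columns use a multinomial draw
from logistic-model probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ParticipantTable

logger = logging.getLogger(__name__)

__all__ = ["ImputedStack", "initial_fill", "mice_sweep", "generate_imputations"]

_PMM_DONORS = 5
_RIDGE = 1e-8  # stabilizes the normal equations; singular designs still fall back


@dataclass
class ImputedStack:
    """m completed copies of one participant table.

    m is required to be odd so the downstream per-participant plurality vote
    over the m rule assignments cannot tie between two arms.
    """

    datasets: list[ParticipantTable]
    seed: int
    n_cycles: int

    @property
    def m(self) -> int:
        return len(self.datasets)


def _design_matrix(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X = df[predictors].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def initial_fill(table: ParticipantTable, seed: int) -> ParticipantTable:
    """Warm start: fill each missing cell with a random draw from the
    observed values of its column."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    df = out.df
    for col in table.covariates:
        miss = df[col].isna()
        if not miss.any():
            continue
        observed = df.loc[~miss, col].to_numpy()
        if observed.size == 0:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        df.loc[miss, col] = rng.choice(observed, size=int(miss.sum()))
    return out


def _impute_continuous(y_obs, X_obs, X_mis, fallback, rng) -> np.ndarray:
    """Linear fit + predictive-mean-matching draw from the k nearest donors."""
    try:
        XtX = X_obs.T @ X_obs + _RIDGE * np.eye(X_obs.shape[1])
        beta = np.linalg.solve(XtX, X_obs.T @ y_obs)
    except np.linalg.LinAlgError:
        logger.warning("singular design in conditional model; marginal donor draw")
        return rng.choice(fallback, size=len(X_mis))
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ beta
    k = min(_PMM_DONORS, len(y_obs))
    out = np.empty(len(X_mis))
    for i, p in enumerate(pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - p), k - 1)[:k]
        out[i] = y_obs[nearest[rng.integers(k)]]
    return out


def _impute_categorical(y_obs, X_obs, X_mis, rng) -> np.ndarray:
    """Multinomial-probability draw from a one-vs-rest logistic model."""
    from sklearn.linear_model import LogisticRegression

    cats, codes = np.unique(y_obs, return_inverse=True)
    if len(cats) < 2:
        return np.full(len(X_mis), cats[0])
    # scale predictors for solver stability; sklearn adds its own intercept
    loc = X_obs[:, 1:].mean(axis=0)
    scale = X_obs[:, 1:].std(axis=0)
    scale[scale == 0] = 1.0
    try:
        model = LogisticRegression(max_iter=1000)
        model.fit((X_obs[:, 1:] - loc) / scale, codes)
        probs = model.predict_proba((X_mis[:, 1:] - loc) / scale)
    except Exception:  # pragma: no cover - defensive
        logger.warning("logistic conditional model failed; marginal donor draw")
        return rng.choice(y_obs, size=len(X_mis))
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return cats[idx]


def mice_sweep(
    table: ParticipantTable,
    mask: pd.DataFrame,
    rng: np.random.Generator,
) -> ParticipantTable:
    """One chained-equations sweep over the columns with missingness.

    ``table`` must already be fully filled (post :func:`initial_fill`);
    ``mask`` marks the originally-missing cells, which are the only cells
    replaced.  Columns are visited in order of increasing missingness
    fraction; each conditional model regresses the column on all other
    covariates plus arm and the six outcome fields.
    """
    out = table.copy()
    df = out.df
    cols = [c for c in table.covariates if c in mask.columns and mask[c].any()]
    cols.sort(key=lambda c: (mask[c].mean(), c))
    outcome_predictors = ["arm", "hba1c_0", "hba1c_18", "qol_0", "qol_18", "bmiz_0", "bmiz_18"]
    for col in cols:
        predictors = [c for c in table.covariates if c != col] + outcome_predictors
        X = _design_matrix(df, predictors)
        miss = mask[col].to_numpy()
        y_obs = df.loc[~miss, col].to_numpy(dtype=float)
        X_obs, X_mis = X[~miss], X[miss]
        kind = table.kinds.get(col, "continuous")
        if kind in ("binary", "categorical"):
            filled = _impute_categorical(y_obs, X_obs, X_mis, rng)
        else:
            filled = _impute_continuous(y_obs, X_obs, X_mis, y_obs, rng)
        df.loc[miss, col] = filled
    return out


def generate_imputations(
    table: ParticipantTable,
    m: int = 11,
    n_cycles: int = 10,
    seed: int = 0,
) -> ImputedStack:
    """Run m independent MICE chains, each for ``n_cycles`` sweeps.

    Observed cells are identical across all m completed datasets and equal to
    the input; only originally-missing covariate cells vary between chains.
    """
    if m % 2 == 0:
        raise ValueError("m must be odd so the plurality vote cannot tie between arms")
    if m < 1:
        raise ValueError("m must be positive")
    mask = table.missing_mask()
    if not mask.to_numpy().any():
        return ImputedStack([table.copy() for _ in range(m)], seed, n_cycles)
    root = np.random.SeedSequence(seed)
    datasets = []
    for chain_seq in root.spawn(m):
        rng = np.random.default_rng(chain_seq)
        filled = initial_fill(table, int(chain_seq.generate_state(1)[0] % 2**31))
        for _ in range(n_cycles):
            filled = mice_sweep(filled, mask, rng)
        datasets.append(filled)
    return ImputedStack(datasets, seed, n_cycles)
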