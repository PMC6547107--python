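"""From counterfactual predictions to the three-group individualized
treatment rule (ITR) and the final plurality-vote assignment.

Within each completed dataset a muting forest is fit to (standardized X,
arm) -> reward, with the arm indicator entering as an ordinary covariate.
Each participant's expected reward is predicted under both arms; they are
assigned to the *intervention* group when the predicted reward is higher
under intervention, to the *control* group when higher under usual care, and
to the *muted* group when the two predictions are identically equal — which
happens exactly when the arm variable was muted off every routing path used
for that participant.  The final label is the plurality winner over the m
per-imputation labels; plurality ties (possible with three categories even
for odd m, e.g. 4/4/3) resolve conservatively to muted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import RLTForest, RLTParams, fit_forest, predict
from .imputation import ImputedStack
from .rewards import standardize_covariates

__all__ = [
    "INTERVENTION",
    "CONTROL",
    "MUTED",
    "GROUP_LABELS",
    "counterfactual_rewards",
    "assign_group",
    "plurality_vote",
    "estimate_itr",
    "ITRResult",
]

INTERVENTION = "intervention"
CONTROL = "control"
MUTED = "muted"
GROUP_LABELS = (INTERVENTION, CONTROL, MUTED)


def counterfactual_rewards(forest: RLTForest, x) -> tuple:
    """Predicted reward under each arm for one participant or a matrix.

    Returns ``(r1_hat, r0_hat)``: the forest prediction with the treatment
    coordinate forced to 1 and to 0 respectively, all other coordinates
    untouched.  The arm indicator is kept on its raw 0/1 coding (binary
    covariates are not standardized).
    """
    if forest.treatment_var is None:
        raise ValueError("forest does not record a treatment_var index")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :].copy() if single else x.copy()
    X[:, forest.treatment_var] = 1.0
    r1 = predict(forest, X)
    X[:, forest.treatment_var] = 0.0
    r0 = predict(forest, X)
    if single:
        return float(r1[0]), float(r0[0])
    return r1, r0


def assign_group(r1_hat, r0_hat, tol: float = 0.0):
    """Three-way group label from the pair of counterfactual predictions.

    tol=0 means the muted label requires *exact* equality, which with this
    forest occurs precisely when the treatment variable sits on no routing
    path; a small positive tol is available for finite-precision robustness.
    """
    r1 = np.asarray(r1_hat, dtype=float)
    r0 = np.asarray(r0_hat, dtype=float)
    if np.any(np.isnan(r1)) or np.any(np.isnan(r0)):
        raise ValueError("assign_group: NaN prediction")
    labels = np.where(
        r1 - r0 > tol, INTERVENTION, np.where(r0 - r1 > tol, CONTROL, MUTED)
    )
    if labels.ndim == 0:
        return str(labels)
    return labels


def plurality_vote(labels, m: int = 11) -> str:
    """Plurality winner over the m per-imputation labels; ties -> muted."""
    labels = list(labels)
    if len(labels) != m:
        raise ValueError(f"expected {m} labels, got {len(labels)}")
    counts = {g: labels.count(g) for g in GROUP_LABELS}
    top = max(counts.values())
    winners = [g for g, c in counts.items() if c == top]
    return winners[0] if len(winners) == 1 else MUTED


@dataclass
class ITRResult:
    """Per-participant assignment table plus the fitted per-imputation forests."""

    assignments: pd.DataFrame  # id, label_1..label_m, votes, final, mean r-hats
    forests: list[RLTForest]

    @property
    def final(self) -> np.ndarray:
        return self.assignments["final"].to_numpy()


def _feature_matrix(table, reward_column: str):
    """Participant features for the forest: baseline covariates plus arm.

    Continuous and count covariates are standardized to mean 0 / SD 1 within
    the dataset; binary covariates keep their 0/1 coding; the arm indicator
    is appended last on its raw 0/1 coding.  Reward columns are outcomes,
    never features.
    """
    from .rewards import REWARD_COLUMNS

    not_features = set(REWARD_COLUMNS.values()) | {reward_column}
    covs = [c for c in table.covariates if c not in not_features]
    df = table.df
    binary = [c for c in covs if table.kinds.get(c) == "binary"]
    # baseline clinical measures are covariates of the rule alongside X
    numeric = [c for c in covs if c not in binary] + ["hba1c_0", "qol_0", "bmiz_0"]
    blocks = []
    names = []
    if numeric:
        Z, _, _ = standardize_covariates(df[numeric])
        blocks.append(np.asarray(Z))
        names.extend(numeric)
    if binary:
        blocks.append(df[binary].to_numpy(dtype=float))
        names.extend(binary)
    blocks.append(df[["arm"]].to_numpy(dtype=float))
    names.append("arm")
    X = np.column_stack(blocks)
    y = df[reward_column].to_numpy(dtype=float)
    return X, y, names


def estimate_itr(
    stack: ImputedStack,
    reward_column: str,
    params: RLTParams = RLTParams(),
    tol: float = 0.0,
) -> ITRResult:
    """Fit one muting forest per completed dataset and vote.

    Per dataset: standardize covariates, fit the forest on (X, arm) ->
    reward with a sub-seed derived from ``params.seed`` and the imputation
    index, predict counterfactual rewards for every participant, and assign
    a three-way label.  The final label is the per-participant plurality
    winner over the m datasets.
    """
    m = stack.m
    if m % 2 == 0:
        raise ValueError("imputation stack must hold an odd number of datasets")
    first = stack.datasets[0]
    ids = first.df["id"].to_numpy()
    n = len(ids)
    label_mat = np.empty((n, m), dtype=object)
    r1_mat = np.empty((n, m))
    r0_mat = np.empty((n, m))
    forests = []
    for j, table in enumerate(stack.datasets):
        if table.df[table.covariates].isna().to_numpy().any():
            raise ValueError(f"imputed dataset {j} still contains missing covariates")
        X, y, names = _feature_matrix(table, reward_column)
        sub_params = RLTParams(**{**params.__dict__, "seed": params.seed + 1000003 * j})
        forest = fit_forest(
            X, y, sub_params, treatment_var=X.shape[1] - 1, feature_names=names
        )
        r1, r0 = counterfactual_rewards(forest, X)
        label_mat[:, j] = assign_group(r1, r0, tol)
        r1_mat[:, j] = r1
        r0_mat[:, j] = r0
        forests.append(forest)

    final = [plurality_vote(list(label_mat[i]), m) for i in range(n)]
    out = pd.DataFrame({"id": ids})
    for j in range(m):
        out[f"label_{j + 1}"] = label_mat[:, j]
    for g in GROUP_LABELS:
        out[f"votes_{g}"] = (label_mat == g).sum(axis=1)
    out["final"] = final
    out["r1_hat_mean"] = r1_mat.mean(axis=1)
    out["r0_hat_mean"] = r0_mat.mean(axis=1)
    return ITRResult(out, forests)
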