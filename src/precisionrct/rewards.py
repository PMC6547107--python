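"""Clinical rewards: scaled univariate outcomes and the hierarchical composite.

Each 18-month change is mapped to a reward in [0, 1] where higher is
clinically better.  The composite reward in [0, 3] encodes a strict clinical
hierarchy — glycemic control first, quality of life second, weight status
last — by tiering: any participant with unacceptable 18-month HbA1c scores in
[0, 1) regardless of QoL or BMIz; acceptable HbA1c with unacceptable QoL
scores in [1, 2); and both acceptable scores in [2, 3], graded by BMIz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RewardConfig",
    "hba1c_reward",
    "qol_reward",
    "bmiz_reward",
    "composite_reward",
    "compute_rewards",
    "standardize_covariates",
    "REWARD_COLUMNS",
]

#: reward column per outcome name, as appended to participant tables
REWARD_COLUMNS = {"hba1c": "r_H", "qol": "r_Q", "bmiz": "r_B", "composite": "r_C"}


@dataclass(frozen=True)
class RewardConfig:
    """Fixed clinical scaling bounds and composite tier thresholds.

    Bounds are on the 18-month *change*; they are fixed clinical constants
    (not per-sample extremes) so the reward scale is identical across
    imputations and bootstrap resamples.  ``bmiz_threshold`` = 1.04 is the
    85th BMI percentile for age and sex, the conventional overweight cut.
    """

    hba1c_delta_bounds: tuple[float, float] = (5.0, -5.0)  # (worst, best) change
    qol_delta_bounds: tuple[float, float] = (-30.0, 30.0)  # (worst, best) change
    bmiz_threshold: float = 1.04
    bmiz_penalty_scale: float = 1.0  # z units of worsening mapping reward to 0
    hba1c_acceptable: float = 9.0  # 18-month level below which HbA1c is acceptable
    qol_acceptable: float = 70.0  # 18-month level at/above which QoL is acceptable

    def validate(self) -> None:
        worst_h, best_h = self.hba1c_delta_bounds
        if not best_h < worst_h:
            raise ValueError("hba1c_delta_bounds: best change must be below worst "
                             "(lower HbA1c change is better)")
        worst_q, best_q = self.qol_delta_bounds
        if not worst_q < best_q:
            raise ValueError("qol_delta_bounds: best change must exceed worst")
        if self.bmiz_penalty_scale <= 0:
            raise ValueError("bmiz_penalty_scale must be positive")
        for name in ("bmiz_threshold", "hba1c_acceptable", "qol_acceptable"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _check_finite(name: str, *arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name}: non-finite input")


def hba1c_reward(h0, h18, cfg: RewardConfig = RewardConfig()):
    """Reward for 18-month HbA1c change; 1 at the best bound (large drop),
    0 at the worst bound (large rise), linear and clipped in between."""
    h0 = np.asarray(h0, dtype=float)
    h18 = np.asarray(h18, dtype=float)
    _check_finite("hba1c_reward", h0, h18)
    worst, best = cfg.hba1c_delta_bounds
    delta = np.clip(h18 - h0, best, worst)
    return (worst - delta) / (worst - best)


def qol_reward(q0, q18, cfg: RewardConfig = RewardConfig()):
    """Reward for 18-month quality-of-life change; higher change is better."""
    q0 = np.asarray(q0, dtype=float)
    q18 = np.asarray(q18, dtype=float)
    _check_finite("qol_reward", q0, q18)
    if np.any((q0 < 0) | (q0 > 100) | (q18 < 0) | (q18 > 100)):
        raise ValueError("qol_reward: PedsQL scores must lie in [0, 100]")
    worst, best = cfg.qol_delta_bounds
    delta = np.clip(q18 - q0, worst, best)
    return (delta - worst) / (best - worst)


def bmiz_reward(b0, b18, cfg: RewardConfig = RewardConfig()):
    """Constrained weight-status reward.

    Full reward (1) for finishing at a healthy BMI z-score (<= threshold) or
    for improving on an unhealthy baseline; otherwise a linear penalty on the
    amount of worsening, reaching 0 at ``bmiz_penalty_scale`` z units.
    """
    b0 = np.asarray(b0, dtype=float)
    b18 = np.asarray(b18, dtype=float)
    _check_finite("bmiz_reward", b0, b18)
    healthy_or_improved = (b18 <= cfg.bmiz_threshold) | (b18 < b0)
    penalty = np.maximum(0.0, 1.0 - (b18 - b0) / cfg.bmiz_penalty_scale)
    return np.where(healthy_or_improved, 1.0, penalty)


def composite_reward(h18, q18, r_H, r_Q, r_B, cfg: RewardConfig = RewardConfig()):
    """Hierarchical composite reward in [0, 3].

    Tier 0 (HbA1c unacceptable): r_C = r_H — a low score regardless of QoL
    and BMIz.  Tier 1 (HbA1c acceptable, QoL unacceptable): r_C = 1 + r_Q.
    Tier 2 (both acceptable): r_C = 2 + r_B.  Every tier-k participant
    therefore scores at least k, at most k + 1.
    """
    h18 = np.asarray(h18, dtype=float)
    q18 = np.asarray(q18, dtype=float)
    r_H = np.asarray(r_H, dtype=float)
    r_Q = np.asarray(r_Q, dtype=float)
    r_B = np.asarray(r_B, dtype=float)
    _check_finite("composite_reward", h18, q18, r_H, r_Q, r_B)
    hba1c_ok = h18 < cfg.hba1c_acceptable
    qol_ok = q18 >= cfg.qol_acceptable
    return np.where(~hba1c_ok, r_H, np.where(~qol_ok, 1.0 + r_Q, 2.0 + r_B))


def compute_rewards(table, cfg: RewardConfig = RewardConfig()):
    """Append reward columns r_H, r_Q, r_B, r_C to a participant table."""
    cfg.validate()
    out = table.copy()
    df = out.df
    df["r_H"] = hba1c_reward(df["hba1c_0"], df["hba1c_18"], cfg)
    df["r_Q"] = qol_reward(df["qol_0"], df["qol_18"], cfg)
    df["r_B"] = bmiz_reward(df["bmiz_0"], df["bmiz_18"], cfg)
    df["r_C"] = composite_reward(
        df["hba1c_18"], df["qol_18"], df["r_H"], df["r_Q"], df["r_B"], cfg
    )
    return out


def standardize_covariates(X):
    """Center/scale each column to sample mean 0 and sample SD 1 (ddof=1).

    Returns ``(Z, location, scale)``; the location/scale vectors let the same
    affine transform be reused on counterfactual feature vectors.
    Zero-variance columns pass through as all-zeros with a warning (their
    scale is reported as 1).
    """
    is_frame = isinstance(X, pd.DataFrame)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("standardize_covariates: need a 2-D array with >= 2 rows")
    loc = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    degenerate = scale == 0
    if np.any(degenerate):
        cols = list(X.columns[degenerate]) if is_frame else np.nonzero(degenerate)[0].tolist()
        msg = f"zero-variance columns passed through as zeros: {cols}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        scale = np.where(degenerate, 1.0, scale)
    Z = (arr - loc) / scale
    if is_frame:
        Z = pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z, loc, scale
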