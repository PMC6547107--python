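"""Inverse-probability-weighted value of a treatment rule, fixed-regime
comparisons, and bootstrap confidence intervals.

The value of a rule d is estimated by the normalized (ratio) Horvitz-
Thompson form over rule-concordant participants,

    V-hat(d) = sum_i I{A_i = d_i} w_i R_i / sum_i I{A_i = d_i} w_i ,
    w_i = 1/p if A_i = 1 else 1/(1 - p),

with p the randomization probability.  The ratio form keeps V-hat inside the
reward's range (e.g. [0, 3] for the composite reward) and reduces exactly to
the within-arm mean for a constant-arm rule.  Participants labelled *muted*
by the ITR are, by default, evaluated under their observed arm — the rule
declares both arms equivalent for them — so every participant remains
eligible for concordance; they can instead be excluded by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assignment import CONTROL, INTERVENTION, MUTED

logger = logging.getLogger(__name__)

__all__ = [
    "Rule",
    "ValueEstimate",
    "ValueComparison",
    "rule_from_labels",
    "ipw_value",
    "fixed_regime_value",
    "value_comparison",
]


@dataclass(frozen=True)
class Rule:
    """Per-participant recommended arm with provenance.

    ``d`` holds one arm in {0, 1} per participant, or -1 for muted
    participants under the 'exclude' handling policy (such rows are dropped
    from the value numerator and denominator).
    """

    d: np.ndarray
    provenance: str = "estimated ITR"

    def __post_init__(self):
        d = np.asarray(self.d)
        if not np.isin(d, (-1, 0, 1)).all():
            raise ValueError("rule entries must be in {-1, 0, 1}")
        object.__setattr__(self, "d", d.astype(int))


def rule_from_labels(labels, A, muted_policy: str = "observed") -> Rule:
    """Build a Rule from three-way ITR labels.

    muted_policy 'observed' maps muted participants to their observed arm
    (both arms are declared equivalent for them); 'exclude' drops them from
    value estimation.
    """
    labels = np.asarray(labels)
    A = np.asarray(A, dtype=int)
    if muted_policy not in ("observed", "exclude"):
        raise ValueError("muted_policy must be 'observed' or 'exclude'")
    d = np.where(labels == INTERVENTION, 1, np.where(labels == CONTROL, 0, -1))
    if muted_policy == "observed":
        d = np.where(labels == MUTED, A, d)
    return Rule(d, provenance="estimated ITR")


@dataclass
class ValueEstimate:
    """Point value of one rule: v_hat on the reward scale, plus the count of
    rule-concordant participants actually contributing to it."""

    v_hat: float
    n_concordant: int
    provenance: str = ""


@dataclass
class ValueComparison:
    """One Table-2-style row: a value difference with a percentile CI."""

    name: str
    diff: float
    lo: float
    hi: float
    B: int
    seed: int
    n_redrawn: int = 0


def ipw_value(A, d, R, p: float = 0.5) -> ValueEstimate:
    """Normalized IPW value of rule ``d`` (array of arms, or a Rule)."""
    A = np.asarray(A, dtype=int)
    R = np.asarray(R, dtype=float)
    rule = d if isinstance(d, Rule) else Rule(np.asarray(d))
    if not 0 < p < 1:
        raise ValueError("randomization probability p must lie strictly in (0, 1)")
    if len(A) != len(R) or len(A) != len(rule.d):
        raise ValueError("A, d and R must have equal length")
    keep = rule.d >= 0  # muted-excluded rows carry -1
    concordant = keep & (A == rule.d)
    if not concordant.any():
        raise ValueError("no rule-concordant participants; value is inestimable")
    w = np.where(A == 1, 1.0 / p, 1.0 / (1.0 - p))
    num = float(np.sum(w[concordant] * R[concordant]))
    den = float(np.sum(w[concordant]))
    return ValueEstimate(num / den, int(concordant.sum()), rule.provenance)


def fixed_regime_value(A, R, arm: int, p: float = 0.5) -> ValueEstimate:
    """Value of the constant rule assigning every participant to ``arm``.

    Under the normalized estimator this equals the mean reward within the
    observed ``arm`` group.
    """
    A = np.asarray(A, dtype=int)
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    if not np.any(A == arm):
        raise ValueError(f"arm {arm} is absent from the data")
    name = "fixed-intervention" if arm == 1 else "fixed-control"
    rule = Rule(np.full(len(A), arm), provenance=name)
    return ipw_value(A, rule, R, p)


def value_comparison(
    A,
    R,
    itr: Rule,
    p: float = 0.5,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Point estimates and percentile bootstrap CIs for the two fixed-regime
    contrasts v_opt - v_trt and v_opt - v_ctrl.

    Participants are resampled with replacement, the rule held fixed; a
    resample in which a required quantity is inestimable (no concordant
    participant, or an arm entirely absent) is redrawn and the redraw count
    logged.  CIs are the 2.5/97.5 percentiles of the B bootstrap differences.
    """
    A = np.asarray(A, dtype=int)
    R = np.asarray(R, dtype=float)
    if B < 100:
        raise ValueError("B must be at least 100")
    v_opt = ipw_value(A, itr, R, p)
    v_trt = fixed_regime_value(A, R, 1, p)
    v_ctrl = fixed_regime_value(A, R, 0, p)

    rng = np.random.default_rng(seed)
    n = len(A)
    diffs = np.empty((B, 2))
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(n, size=n)
        try:
            vo = ipw_value(A[idx], Rule(itr.d[idx]), R[idx], p).v_hat
            vt = fixed_regime_value(A[idx], R[idx], 1, p).v_hat
            vc = fixed_regime_value(A[idx], R[idx], 0, p).v_hat
        except ValueError:
            n_redrawn += 1
            if n_redrawn > 100 * B:
                raise RuntimeError("bootstrap cannot find estimable resamples")
            continue
        diffs[b] = (vo - vt, vo - vc)
        b += 1
    if n_redrawn:
        logger.warning("bootstrap redrew %d inestimable resamples", n_redrawn)

    out = {"v_opt": v_opt, "v_trt": v_trt, "v_ctrl": v_ctrl}
    for j, (name, v_fixed) in enumerate((("v_opt - v_trt", v_trt), ("v_opt - v_ctrl", v_ctrl))):
        lo, hi = np.percentile(diffs[:, j], (2.5, 97.5))
        out[name] = ValueComparison(
            name, v_opt.v_hat - v_fixed.v_hat, float(lo), float(hi), B, seed, n_redrawn
        )
    return out
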