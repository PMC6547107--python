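"""End-to-end orchestration: simulate (or load) -> eligibility -> rewards ->
impute -> per-outcome ITR -> value evaluation -> subgroup profiles.

A single master seed governs every stage; stage sub-seeds are derived
deterministically and independently, so changing, say, the number of
bootstrap replicates never changes the ITR assignments.  A run manifest
records participant-flow counts (CONSORT-style), sub-seeds, and the
reconstruction flags of the analysis (composite tier thresholds, the
normalized form of the value estimator, rule-fixed bootstrap).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assignment as asg
from . import cohort as ch
from . import imputation as imp
from . import profiles as prof
from . import rewards as rw
from . import value as val
from .forest import RLTParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_analysis"]

OUTCOME_CHOICES = ("hba1c", "qol", "bmiz", "composite")

# stage-name -> fixed offset used to derive independent sub-seeds
_STAGE_OFFSETS = {"simulate": 1, "impute": 2, "itr": 3, "value": 4, "profile": 5}


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_csv: str | None = None  # when None, a cohort is simulated
    n_enrolled: int = 258
    effect_scale: float = 1.0
    reward: rw.RewardConfig = field(default_factory=rw.RewardConfig)
    m_imputations: int = 11
    n_cycles: int = 10
    rlt: RLTParams = field(default_factory=RLTParams)
    randomization_prob: float = 0.5
    bootstrap_B: int = 1000
    outcomes: tuple[str, ...] = OUTCOME_CHOICES
    complete_cases: bool = False  # sensitivity mode: skip imputation, drop incomplete rows
    seed: int = 0
    outdir: str = "precisionrct_run"

    def validate(self) -> None:
        if not self.outcomes:
            raise ValueError("outcomes must be non-empty")
        unknown = set(self.outcomes) - set(OUTCOME_CHOICES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")
        self.reward.validate()
        self.rlt.validate()
        if self.m_imputations % 2 == 0:
            raise ValueError("m_imputations must be odd")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reward = rw.RewardConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("reward", {}).items()
        })
        rlt = RLTParams(**raw.pop("rlt", {}))
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        cfg = cls(reward=reward, rlt=rlt, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Reproducibility record written next to the stage outputs."""

    config_hash: str
    seed: int
    sub_seeds: dict
    flow: dict  # CONSORT-style stage-by-stage row counts
    reconstruction_flags: tuple[str, ...] = (
        "composite tier thresholds (HbA1c 9.0 %, QoL 70) are configurable reconstructions",
        "value estimator uses the normalized (ratio) IPW form",
        "bootstrap holds the estimated rule fixed across resamples",
    )
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sub_seed(master: int, stage: str, k: int = 0) -> int:
    return int(
        np.random.SeedSequence([master, _STAGE_OFFSETS[stage], k]).generate_state(1)[0]
        % 2**31
    )


def _default_schema(table: ch.ParticipantTable) -> list[prof.Variable]:
    schema = []
    for c in table.covariates:
        kind = table.kinds.get(c, "continuous")
        if kind == "binary":
            schema.append(prof.Variable(c, "categorical", (0.0, 1.0)))
        elif kind == "count":
            # CGM-derived hypoglycemia counts are right skewed
            schema.append(prof.Variable(c, "skewed"))
        else:
            schema.append(prof.Variable(c, "continuous"))
    schema.append(prof.Variable("hba1c_0", "continuous"))
    schema.append(prof.Variable("qol_0", "continuous"))
    schema.append(prof.Variable("bmiz_0", "continuous"))
    return schema


def run_analysis(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all stage outputs to
    ``config.outdir``.  Returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    flow = {}
    sub_seeds = {}
    warnings_log: list[str] = []

    # --- cohort ---------------------------------------------------------
    if config.input_csv is None:
        sub_seeds["simulate"] = _sub_seed(config.seed, "simulate")
        spec = ch.default_cohort_spec(
            n_enrolled=config.n_enrolled,
            seed=sub_seeds["simulate"],
            effect_scale=config.effect_scale,
        )
        table = ch.generate_cohort(spec)
    else:
        table = ch.ParticipantTable.from_csv(config.input_csv)
    flow["enrolled"] = table.n
    table.to_csv(outdir / "cohort_enrolled.csv")

    table, counts = ch.apply_eligibility(table)
    flow["excluded_cgm_incomplete"] = counts.n_cgm_incomplete
    flow["excluded_outcome_missing"] = counts.n_outcome_missing
    flow["analyzed"] = counts.n_retained
    if flow["enrolled"] - flow["excluded_cgm_incomplete"] - flow["excluded_outcome_missing"] != flow["analyzed"]:
        raise RuntimeError("participant-flow counts do not telescope")

    # --- rewards --------------------------------------------------------
    table = rw.compute_rewards(table, config.reward)
    table.to_csv(outdir / "cohort_rewards.csv")

    # --- imputation -----------------------------------------------------
    if config.complete_cases:
        complete = table.df[table.covariates].notna().all(axis=1)
        cc = ch.ParticipantTable(table.df[complete].reset_index(drop=True), dict(table.kinds))
        flow["complete_cases"] = cc.n
        stack = imp.ImputedStack([cc], seed=config.seed, n_cycles=0)
        table = cc
    else:
        sub_seeds["impute"] = _sub_seed(config.seed, "impute")
        stack = imp.generate_imputations(
            table, m=config.m_imputations, n_cycles=config.n_cycles,
            seed=sub_seeds["impute"],
        )
    flow["imputed_datasets"] = stack.m

    # --- per-outcome ITR, value, profile --------------------------------
    A = table.df["arm"].to_numpy(dtype=int)
    schema = _default_schema(table)
    for k, outcome in enumerate(config.outcomes):
        reward_col = rw.REWARD_COLUMNS[outcome]
        rlt = RLTParams(**{**config.rlt.__dict__, "seed": _sub_seed(config.seed, "itr", k)})
        sub_seeds[f"itr_{outcome}"] = rlt.seed
        itr = asg.estimate_itr(stack, reward_col, rlt)
        itr.assignments.to_csv(outdir / f"itr_{outcome}.csv", index=False)
        if itr.forests:
            (outdir / f"forest_{outcome}.json").write_text(itr.forests[0].to_json())

        R = table.df[reward_col].to_numpy(dtype=float)
        rule = val.rule_from_labels(itr.final, A, muted_policy="observed")
        sub_seeds[f"value_{outcome}"] = _sub_seed(config.seed, "value", k)
        comp = val.value_comparison(
            A, R, rule, p=config.randomization_prob,
            B=config.bootstrap_B, seed=sub_seeds[f"value_{outcome}"],
        )
        rows = [
            {"quantity": "v_opt", "estimate": comp["v_opt"].v_hat, "lo": "", "hi": ""},
            {"quantity": "v_trt", "estimate": comp["v_trt"].v_hat, "lo": "", "hi": ""},
            {"quantity": "v_ctrl", "estimate": comp["v_ctrl"].v_hat, "lo": "", "hi": ""},
        ]
        for key in ("v_opt - v_trt", "v_opt - v_ctrl"):
            c = comp[key]
            rows.append({"quantity": key, "estimate": c.diff, "lo": c.lo, "hi": c.hi})
            if c.n_redrawn:
                warnings_log.append(f"{outcome}: {c.n_redrawn} bootstrap resamples redrawn")
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / f"value_{outcome}.csv", index=False)

        rng = np.random.default_rng(_sub_seed(config.seed, "profile", k))
        summary, tests = prof.profile_report(table, itr.final, schema, rng=rng)
        summary.to_csv(outdir / f"profile_summary_{outcome}.csv", index=False)
        tests.to_csv(outdir / f"profile_tests_{outcome}.csv", index=False)

    manifest = RunManifest(config_hash, config.seed, sub_seeds, flow, warnings=warnings_log)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
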