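"""Scenario definitions, replicate execution and aggregation.

Six reference scenarios combine two goals.  Scenarios b1-b3 aim at improving
the functional trait B (cryobank bulls chosen by highest total merit index
and/or a stage-2 criterion switch from EBVA to the TMI); scenarios d1-d3 aim
at restoring genetic diversity (cryobank bulls chosen by minimum mean
kinship with the current population and/or conservation of male lines):

====  ===================  =========  =========  =================
code  cryobank choice      % sons     criterion  male lines
====  ===================  =========  =========  =================
b1    best_TMI             40         EBVA       no
b2    (not used)           0          TMI        no
b3    best_TMI             40         TMI        no
d1    min_mean_kinship     40         EBVA       no
d2    (not used)           0          EBVA       conserved
d3    min_mean_kinship     40         EBVA       conserved
====  ===================  =========  =========  =================

Replicates are reproducible: a master seed spawns one independent substream
per replicate, and inside a replicate one substream per stage/branch.
Because stage 1 is identical in distribution for every scenario, several
scenarios can share each replicate's stage-1 run and branch at generation 8;
:func:`run_replicates_shared` does exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cryobank as cb
from .scheme import (
    BANK_ALL,
    BANK_FRENCH,
    CRITERION_EBVA,
    CRITERION_TMI,
    ScenarioRun,
    SchemeConfig,
    run_stage1,
    run_stage2,
)

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "AggregateSummary",
    "build_scenario",
    "run_replicates",
    "run_replicates_shared",
    "aggregate",
    "contrast",
    "replicate_metric",
]

SCENARIO_CODES = ("b1", "b2", "b3", "d1", "d2", "d3")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full stage-2 parameterisation of one scenario."""

    code: str
    cryobank_choice: str  # "best_TMI" | "min_mean_kinship" | "none"
    fraction_cryobank_sons: float
    stage2_criterion: str  # "EBVA" | "TMI"
    w_b: float = 0.5
    male_line_conservation: bool = False
    bank_mode: str = BANK_FRENCH

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_cryobank_sons <= 1.0:
            raise ValueError("fraction of cryobank sons must lie in [0, 1]")
        if not 0.0 <= self.w_b <= 1.0:
            raise ValueError("w_B must lie in [0, 1]")
        if self.stage2_criterion not in (CRITERION_EBVA, CRITERION_TMI):
            raise ValueError(f"unknown criterion {self.stage2_criterion!r}")
        if self.cryobank_choice not in ("best_TMI", "min_mean_kinship", "none"):
            raise ValueError(f"unknown cryobank choice {self.cryobank_choice!r}")
        if self.cryobank_choice == "none" and self.fraction_cryobank_sons > 0:
            raise ValueError("cryobank sons requested without a choice method")
        if self.bank_mode not in (BANK_FRENCH, BANK_ALL):
            raise ValueError(f"unknown bank mode {self.bank_mode!r}")


_TABLE: dict[str, dict] = {
    "b1": dict(cryobank_choice="best_TMI", fraction_cryobank_sons=0.4,
               stage2_criterion=CRITERION_EBVA, male_line_conservation=False),
    "b2": dict(cryobank_choice="none", fraction_cryobank_sons=0.0,
               stage2_criterion=CRITERION_TMI, male_line_conservation=False),
    "b3": dict(cryobank_choice="best_TMI", fraction_cryobank_sons=0.4,
               stage2_criterion=CRITERION_TMI, male_line_conservation=False),
    "d1": dict(cryobank_choice="min_mean_kinship", fraction_cryobank_sons=0.4,
               stage2_criterion=CRITERION_EBVA, male_line_conservation=False),
    "d2": dict(cryobank_choice="none", fraction_cryobank_sons=0.0,
               stage2_criterion=CRITERION_EBVA, male_line_conservation=True),
    "d3": dict(cryobank_choice="min_mean_kinship", fraction_cryobank_sons=0.4,
               stage2_criterion=CRITERION_EBVA, male_line_conservation=True),
}


def build_scenario(
    code: str,
    w_b: float | None = None,
    fraction: float | None = None,
    bank_mode: str | None = None,
) -> ScenarioConfig:
    """Scenario from its code, with optional overrides.

    ``w_b`` overrides the TMI weight (the b3 weight sweep), ``fraction`` the
    share of generation-9 bull calves sired by cryobank bulls (e.g. 0.8 for
    the intensified-use variant), ``bank_mode`` the sampling variant.
    """
    if code not in _TABLE:
        raise ValueError(f"unknown scenario code {code!r}; valid: {SCENARIO_CODES}")
    sc = ScenarioConfig(code=code, **_TABLE[code])
    overrides = {}
    if w_b is not None:
        overrides["w_b"] = w_b
    if fraction is not None:
        overrides["fraction_cryobank_sons"] = fraction
    if bank_mode is not None:
        overrides["bank_mode"] = bank_mode
    return replace(sc, **overrides) if overrides else sc


@dataclass
class ReplicateResult:
    """Per-replicate trajectories and scalar outcomes for one scenario."""

    scenario: ScenarioConfig
    replicate: int
    seed_entropy: int
    trajectories: pd.DataFrame  # generation, group, mean_a/b/f/phi
    progeny_sd: pd.DataFrame
    bank_total: int
    bank_reason_counts: dict[str, int]
    bank_birth_generations: dict[str, float]  # per reason, mean birth gen
    used_bull_birth_generation: float
    used_reason_shares: dict[str, float]
    contributions: dict[int, float]


@dataclass
class AggregateSummary:
    """Across-replicate means and standard deviations."""

    n_replicates: int
    trajectories: pd.DataFrame  # mean and sd per generation/group/metric
    bank_table: pd.DataFrame  # Table-2 style layout
    usage_table: pd.DataFrame  # Table-3 style layout
    scalars: pd.DataFrame  # per-metric mean/sd of the scalar outcomes


def _bank_stats(bank: cb.Cryobank) -> tuple[dict[str, int], dict[str, float]]:
    counts = bank.reason_counts()
    birth: dict[str, float] = {}
    for reason in counts:
        gens = [e.birth_generation for e in bank.entries.values()
                if reason in e.reasons]
        birth[reason] = float(np.mean(gens)) if gens else np.nan
    return counts, birth


def _result_from_run(
    scenario: ScenarioConfig, replicate: int, entropy: int, run: ScenarioRun
) -> ReplicateResult:
    reason_shares = {r: 0.0 for r in cb.RULE_REASONS}
    for reasons in run.used_bull_reasons:
        for r in reasons:
            # split credit when a bull satisfies several rules
            reason_shares[r] = reason_shares.get(r, 0.0) + 1.0 / len(reasons)
    n_used = max(len(run.used_bull_reasons), 1)
    reason_shares = {r: v / n_used for r, v in reason_shares.items()}
    counts, birth = _bank_stats(run.bank)
    return ReplicateResult(
        scenario=scenario,
        replicate=replicate,
        seed_entropy=entropy,
        trajectories=pd.DataFrame(run.summaries),
        progeny_sd=pd.DataFrame(run.progeny_sd),
        bank_total=len(run.bank),
        bank_reason_counts=counts,
        bank_birth_generations=birth,
        used_bull_birth_generation=(
            float(np.mean(run.used_bull_birth_generations))
            if len(run.used_bull_birth_generations)
            else np.nan
        ),
        used_reason_shares=reason_shares,
        contributions=dict(run.contributions),
    )


def run_replicates_shared(
    scenarios: list[ScenarioConfig],
    cfg: SchemeConfig,
    n_replicates: int,
    master_seed: int,
) -> dict[str, list[ReplicateResult]]:
    """Run replicates with one shared stage-1 run per replicate.

    All scenarios must share the same ``bank_mode``.  Each replicate draws
    its own substream from the master seed; within a replicate, stage 1 and
    every scenario branch get independent substreams, so results for a given
    (master_seed, replicate, scenario) triple are bitwise reproducible.
    Keys of the returned dict are ``f"{code}@wb={w_b}"``-style labels when
    codes repeat, plain codes otherwise.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    modes = {s.bank_mode for s in scenarios}
    if len(modes) != 1:
        raise ValueError("shared stage 1 requires a single bank mode")
    bank_mode = modes.pop()
    labels = [scenario_label(s) for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError(f"scenario labels are not unique: {labels}")
    out: dict[str, list[ReplicateResult]] = {lab: [] for lab in labels}
    root = np.random.SeedSequence(master_seed)
    for rep, rep_seq in enumerate(root.spawn(n_replicates)):
        streams = rep_seq.spawn(1 + len(scenarios))
        stage1 = run_stage1(cfg, np.random.default_rng(streams[0]), bank_mode)
        for scenario, lab, stream in zip(scenarios, labels, streams[1:]):
            run = run_stage2(stage1, scenario, cfg, np.random.default_rng(stream))
            out[lab].append(
                _result_from_run(scenario, rep, int(rep_seq.entropy or 0), run)
            )
    return out


def scenario_label(s: ScenarioConfig) -> str:
    parts = [s.code]
    if s.w_b != 0.5:
        parts.append(f"wb={s.w_b:g}")
    if s.fraction_cryobank_sons not in (0.0, 0.4):
        parts.append(f"frac={s.fraction_cryobank_sons:g}")
    if s.bank_mode != BANK_FRENCH:
        parts.append(s.bank_mode)
    return "|".join(parts)


def run_replicates(
    scenario: ScenarioConfig,
    cfg: SchemeConfig,
    n_replicates: int,
    master_seed: int,
) -> list[ReplicateResult]:
    """Independent full replicates (stage 1 + stage 2) of one scenario."""
    return run_replicates_shared([scenario], cfg, n_replicates, master_seed)[
        scenario_label(scenario)
    ]


# ---------------------------------------------------------------------------
# aggregation and contrasts
# ---------------------------------------------------------------------------

_REASON_LABELS = {
    cb.REASON_HIGH_EBVA: "> +3 s.d. EBVA",
    cb.REASON_LOW_EBVA: "< -3 s.d. EBVA",
    cb.REASON_HIGH_EBVB: "> +2 s.d. EBVB",
    cb.REASON_UNUSED_SIRE: "sire of sires with no selected son",
    cb.REASON_ALL: "all young bulls",
}


def aggregate(results: list[ReplicateResult]) -> AggregateSummary:
    """Across-replicate means and s.d. in the layout of the result tables."""
    if not results:
        raise ValueError("no replicates to aggregate")
    n = len(results)
    traj = pd.concat([r.trajectories for r in results])
    traj_agg = (
        traj.groupby(["generation", "group"])
        .agg(["mean", "std"])
        .reset_index()
    )
    traj_agg.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c
        for c in traj_agg.columns
    ]

    bank_rows = []
    totals = np.array([r.bank_total for r in results], dtype=float)
    for reason in cb.RULE_REASONS + (cb.REASON_ALL,):
        counts = np.array([r.bank_reason_counts.get(reason, 0) for r in results],
                          dtype=float)
        if counts.sum() == 0:
            continue
        births = np.array([r.bank_birth_generations.get(reason, np.nan)
                           for r in results])
        finite = births[~np.isnan(births)]
        bank_rows.append(
            {
                "criterion": _REASON_LABELS[reason],
                "bulls_per_replicate": counts.mean(),
                "bulls_per_replicate_sd": counts.std(ddof=1) if n > 1 else 0.0,
                "pct_of_bank": 100.0 * counts.mean() / totals.mean(),
                "birth_generation": float(finite.mean()) if len(finite) else np.nan,
                "birth_generation_sd": (
                    float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
                ),
            }
        )
    bank_rows.append(
        {
            "criterion": "total",
            "bulls_per_replicate": totals.mean(),
            "bulls_per_replicate_sd": totals.std(ddof=1) if n > 1 else 0.0,
            "pct_of_bank": 100.0,
            "birth_generation": np.nan,
            "birth_generation_sd": np.nan,
        }
    )
    bank_table = pd.DataFrame(bank_rows)

    usage_rows = []
    for reason in cb.RULE_REASONS:
        shares = np.array([100.0 * r.used_reason_shares.get(reason, 0.0)
                           for r in results])
        usage_rows.append(
            {
                "metric": f"pct_used_{reason}",
                "mean": shares.mean(),
                "sd": shares.std(ddof=1) if n > 1 else 0.0,
            }
        )
    births = np.array([r.used_bull_birth_generation for r in results])
    finite = births[~np.isnan(births)]
    usage_rows.append(
        {
            "metric": "birth_generation_of_used_bulls",
            "mean": float(finite.mean()) if len(finite) else np.nan,
            "sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
        }
    )
    for g in sorted(results[0].contributions):
        vals = np.array([100.0 * r.contributions[g] for r in results])
        usage_rows.append(
            {
                "metric": f"pct_genes_from_cryobank_gen{g}",
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if n > 1 else 0.0,
            }
        )
    usage_table = pd.DataFrame(usage_rows)

    scalar_rows = []
    for name in ("bank_total",):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        scalar_rows.append({"metric": name, "mean": vals.mean(),
                            "sd": vals.std(ddof=1) if n > 1 else 0.0})
    for col in ("male_path_sd", "female_path_sd"):
        per_rep = [r.progeny_sd[col].mean() for r in results]
        scalar_rows.append(
            {"metric": f"mean_{col}", "mean": float(np.mean(per_rep)),
             "sd": float(np.std(per_rep, ddof=1)) if n > 1 else 0.0}
        )
    scalars = pd.DataFrame(scalar_rows)

    return AggregateSummary(
        n_replicates=n,
        trajectories=traj_agg,
        bank_table=bank_table,
        usage_table=usage_table,
        scalars=scalars,
    )


def replicate_metric(result: ReplicateResult, metric: str) -> float:
    """Resolve a named scalar from one replicate.

    Understood forms: ``"mean_a@12:all"`` (trajectory value at a generation
    for a group, metrics mean_a/mean_b/mean_f/mean_phi),
    ``"contribution@12"`` (cryobank gene fraction), ``"bank_total"``,
    ``"male_path_sd"``/``"female_path_sd"`` (stage-averaged progeny-count
    dispersion), ``"delta_f"`` (mean per-generation rate of inbreeding over
    stage 1).
    """
    if "@" in metric:
        name, rest = metric.split("@", 1)
        if name == "contribution":
            return float(result.contributions[int(rest)])
        gen_s, group = rest.split(":")
        traj = result.trajectories
        row = traj[(traj.generation == int(gen_s)) & (traj.group == group)]
        if row.empty:
            raise KeyError(f"no trajectory point for {metric!r}")
        return float(row[name].iloc[0])
    if metric == "bank_total":
        return float(result.bank_total)
    if metric in ("male_path_sd", "female_path_sd"):
        return float(result.progeny_sd[metric].mean())
    if metric == "delta_f":
        return stage1_delta_f(result)
    raise KeyError(f"unknown metric {metric!r}")


def stage1_delta_f(
    result: ReplicateResult,
    first_generation: int = 1,
    last_generation: int = 8,
) -> float:
    """Mean per-generation rate of inbreeding over the given increments.

    delta_F(t) = (F_t - F_{t-1}) / (1 - F_{t-1}) on whole-population means,
    averaged over t = first..last.  Because founders are unrelated, the first
    increments are structurally near zero; the scheme's realized rate is the
    average over the stabilized regime (generations 5-8 of stage 1).
    """
    traj = result.trajectories
    f = (
        traj[traj.group == "all"]
        .sort_values("generation")
        .set_index("generation")["mean_f"]
    )
    rates = [
        (f[t] - f[t - 1]) / (1.0 - f[t - 1])
        for t in range(first_generation, last_generation + 1)
    ]
    return float(np.mean(rates))


def contrast(
    results_a: list[ReplicateResult],
    results_b: list[ReplicateResult],
    metric: str,
) -> tuple[float, float]:
    """Welch two-sample comparison of a replicate-level metric.

    Returns (mean_A - mean_B, two-sided p-value).
    """
    if len(results_a) < 2 or len(results_b) < 2:
        raise ValueError("contrast needs at least two replicates per side")
    a = np.array([replicate_metric(r, metric) for r in results_a])
    b = np.array([replicate_metric(r, metric) for r in results_b])
    t = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t.pvalue)
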