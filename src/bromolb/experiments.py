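"""Reusable study experiments: logistic parameter recovery on simulated
cohorts and the phantom route-classification fidelity study.

These are the computations the validation scripts and the acceptance checks
run; keeping them here makes every reported number a plain function call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .broml import BromOlbConfig, assess_case
from .diagnostics import logistic_fit
from .phantom import CohortSimParams, PhantomParams, cohort_to_frame, \
    generate_cohort, generate_phantom


def _rep_seed(seed: int, i: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RecoveryResult:
    """Replicated logistic-refit summary for one coefficient."""

    truth_log_odds: float
    or_geometric_mean: float       # exp(mean recovered log-odds)
    or_values: np.ndarray
    ci_coverage: float             # fraction of 95% Wald CIs covering exp(truth)
    n_cases: int
    n_replicates: int


def recover_pneumothorax_or(n_cases: int = 5000, n_replicates: int = 50,
                            seed: int = 0,
                            params: CohortSimParams | None = None) -> RecoveryResult:
    """Simulate cohorts at the pneumothorax-model truth and refit the
    bivariable logistic model (BROM-OLB MinIP positivity + procedure time);
    report the recovered positivity odds ratio."""
    base = params or CohortSimParams()
    truth = base.ptx_coef_bromolb
    bs, cover = [], 0
    for r in range(n_replicates):
        p = dataclasses.replace(base, n_cases=n_cases, seed=_rep_seed(seed, r))
        df = cohort_to_frame(generate_cohort(p))
        fit = logistic_fit(df[["brom_olb_minip", "procedure_time"]].astype(float),
                           df["pneumothorax"].astype(int))
        bs.append(fit.coef[1])
        cover += fit.ci_low[1] <= np.exp(truth) <= fit.ci_high[1]
    bs = np.asarray(bs)
    return RecoveryResult(truth_log_odds=truth,
                          or_geometric_mean=float(np.exp(bs.mean())),
                          or_values=np.exp(bs), ci_coverage=cover / n_replicates,
                          n_cases=n_cases, n_replicates=n_replicates)


def recover_hemorrhage_or(n_cases: int = 5000, n_replicates: int = 50,
                          seed: int = 0,
                          params: CohortSimParams | None = None) -> RecoveryResult:
    """Simulate cohorts at the hemorrhage-model truth and refit the
    univariable logistic model (grade >= 2 hemorrhage on lung-window density);
    report the recovered per-HU odds ratio."""
    base = params or CohortSimParams()
    truth = base.hem_coef_lw
    bs, cover = [], 0
    for r in range(n_replicates):
        p = dataclasses.replace(base, n_cases=n_cases, seed=_rep_seed(seed, 1_000_000 + r))
        df = cohort_to_frame(generate_cohort(p))
        fit = logistic_fit(df[["lw_value"]].astype(float),
                           (df["hemorrhage_grade"] >= 2).astype(int))
        bs.append(fit.coef[1])
        cover += fit.ci_low[1] <= np.exp(truth) <= fit.ci_high[1]
    bs = np.asarray(bs)
    return RecoveryResult(truth_log_odds=truth,
                          or_geometric_mean=float(np.exp(bs.mean())),
                          or_values=np.exp(bs), ci_coverage=cover / n_replicates,
                          n_cases=n_cases, n_replicates=n_replicates)


@dataclass
class RouteStudyResult:
    """Phantom construction-vs-call fidelity over randomized geometries."""

    n_constructions: int
    n_match: int                  # call (LW and MinIP) equals planted truth
    match_rate: float
    n_unevaluable: int
    minip_le_lw_everywhere: bool


def route_classification_study(n_constructions: int = 200, seed: int = 7000,
                               cfg: BromOlbConfig | None = None) -> RouteStudyResult:
    """Alternately plant an emphysema cluster on / off the needle corridor in
    noise-free vertical-gradient phantoms with randomized geometry and patient
    position, and compare the BROM-OLB calls with the planted truth.

    Noise-free phantoms are used because the strict majority vote carries no
    tie tolerance; the vertical gradient stays on so the rule-based placement
    is actually exercised.
    """
    cfg = cfg or BromOlbConfig()
    positions = ["supine", "lateral", "prone"]
    n_match = n_unev = 0
    minip_le_lw = True
    for i in range(n_constructions):
        on_route = i % 2 == 0
        params = PhantomParams(
            seed=seed + i,
            normal_sd_hu=0.0, radial_gradient_hu=0.0,
            patient_position=positions[i % 3],
            emphysema_placement="on_route" if on_route else "off_route",
            n_emphysema_clusters=2 if on_route else 3)
        vol, masks, path = generate_phantom(params)
        a = assess_case(vol, masks, path, cfg)
        minip_le_lw &= a.minip_value <= a.lw_value + 1e-12
        if not a.evaluable:
            n_unev += 1
            continue
        if a.positive_lw == on_route and a.positive_minip == on_route:
            n_match += 1
    return RouteStudyResult(n_constructions=n_constructions, n_match=n_match,
                            match_rate=n_match / n_constructions,
                            n_unevaluable=n_unev,
                            minip_le_lw_everywhere=bool(minip_le_lw))
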