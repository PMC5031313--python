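"""Probabilistic sensitivity analysis (PSA).

Each Monte Carlo replicate (default 1000) re-creates both surveys
with a design-preserving Rao-Wu rescaling bootstrap, redraws the cost
parameters from their uncertainty distributions, re-runs the prevalence and
burden stages, and records every output quantity.  Intervals are empirical
percentiles of the replicate outputs (5th/95th at the default 90% level);
the point estimate is the unresampled deterministic run, reported alongside
the replicate mean.

Two interval modes mirror how the global malnutrition cost multiplier dMN
is treated: held constant across replicates (``vary_global_delta=False``,
so states remain comparable to each other) or redrawn per replicate from
its own distribution (describing sensitivity of the overall results).

Rao-Wu rescaling bootstrap: within each stratum of n_h clusters, n_h - 1
clusters are drawn with replacement; every record's weight is multiplied by
m_c * n_h / (n_h - 1) where m_c is the number of times its cluster was
drawn.  Strata with a single cluster are first merged with the adjacent
stratum in identifier order.  The record set is unchanged; only weights
change, so E[bootstrap weight] equals the original weight.

Randomness discipline: one master seed; replicate r uses the substream
``SeedSequence(master_seed, spawn_key=(r,))`` so any replicate is
reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .burden import BurdenResult, burden_matrices, compute_burden
from .costs import CostParameterSet
from .demographics import AGE_BANDS, ALL_CELLS
from .diseases import DISEASES, Disease, default_diseases
from .io import population_matrix
from .malnutrition import Thresholds, classify_records
from .prevalence import (
    MIN_CELL_N,
    SurveyDesign,
    build_design,
    disease_cell_sums,
    estimate_pmn,
    estimate_rho,
    flags_matrix,
    pooled_estimates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsaConfig:
    """Configuration of the probabilistic sensitivity analysis."""

    n_reps: int = 1000
    ci_level: float = 0.90
    vary_global_delta: bool = False
    seed: int = 0
    resample_surveys: bool = True
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PsaResult:
    """Point estimates, percentile bounds and replicate diagnostics."""

    point: BurdenResult
    lower: BurdenResult | None
    upper: BurdenResult | None
    national_total_draws: np.ndarray
    national_interval: tuple[float, float]
    national_replicate_mean: float
    n_replicates_used: int
    n_failures: int
    state_intervals: pd.DataFrame
    state_disease_intervals: pd.DataFrame
    #: entries where the percentile interval fails to bracket the point run
    bracket_violations: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Rao-Wu rescaling bootstrap
# ---------------------------------------------------------------------------

def merge_singleton_strata(cluster_stratum: np.ndarray) -> np.ndarray:
    """Merge single-cluster strata into the adjacent stratum (by code order).

    Returns a remapped per-cluster stratum code array.  Raises if merging
    cannot produce strata of >= 2 clusters (i.e. only one cluster total).
    """
    cluster_stratum = np.asarray(cluster_stratum)
    n_strata = int(cluster_stratum.max()) + 1 if len(cluster_stratum) else 0
    counts = np.bincount(cluster_stratum, minlength=n_strata)
    remap = np.arange(n_strata)
    order = [h for h in range(n_strata) if counts[h] > 0]
    for pos, h in enumerate(order):
        if counts[remap[h]] == 1:
            # merge into the next stratum in identifier order (previous for the last)
            neighbor = order[pos + 1] if pos + 1 < len(order) else (
                order[pos - 1] if pos > 0 else None)
            if neighbor is None:
                raise ValueError("survey has a single cluster; bootstrap requires >= 2")
            target = remap[neighbor]
            counts[target] += counts[remap[h]]
            counts[remap[h]] = 0
            remap[remap == remap[h]] = target
    merged = remap[cluster_stratum]
    merged_counts = np.bincount(merged, minlength=n_strata)
    if np.any(merged_counts == 1):
        raise ValueError("a stratum still has one cluster after merging")
    return merged


def rao_wu_multipliers(cluster_stratum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap draw: weight multiplier per cluster.

    Within each stratum of n_h clusters, n_h - 1 are drawn with replacement
    and each cluster's multiplier is m_c * n_h / (n_h - 1).
    """
    merged = merge_singleton_strata(cluster_stratum)
    mult = np.zeros(len(merged))
    for h in np.unique(merged):
        members = np.flatnonzero(merged == h)
        n_h = len(members)
        draws = rng.integers(0, n_h, size=n_h - 1)
        m = np.bincount(draws, minlength=n_h)
        mult[members] = m * n_h / (n_h - 1)
    return mult


def bootstrap_resample_survey(
    records: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Return a copy of the survey with Rao-Wu bootstrap-adjusted weights."""
    design = build_design(records)
    mult = rao_wu_multipliers(design.cluster_stratum, rng)
    out = records.copy()
    out["sample_weight"] = design.weights * mult[design.cluster_idx]
    return out


# ---------------------------------------------------------------------------
# Cost parameter draws
# ---------------------------------------------------------------------------

def draw_cost_parameters(
    params: CostParameterSet, rng: np.random.Generator, vary_global_delta: bool = False
) -> CostParameterSet:
    """One random realization of the cost parameters.

    Per-disease costs always vary according to their specs; the global dMN
    is redrawn only when ``vary_global_delta`` is set, else held at its
    point value.
    """
    realized = {d: params.cost_dist[d].draw(params.mean_cost[d], rng) for d in DISEASES}
    delta = params.delta_dist.draw(params.delta_mn, rng) if vary_global_delta else params.delta_mn
    return params.with_values(realized, delta)


# ---------------------------------------------------------------------------
# Fast replicate machinery
# ---------------------------------------------------------------------------

@dataclass
class _FastSurvey:
    """Precomputed arrays for the per-replicate estimation path."""

    design: SurveyDesign
    flags: np.ndarray               # (n, 8)
    indicator: np.ndarray | None    # (n,) malnutrition screen, exam only
    merged_stratum: np.ndarray      # per-cluster merged stratum codes

    @classmethod
    def from_records(cls, records: pd.DataFrame, exam: bool,
                     thresholds: Thresholds) -> "_FastSurvey":
        design = build_design(records)
        ind = classify_records(records, thresholds)[0] if exam else None
        return cls(design, flags_matrix(records), ind,
                   merge_singleton_strata(design.cluster_stratum))

    def replicate_weights(self, rng: np.random.Generator) -> np.ndarray:
        mult = np.zeros(len(self.merged_stratum))
        for h in np.unique(self.merged_stratum):
            members = np.flatnonzero(self.merged_stratum == h)
            n_h = len(members)
            draws = rng.integers(0, n_h, size=n_h - 1)
            mult[members] = np.bincount(draws, minlength=n_h) * n_h / (n_h - 1)
        return self.design.weights * mult[self.design.cluster_idx]


def _replicate_matrices(
    exam: _FastSurvey,
    interview: _FastSurvey,
    diseases: Sequence[Disease],
    w_exam: np.ndarray,
    w_int: np.ndarray,
    min_cell_n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """PMN and rho (8, 30) matrices for one replicate's weights."""
    child_cells = np.array([c.age_band == AGE_BANDS[0] for c in ALL_CELLS])
    e_design = SurveyDesign(w_exam, exam.design.cell_idx, exam.design.cluster_idx,
                            exam.design.cluster_stratum, exam.design.n_strata)
    i_design = SurveyDesign(w_int, interview.design.cell_idx, interview.design.cluster_idx,
                            interview.design.cluster_stratum, interview.design.n_strata)

    num, den, cnt = disease_cell_sums(e_design, exam.flags, exam.indicator)
    pmn, _ = pooled_estimates(num, den, cnt, min_cell_n)

    e_num, e_den, e_cnt = disease_cell_sums(e_design, exam.flags)
    i_num, i_den, i_cnt = disease_cell_sums(i_design, interview.flags)
    by_id = {d.id: d for d in diseases}
    r_num = np.empty_like(e_num)
    r_den = np.empty_like(e_den)
    r_cnt = np.empty_like(e_cnt)
    marg = np.empty((len(DISEASES), 3))
    for i, d in enumerate(DISEASES):
        if by_id[d].prevalence_source == "examination":
            r_num[i], r_den[i], r_cnt[i] = e_num[i], e_den[i], e_cnt[i]
            marg[i] = (e_num[i].sum(), e_den[i].sum(), e_cnt[i].sum())
        else:
            r_num[i] = np.where(child_cells, e_num[i], i_num[i])
            r_den[i] = np.where(child_cells, e_den[i], i_den[i])
            r_cnt[i] = np.where(child_cells, e_cnt[i], i_cnt[i])
            marg[i] = (i_num[i].sum(), i_den[i].sum(), i_cnt[i].sum())
    rho, _ = pooled_estimates(r_num, r_den, r_cnt, min_cell_n,
                              marg_num=marg[:, 0], marg_den=marg[:, 1], marg_cnt=marg[:, 2])
    return pmn, rho


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Substream generator for one replicate (counter-indexed spawn key)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def run_psa(
    exam_records: pd.DataFrame,
    interview_records: pd.DataFrame,
    population: pd.DataFrame,
    cost_params: CostParameterSet,
    config: PsaConfig,
    diseases: Sequence[Disease] | None = None,
    states: Sequence[str] | None = None,
    thresholds: Thresholds = Thresholds(),
    min_cell_n: int = MIN_CELL_N,
) -> PsaResult:
    """Full probabilistic sensitivity analysis.

    Point estimates come from the unresampled deterministic pipeline;
    intervals are percentile bounds over ``config.n_reps`` replicates.
    Failed replicates are dropped and counted; more than
    ``max_failure_fraction`` of failures aborts the analysis.
    """
    diseases = tuple(diseases) if diseases is not None else default_diseases()

    pmn_pt = estimate_pmn(exam_records, diseases, thresholds, min_cell_n)
    rho_pt = estimate_rho(interview_records, exam_records, diseases, min_cell_n)
    point = compute_burden(pmn_pt, rho_pt, population, cost_params, states)
    state_list = point.states
    pop = population_matrix(population, state_list)

    exam_fast = _FastSurvey.from_records(exam_records, True, thresholds)
    int_fast = _FastSurvey.from_records(interview_records, False, thresholds)

    n_states = len(state_list)
    draws_total = np.empty(config.n_reps)
    draws_state = np.empty((config.n_reps, n_states))
    draws_state65 = np.empty((config.n_reps, n_states))
    draws_sd = np.empty((config.n_reps, n_states, len(DISEASES)))
    draws_nat_d = np.empty((config.n_reps, len(DISEASES)))
    ok = np.zeros(config.n_reps, dtype=bool)

    for r in range(config.n_reps):
        rng = replicate_rng(config.seed, r)
        try:
            if config.resample_surveys:
                w_e = exam_fast.replicate_weights(rng)
                w_i = int_fast.replicate_weights(rng)
            else:
                w_e = exam_fast.design.weights
                w_i = int_fast.design.weights
            realized = draw_cost_parameters(cost_params, rng, config.vary_global_delta)
            pmn, rho = _replicate_matrices(exam_fast, int_fast, diseases, w_e, w_i, min_cell_n)
            cost, cost65 = burden_matrices(pmn, rho, pop, realized)
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            logger.warning("PSA replicate %d failed: %s", r, exc)
            continue
        draws_sd[r] = cost
        draws_state[r] = cost.sum(axis=1)
        draws_state65[r] = cost65.sum(axis=1)
        draws_nat_d[r] = cost.sum(axis=0)
        draws_total[r] = cost.sum()
        ok[r] = True

    n_fail = int((~ok).sum())
    if n_fail > config.max_failure_fraction * config.n_reps:
        raise RuntimeError(
            f"{n_fail}/{config.n_reps} PSA replicates failed "
            f"(> {config.max_failure_fraction:.0%} allowed)"
        )

    alpha = (1 - config.ci_level) / 2
    q = [100 * alpha, 100 * (1 - alpha)]

    def pct(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = np.percentile(a[ok], q, axis=0)
        return lo, hi

    tot_lo, tot_hi = pct(draws_total)
    st_lo, st_hi = pct(draws_state)
    st65_lo, st65_hi = pct(draws_state65)
    sd_lo, sd_hi = pct(draws_sd)
    nd_lo, nd_hi = pct(draws_nat_d)

    state_intervals = pd.DataFrame({
        "state": state_list + ["National"],
        "cost_total_lower": np.append(st_lo, float(np.atleast_1d(tot_lo)[0])),
        "cost_total_upper": np.append(st_hi, float(np.atleast_1d(tot_hi)[0])),
        "cost_total_65plus_lower": np.append(st65_lo, np.percentile(draws_state65[ok].sum(axis=1), q[0])),
        "cost_total_65plus_upper": np.append(st65_hi, np.percentile(draws_state65[ok].sum(axis=1), q[1])),
    })
    sd_rows = []
    for si, s in enumerate(state_list):
        for di, d in enumerate(DISEASES):
            sd_rows.append((s, d, sd_lo[si, di], sd_hi[si, di]))
    for di, d in enumerate(DISEASES):
        sd_rows.append(("National", d, nd_lo[di], nd_hi[di]))
    state_disease_intervals = pd.DataFrame(
        sd_rows, columns=["state", "disease", "cost_total_lower", "cost_total_upper"]
    )

    point.intervals["state"] = state_intervals
    point.intervals["state_disease"] = state_disease_intervals

    # flag (do not enforce) entries where the interval misses the point run
    pt_state = point.state_totals()
    viol = [
        {"quantity": "state_total", "key": s, "point": pt_state[si],
         "lower": st_lo[si], "upper": st_hi[si]}
        for si, s in enumerate(state_list)
        if not (st_lo[si] <= pt_state[si] <= st_hi[si])
    ]
    pt_total = point.national_total()
    if not (tot_lo <= pt_total <= tot_hi):
        viol.append({"quantity": "national_total", "key": "National",
                     "point": pt_total, "lower": float(tot_lo), "upper": float(tot_hi)})

    return PsaResult(
        point=point,
        lower=None,
        upper=None,
        national_total_draws=draws_total[ok],
        national_interval=(float(tot_lo), float(tot_hi)),
        national_replicate_mean=float(draws_total[ok].mean()),
        n_replicates_used=int(ok.sum()),
        n_failures=n_fail,
        state_intervals=state_intervals,
        state_disease_intervals=state_disease_intervals,
        bracket_violations=pd.DataFrame(viol),
    )


def replicate_long_table(result: PsaResult) -> pd.DataFrame:
    """Per-replicate national totals in long format (for export)."""
    return pd.DataFrame({
        "replicate": np.arange(len(result.national_total_draws)),
        "national_total": result.national_total_draws,
    })
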