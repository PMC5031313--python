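"""Design-weighted prevalence estimation over diseases x demographic cells.

Two quantities drive the cost model: rho_ij, the prevalence of disease i in
demographic cell j, and PMN_ij, the prevalence of malnutrition among persons
with disease i in cell j.  Both are estimated with the standard design-based
ratio estimator

    p_hat = sum(w_k * y_k) / sum(w_k)

over in-domain records with a known indicator, with standard errors by
Taylor linearization of the ratio across the survey's strata and primary
sampling units (clusters).  When the design is degenerate (no stratum has
two or more clusters) the SE falls back to the simple-random-sampling
binomial form sqrt(p(1-p)/n).

Sparse cells are filled by a deterministic pooling ladder: a cell whose
domain holds fewer than ``min_cell_n`` contributing records is estimated by
pooling over race within (age band, sex); if still sparse, over sex within
the age band; and finally from the disease-wide marginal.  The ladder level
used is recorded per cell so every filled value is traceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .demographics import AGE_BANDS, ALL_CELLS, N_CELLS, RACES, SEXES
from .diseases import DISEASES, Disease, default_diseases, flag_column
from .malnutrition import Thresholds, classify_records

#: default minimum contributing records for a direct (unpooled) cell estimate
MIN_CELL_N = 10

_SHAPE = (len(AGE_BANDS), len(SEXES), len(RACES))  # (5, 2, 3) cell lattice


@dataclass
class SurveyDesign:
    """Compact array view of a survey's weights and sampling design."""

    weights: np.ndarray          # (n,)
    cell_idx: np.ndarray         # (n,) canonical cell index
    cluster_idx: np.ndarray      # (n,) global cluster code
    cluster_stratum: np.ndarray  # (n_clusters,) stratum code per cluster
    n_strata: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_stratum)

    @property
    def clusters_per_stratum(self) -> np.ndarray:
        return np.bincount(self.cluster_stratum, minlength=self.n_strata)


def build_design(records: pd.DataFrame, weights: np.ndarray | None = None) -> SurveyDesign:
    """Extract the design arrays from a standardized survey table."""
    strat = records["stratum_id"].astype(str).to_numpy()
    clus = records["cluster_id"].astype(str).to_numpy()
    stratum_codes, stratum_idx = np.unique(strat, return_inverse=True)
    # clusters are nested in strata: key on the pair
    pair = np.char.add(np.char.add(strat, "\x1f"), clus)
    cluster_codes, cluster_idx = np.unique(pair, return_inverse=True)
    cluster_stratum = np.empty(len(cluster_codes), dtype=int)
    cluster_stratum[cluster_idx] = stratum_idx
    w = records["sample_weight"].to_numpy(dtype=float) if weights is None else np.asarray(weights, float)
    return SurveyDesign(
        weights=w,
        cell_idx=records["cell_idx"].to_numpy(dtype=int),
        cluster_idx=cluster_idx,
        cluster_stratum=cluster_stratum,
        n_strata=len(stratum_codes),
    )


def _ratio_with_se(
    design: SurveyDesign, y: np.ndarray, mask: np.ndarray
) -> tuple[float, float, int]:
    """Weighted proportion, linearized SE and contributing count on a domain."""
    w = design.weights
    m = mask & np.isfinite(y) & (w > 0)
    n = int(m.sum())
    if n == 0:
        return float("nan"), float("nan"), 0
    W = float(w[m].sum())
    p = float((w[m] * y[m]).sum() / W)

    def degenerate_se() -> float:
        # all indicators equal: the linearized variance collapses to zero,
        # which understates uncertainty; report the add-one adjusted
        # binomial SE instead (p~ = (k+1)/(n+2))
        k = float((y[m] == 1).sum())
        p_adj = (k + 1.0) / (n + 2.0)
        return float(np.sqrt(p_adj * (1 - p_adj) / n))

    n_h = design.clusters_per_stratum
    usable = n_h >= 2
    if not usable.any():
        if p in (0.0, 1.0):
            return p, degenerate_se(), n
        se = float(np.sqrt(max(p * (1 - p), 0.0) / n))
        return p, se, n
    # score residuals; records outside the domain contribute zero
    z = np.zeros(len(w))
    z[m] = w[m] * (y[m] - p) / W
    tot = np.bincount(design.cluster_idx, weights=z, minlength=design.n_clusters)
    strat_sum = np.bincount(design.cluster_stratum, weights=tot, minlength=design.n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        strat_mean = np.where(n_h > 0, strat_sum / np.maximum(n_h, 1), 0.0)
    dev2 = (tot - strat_mean[design.cluster_stratum]) ** 2
    ss = np.bincount(design.cluster_stratum, weights=dev2, minlength=design.n_strata)
    var = float((n_h[usable] / (n_h[usable] - 1) * ss[usable]).sum())
    if var == 0.0:
        return p, degenerate_se(), n
    return p, float(np.sqrt(var)), n


def weighted_domain_prevalence(
    records: pd.DataFrame,
    indicator: np.ndarray | Callable,
    domain: np.ndarray | Callable | None = None,
) -> tuple[float, float, int]:
    """Design-weighted prevalence of an indicator on a subpopulation.

    ``indicator`` gives 1/0/NaN per record (NaN = unknown, excluded from
    numerator and denominator); ``domain`` restricts to a subpopulation
    (default: all records).  Both may be arrays or callables applied to the
    table.  Returns ``(estimate, se, n_contributing)``; an empty domain
    returns ``(nan, nan, 0)`` rather than 0/0.
    """
    y = np.asarray(indicator(records) if callable(indicator) else indicator, dtype=float)
    if domain is None:
        m = np.ones(len(records), dtype=bool)
    else:
        m = np.asarray(domain(records) if callable(domain) else domain, dtype=bool)
    if len(y) != len(records) or len(m) != len(records):
        raise ValueError("indicator/domain length must match the record count")
    design = build_design(records)
    return _ratio_with_se(design, y, m)


@dataclass
class PrevalenceTable:
    """Estimates keyed by (disease, cell) with SEs, counts and provenance.

    ``pooled_level`` per entry: 0 = direct cell estimate, 1 = pooled over
    race, 2 = pooled over race and sex, 3 = disease-wide marginal,
    -1 = empty even after pooling (estimate NaN, flagged).
    """

    table: pd.DataFrame  # disease, age_band, sex, race, estimate, se, n, source, pooled_level

    def matrix(self) -> np.ndarray:
        """Estimates as an (8, 30) array in canonical order."""
        return self.table["estimate"].to_numpy(dtype=float).reshape(len(DISEASES), N_CELLS)

    def se_matrix(self) -> np.ndarray:
        return self.table["se"].to_numpy(dtype=float).reshape(len(DISEASES), N_CELLS)

    def entry(self, disease: str, cell) -> pd.Series:
        i = DISEASES.index(disease) * N_CELLS + cell.index
        return self.table.iloc[i]

    def flagged_empty(self) -> pd.DataFrame:
        return self.table[self.table["pooled_level"] == -1]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def from_matrices(
        estimate: np.ndarray, se: np.ndarray, n: np.ndarray,
        source: Sequence[str] | np.ndarray, pooled_level: np.ndarray,
    ) -> "PrevalenceTable":
        rows = []
        src = np.broadcast_to(np.asarray(source, dtype=object).reshape(len(DISEASES), -1),
                              (len(DISEASES), N_CELLS))
        for i, d in enumerate(DISEASES):
            for j, c in enumerate(ALL_CELLS):
                rows.append((d, c.age_band, c.sex, c.race, estimate[i, j], se[i, j],
                             int(n[i, j]), src[i, j], int(pooled_level[i, j])))
        return PrevalenceTable(pd.DataFrame(
            rows, columns=["disease", "age_band", "sex", "race",
                           "estimate", "se", "n", "source", "pooled_level"]
        ))


def cell_group_masks() -> tuple[np.ndarray, np.ndarray]:
    """Ladder group ids per cell: (age,sex) group and age group."""
    lattice = np.arange(N_CELLS).reshape(_SHAPE)
    agesex = np.empty(N_CELLS, dtype=int)
    age = np.empty(N_CELLS, dtype=int)
    for a in range(_SHAPE[0]):
        for s in range(_SHAPE[1]):
            agesex[lattice[a, s, :]] = a * _SHAPE[1] + s
        age[lattice[a].ravel()] = a
    return agesex, age


_AGESEX_GROUP, _AGE_GROUP = cell_group_masks()


def pooled_estimates(
    num: np.ndarray, den: np.ndarray, cnt: np.ndarray, min_n: int = MIN_CELL_N,
    marg_num: np.ndarray | None = None, marg_den: np.ndarray | None = None,
    marg_cnt: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the pooling ladder to per-(disease, cell) weighted sums.

    ``num``/``den``/``cnt`` are (8, 30): weighted indicator sums, weighted
    domain sizes and unweighted contributing counts.  Optional ``marg_*``
    (8,) arrays override the level-3 disease-wide marginal (used when the
    marginal must come from a single declared source survey).  Returns
    ``(estimate, level)`` arrays of shape (8, 30).
    """

    def grouped(a: np.ndarray, groups: np.ndarray) -> np.ndarray:
        out = np.zeros_like(a)
        for g in np.unique(groups):
            sel = groups == g
            out[:, sel] = a[:, sel].sum(axis=1, keepdims=True)
        return out

    n1, d1, c1 = (grouped(x, _AGESEX_GROUP) for x in (num, den, cnt))
    n2, d2, c2 = (grouped(x, _AGE_GROUP) for x in (num, den, cnt))
    if marg_num is None:
        n3, d3, c3 = num.sum(axis=1), den.sum(axis=1), cnt.sum(axis=1)
    else:
        n3, d3, c3 = marg_num, marg_den, marg_cnt
    n3 = np.broadcast_to(n3[:, None], num.shape)
    d3 = np.broadcast_to(d3[:, None], num.shape)
    c3 = np.broadcast_to(c3[:, None], num.shape)

    level = np.full(num.shape, -1, dtype=int)
    est = np.full(num.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for lvl, (nn, dd, cc) in enumerate(
            [(num, den, cnt), (n1, d1, c1), (n2, d2, c2), (n3, d3, c3)]
        ):
            ok = (level == -1) & (cc >= min_n) & (dd > 0)
            est[ok] = (nn / dd)[ok]
            level[ok] = lvl
        # last resort: any nonzero denominator at the marginal, even if sparse
        ok = (level == -1) & (c3 > 0) & (d3 > 0)
        est[ok] = (n3 / d3)[ok]
        level[ok] = 3
    return est, level


def disease_cell_sums(
    design: SurveyDesign, flags: np.ndarray, indicator: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted sums per (disease, cell).

    With ``indicator`` given (malnutrition screen), the domain per disease is
    flag == 1 with known indicator; numerator sums w*indicator (PMN).  Without
    it, the domain is known-flag records and the numerator sums w*flag (rho).
    Returns (num, den, cnt), each (8, 30).
    """
    n_d = len(DISEASES)
    num = np.zeros((n_d, N_CELLS))
    den = np.zeros((n_d, N_CELLS))
    cnt = np.zeros((n_d, N_CELLS))
    w = design.weights
    for i in range(n_d):
        f = flags[:, i]
        if indicator is None:
            m = np.isfinite(f) & (w > 0)
            y = f
        else:
            m = (f == 1) & np.isfinite(indicator) & (w > 0)
            y = indicator
        if not m.any():
            continue
        cells = design.cell_idx[m]
        num[i] = np.bincount(cells, weights=(w[m] * y[m]), minlength=N_CELLS)
        den[i] = np.bincount(cells, weights=w[m], minlength=N_CELLS)
        cnt[i] = np.bincount(cells, minlength=N_CELLS)
    return num, den, cnt


def flags_matrix(records: pd.DataFrame) -> np.ndarray:
    """Disease flags as an (n, 8) float array (NaN = unknown)."""
    return np.column_stack([records[flag_column(d)].to_numpy(dtype=float) for d in DISEASES])


def _domain_mask_for_level(
    design: SurveyDesign, flag: np.ndarray, level: int, cell_j: int,
    cell_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Record mask for the pooled domain serving cell ``cell_j`` at a ladder level."""
    cells = design.cell_idx
    if level == 0:
        in_group = cells == cell_j
    elif level == 1:
        in_group = _AGESEX_GROUP[cells] == _AGESEX_GROUP[cell_j]
    elif level == 2:
        in_group = _AGE_GROUP[cells] == _AGE_GROUP[cell_j]
    else:
        in_group = np.ones(len(cells), dtype=bool)
    if cell_subset is not None:
        in_group &= cell_subset[cells]
    return in_group & (flag == 1)


def estimate_pmn(
    exam_records: pd.DataFrame,
    diseases: Sequence[Disease] | None = None,
    thresholds: Thresholds = Thresholds(),
    min_cell_n: int = MIN_CELL_N,
) -> PrevalenceTable:
    """PMN_ij: malnutrition prevalence within each disease x cell.

    Domains are diseased persons (flag == 1) in the examination survey whose
    malnutrition status is determinable; sparse cells are filled by the
    pooling ladder.  SEs are linearized on the pooled domain actually used.
    """
    diseases = tuple(diseases) if diseases is not None else default_diseases()
    design = build_design(exam_records)
    indicator, _ = classify_records(exam_records, thresholds)
    flags = flags_matrix(exam_records)

    num, den, cnt = disease_cell_sums(design, flags, indicator)
    est, level = pooled_estimates(num, den, cnt, min_cell_n)

    se = np.full(est.shape, np.nan)
    n_out = np.zeros(est.shape, dtype=int)
    for i in range(len(DISEASES)):
        cache: dict[tuple[int, int], tuple[float, float, int]] = {}
        for j in range(N_CELLS):
            lvl = level[i, j]
            if lvl < 0:
                continue
            key = (lvl, _group_key(lvl, j))
            if key not in cache:
                m = _domain_mask_for_level(design, flags[:, i], lvl, j)
                cache[key] = _ratio_with_se(design, indicator, m)
            p, s, n = cache[key]
            se[i, j], n_out[i, j] = s, n
    return PrevalenceTable.from_matrices(est, se, n_out, ["examination"] * len(DISEASES), level)


def _group_key(level: int, j: int) -> int:
    if level == 0:
        return j
    if level == 1:
        return int(_AGESEX_GROUP[j])
    if level == 2:
        return int(_AGE_GROUP[j])
    return 0


def estimate_rho(
    interview_records: pd.DataFrame,
    exam_records: pd.DataFrame,
    diseases: Sequence[Disease] | None = None,
    min_cell_n: int = MIN_CELL_N,
) -> PrevalenceTable:
    """rho_ij: disease prevalence per cell, routed to each disease's source.

    Diseases declared ``interview`` use the interview survey, except the
    child (0-18) cells which fall back to the examination survey; diseases
    declared ``examination`` use the examination survey throughout.  Pooled
    levels 1-2 stay within one survey by construction (same age band); the
    disease-wide marginal (level 3) uses the declared source survey.
    """
    diseases = tuple(diseases) if diseases is not None else default_diseases()
    by_id = {d.id: d for d in diseases}
    missing = [d for d in DISEASES if d not in by_id]
    if missing:
        raise ValueError(f"prevalence_source not declared for: {', '.join(missing)}")

    exam_design = build_design(exam_records)
    int_design = build_design(interview_records)
    exam_flags = flags_matrix(exam_records)
    int_flags = flags_matrix(interview_records)

    child_cells = np.array([c.age_band == AGE_BANDS[0] for c in ALL_CELLS])

    e_num, e_den, e_cnt = disease_cell_sums(exam_design, exam_flags)
    i_num, i_den, i_cnt = disease_cell_sums(int_design, int_flags)

    num = np.empty_like(e_num)
    den = np.empty_like(e_den)
    cnt = np.empty_like(e_cnt)
    marg = np.empty((len(DISEASES), 3))
    source = np.empty((len(DISEASES), N_CELLS), dtype=object)
    for i, d in enumerate(DISEASES):
        if by_id[d].prevalence_source == "examination":
            num[i], den[i], cnt[i] = e_num[i], e_den[i], e_cnt[i]
            source[i, :] = "examination"
            marg[i] = (e_num[i].sum(), e_den[i].sum(), e_cnt[i].sum())
        else:
            use_exam = child_cells
            num[i] = np.where(use_exam, e_num[i], i_num[i])
            den[i] = np.where(use_exam, e_den[i], i_den[i])
            cnt[i] = np.where(use_exam, e_cnt[i], i_cnt[i])
            source[i, :] = np.where(use_exam, "examination", "interview")
            marg[i] = (i_num[i].sum(), i_den[i].sum(), i_cnt[i].sum())

    est, level = pooled_estimates(
        num, den, cnt, min_cell_n,
        marg_num=marg[:, 0], marg_den=marg[:, 1], marg_cnt=marg[:, 2],
    )

    se = np.full(est.shape, np.nan)
    n_out = np.zeros(est.shape, dtype=int)
    for i, d in enumerate(DISEASES):
        interview_src = by_id[d].prevalence_source == "interview"
        cache: dict[tuple[int, int, bool], tuple[float, float, int]] = {}
        for j in range(N_CELLS):
            lvl = level[i, j]
            if lvl < 0:
                continue
            # which survey serves this (cell, level)?
            from_exam = (not interview_src) or (lvl < 3 and child_cells[j])
            key = (lvl, _group_key(lvl, j), from_exam)
            if key not in cache:
                design = exam_design if from_exam else int_design
                flag = exam_flags[:, i] if from_exam else int_flags[:, i]
                subset = None
                if interview_src and lvl < 3:
                    subset = child_cells if from_exam else ~child_cells
                m = _cells_mask(design, lvl, j, subset) & np.isfinite(flag)
                cache[key] = _ratio_with_se(design, flag, m)
            p, s, n = cache[key]
            se[i, j], n_out[i, j] = s, n
    return PrevalenceTable.from_matrices(est, se, n_out, source, level)


def _cells_mask(
    design: SurveyDesign, level: int, cell_j: int, cell_subset: np.ndarray | None
) -> np.ndarray:
    cells = design.cell_idx
    if level == 0:
        m = cells == cell_j
    elif level == 1:
        m = _AGESEX_GROUP[cells] == _AGESEX_GROUP[cell_j]
    elif level == 2:
        m = _AGE_GROUP[cells] == _AGE_GROUP[cell_j]
    else:
        m = np.ones(len(cells), dtype=bool)
    if cell_subset is not None:
        m &= cell_subset[cells]
    return m
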