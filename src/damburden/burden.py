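"""The attributable-cost model for disease-associated malnutrition.

For disease i, demographic cell j and state s the annual direct medical
cost attributable to malnutrition is

    cost(s, i, j) = C_i * AF(PMN_ij, dMN_i) * rho_ij * POP_j(s)

where C_i is the mean annual direct medical spending per patient with
disease i, rho_ij the disease prevalence, POP_j(s) the state's cell
population, and

    AF(PMN, dMN) = PMN * dMN / (1 + PMN * dMN)

the fraction of total spending on disease i in cell j that is excess
spending caused by malnutrition.  dMN is the proportional excess cost of a
malnourished patient (malnourished cost = (1 + dMN) x non-malnourished):
if a fraction PMN of patients each cost (1 + dMN) * c and the rest cost c,
average spending is c * (1 + PMN * dMN) = C, and the excess share of the
total is exactly AF.

Totals roll up by fixed canonical order (diseases in reporting order, cells
in canonical order, states alphabetical) using compensated summation so
reruns are bit-identical and conservation holds: national total = sum of
state totals = sum of national per-disease totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .costs import CostParameterSet
from .demographics import MASK_65PLUS, N_CELLS
from .diseases import DISEASES
from .prevalence import PrevalenceTable


def attributable_fraction(pmn, delta_mn):
    """Cost-attributable fraction PMN*dMN / (1 + PMN*dMN).

    Strictly increasing in both arguments, 0 iff either is 0, and bounded
    below 1.  Accepts scalars or arrays; PMN must lie in [0, 1] and dMN
    must be nonnegative.
    """
    p = np.asarray(pmn, dtype=float)
    d = np.asarray(delta_mn, dtype=float)
    valid = np.isnan(p) | ((p >= 0) & (p <= 1))
    if not np.all(valid):
        raise ValueError("PMN must lie in [0, 1]")
    if np.any(d < 0):
        raise ValueError("delta_mn must be nonnegative")
    x = p * d
    out = x / (1.0 + x)
    if np.ndim(pmn) == 0 and np.ndim(delta_mn) == 0:
        return float(out)
    return out


def cell_cost(C: float, pmn: float, delta_mn: float, rho: float, pop: float) -> float:
    """Attributable cost (USD/year) for one (state, disease, cell) triple."""
    if C <= 0:
        raise ValueError("C must be positive")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if pop < 0:
        raise ValueError("POP must be nonnegative")
    return C * attributable_fraction(pmn, delta_mn) * rho * pop


@dataclass
class BurdenResult:
    """State x disease attributable costs plus all roll-ups.

    ``cost_matrix`` holds per-(state, disease) totals (USD/year); state and
    national tables are derived views.  Optional interval bounds (filled by
    the sensitivity analysis) live in ``intervals``.
    """

    states: list[str]
    cost_matrix: np.ndarray        # (n_states, 8)
    cost_matrix_65plus: np.ndarray  # (n_states, 8)
    population: np.ndarray         # (n_states,) total persons
    population_65plus: np.ndarray  # (n_states,)
    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)

    # -- roll-ups ---------------------------------------------------------
    def state_totals(self) -> np.ndarray:
        return np.array([math.fsum(row) for row in self.cost_matrix])

    def state_totals_65plus(self) -> np.ndarray:
        return np.array([math.fsum(row) for row in self.cost_matrix_65plus])

    def national_by_disease(self) -> np.ndarray:
        return np.array([math.fsum(self.cost_matrix[:, i]) for i in range(len(DISEASES))])

    def national_total(self) -> float:
        return math.fsum(self.cost_matrix.ravel(order="C"))

    def national_total_65plus(self) -> float:
        return math.fsum(self.cost_matrix_65plus.ravel(order="C"))

    def per_capita(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.population > 0, self.state_totals() / self.population, 0.0)

    def per_capita_65plus(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.population_65plus > 0,
                self.state_totals_65plus() / self.population_65plus, 0.0,
            )

    # -- tables -----------------------------------------------------------
    def state_table(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "state": self.states,
            "cost_total": self.state_totals(),
            "cost_per_capita": self.per_capita(),
            "cost_total_65plus": self.state_totals_65plus(),
            "cost_per_capita_65plus": self.per_capita_65plus(),
        })
        pop, pop65 = math.fsum(self.population), math.fsum(self.population_65plus)
        national = {
            "state": "National",
            "cost_total": self.national_total(),
            "cost_per_capita": self.national_total() / pop if pop else 0.0,
            "cost_total_65plus": self.national_total_65plus(),
            "cost_per_capita_65plus": self.national_total_65plus() / pop65 if pop65 else 0.0,
        }
        df = pd.concat([df, pd.DataFrame([national])], ignore_index=True)
        if "state" in self.intervals:
            df = df.merge(self.intervals["state"], on="state", how="left")
        return df

    def state_disease_table(self) -> pd.DataFrame:
        rows = [
            {"state": s, "disease": d, "cost_total": self.cost_matrix[si, di]}
            for si, s in enumerate(self.states)
            for di, d in enumerate(DISEASES)
        ]
        nat = self.national_by_disease()
        rows += [{"state": "National", "disease": d, "cost_total": nat[di]}
                 for di, d in enumerate(DISEASES)]
        df = pd.DataFrame(rows)
        if "state_disease" in self.intervals:
            df = df.merge(self.intervals["state_disease"], on=["state", "disease"], how="left")
        return df

    def conservation_gap(self) -> float:
        """Max absolute discrepancy among the three national roll-up orders."""
        t = self.national_total()
        return max(
            abs(t - math.fsum(self.state_totals())),
            abs(t - math.fsum(self.national_by_disease())),
        )


def burden_matrices(
    pmn: np.ndarray,
    rho: np.ndarray,
    pop: np.ndarray,
    cost_params: CostParameterSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized core: (n_states, 8) cost totals, all cells and 65+ only.

    ``pmn``/``rho`` are (8, 30) matrices, ``pop`` an (n_states, 30) matrix.
    Raises if a needed prevalence entry is missing (NaN) where it would
    contribute (nonzero population and nonzero companion factor).
    """
    if pmn.shape != (len(DISEASES), N_CELLS) or rho.shape != (len(DISEASES), N_CELLS):
        raise ValueError("pmn/rho must be (8, 30) matrices")
    needed = (pop.sum(axis=0) > 0)[None, :]
    bad = needed & (np.isnan(pmn) | np.isnan(rho))
    if bad.any():
        di, ci = np.argwhere(bad)[0]
        raise ValueError(
            f"missing prevalence entry for disease {DISEASES[di]!r}, cell index {ci} "
            "(unfilled after pooling)"
        )
    C = cost_params.cost_vector()          # (8,)
    delta = cost_params.delta_vector()     # (8,)
    af = attributable_fraction(np.nan_to_num(pmn), delta[:, None])  # (8, 30)
    per_cell = C[:, None] * af * np.nan_to_num(rho)                 # (8, 30) per person
    cost = pop @ per_cell.T                                         # (n_states, 8)
    cost65 = (pop * MASK_65PLUS[None, :]) @ per_cell.T
    return cost, cost65


def compute_burden(
    pmn_table: PrevalenceTable | np.ndarray,
    rho_table: PrevalenceTable | np.ndarray,
    population: pd.DataFrame,
    cost_params: CostParameterSet,
    states: Sequence[str] | None = None,
) -> BurdenResult:
    """Full burden computation over states x diseases x cells.

    ``population`` is the standardized population table (one row per state x
    cell); ``states`` restricts and orders the output (default: all states
    in the table, alphabetical).  Raises if a requested state is absent.
    """
    from .io import population_matrix

    if states is None:
        states = sorted(population["state"].unique())
    else:
        states = sorted(states)
        known = set(population["state"].unique())
        missing = [s for s in states if s not in known]
        if missing:
            raise ValueError(f"state(s) absent from population table: {', '.join(missing)}")
    pop = population_matrix(population, states)
    pmn = pmn_table.matrix() if isinstance(pmn_table, PrevalenceTable) else np.asarray(pmn_table)
    rho = rho_table.matrix() if isinstance(rho_table, PrevalenceTable) else np.asarray(rho_table)
    cost, cost65 = burden_matrices(pmn, rho, pop, cost_params)
    return BurdenResult(
        states=list(states),
        cost_matrix=cost,
        cost_matrix_65plus=cost65,
        population=pop.sum(axis=1),
        population_65plus=(pop * MASK_65PLUS[None, :]).sum(axis=1),
    )
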