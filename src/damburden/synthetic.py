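"""Synthetic survey microdata with known ground truth.

The pipeline's real-world inputs are an examination survey (measurements:
height, weight, serum albumin), a larger interview survey (disease flags
only), and census-style state population tables.  This module generates all
three from an explicit :class:`GroundTruth`, so every estimation stage can
be checked against the parameters that produced the data.

Generation mechanism (examination survey):

* each person's demographic cell is drawn from a stated cell-probability
  vector; an integer age is drawn uniformly within the band;
* strata and clusters are assigned round-robin, and sampling weights are a
  per-cluster lognormal factor (mean 1, dispersion configurable);
* disease flags are independent Bernoulli(rho_true[disease, cell]) draws,
  optionally perturbed by a per-cluster random effect on the log-odds;
* a single latent malnutrition status is drawn per person —
  Bernoulli(pmn_true[d*, cell]) with d* the person's first flagged disease
  in canonical order, or a background rate for disease-free persons — and
  then *realized through measurements*: malnourished persons get either low
  albumin (uniform on [2.5, 3.4] g/dL) or low weight (uniform fraction on
  [0.75, 0.89] of Hamwi ideal weight), fair-coin choice; non-malnourished
  persons get albumin on [3.6, 5.0] and weight on [0.95, 1.30] of ideal.

The bands straddle the diagnostic thresholds (0.90 of ideal weight,
3.5 g/dL) with a margin wider than the 0.1-unit storage rounding, so the
classifier reproduces the latent label exactly: generation and
classification are threshold-disjoint by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import CostParameterSet
from .demographics import AGE_BANDS, ALL_CELLS, N_CELLS, RACES, SEXES
from .diseases import DISEASES, flag_column
from .io import cost_parameters_from_dict, default_cost_parameters, _dist_to_dict
from .malnutrition import KG_PER_LB, hamwi_ideal_weight

#: integer age ranges (inclusive) per band for drawing ages
_AGE_RANGES = {"0-18": (0, 18), "19-45": (19, 45), "46-55": (46, 55),
               "56-64": (56, 64), "65+": (65, 90)}

#: sex-specific height distributions, cm (adult U.S.-like)
HEIGHT_MEAN_CM = {"male": 175.6, "female": 162.1}
HEIGHT_SD_CM = {"male": 7.1, "female": 6.6}
_HEIGHT_CLIP_CM = (140.0, 205.0)

# measurement-realization bands (disjoint from the 0.90 / 3.5 thresholds)
_ALBUMIN_LOW = (2.5, 3.4)
_ALBUMIN_NORMAL = (3.6, 5.0)
_WEIGHT_FRAC_LOW = (0.75, 0.89)
_WEIGHT_FRAC_NORMAL = (0.95, 1.30)


@dataclass(frozen=True)
class DesignSpec:
    """Stratified-cluster design of a generated survey."""

    n_strata: int = 15
    clusters_per_stratum: int = 4
    weight_dispersion: float = 0.3  # sigma of the per-cluster lognormal factor
    cluster_disease_sd: float = 0.0  # log-odds random effect; 0 = off

    def __post_init__(self) -> None:
        if self.n_strata < 1 or self.clusters_per_stratum < 1:
            raise ValueError("design counts must be >= 1")
        if self.weight_dispersion < 0 or self.cluster_disease_sd < 0:
            raise ValueError("dispersions must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs, and everything recovery tests check.

    ``rho`` and ``pmn`` are (8, 30) probability matrices in canonical
    disease x cell order; ``states`` maps state codes to length-30 integer
    cell counts; ``cell_probs`` is the length-30 sampling distribution of
    cells in the surveys.
    """

    cell_probs: np.ndarray
    rho: np.ndarray
    pmn: np.ndarray
    states: Mapping[str, np.ndarray]
    cost_params: CostParameterSet
    exam_design: DesignSpec = field(default_factory=DesignSpec)
    interview_design: DesignSpec = field(default_factory=lambda: DesignSpec(n_strata=30))
    background_pmn: float = 0.06

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_probs", np.asarray(self.cell_probs, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        object.__setattr__(self, "pmn", np.asarray(self.pmn, dtype=float))
        object.__setattr__(
            self, "states",
            {k: np.asarray(v, dtype=np.int64) for k, v in self.states.items()},
        )
        if self.cell_probs.shape != (N_CELLS,):
            raise ValueError("cell_probs must have length 30")
        if not np.isclose(self.cell_probs.sum(), 1.0):
            raise ValueError("cell_probs must sum to 1")
        if np.any(self.cell_probs < 0):
            raise ValueError("cell_probs must be nonnegative")
        for name, mat in (("rho", self.rho), ("pmn", self.pmn)):
            if mat.shape != (len(DISEASES), N_CELLS):
                raise ValueError(f"{name} must be an (8, 30) matrix")
            if np.any((mat < 0) | (mat > 1)):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        if not 0 <= self.background_pmn <= 1:
            raise ValueError("background_pmn must lie in [0, 1]")
        for st, counts in self.states.items():
            if counts.shape != (N_CELLS,):
                raise ValueError(f"state {st}: counts must have length 30")
            if np.any(counts < 0):
                raise ValueError(f"state {st}: counts must be nonnegative")
        if not self.states:
            raise ValueError("at least one state is required")

    def effective_pmn(self) -> np.ndarray:
        """The generator's implied P(malnourished | disease i, cell j).

        A person's single latent malnutrition status is drawn from
        ``pmn[d*, cell]`` with d* their *first* flagged disease, so for a
        comorbid person with disease i the status may have been drawn from
        an earlier disease's rate.  Conditioning on flag_i = 1 and using
        flag independence:

            eff[i, j] = sum_{k < i} rho_kj * prod_{m < k}(1 - rho_mj) * pmn_kj
                        + prod_{m < i}(1 - rho_mj) * pmn_ij

        This, not ``pmn`` itself, is the estimand of the malnutrition-
        within-disease stage on generated data; the two coincide when
        ``pmn`` does not vary across diseases within a cell.
        """
        eff = np.empty_like(self.pmn)
        for j in range(N_CELLS):
            acc = 1.0  # P(no disease flagged before i)
            cum = 0.0  # sum over earlier-first diseases of P(first=k) * pmn_k
            for i in range(len(DISEASES)):
                eff[i, j] = cum + acc * self.pmn[i, j]
                cum += acc * self.rho[i, j] * self.pmn[i, j]
                acc *= 1.0 - self.rho[i, j]
        return eff


# ---------------------------------------------------------------------------
# default ground truth: the conditions of the bundled synthetic world
# ---------------------------------------------------------------------------

def _default_rho() -> np.ndarray:
    """Disease prevalence by age band with mild sex/race variation."""
    age_profiles = {
        "stroke": [0.001, 0.006, 0.025, 0.045, 0.080],
        "copd": [0.004, 0.015, 0.045, 0.075, 0.100],
        "chf": [0.001, 0.005, 0.020, 0.040, 0.090],
        "colorectal_cancer": [0.0005, 0.002, 0.008, 0.015, 0.025],
        "breast_cancer": [0.0005, 0.004, 0.015, 0.025, 0.035],
        "dementia": [0.005, 0.040, 0.070, 0.100, 0.125],
        "musculoskeletal": [0.010, 0.050, 0.100, 0.140, 0.180],
        "depression": [0.020, 0.080, 0.100, 0.090, 0.070],
    }
    sex_mult = {d: {"male": 1.1, "female": 0.9} for d in DISEASES}
    sex_mult["breast_cancer"] = {"male": 0.05, "female": 1.0}
    sex_mult["depression"] = {"male": 0.8, "female": 1.2}
    race_mult = {"white": 1.0, "black": 1.15, "other": 0.9}
    rho = np.zeros((len(DISEASES), N_CELLS))
    for i, d in enumerate(DISEASES):
        for j, c in enumerate(ALL_CELLS):
            a = AGE_BANDS.index(c.age_band)
            rho[i, j] = age_profiles[d][a] * sex_mult[d][c.sex] * race_mult[c.race]
    return np.clip(rho, 0.0, 1.0)


def _default_pmn() -> np.ndarray:
    """Malnutrition-given-disease prevalence: higher at the age extremes."""
    age_base = [0.10, 0.05, 0.06, 0.07, 0.09]
    disease_mult = {
        "stroke": 1.0, "copd": 1.1, "chf": 1.0, "colorectal_cancer": 1.4,
        "breast_cancer": 1.4, "dementia": 1.2, "musculoskeletal": 0.9, "depression": 1.0,
    }
    pmn = np.zeros((len(DISEASES), N_CELLS))
    for i, d in enumerate(DISEASES):
        for j, c in enumerate(ALL_CELLS):
            a = AGE_BANDS.index(c.age_band)
            sex_f = 1.05 if c.sex == "female" else 1.0
            pmn[i, j] = age_base[a] * disease_mult[d] * sex_f
    return np.clip(pmn, 0.0, 1.0)


def _default_cell_probs() -> np.ndarray:
    age_p = np.array([0.24, 0.35, 0.13, 0.12, 0.16])
    sex_p = np.array([0.49, 0.51])
    race_p = np.array([0.72, 0.13, 0.15])
    probs = np.einsum("a,s,r->asr", age_p, sex_p, race_p).ravel()
    return probs / probs.sum()


def _default_states() -> dict[str, np.ndarray]:
    """Six synthetic states with census-like cell counts (fixed inputs)."""
    base = _default_cell_probs()
    pops = {"SA": 4_800_000, "SB": 2_100_000, "SC": 9_500_000,
            "SD": 650_000, "SE": 1_300_000, "SF": 3_200_000}
    # deterministic per-state age tilt: older SB/SD, younger SC/SF
    tilt = {"SA": 1.00, "SB": 1.35, "SC": 0.85, "SD": 1.25, "SE": 1.00, "SF": 0.90}
    age_idx = np.repeat(np.arange(len(AGE_BANDS)), len(SEXES) * len(RACES))
    states = {}
    for st, pop in pops.items():
        shape = base * np.where(age_idx == len(AGE_BANDS) - 1, tilt[st], 1.0)
        shape = shape / shape.sum()
        counts = np.floor(shape * pop).astype(np.int64)
        counts[0] += pop - counts.sum()  # exact state total
        states[st] = counts
    return states


def default_ground_truth() -> GroundTruth:
    """The bundled synthetic world used by tests, the CLI and examples."""
    return GroundTruth(
        cell_probs=_default_cell_probs(),
        rho=_default_rho(),
        pmn=_default_pmn(),
        states=_default_states(),
        cost_params=default_cost_parameters(),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _assign_design(n: int, design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Round-robin stratum/cluster assignment; returns (stratum, global cluster)."""
    n_clusters = design.n_strata * design.clusters_per_stratum
    cluster = np.arange(n) % n_clusters
    stratum = cluster // design.clusters_per_stratum
    return stratum, cluster


def _draw_common(truth: GroundTruth, n: int, design: DesignSpec,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, design, weights and disease flags (both surveys)."""
    cell = rng.choice(N_CELLS, size=n, p=truth.cell_probs)
    bands = np.array([c.age_band for c in ALL_CELLS])[cell]
    lo = np.array([_AGE_RANGES[b][0] for b in bands])
    hi = np.array([_AGE_RANGES[b][1] for b in bands])
    age = rng.integers(lo, hi + 1)
    sex = np.array([c.sex for c in ALL_CELLS])[cell]
    race = np.array([c.race for c in ALL_CELLS])[cell]

    stratum, cluster = _assign_design(n, design)
    n_clusters = design.n_strata * design.clusters_per_stratum
    sigma = design.weight_dispersion
    factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_clusters) if sigma > 0 \
        else np.ones(n_clusters)
    weight = factor[cluster]

    # disease flags: independent Bernoulli(rho), optional cluster effect on log-odds
    p = truth.rho[:, cell].T  # (n, 8)
    if design.cluster_disease_sd > 0:
        offs = rng.normal(0.0, design.cluster_disease_sd, size=(n_clusters, len(DISEASES)))
        with np.errstate(divide="ignore"):
            logit = np.log(p) - np.log1p(-p)
        logit = logit + offs[cluster]
        p = np.where(p <= 0, 0.0, np.where(p >= 1, 1.0, 1.0 / (1.0 + np.exp(-logit))))
    flags = (rng.random((n, len(DISEASES))) < p).astype(float)

    df = pd.DataFrame({
        "person_id": [f"P{k:07d}" for k in range(n)],
        "age": age,
        "sex": sex,
        "race": race,
        "sample_weight": np.round(weight, 6),
        "stratum_id": [f"S{h:03d}" for h in stratum],
        "cluster_id": [f"C{c:04d}" for c in cluster],
    })
    for i, d in enumerate(DISEASES):
        df[flag_column(d)] = flags[:, i]
    df["cell_idx"] = cell
    df["age_band"] = bands
    return df


def _latent_malnutrition(truth: GroundTruth, df: pd.DataFrame,
                         rng: np.random.Generator) -> np.ndarray:
    """Person-level latent status: pmn of the first flagged disease, else background."""
    cell = df["cell_idx"].to_numpy()
    flags = np.column_stack([df[flag_column(d)].to_numpy() for d in DISEASES])
    any_flag = flags.any(axis=1)
    first = np.argmax(flags, axis=1)  # first flagged disease in canonical order
    p = np.where(any_flag, truth.pmn[first, cell], truth.background_pmn)
    return rng.random(len(df)) < p


def generate_examination_survey(truth: GroundTruth, n: int, seed: int) -> pd.DataFrame:
    """Examination survey: demographics, design, flags and measurements."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    df = _draw_common(truth, n, truth.exam_design, rng)
    mal = _latent_malnutrition(truth, df, rng)

    sex = df["sex"].to_numpy()
    height = rng.normal(
        np.where(sex == "male", HEIGHT_MEAN_CM["male"], HEIGHT_MEAN_CM["female"]),
        np.where(sex == "male", HEIGHT_SD_CM["male"], HEIGHT_SD_CM["female"]),
    )
    height = np.round(np.clip(height, *_HEIGHT_CLIP_CM), 1)
    ibw_kg = hamwi_ideal_weight(sex, height) * KG_PER_LB  # from stored (rounded) heights

    low_weight_route = mal & (rng.random(n) < 0.5)
    albumin = np.where(
        mal & ~low_weight_route,
        rng.uniform(*_ALBUMIN_LOW, size=n),
        rng.uniform(*_ALBUMIN_NORMAL, size=n),
    )
    frac = np.where(
        low_weight_route,
        rng.uniform(*_WEIGHT_FRAC_LOW, size=n),
        rng.uniform(*_WEIGHT_FRAC_NORMAL, size=n),
    )
    df["height_cm"] = height
    df["weight_kg"] = np.round(frac * ibw_kg, 1)
    df["albumin_gdl"] = np.round(albumin, 1)
    df["malnourished_true"] = mal.astype(int)
    return df


def generate_interview_survey(truth: GroundTruth, n: int, seed: int) -> pd.DataFrame:
    """Interview survey: demographics, design and disease flags only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _draw_common(truth, n, truth.interview_design, rng)


def generate_population(truth: GroundTruth) -> pd.DataFrame:
    """State population table exactly as specified in the truth (no noise)."""
    rows = []
    for st in sorted(truth.states):
        counts = truth.states[st]
        for j, c in enumerate(ALL_CELLS):
            rows.append((st, c.age_band, c.sex, c.race, int(counts[j])))
    return pd.DataFrame(rows, columns=["state", "age_band", "sex", "race", "count"])


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize a GroundTruth to JSON (round-trips with read_ground_truth)."""
    doc = {
        "cell_probs": truth.cell_probs.tolist(),
        "rho": truth.rho.tolist(),
        "pmn": truth.pmn.tolist(),
        "states": {k: v.tolist() for k, v in truth.states.items()},
        "background_pmn": truth.background_pmn,
        "exam_design": truth.exam_design.__dict__,
        "interview_design": truth.interview_design.__dict__,
        "cost_params": {
            "delta_mn": {
                "value": truth.cost_params.delta_mn,
                "distribution": _dist_to_dict(truth.cost_params.delta_dist),
                "per_disease": dict(truth.cost_params.delta_overrides),
            },
            "diseases": {
                d: {
                    "mean_annual_cost": truth.cost_params.mean_cost[d],
                    "distribution": _dist_to_dict(truth.cost_params.cost_dist[d]),
                }
                for d in DISEASES
            },
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return GroundTruth(
        cell_probs=np.array(doc["cell_probs"]),
        rho=np.array(doc["rho"]),
        pmn=np.array(doc["pmn"]),
        states={k: np.array(v) for k, v in doc["states"].items()},
        cost_params=cost_parameters_from_dict(doc["cost_params"], source=str(path)),
        exam_design=DesignSpec(**doc["exam_design"]),
        interview_design=DesignSpec(**doc["interview_design"]),
        background_pmn=doc["background_pmn"],
    )
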