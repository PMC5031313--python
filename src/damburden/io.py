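"""Readers and writers for all tabular inputs and outputs.

Survey microdata, state population tables and burden outputs travel as
delimited text (comma-separated by default, tab-separated accepted) with a
required header row, UTF-8 encoded.  Cost parameters travel as YAML.  All
readers validate totally: a malformed row never enters the pipeline
silently — it either raises with row-numbered diagnostics or (for absent
population cells) is zero-filled with a logged warning.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .costs import CostDistribution, CostParameterSet
from .demographics import (
    AGE_BANDS,
    ALL_CELLS,
    N_CELLS,
    SEXES,
    cell_index_from_columns,
    normalize_race,
)
from .diseases import DISEASES, flag_column

logger = logging.getLogger(__name__)

SCHEMAS = ("examination", "interview")

_BASE_COLUMNS = ["person_id", "age", "sex", "race", "sample_weight", "stratum_id", "cluster_id"]
_EXAM_COLUMNS = _BASE_COLUMNS + ["height_cm", "weight_kg"]


class SchemaError(ValueError):
    """A table is structurally unusable (missing/duplicate columns, bad labels)."""


class ValidationError(ValueError):
    """Individual rows violate the record invariants."""


def _read_delimited(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    return pd.to_numeric(df[col], errors="coerce")


def _offending(rows: Iterable[int]) -> str:
    shown = [str(r + 2) for r in list(rows)[:20]]  # +2: header + 1-based file lines
    return ", ".join(shown)


def read_survey_table(
    path: str | Path,
    schema: str,
    sep: str | None = None,
    race_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a survey microdata table.

    ``schema`` is ``"examination"`` (height/weight columns required, albumin
    optional) or ``"interview"`` (measurements not required).  Returns a
    DataFrame with standardized columns including the canonical ``cell_idx``
    and ``age_band``; missing albumin and missing disease flags stay missing
    (NaN), never coerced to zero.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {SCHEMAS}, got {schema!r}")
    raw = _read_delimited(path, sep)
    required = _EXAM_COLUMNS if schema == "examination" else _BASE_COLUMNS
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    out = pd.DataFrame()
    out["person_id"] = raw["person_id"].astype(str)
    out["age"] = _numeric(raw, "age")
    out["sex"] = raw["sex"].astype(str).str.strip().str.lower()
    out["race"] = [normalize_race(r, race_map) for r in raw["race"]]
    out["sample_weight"] = _numeric(raw, "sample_weight")
    out["stratum_id"] = raw["stratum_id"].astype(str)
    out["cluster_id"] = raw["cluster_id"].astype(str)
    for col in ("height_cm", "weight_kg", "albumin_gdl"):
        out[col] = _numeric(raw, col) if col in raw.columns else np.nan
    for d in DISEASES:
        col = flag_column(d)
        out[col] = _numeric(raw, col) if col in raw.columns else np.nan

    problems: list[str] = []
    bad = out.index[out["age"].isna() | (out["age"] < 0)]
    if len(bad):
        problems.append(f"invalid age at row(s) {_offending(bad)}")
    bad = out.index[~out["sex"].isin(SEXES)]
    if len(bad):
        problems.append(f"sex must be male/female at row(s) {_offending(bad)}")
    bad = out.index[out["sample_weight"].isna() | (out["sample_weight"] < 0)]
    if len(bad):
        problems.append(f"sample_weight must be a nonnegative number at row(s) {_offending(bad)}")
    for col in ("height_cm", "weight_kg"):
        bad = out.index[out[col].notna() & (out[col] <= 0)]
        if len(bad):
            problems.append(f"{col} must be positive when present at row(s) {_offending(bad)}")
    for d in DISEASES:
        col = flag_column(d)
        vals = out[col]
        bad = out.index[vals.notna() & ~vals.isin([0.0, 1.0])]
        if len(bad):
            problems.append(f"{col} must be 0/1/missing at row(s) {_offending(bad)}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    out["cell_idx"] = cell_index_from_columns(
        out["age"].to_numpy(), out["sex"], raw["race"], race_map
    )
    out["age_band"] = [ALL_CELLS[i].age_band for i in out["cell_idx"]]
    return out


def write_survey_table(records: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a survey table in the on-disk schema (inverse of the reader)."""
    cols = [c for c in _EXAM_COLUMNS + ["albumin_gdl"] if c in records.columns]
    cols += [flag_column(d) for d in DISEASES if flag_column(d) in records.columns]
    records.to_csv(path, sep=sep, columns=cols, index=False)


def read_population_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a state population table keyed by state, age_band, sex, race.

    Returns one row per (state, cell) in canonical order with an integer
    ``count``; cells absent from the file default to zero with a logged
    warning.  Duplicate (state, cell) rows and unknown band labels raise.
    """
    raw = _read_delimited(path, sep)
    required = ["state", "age_band", "sex", "race", "count"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = raw.copy()
    df["state"] = df["state"].astype(str).str.strip()
    df["age_band"] = df["age_band"].astype(str).str.strip()
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["race"] = [normalize_race(r) for r in df["race"]]
    bad = df.index[~df["age_band"].isin(AGE_BANDS)]
    if len(bad):
        labels = sorted(set(df.loc[bad, "age_band"]))
        raise SchemaError(f"{path}: unknown age-band label(s) {labels}; expected {AGE_BANDS}")
    bad = df.index[~df["sex"].isin(SEXES)]
    if len(bad):
        raise SchemaError(f"{path}: sex must be male/female at row(s) {_offending(bad)}")
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[df["count"].isna() | (df["count"] < 0)]
    if len(bad):
        raise ValidationError(f"{path}: count must be a nonnegative number at row(s) {_offending(bad)}")

    key = ["state", "age_band", "sex", "race"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        rows = df.loc[dup, key].drop_duplicates().itertuples(index=False)
        pairs = "; ".join("/".join(t) for t in rows)
        raise ValidationError(f"{path}: duplicate (state, cell) row(s): {pairs}")

    states = sorted(df["state"].unique())
    full = pd.DataFrame(
        [(st, c.age_band, c.sex, c.race) for st in states for c in ALL_CELLS],
        columns=key,
    )
    merged = full.merge(df[key + ["count"]], on=key, how="left")
    absent = merged["count"].isna()
    if absent.any():
        for st, n_abs in merged.loc[absent, "state"].value_counts().sort_index().items():
            logger.warning("population table %s: state %s missing %d cell(s); zero-filled",
                           path, st, n_abs)
        merged["count"] = merged["count"].fillna(0)
    merged["count"] = merged["count"].round().astype(np.int64)
    return merged


def population_matrix(population: pd.DataFrame, states: Sequence[str]) -> np.ndarray:
    """POP_j per state as an (n_states, 30) array in canonical cell order."""
    from .demographics import CELL_INDEX, DemographicCell

    pivot = {}
    for st, grp in population.groupby("state"):
        vec = np.zeros(N_CELLS)
        for band, sex, race, count in zip(grp["age_band"], grp["sex"], grp["race"], grp["count"]):
            vec[CELL_INDEX[DemographicCell(band, sex, race)]] = count
        pivot[st] = vec
    missing = [s for s in states if s not in pivot]
    if missing:
        raise ValueError(f"state(s) absent from population table: {', '.join(missing)}")
    return np.stack([pivot[s] for s in states])


def _parse_distribution(node: Mapping) -> CostDistribution:
    if not isinstance(node, Mapping) or len(node) != 1:
        raise SchemaError(f"distribution spec must have exactly one kind, got {node!r}")
    kind, params = next(iter(node.items()))
    params = params or {}
    if kind == "gamma":
        return CostDistribution("gamma", se=float(params.get("se", 0.0)))
    if kind == "uniform":
        return CostDistribution("uniform", pct=float(params.get("pct", 0.20)))
    raise SchemaError(f"unknown distribution kind {kind!r}")


def read_cost_config(path: str | Path) -> CostParameterSet:
    """Read a YAML cost-parameter config (8 diseases + global dMN)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return cost_parameters_from_dict(doc, source=str(path))


def cost_parameters_from_dict(doc: Mapping, source: str = "<config>") -> CostParameterSet:
    if not isinstance(doc, Mapping) or "diseases" not in doc:
        raise SchemaError(f"{source}: cost config must contain a 'diseases' mapping")
    dis = doc["diseases"]
    missing = [d for d in DISEASES if d not in dis]
    if missing:
        raise SchemaError(f"{source}: cost config missing disease(s): {', '.join(missing)}")
    mean_cost, cost_dist = {}, {}
    for d in DISEASES:
        node = dis[d]
        try:
            mean_cost[d] = float(node["mean_annual_cost"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{source}: disease {d}: bad mean_annual_cost") from exc
        if mean_cost[d] <= 0:
            raise ValidationError(f"{source}: disease {d}: mean_annual_cost must be > 0")
        cost_dist[d] = _parse_distribution(node.get("distribution", {"uniform": {}}))
    delta_node = doc.get("delta_mn", {})
    delta_value = float(delta_node.get("value", 0.0))
    delta_dist = _parse_distribution(delta_node.get("distribution", {"uniform": {}}))
    overrides = {k: float(v) for k, v in (delta_node.get("per_disease") or {}).items()}
    return CostParameterSet(
        mean_cost=mean_cost, cost_dist=cost_dist,
        delta_mn=delta_value, delta_dist=delta_dist, delta_overrides=overrides,
    )


def default_cost_parameters() -> CostParameterSet:
    """The bundled default cost fixture."""
    ref = resources.files("damburden").joinpath("data/default_costs.yaml")
    with ref.open(encoding="utf-8") as fh:
        return cost_parameters_from_dict(yaml.safe_load(fh), source="default_costs.yaml")


def write_cost_config(params: CostParameterSet, path: str | Path) -> None:
    """Serialize a CostParameterSet back to YAML (round-trips with the reader)."""
    doc: dict = {
        "delta_mn": {
            "value": params.delta_mn,
            "distribution": _dist_to_dict(params.delta_dist),
            "per_disease": dict(params.delta_overrides),
        },
        "diseases": {
            d: {
                "mean_annual_cost": params.mean_cost[d],
                "distribution": _dist_to_dict(params.cost_dist[d]),
            }
            for d in DISEASES
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _dist_to_dict(dist: CostDistribution) -> dict:
    if dist.kind == "gamma":
        return {"gamma": {"se": dist.se}}
    return {"uniform": {"pct": dist.pct}}


def write_burden_tables(result, out_dir: str | Path) -> dict[str, Path]:
    """Write the two burden output tables.

    ``state_burden.csv``: one row per state (alphabetical) plus a final
    National row, with total / per-capita / 65+ columns and interval bounds
    when present.  ``state_disease_burden.csv``: one row per state x disease
    in canonical disease order.  Values are plain decimals.
    """
    from .burden import BurdenResult  # local import to avoid a cycle

    if not isinstance(result, BurdenResult):
        raise TypeError("write_burden_tables expects a BurdenResult")
    if not result.states:
        raise ValueError("cannot write burden tables for an empty state list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state_path = out_dir / "state_burden.csv"
    sd_path = out_dir / "state_disease_burden.csv"
    result.state_table().to_csv(state_path, index=False)
    result.state_disease_table().to_csv(sd_path, index=False)
    return {"state": state_path, "state_disease": sd_path}
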