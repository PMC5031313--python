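"""Report rendering: rankings, disease decomposition, elderly share.

CSV tables are the contract; plots are optional presentation and never the
acceptance surface of a run.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .burden import BurdenResult
from .diseases import DISEASES


def report(result: BurdenResult, out_dir: str | Path, plots: bool = False) -> dict[str, Path]:
    """Emit the summary report tables for a burden (or PSA point) result.

    Writes: ``per_capita_ranking.csv`` (states sorted descending by
    per-capita cost), ``national_disease_decomposition.csv`` (per-disease
    national totals and shares), and ``age65_share_summary.csv`` (elderly
    versus all-ages cost and population shares).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ranking = pd.DataFrame({
        "state": result.states,
        "cost_per_capita": result.per_capita(),
        "cost_total": result.state_totals(),
    }).sort_values(["cost_per_capita", "state"], ascending=[False, True], kind="mergesort")
    ranking.insert(0, "rank", range(1, len(ranking) + 1))
    paths["ranking"] = out_dir / "per_capita_ranking.csv"
    ranking.to_csv(paths["ranking"], index=False)

    nat = result.national_by_disease()
    total = result.national_total()
    decomposition = pd.DataFrame({
        "disease": DISEASES,
        "cost_total": nat,
        "share": nat / total if total else 0.0,
    })
    paths["decomposition"] = out_dir / "national_disease_decomposition.csv"
    decomposition.to_csv(paths["decomposition"], index=False)

    pop = float(result.population.sum())
    pop65 = float(result.population_65plus.sum())
    summary = pd.DataFrame([{
        "cost_total": total,
        "cost_total_65plus": result.national_total_65plus(),
        "cost_share_65plus": result.national_total_65plus() / total if total else 0.0,
        "population_share_65plus": pop65 / pop if pop else 0.0,
        "cost_per_capita": total / pop if pop else 0.0,
        "cost_per_capita_65plus": result.national_total_65plus() / pop65 if pop65 else 0.0,
    }])
    paths["age65"] = out_dir / "age65_share_summary.csv"
    summary.to_csv(paths["age65"], index=False)

    if plots:  # pragma: no cover - presentation only
        _render_plots(ranking, decomposition, out_dir)
    return paths


def _render_plots(ranking: pd.DataFrame, decomposition: pd.DataFrame,
                  out_dir: Path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.3 * len(ranking) + 1))
    ax.barh(ranking["state"], ranking["cost_per_capita"])
    ax.set_xlabel("Attributable cost per capita (USD/year)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(out_dir / "per_capita_ranking.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(decomposition["disease"], decomposition["cost_total"] / 1e6)
    ax.set_ylabel("National attributable cost (million USD/year)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_dir / "national_disease_decomposition.png", dpi=120)
    plt.close(fig)
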