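"""Published reference estimates used for internal-consistency checks.

The original U.S. study that this model re-implements printed state-level
point estimates built from real survey microdata and literature cost inputs
that are not distributed with it, so its dollar values cannot be recomputed
from scratch.  What *can* be checked is the arithmetic of its printed
tables: per-disease rows must sum to their printed state totals, the
per-disease national estimates must sum to the printed national total, and
the printed elderly share must equal the ratio of the printed 65+ and
all-ages national costs.  The constants below carry exactly those printed
numbers.
"""

from __future__ import annotations

from .diseases import DISEASES

#: printed national all-ages total, USD/year
NATIONAL_TOTAL_USD = 15_598_520_320
#: printed national 65+ total, USD/year
NATIONAL_TOTAL_65PLUS_USD = 4_320_378_880
#: printed elderly share of the national burden, percent
NATIONAL_65PLUS_SHARE_PCT = 28

#: printed per-disease point estimates, million USD/year, canonical order
#: (stroke, copd, chf, colorectal_cancer, breast_cancer, dementia,
#:  musculoskeletal, depression)
STATE_DISEASE_MUSD = {
    "Alabama": [22.0, 30.7, 8.7, 3.0, 1.1, 152.4, 10.6, 38.4],
    "Texas": [87.4, 129.2, 37.8, 12.2, 5.1, 680.7, 58.6, 201.0],
    "National": [1165.0, 1724.0, 536.0, 182.0, 76.0, 8721.0, 733.0, 2460.0],
}

#: printed state/national totals of the same table, million USD/year
STATE_TOTAL_MUSD = {
    "Alabama": 267.0,
    "Texas": 1212.2,
    "National": 15599.0,
}


def disease_row_sum(key: str) -> float:
    """Sum of the printed per-disease estimates for a row (million USD)."""
    vals = STATE_DISEASE_MUSD[key]
    assert len(vals) == len(DISEASES)
    return float(sum(vals))


def elderly_share_pct() -> float:
    """Elderly share implied by the printed national costs, percent."""
    return 100.0 * NATIONAL_TOTAL_65PLUS_USD / NATIONAL_TOTAL_USD
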