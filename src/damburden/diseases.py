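"""The eight modeled diseases (index i of the cost model).

The disease set is fixed: eight moderate-prevalence conditions chosen so that
a malnourished person is unlikely to be counted under more than one of them.
Each disease declares which survey supplies its prevalence: the larger
interview survey where its case definition is available there, otherwise the
examination survey (dementia and depression; all child prevalences also fall
back to the examination survey regardless of source).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

#: canonical reporting order (columns of the per-disease output tables)
DISEASES: tuple[str, ...] = (
    "stroke",
    "copd",
    "chf",
    "colorectal_cancer",
    "breast_cancer",
    "dementia",
    "musculoskeletal",
    "depression",
)

DISEASE_LABELS: Mapping[str, str] = {
    "stroke": "Stroke",
    "copd": "COPD",
    "chf": "CHF",
    "colorectal_cancer": "Colorectal Cancer",
    "breast_cancer": "Breast Cancer",
    "dementia": "Dementia",
    "musculoskeletal": "Musculoskeletal",
    "depression": "Depression",
}

PREVALENCE_SOURCES: tuple[str, ...] = ("interview", "examination")

#: default routing of disease prevalence to a survey
DEFAULT_PREVALENCE_SOURCE: Mapping[str, str] = {
    "stroke": "interview",
    "copd": "interview",
    "chf": "interview",
    "colorectal_cancer": "interview",
    "breast_cancer": "interview",
    "dementia": "examination",
    "depression": "examination",
    "musculoskeletal": "interview",
}

DISEASE_INDEX: Mapping[str, int] = {d: i for i, d in enumerate(DISEASES)}
N_DISEASES = len(DISEASES)


@dataclass(frozen=True)
class Disease:
    """A study disease and the survey that supplies its prevalence."""

    id: str
    prevalence_source: str

    def __post_init__(self) -> None:
        if self.id not in DISEASES:
            raise ValueError(f"unknown disease {self.id!r}; expected one of {DISEASES}")
        if self.prevalence_source not in PREVALENCE_SOURCES:
            raise ValueError(
                f"prevalence_source must be one of {PREVALENCE_SOURCES}, "
                f"got {self.prevalence_source!r}"
            )


def default_diseases() -> tuple[Disease, ...]:
    """The eight diseases with their default prevalence routing."""
    return tuple(Disease(d, DEFAULT_PREVALENCE_SOURCE[d]) for d in DISEASES)


def flag_column(disease_id: str) -> str:
    """Name of the microdata indicator column for a disease."""
    return f"flag_{disease_id}"
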