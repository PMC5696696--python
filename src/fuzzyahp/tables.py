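"""Published factor/subfactor priority tables for military hospital-bed planning.

These fixtures reproduce, verbatim, the published two-level criterion
hierarchy for prioritizing the development of military hospital beds: eight
factors (F1-F8) and their 54 subfactors (C1-C55; the code C31 is absent in
the published listing and the gap is preserved rather than renumbered).
Each row carries the published extent-analysis score (3 decimals, local to
its block) and the published priority rank.  Scores within a block are local
weights — they sum to ~1 per block at printed precision.

The fixtures are the package's regression anchor: the dense-ranking rule
applied to the score columns must reproduce every printed priority integer,
including the shared rank of the tied C8/C9 rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import pandas as pd

from .scale import SCALE, LinguisticScaleEntry

#: (code, label, score, priority) for the eight top-level factors.
FACTOR_ROWS: tuple[tuple[str, str, float, int], ...] = (
    ("F1", "Geographic situation", 0.109, 4),
    ("F2", "Demographic status", 0.087, 6),
    ("F3", "Economic status", 0.040, 8),
    ("F4", "Health status", 0.080, 7),
    ("F5", "Health care centers and organizations", 0.154, 3),
    ("F6", "Financial and human resources", 0.096, 5),
    ("F7", "Laws and regulations and bylaws", 0.184, 2),
    ("F8", "The military nature of service recipients", 0.249, 1),
)

#: factor code -> ((subfactor code, label, score, priority), ...)
SUBFACTOR_ROWS: Mapping[str, tuple[tuple[str, str, float, int], ...]] = MappingProxyType({
    "F1": (
        ("C1", "Province distance from the major and big cities", 0.055, 5),
        ("C2", "Position and situation of the health care center and organization", 0.260, 2),
        ("C3", "Boundary conditions of the province", 0.123, 4),
        ("C4", "Distance from the nearest equipped military health care center and organization", 0.200, 3),
        ("C5", "Population density in the urban and rural areas", 0.361, 1),
    ),
    "F2": (
        ("C6", "Need for full implementation of the Adaptation Plan", 0.160, 3),
        ("C7", "Being a host province", 0.119, 4),
        ("C8", "Sex and age distribution of the urban and rural population", 0.088, 5),
        ("C9", "Annual population growth rate", 0.088, 5),
        ("C10", "Rates of births and deaths", 0.054, 6),
        ("C11", "Rates of illiteracy and literacy", 0.035, 7),
        ("C12", "Cultural values, social and political characteristics", 0.201, 2),
        ("C13", "Population of the considered province or city/pato-geographic status", 0.255, 1),
    ),
    "F3": (
        ("C14", "High cost of civilian health care services", 0.075, 6),
        ("C15", "Economic evaluation of providing services", 0.319, 1),
        ("C16", "Sources of income", 0.176, 2),
        ("C17", "Per capita income per year", 0.102, 4),
        ("C18", "Employment rate", 0.045, 8),
        ("C19", "Rate of inflation", 0.060, 7),
        ("C20", "Interest rate for investment in the health insurance", 0.137, 3),
        ("C21", "Being an industrial province", 0.085, 5),
    ),
    "F4": (
        ("C22", "Common diseases in the military forces", 0.136, 3),
        ("C23", "Understanding the epidemiology of diseases and the number of patients in the society", 0.049, 7),
        ("C24", "Vulnerable groups", 0.099, 5),
        ("C25", "Vulnerability to common diseases in the region", 0.075, 6),
        ("C26", "Life expectancy", 0.134, 4),
        ("C27", "Health Promotion", 0.186, 2),
        ("C28", "Equity in health care", 0.322, 1),
    ),
    "F5": (
        ("C29", "Existence of empty capacities in the province", 0.050, 7),
        ("C30", "Training and research services", 0.131, 4),
        ("C32", "Lack of appropriate health care centers and organizations and the ease of service delivery to the armed forces", 0.325, 1),
        ("C33", "Bed occupancy rate", 0.165, 2),
        ("C34", "Admission rate per bed in each year", 0.102, 5),
        ("C35", "Average length of stay", 0.092, 6),
        ("C36", "Existence of physical spaces", 0.135, 3),
    ),
    "F6": (
        ("C37", "Status of the existing health technologies", 0.047, 6),
        ("C38", "Resources available to build the new hospital wards", 0.197, 3),
        ("C39", "Having the potential for developing the existing hospital beds", 0.242, 2),
        ("C40", "Existence of modern and updated equipment", 0.071, 5),
        ("C41", "Having extensive specialty and subspecialty facilities and equipment", 0.091, 4),
        ("C42", "Having access to medical and paramedical personnel", 0.353, 1),
    ),
    "F7": (
        ("C43", "Health policies at the national level", 0.115, 3),
        ("C44", "Empathy among the commanders of military units stationed in the province", 0.444, 1),
        ("C45", "Having appropriate intersectoral cooperation in the province", 0.069, 5),
        ("C46", "Cooperation among province authorities in setting up a specialty hospital", 0.048, 6),
        ("C47", "Hospital beds per capita approved by the General Staff of the Armed Forces", 0.085, 4),
        ("C48", "Hospital beds per capita approved by the Ministry of Health", 0.198, 2),
    ),
    "F8": (
        ("C49", "Maintaining dignity and increasing job satisfaction", 0.087, 4),
        ("C50", "Maintaining the dignity of military personnel", 0.081, 5),
        ("C51", "Necessity for paying attention to the military families' well-being", 0.057, 6),
        ("C52", "Necessity for direct treatment of the military forces, especially in the crises", 0.258, 2),
        ("C53", "Necessity for maintaining the security of the armed forces", 0.293, 1),
        ("C54", "Necessity for conducting special clinical studies on the military forces", 0.041, 7),
        ("C55", "Number of military forces in the province", 0.183, 3),
    ),
})

GOAL_LABEL = "Development of military hospital beds"


@dataclass(frozen=True)
class PrintedTables:
    """Immutable bundle of the published scale and priority tables."""

    scale: tuple[LinguisticScaleEntry, ...]
    factors: tuple[tuple[str, str, float, int], ...]
    subfactors: Mapping[str, tuple[tuple[str, str, float, int], ...]]

    @property
    def table2(self) -> pd.DataFrame:
        """Factor-level scores and priorities as a DataFrame."""
        return pd.DataFrame(
            self.factors, columns=["code", "label", "score", "priority"]
        )

    @property
    def table3(self) -> dict[str, pd.DataFrame]:
        """Per-factor subfactor blocks as DataFrames keyed by factor code."""
        return {
            f: pd.DataFrame(rows, columns=["code", "label", "score", "priority"])
            for f, rows in self.subfactors.items()
        }


def fixtures() -> PrintedTables:
    """Return the published scale and priority tables (fresh copies of frames)."""
    return PrintedTables(scale=SCALE, factors=FACTOR_ROWS, subfactors=SUBFACTOR_ROWS)
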