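"""The nine-level linguistic judgment scale.

Each rung of the ladder pairs a verbal definition ("Moderately more
important", ...) with a triangular fuzzy number used when the row item is
preferred to the column item, and the reciprocal triple used for the mirror
cell.  Odd intensities (1, 3, 5, 7, 9) are the pure grades; even intensities
(2, 4, 6, 8) are the intermediate "X to Y more important" grades, so all
nine rungs are reachable from an integer intensity.

The reciprocal triples stored here are the conventional 2-decimal printed
values.  They agree with the analytic reciprocal ``(1/u, 1/m, 1/l)`` after
half-up rounding for every rung except the upper component of intensity 9,
where the customary printed value is 0.13 although 1/7 rounds to 0.14; see
:data:`PRINTED_RECIPROCAL_ANOMALIES`.  Validation and synthetic-matrix
construction always use the analytic reciprocal, never the rounded one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import yaml

from .tfn import TriangularFuzzyNumber as TFN


@dataclass(frozen=True)
class LinguisticScaleEntry:
    """One rung of the nine-level scale."""

    intensity: int
    label: str
    forward: TFN
    reciprocal: TFN  # 2-decimal conventional values, as printed on forms


_RAW_SCALE: tuple[tuple[int, str, tuple, tuple], ...] = (
    (1, "Equally important", (1, 1, 1), (1, 1, 1)),
    (2, "Equally important to moderately more important", (1, 2, 3), (0.33, 0.5, 1)),
    (3, "Moderately more important", (1, 3, 5), (0.2, 0.33, 1)),
    (4, "Moderately more important to strongly more important", (3, 4, 5), (0.2, 0.25, 0.33)),
    (5, "Strongly more important", (3, 5, 7), (0.14, 0.2, 0.33)),
    (6, "Strongly to very Strongly more important", (5, 6, 7), (0.14, 0.17, 0.2)),
    (7, "Very Strongly more important", (5, 7, 9), (0.11, 0.14, 0.2)),
    (8, "Very Strongly to extremely more important", (7, 8, 9), (0.11, 0.13, 0.14)),
    (9, "Extremely more important", (7, 9, 9), (0.11, 0.11, 0.13)),
)

SCALE: tuple[LinguisticScaleEntry, ...] = tuple(
    LinguisticScaleEntry(i, label, TFN(*fwd), TFN(*rec))
    for i, label, fwd, rec in _RAW_SCALE
)

#: (intensity, component) pairs where the conventional printed reciprocal
#: differs from the analytically computed one even after 2-decimal rounding.
#: The single known case: intensity 9 has forward (7, 9, 9); 1/7 = 0.142857
#: rounds to 0.14, yet 0.13 is the customary printed upper component.
PRINTED_RECIPROCAL_ANOMALIES: tuple[tuple[int, str], ...] = ((9, "u"),)

_BY_INTENSITY = {e.intensity: e for e in SCALE}
_BY_LABEL = {e.label.lower(): e for e in SCALE}

MIN_INTENSITY = 1
MAX_INTENSITY = 9


def scale_lookup(key: Union[int, str]) -> LinguisticScaleEntry:
    """Return the scale entry for an intensity 1-9 or a verbal label.

    Label matching is case-insensitive but otherwise exact.  Unknown keys
    raise ``KeyError`` naming the valid choices.
    """
    if isinstance(key, str):
        entry = _BY_LABEL.get(key.strip().lower())
        if entry is None:
            valid = "; ".join(e.label for e in SCALE)
            raise KeyError(f"unknown scale label {key!r}; valid labels: {valid}")
        return entry
    if isinstance(key, (int,)) and not isinstance(key, bool):
        entry = _BY_INTENSITY.get(key)
        if entry is None:
            raise KeyError(f"unknown scale intensity {key!r}; valid intensities: 1-9")
        return entry
    raise TypeError(f"scale key must be an int or str, got {type(key).__name__}")


def scale_to_records(scale: Iterable[LinguisticScaleEntry] = SCALE) -> list[dict]:
    return [
        {
            "intensity": e.intensity,
            "label": e.label,
            "forward": list(e.forward),
            "reciprocal": list(e.reciprocal),
        }
        for e in scale
    ]


def save_scale(path: Union[str, Path], scale: Iterable[LinguisticScaleEntry] = SCALE) -> None:
    """Write a scale as YAML (``.yml``/``.yaml``) or JSON (anything else)."""
    path = Path(path)
    records = scale_to_records(scale)
    if path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        path.write_text(json.dumps(records, indent=2) + "\n")


def load_scale(path: Union[str, Path]) -> tuple[LinguisticScaleEntry, ...]:
    """Load a (possibly user-defined) scale saved by :func:`save_scale`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        records = yaml.safe_load(text)
    else:
        records = json.loads(text)
    return tuple(
        LinguisticScaleEntry(
            int(r["intensity"]), str(r["label"]), TFN(*r["forward"]), TFN(*r["reciprocal"])
        )
        for r in records
    )
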