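"""Two-level criterion hierarchy, weight composition, and dense ranking.

The decision model is a goal node whose children are factors, whose children
in turn are leaf subfactors.  Each node may carry a *local* weight (its
share among siblings); multiplying local weights down a branch yields the
*global* weight of a leaf.

Ranking follows the dense convention used in published priority tables:
the highest score gets priority 1, tied scores share a priority, and the
next distinct score gets the previous priority plus one (so ties never
create gaps — a tie at rank 5 is followed by rank 6, not 7).  Ties are
reported as shared ranks, never broken arbitrarily.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from . import tables


@dataclass
class CriterionNode:
    """A node of the criterion tree (goal, factor, or leaf subfactor)."""

    code: str
    label: str
    children: list["CriterionNode"] = field(default_factory=list)
    local_weight: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def child(self, code: str) -> "CriterionNode":
        for c in self.children:
            if c.code == code:
                return c
        raise KeyError(f"node {self.code!r} has no child {code!r}")

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def set_local_weights(self, weights: dict[str, float]) -> None:
        """Assign local weights to this node's children by code."""
        for c in self.children:
            if c.code not in weights:
                raise KeyError(f"no weight provided for child {c.code!r} of {self.code!r}")
            c.local_weight = float(weights[c.code])


@dataclass(frozen=True)
class RankingTable:
    """Scores with dense descending priorities (1 = best; ties share a rank)."""

    items: tuple[str, ...]
    scores: tuple[float, ...]
    priorities: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": self.items, "score": self.scores, "priority": self.priorities}
        )


def rank_dense(
    scores: Sequence[float], items: Optional[Sequence[str]] = None
) -> RankingTable:
    """Dense descending ranking: highest score -> 1, equal scores -> equal rank.

    Tie detection uses exact equality on the stored values, matching tables
    where rows tie at identical printed scores.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("rank_dense requires a non-empty score list")
    if items is None:
        items = [str(i + 1) for i in range(len(scores))]
    elif len(items) != len(scores):
        raise ValueError("items and scores must have equal length")
    priorities = rankdata([-s for s in scores], method="dense").astype(int)
    return RankingTable(tuple(items), tuple(float(s) for s in scores), tuple(priorities))


# -- hierarchy assembly ------------------------------------------------------


def assemble_hierarchy(config: dict) -> CriterionNode:
    """Build and validate a goal/factor/subfactor tree from a plain mapping.

    ``config`` has the form::

        {"goal": {"code": ..., "label": ...},
         "factors": [{"code": ..., "label": ...,
                      "subfactors": [{"code": ..., "label": ...}, ...]}, ...]}

    Codes must be unique across the whole tree; every subfactor must sit
    under exactly one factor (no orphans by construction).
    """
    goal_cfg = config.get("goal") or {}
    root = CriterionNode(
        code=str(goal_cfg.get("code", "goal")), label=str(goal_cfg.get("label", "Goal"))
    )
    seen: set[str] = {root.code}
    for fac in config.get("factors", []):
        fnode = CriterionNode(code=str(fac["code"]), label=str(fac["label"]))
        if fnode.code in seen:
            raise ValueError(f"duplicate criterion code {fnode.code!r}")
        seen.add(fnode.code)
        for sub in fac.get("subfactors", []):
            snode = CriterionNode(code=str(sub["code"]), label=str(sub["label"]))
            if snode.code in seen:
                raise ValueError(f"duplicate criterion code {snode.code!r}")
            seen.add(snode.code)
            fnode.children.append(snode)
        root.children.append(fnode)
    if not root.children:
        raise ValueError("hierarchy must define at least one factor")
    return root


def default_hierarchy() -> CriterionNode:
    """The shipped hierarchy: 8 factors, 54 subfactors (C31 absent as published)."""
    return assemble_hierarchy(
        {
            "goal": {"code": "goal", "label": tables.GOAL_LABEL},
            "factors": [
                {
                    "code": code,
                    "label": label,
                    "subfactors": [
                        {"code": c, "label": lab}
                        for c, lab, _s, _p in tables.SUBFACTOR_ROWS[code]
                    ],
                }
                for code, label, _s, _p in tables.FACTOR_ROWS
            ],
        }
    )


def hierarchy_to_config(root: CriterionNode) -> dict:
    return {
        "goal": {"code": root.code, "label": root.label},
        "factors": [
            {
                "code": f.code,
                "label": f.label,
                "subfactors": [{"code": s.code, "label": s.label} for s in f.children],
            }
            for f in root.children
        ],
    }


def save_hierarchy(root: CriterionNode, path: Union[str, Path]) -> None:
    path = Path(path)
    cfg = hierarchy_to_config(root)
    if path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2) + "\n")


def load_hierarchy(path: Union[str, Path]) -> CriterionNode:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    return assemble_hierarchy(cfg)


# -- weight composition ------------------------------------------------------


def check_sibling_weights(root: CriterionNode, tol: float = 1e-6) -> None:
    """Verify that, wherever set, sibling local weights sum to 1 within tol."""
    for node in root.walk():
        if not node.children:
            continue
        ws = [c.local_weight for c in node.children]
        if all(w is None for w in ws):
            continue
        if any(w is None for w in ws):
            unset = [c.code for c in node.children if c.local_weight is None]
            raise ValueError(f"node {node.code!r}: unset local weights for {unset}")
        total = float(np.sum(ws))
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"node {node.code!r}: sibling local weights sum to {total}, not 1"
            )


def global_weights(root: CriterionNode, tol: float = 1e-6) -> pd.DataFrame:
    """Compose local weights down the tree into per-leaf global weights.

    Requires every level on the path to each leaf to carry a local weight
    (the goal's own local weight defaults to 1).  Returns a frame with
    columns code, label, global_weight; the column sums to 1 whenever each
    sibling block does.
    """
    check_sibling_weights(root, tol=tol)
    rows: list[dict] = []

    def descend(node: CriterionNode, acc: float) -> None:
        if node.is_leaf:
            rows.append({"code": node.code, "label": node.label, "global_weight": acc})
            return
        for c in node.children:
            if c.local_weight is None:
                raise ValueError(f"local weight unset for node {c.code!r}")
            descend(c, acc * c.local_weight)

    descend(root, 1.0 if root.local_weight is None else root.local_weight)
    return pd.DataFrame(rows)
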