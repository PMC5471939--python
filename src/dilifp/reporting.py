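"""Structural-alert tables and multi-model consensus summaries.

An alert table lists the fingerprint bits whose log2 odds ratio clears
the selection threshold — the substructures over-represented in
hepatotoxic compounds — annotated with the section of the 881-bit
PubChem-type fingerprint each bit belongs to (element counts, ring
systems, atom pairs, nearest-neighbor patterns, SMARTS patterns).

The per-bit section ranges below follow the public PubChem fingerprint
layout.  Per-bit substructure text can be supplied through the
``annotation`` mapping; bits without an entry get a category-level
placeholder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weighting import SubstructureStats

#: Half-open bit ranges of the PubChem fingerprint sections.
CATEGORY_RANGES: tuple[tuple[int, int, str], ...] = (
    (0, 115, "element count"),
    (115, 263, "ring system"),
    (263, 327, "atom pair"),
    (327, 460, "nearest neighbor"),
    (460, 881, "SMARTS pattern"),
)


def bit_category(bit_index: int) -> str:
    """Fingerprint section a bit belongs to."""
    for lo, hi, name in CATEGORY_RANGES:
        if lo <= bit_index < hi:
            return name
    raise ValueError(f"bit index {bit_index} outside [0, 881)")


def default_annotation(n_bits: int = 881) -> dict[int, str]:
    """Category-level descriptions for every bit (placeholder text)."""
    return {j: f"{bit_category(j)} bit PubchemFP{j}" for j in range(n_bits)}


@dataclass
class AlertRow:
    bit_index: int
    log_odds: float
    c_sp: int
    c_sn: int
    description: str
    category: str


@dataclass
class AlertTable:
    theta: float
    rows: list[AlertRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bit_index": r.bit_index,
                    "L": r.log_odds,
                    "c_SP": r.c_sp,
                    "c_SN": r.c_sn,
                    "category": r.category,
                    "description": r.description,
                }
                for r in self.rows
            ],
            columns=["bit_index", "L", "c_SP", "c_SN", "category", "description"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_text(self, path: str | Path) -> None:
        lines = [f"Substructure alerts (log2 odds ratio >= {self.theta})", ""]
        for r in self.rows:
            lines.append(
                f"  bit {r.bit_index:4d}  L={r.log_odds:6.3f}  "
                f"pos {r.c_sp:4d}  neg {r.c_sn:4d}  [{r.category}] {r.description}"
            )
        if not self.rows:
            lines.append("  (no bit reached the threshold)")
        Path(path).write_text("\n".join(lines) + "\n")


def alert_table(
    stats: SubstructureStats,
    theta: float,
    annotation: Mapping[int, str] | None = None,
) -> AlertTable:
    """Rank the bits with ``L >= theta`` by descending log odds ratio.

    Ties are broken by ascending bit index.  Missing annotations fall
    back to a category placeholder.
    """
    if annotation is None:
        annotation = default_annotation(stats.n_bits)
    L = stats.log_odds
    selected = np.flatnonzero(L >= theta)
    order = sorted(selected, key=lambda j: (-L[j], j))
    rows = [
        AlertRow(
            bit_index=int(j),
            log_odds=float(L[j]),
            c_sp=int(stats.counts.c_sp[j]),
            c_sn=int(stats.counts.c_sn[j]),
            description=annotation.get(int(j), f"unannotated bit PubchemFP{j}"),
            category=bit_category(int(j)) if j < 881 else "SMARTS pattern",
        )
        for j in order
    ]
    return AlertTable(theta=float(theta), rows=rows)


# ---------------------------------------------------------------------------
# Consensus over multiple models
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSummary:
    """Positive-call overlap between models run on the same compound list."""

    n_total: int
    n_pos_by_model: dict[str, int]
    n_pos_intersection: int
    n_pos_union: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def consensus(predictions: Mapping[str, Sequence[str]]) -> ConsensusSummary:
    """Summarize agreement of per-model label lists (same compound order).

    The intersection counts compounds called positive by every model, the
    union those called positive by at least one.
    """
    if not predictions:
        raise ValueError("need at least one model's predictions")
    lengths = {name: len(labels) for name, labels in predictions.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"prediction lists differ in length: {lengths}")
    n = next(iter(lengths.values()))
    masks = {
        name: np.asarray([lab == "positive" for lab in labels])
        for name, labels in predictions.items()
    }
    stack = np.vstack(list(masks.values())) if n else np.zeros((len(masks), 0), bool)
    return ConsensusSummary(
        n_total=n,
        n_pos_by_model={name: int(m.sum()) for name, m in masks.items()},
        n_pos_intersection=int(stack.all(axis=0).sum()) if n else 0,
        n_pos_union=int(stack.any(axis=0).sum()) if n else 0,
    )
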