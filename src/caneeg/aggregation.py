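"""Cross-subject summaries of the significance matrix.

Counts and percentages of significant classifications over time (the
per-interval fraction across subjects and tasks) and over divisions of the
scrambled-vs-other task family: by species, by expression, and by the
combined species x expression categories, each with object-vs-scrambled as
the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import CategoryLabel
from .permutation import SignificanceMatrix


@dataclass(frozen=True)
class DivisionSpec:
    """Named grouping of tasks, with a reference group.

    ``groups`` maps a group name to a tuple of task names (each task in at
    most one group); ``reference`` names the group serving as the baseline
    comparison (object vs. scrambled in the standard divisions).
    """

    name: str
    groups: dict
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.groups:
            raise ValueError(f"reference group {self.reference!r} is not defined")
        seen = {}
        for gname, tasks in self.groups.items():
            for t in tasks:
                if t in seen:
                    raise ValueError(
                        f"task {t!r} mapped to both {seen[t]!r} and {gname!r}"
                    )
                seen[t] = gname


def _vs_s(code: str) -> str:
    return f"{code}_vs_S"


def standard_divisions() -> dict:
    """The three task divisions of the scrambled-vs-other family."""
    faces = [c for c in CategoryLabel if c.is_face]
    ref = {"object": (_vs_s("OB"),)}
    by_species = {
        sp: tuple(_vs_s(c.value) for c in faces if c.species == sp)
        for sp in ("dog", "human")
    }
    by_expr = {
        ex: tuple(_vs_s(c.value) for c in faces if c.expression == ex)
        for ex in ("happy", "neutral", "aggressive")
    }
    combined = {c.value: (_vs_s(c.value),) for c in faces}
    return {
        "species": DivisionSpec("species", {**by_species, **ref}, "object"),
        "expressions": DivisionSpec("expressions", {**by_expr, **ref}, "object"),
        "combined": DivisionSpec("combined", {**combined, **ref}, "object"),
    }


def _task_indices(matrix: SignificanceMatrix, tasks) -> np.ndarray:
    idx = []
    for t in tasks:
        if t not in matrix.task_names:
            raise ValueError(f"task {t!r} not present in the significance matrix")
        idx.append(matrix.task_names.index(t))
    return np.asarray(idx, dtype=int)


def significant_fraction_timecourse(
    matrix: SignificanceMatrix, tasks=None
) -> pd.DataFrame:
    """Percentage of significant cells per interval across subjects x tasks.

    With the full scrambled-vs-other family this is the fraction out of 56
    cells (8 subjects x 7 tasks) at each 20-ms interval.
    """
    if tasks is None:
        tasks = matrix.task_names
    idx = _task_indices(matrix, tasks)
    sub = matrix.significant[:, idx, :]  # (n_sub, n_tasks, n_int)
    denom = sub.shape[0] * sub.shape[1]
    pct = 100.0 * sub.sum(axis=(0, 1)) / denom
    return pd.DataFrame(
        {
            "interval_start_ms": matrix.interval_starts_ms,
            "n_significant": sub.sum(axis=(0, 1)),
            "n_total": denom,
            "percent_significant": pct,
        }
    )


def division_fractions(
    matrix: SignificanceMatrix, division: DivisionSpec
) -> pd.DataFrame:
    """Per-group percentage of significant cells over subjects, tasks and
    intervals; the reference group is computed identically."""
    rows = []
    for gname, tasks in division.groups.items():
        if not tasks:
            raise ValueError(f"group {gname!r} of division {division.name!r} is empty")
        idx = _task_indices(matrix, tasks)
        cells = matrix.significant[:, idx, :]
        total = cells.size
        rows.append(
            {
                "division": division.name,
                "group": gname,
                "is_reference": gname == division.reference,
                "n_significant": int(cells.sum()),
                "n_total": int(total),
                "percent_significant": 100.0 * cells.sum() / total,
            }
        )
    return pd.DataFrame(rows)
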