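"""WAIC model competition: fit every admissible structure, rank, report.

Fits are independent (results do not depend on submission or execution
order); failed fits are recorded with their reason and excluded from the
ranking.  Ties in WAIC break to the lexicographically smaller structure id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import FitResult, FitSettings, Priors, fit
from .structures import ModelStructure

__all__ = ["Leaderboard", "run_competition", "select_best"]


@dataclass
class Leaderboard:
    table: pd.DataFrame                    # sorted ascending by WAIC
    fits: dict = field(default_factory=dict)      # structure_id -> FitResult
    failures: dict = field(default_factory=dict)  # structure_id -> reason

    def best_per_family(self) -> pd.DataFrame:
        return self.table.groupby("family", as_index=False).first()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_competition(
    structures: list[ModelStructure],
    paired_table: pd.DataFrame,
    mesh=None,
    priors: Priors | None = None,
    settings: FitSettings | None = None,
    keep_fits: bool = True,
) -> Leaderboard:
    """Fit all structures on the same data/mesh and rank them by WAIC."""
    if not structures:
        raise ValueError("need at least one structure")
    rows = []
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for s in sorted(structures, key=lambda s: s.structure_id):
        try:
            fr = fit(s, paired_table, mesh=mesh, priors=priors, settings=settings)
        except Exception as exc:  # noqa: BLE001 — failed fits are data, not bugs
            failures[s.structure_id] = f"{type(exc).__name__}: {exc}"
            continue
        rows.append({
            "structure_id": s.structure_id,
            "family": s.family,
            "waic": fr.waic,
            "p_waic": fr.p_waic,
        })
        if keep_fits:
            fits[s.structure_id] = fr
    if not rows:
        raise RuntimeError(f"all fits failed: {failures}")
    table = pd.DataFrame(rows).sort_values(
        ["waic", "structure_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta_waic"] = table["waic"] - table["waic"].iloc[0]
    return Leaderboard(table=table, fits=fits, failures=failures)


def select_best(leaderboard: Leaderboard) -> str:
    """Structure id with the lowest WAIC (lexicographic tie-break)."""
    if len(leaderboard.table) == 0:
        raise ValueError("empty leaderboard")
    return str(leaderboard.table["structure_id"].iloc[0])
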