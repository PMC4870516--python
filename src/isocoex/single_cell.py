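"""Single-cell isoform co-expression analysis.

Cells assayed for a housekeeping marker (Gapdh), a neuronal marker (NeuN)
and an astroglial marker (Gfap) are classified into neurons (NeuN+/Gfap-),
astrocytes (NeuN-/Gfap+), other (ambiguous) or excluded (no housekeeping
signal).  Per-cell psi for a two-isoform choice is computed from the two
isoform counts, groups are summarised by their median psi, and compared
with Welch's unequal-variance t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = ["CellProfile", "classify_cell", "summarize_composition",
           "per_cell_psi", "compare_psi_groups",
           "SingleCellCoexpressionModel", "SingleCellResults"]

PROFILE_COLUMNS = ["cell_id", "gapdh", "neun", "gfap", "e6", "e7"]


@dataclass(frozen=True)
class CellProfile:
    cell_id: str
    gapdh: int
    neun: int
    gfap: int
    e6: int   # UA3E isoform count
    e7: int   # AIDE isoform count

    def __post_init__(self):
        for f in ("gapdh", "neun", "gfap", "e6", "e7"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} count must be non-negative")


def classify_cell(profile: CellProfile, threshold: int = 1) -> str:
    """Marker-based cell class: neuron, astrocyte, other or excluded.

    Cells without housekeeping signal are excluded; double-positive and
    double-negative cells are 'other'.
    """
    if profile.gapdh < threshold:
        return "excluded"
    neun = profile.neun >= threshold
    gfap = profile.gfap >= threshold
    if neun and not gfap:
        return "neuron"
    if gfap and not neun:
        return "astrocyte"
    return "other"


def summarize_composition(classes) -> dict:
    """Percentage of each class among non-excluded cells.

    Returns {class: (percent rounded to 2 decimals, raw fraction)}.
    """
    counts = pd.Series(list(classes)).value_counts()
    kept = counts.drop("excluded", errors="ignore")
    total = int(kept.sum())
    if total == 0:
        raise ValueError("no classifiable (non-excluded) cells")
    return {cls: (round(100.0 * n / total, 2), n / total)
            for cls, n in kept.items()}


def per_cell_psi(profile: CellProfile) -> float:
    """Percent of the UA3E isoform among the two isoform counts."""
    total = profile.e6 + profile.e7
    if total == 0:
        return float("nan")
    return 100.0 * profile.e6 / total


def compare_psi_groups(group_a, group_b):
    """Welch's two-sided t test; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 2:
            raise ValueError(f"group {name} needs at least 2 values")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance")
    res = _sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


class SingleCellCoexpressionModel:
    """Marker classification and per-cell isoform quantification.

    Accepts a DataFrame with columns cell_id, gapdh, neun, gfap, e6, e7
    (or a list of :class:`CellProfile`).
    """

    def __init__(self, profiles):
        if isinstance(profiles, pd.DataFrame):
            missing = set(PROFILE_COLUMNS) - set(profiles.columns)
            if missing:
                raise ValueError(f"profile table missing columns {sorted(missing)}")
            self.profiles = [CellProfile(str(r.cell_id), int(r.gapdh), int(r.neun),
                                         int(r.gfap), int(r.e6), int(r.e7))
                             for r in profiles.itertuples(index=False)]
        else:
            self.profiles = list(profiles)
        if not self.profiles:
            raise ValueError("no cell profiles given")

    def fit(self, threshold: int = 1) -> "SingleCellResults":
        rows = []
        for p in self.profiles:
            rows.append((p.cell_id, classify_cell(p, threshold), per_cell_psi(p),
                         p.e6 + p.e7))
        cells = pd.DataFrame(rows, columns=["cell_id", "cell_class", "psi", "total"])
        composition = summarize_composition(cells["cell_class"])
        return SingleCellResults(cells=cells, composition=composition,
                                 threshold=threshold)


@dataclass
class SingleCellResults:
    cells: pd.DataFrame
    composition: dict
    threshold: int

    def psi_values(self, cell_class: str) -> np.ndarray:
        m = (self.cells["cell_class"] == cell_class) & self.cells["psi"].notna()
        return self.cells.loc[m, "psi"].to_numpy()

    def group_summary(self) -> pd.DataFrame:
        rows = []
        for cls in ("neuron", "astrocyte", "other"):
            v = self.psi_values(cls)
            rows.append((cls, len(v),
                         float(np.median(v)) if len(v) else np.nan))
        return pd.DataFrame(rows, columns=["cell_class", "n", "psi_median"])

    def compare(self, class_a: str = "neuron", class_b: str = "astrocyte"):
        """Welch comparison of per-cell psi between two classes."""
        t, df, p = compare_psi_groups(self.psi_values(class_a),
                                      self.psi_values(class_b))
        return {"class_a": class_a, "class_b": class_b, "t": t, "df": df, "p": p}

    def summary(self) -> str:
        gs = self.group_summary().set_index("cell_class")
        lines = ["Single-cell isoform co-expression",
                 "=" * 44,
                 f"cells                  {len(self.cells)}",
                 f"marker threshold       {self.threshold}"]
        for cls, (pct, _) in sorted(self.composition.items()):
            lines.append(f"{cls:22s} {pct:6.2f} %")
        for cls in ("neuron", "astrocyte"):
            if cls in gs.index and gs.loc[cls, "n"] > 0:
                lines.append(f"median psi {cls:11s} {gs.loc[cls, 'psi_median']:6.1f} %"
                             f"  (n={int(gs.loc[cls, 'n'])})")
        return "\n".join(lines)
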