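"""Percent-spliced-in quantification and differential-usage calling.

psi for an event in a sample is estimated from the two junction reads that
discriminate the isoforms -- shared donor to the UA3E acceptor (inclusion)
and shared donor to the AIDE acceptor (exclusion):

    psi = 100 * inclusion / (inclusion + exclusion)

Regulation calls pool replicate counts within a stage or condition and
compare groups with Fisher's exact test on the 2x2 junction-count table,
gated on an absolute psi change, with Benjamini-Hochberg adjustment across
events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .coexpression import bh_adjust

__all__ = [
    "PsiEstimate",
    "JunctionCountTable",
    "OverlapEnrichment",
    "compute_psi",
    "compute_psi_frame",
    "psi_matrix",
    "flag_detectable",
    "fisher_exact_2x2",
    "overlap_enrichment",
    "estimate_overdispersion",
    "TimecourseRegulationModel",
    "KnockdownRegulationModel",
    "RegulationResults",
]


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    sample_id: str
    psi: float  # percent, NaN when undefined
    total: int
    detectable: bool


@dataclass(frozen=True)
class OverlapEnrichment:
    a_and_b: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p: float


def compute_psi(inclusion: int, exclusion: int) -> float:
    """psi in percent; NaN when there is no junction coverage at all."""
    if inclusion < 0 or exclusion < 0:
        raise ValueError("junction counts must be non-negative")
    total = inclusion + exclusion
    if total == 0:
        return float("nan")
    return 100.0 * inclusion / total


class JunctionCountTable:
    """Junction counts per (event, sample) plus the sample sheet.

    counts columns: event_id, sample_id, inclusion, exclusion.
    samples columns: sample_id, stage (and/or condition), replicate.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        for col in ("event_id", "sample_id", "inclusion", "exclusion"):
            if col not in counts.columns:
                raise ValueError(f"counts table missing column {col!r}")
        if "sample_id" not in samples.columns:
            raise ValueError("sample sheet missing column 'sample_id'")
        if not ({"stage", "condition"} & set(samples.columns)):
            raise ValueError("sample sheet needs a 'stage' or 'condition' column")
        c = counts.copy()
        if (c["inclusion"] < 0).any() or (c["exclusion"] < 0).any():
            raise ValueError("junction counts must be non-negative")
        self.counts = c
        self.samples = samples.copy()
        missing = set(c["sample_id"]) - set(samples["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "JunctionCountTable":
        return cls(pd.read_csv(counts_path, sep="\t"),
                   pd.read_csv(samples_path, sep="\t"))

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)

    def stage_order(self) -> list:
        stages = self.samples["stage"]
        if isinstance(stages.dtype, pd.CategoricalDtype) and stages.cat.ordered:
            return list(stages.cat.categories)
        return list(pd.unique(stages))

    def merged(self) -> pd.DataFrame:
        return self.counts.merge(self.samples, on="sample_id", how="left")


def compute_psi_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Long-format psi table from a junction count frame."""
    out = counts[["event_id", "sample_id"]].copy()
    total = counts["inclusion"] + counts["exclusion"]
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = 100.0 * counts["inclusion"] / total
    out["psi"] = psi.where(total > 0, np.nan)
    out["total"] = total
    return out


def psi_matrix(table: JunctionCountTable) -> pd.DataFrame:
    """Events x samples matrix of psi values (percent)."""
    frame = compute_psi_frame(table.counts)
    return frame.pivot(index="event_id", columns="sample_id", values="psi")


def flag_detectable(table: JunctionCountTable, min_total_per_sample: int = 20,
                    min_stages: int = 1, rule: str = "all_replicates") -> pd.Series:
    """Detectability flag per event.

    An event is detectable when at least ``min_stages`` stages support it:
    a stage supports the event if every replicate (rule='all_replicates')
    or the replicate mean (rule='mean') of the junction total reaches
    ``min_total_per_sample``.
    """
    if rule not in ("all_replicates", "mean"):
        raise ValueError(f"unknown rule {rule!r}")
    df = table.merged()
    if df["stage"].isna().any():
        bad = df.loc[df["stage"].isna(), "sample_id"].unique()
        raise ValueError(f"samples with unknown stage: {list(bad)[:5]}")
    df["total"] = df["inclusion"] + df["exclusion"]
    grp = df.groupby(["event_id", "stage"], observed=True)["total"]
    per_stage = grp.min() if rule == "all_replicates" else grp.mean()
    ok = (per_stage >= min_total_per_sample).groupby("event_id").sum()
    flags = (ok >= min_stages)
    flags.name = "detectable"
    return flags.reindex(pd.unique(table.counts["event_id"]), fill_value=False)


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided"):
    """Fisher's exact test for [[a, b], [c, d]].

    Two-sided p sums hypergeometric table probabilities not exceeding the
    observed table's.  The reported odds ratio is the sample odds ratio
    a*d / (b*c), with inf when b*c == 0 and a*d > 0, and NaN for 0/0.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    p = float(_sps.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    if b * c > 0:
        orr = (a * d) / (b * c)
    elif a * d > 0:
        orr = math.inf
    else:
        orr = math.nan
    return orr, p


def overlap_enrichment(set_a, set_b, universe) -> OverlapEnrichment:
    """Fisher's exact test for the overlap of two event sets in a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must not be empty")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    ab = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - ab - a_only - b_only
    orr, p = fisher_exact_2x2(ab, a_only, b_only, neither)
    return OverlapEnrichment(a_and_b=ab, a_only=a_only, b_only=b_only,
                             neither=neither, odds_ratio=orr, p=p)


# ---------------------------------------------------------------------------
# Regulation models
# ---------------------------------------------------------------------------

def _pooled(df: pd.DataFrame, by: str) -> pd.DataFrame:
    out = df.groupby(["event_id", by], observed=True)[["inclusion", "exclusion"]].sum()
    return out.reset_index()


def estimate_overdispersion(table: JunctionCountTable, by: str = "stage") -> float:
    """Method-of-moments estimate of the beta-binomial rho across replicates.

    Within each (event, group) cell the replicate inclusion counts are
    compared to the binomial expectation at the pooled proportion; the
    aggregate chi-square inflation is converted to an intraclass
    correlation via the design-effect relation E[X2/df] = 1 + (n-1) rho.
    Returns 0.0 when replication or variation is insufficient.
    """
    df = table.merged()
    df["total"] = df["inclusion"] + df["exclusion"]
    chi2 = 0.0
    dof = 0
    tot_n, n_cells = 0.0, 0
    for (_, _), g in df.groupby(["event_id", by], observed=True):
        g = g[g["total"] > 0]
        if len(g) < 2:
            continue
        p = g["inclusion"].sum() / g["total"].sum()
        if p <= 0 or p >= 1:
            continue
        expect = g["total"] * p
        chi2 += float((((g["inclusion"] - expect) ** 2)
                       / (g["total"] * p * (1 - p))).sum())
        dof += len(g) - 1
        tot_n += float(g["total"].mean())
        n_cells += 1
    if dof == 0 or n_cells == 0:
        return 0.0
    mean_n = tot_n / n_cells
    if mean_n <= 1:
        return 0.0
    return float(max(0.0, (chi2 / dof - 1.0) / (mean_n - 1.0)))


def _design_effect(rho: float, mean_count: float) -> float:
    return max(1.0, 1.0 + (mean_count - 1.0) * rho)


def _pair_test(i1, e1, i2, e2, design_effect: float = 1.0):
    """Exact-test p and pooled delta-psi between two count groups.

    Counts are scaled down by the replicate design effect
    1 + (n - 1) rho before the exact test, so that the effective sample
    size matches the information content of overdispersed replicates;
    delta psi is computed on the raw pooled proportions.
    """
    t1, t2 = i1 + e1, i2 + e2
    if t1 < 1 or t2 < 1:
        return np.nan, np.nan
    dpsi = 100.0 * (i2 / t2 - i1 / t1)
    cells = [int(round(v / design_effect)) for v in (i1, e1, i2, e2)]
    if cells[0] + cells[1] < 1 or cells[2] + cells[3] < 1:
        return np.nan, np.nan
    _, p = fisher_exact_2x2(*cells)
    return p, dpsi


class TimecourseRegulationModel:
    """Developmental splicing-regulation calls over an ordered stage series.

    Replicate counts are pooled within each stage; every consecutive stage
    pair is tested with Fisher's exact test on the pooled 2x2 junction
    table.  The per-event p value is the smallest pair p, Bonferroni-scaled
    by the number of testable pairs, then BH-adjusted across events.  An
    event is called regulated when the adjusted p passes ``alpha`` and the
    largest pooled |delta psi| between consecutive stages reaches
    ``min_delta_psi`` (percentage points).

    Biological replicates of splicing ratios are overdispersed relative to
    the binomial; pooled counts are therefore scaled by the replicate
    design effect 1 + (n - 1) rho before testing.  ``dispersion`` may be
    'estimate' (method-of-moments rho from the table, the default), a
    fixed rho, or 0 to disable the correction.
    """

    def __init__(self, table: JunctionCountTable):
        self.table = table
        self.stages = table.stage_order()
        if len(self.stages) < 2:
            raise ValueError("need at least two stages to test regulation")

    def fit(self, alpha: float = 0.05, min_delta_psi: float = 10.0,
            dispersion="estimate") -> "RegulationResults":
        merged = self.table.merged()
        rho = (estimate_overdispersion(self.table, by="stage")
               if dispersion == "estimate" else float(dispersion))
        mean_count = float((merged["inclusion"] + merged["exclusion"]).mean())
        deff = _design_effect(rho, mean_count)
        pooled = _pooled(merged, "stage")
        rows = []
        skipped = []
        for event_id, g in pooled.groupby("event_id", sort=True):
            counts = {s: (0, 0) for s in self.stages}
            for r in g.itertuples(index=False):
                counts[r.stage] = (int(r.inclusion), int(r.exclusion))
            ps, dpsis = [], []
            for s1, s2 in zip(self.stages[:-1], self.stages[1:]):
                i1, e1 = counts[s1]
                i2, e2 = counts[s2]
                p, dpsi = _pair_test(i1, e1, i2, e2, design_effect=deff)
                if np.isnan(p):
                    skipped.append((event_id, s1, s2))
                    continue
                ps.append(p)
                dpsis.append(dpsi)
            if not ps:
                rows.append((event_id, np.nan, np.nan, np.nan))
                continue
            p_event = min(1.0, min(ps) * len(ps))
            k = int(np.argmax(np.abs(dpsis)))
            rows.append((event_id, p_event, dpsis[k], float(np.max(np.abs(dpsis)))))
        calls = pd.DataFrame(rows, columns=["event_id", "p", "delta_psi",
                                            "max_abs_delta_psi"])
        tested = calls["p"].notna()
        calls["p_adj"] = np.nan
        calls.loc[tested, "p_adj"] = bh_adjust(calls.loc[tested, "p"].to_numpy())
        calls["regulated"] = (tested
                              & (calls["p_adj"] < alpha)
                              & (calls["max_abs_delta_psi"] >= min_delta_psi))
        return RegulationResults(calls=calls, alpha=alpha,
                                 min_delta_psi=min_delta_psi,
                                 mode="timecourse", skipped_pairs=skipped,
                                 call_column="regulated", rho=rho,
                                 design_effect=deff)


class KnockdownRegulationModel:
    """Knockdown-dependence calls from control / single / double knockdowns.

    Both contrasts (kd1 vs control, kd12 vs control) are tested on pooled
    counts with the same exact-test and |delta psi| gates; an event is
    dependent only when both pass and the psi shift has the same sign in
    both ("consistently regulated").
    """

    def __init__(self, table: JunctionCountTable,
                 conditions=("control", "kd1", "kd12")):
        if "condition" not in table.samples.columns:
            raise ValueError("sample sheet needs a 'condition' column")
        present = set(table.samples["condition"])
        missing = set(conditions) - present
        if missing:
            raise ValueError(f"missing conditions: {sorted(missing)}")
        self.table = table
        self.conditions = tuple(conditions)

    def fit(self, alpha: float = 0.05, min_delta_psi: float = 10.0,
            dispersion="estimate") -> "RegulationResults":
        ctrl, kd1, kd12 = self.conditions
        merged = self.table.merged()
        rho = (estimate_overdispersion(self.table, by="condition")
               if dispersion == "estimate" else float(dispersion))
        mean_count = float((merged["inclusion"] + merged["exclusion"]).mean())
        deff = _design_effect(rho, mean_count)
        pooled = _pooled(merged, "condition")
        rows = []
        for event_id, g in pooled.groupby("event_id", sort=True):
            counts = {r.condition: (int(r.inclusion), int(r.exclusion))
                      for r in g.itertuples(index=False)}
            i0, e0 = counts.get(ctrl, (0, 0))
            stats = {}
            for kd in (kd1, kd12):
                ik, ek = counts.get(kd, (0, 0))
                stats[kd] = _pair_test(i0, e0, ik, ek, design_effect=deff)
            p1, d1 = stats[kd1]
            p2, d2 = stats[kd12]
            ps = [p for p in (p1, p2) if not np.isnan(p)]
            p_event = min(1.0, min(ps) * len(ps)) if ps else np.nan
            dependent = (not np.isnan(p1) and not np.isnan(p2)
                         and abs(d1) >= min_delta_psi and abs(d2) >= min_delta_psi
                         and np.sign(d1) == np.sign(d2) and np.sign(d1) != 0)
            rows.append((event_id, p1, d1, p2, d2, p_event, dependent))
        calls = pd.DataFrame(rows, columns=["event_id", "p_kd1", "delta_psi_kd1",
                                            "p_kd12", "delta_psi_kd12", "p",
                                            "sign_consistent"])
        tested = calls[["p_kd1", "p_kd12"]].notna().all(axis=1)
        for col in ("p_kd1", "p_kd12"):
            adj = np.full(len(calls), np.nan)
            m = calls[col].notna()
            adj[m.to_numpy()] = bh_adjust(calls.loc[m, col].to_numpy())
            calls[col + "_adj"] = adj
        calls["dependent"] = (tested & calls["sign_consistent"]
                              & (calls["p_kd1_adj"] < alpha)
                              & (calls["p_kd12_adj"] < alpha))
        calls["p_adj"] = calls[["p_kd1_adj", "p_kd12_adj"]].max(axis=1)
        return RegulationResults(calls=calls, alpha=alpha,
                                 min_delta_psi=min_delta_psi,
                                 mode="knockdown", skipped_pairs=[],
                                 call_column="dependent", rho=rho,
                                 design_effect=deff)


@dataclass
class RegulationResults:
    calls: pd.DataFrame
    alpha: float
    min_delta_psi: float
    mode: str
    skipped_pairs: list
    call_column: str
    rho: float = 0.0
    design_effect: float = 1.0

    @property
    def called_events(self) -> list:
        m = self.calls[self.call_column].fillna(False).astype(bool)
        return self.calls.loc[m, "event_id"].tolist()

    @property
    def n_called(self) -> int:
        return len(self.called_events)

    def summary(self) -> str:
        n = len(self.calls)
        lines = [
            f"Splicing regulation calls ({self.mode})",
            "=" * 44,
            f"events tested          {n}",
            f"alpha (BH-adjusted)    {self.alpha}",
            f"min |delta psi|        {self.min_delta_psi}",
            f"replicate rho          {self.rho:.4f} (design effect {self.design_effect:.2f})",
            f"{self.call_column:22s} {self.n_called}",
        ]
        if self.skipped_pairs:
            lines.append(f"skipped stage pairs    {len(self.skipped_pairs)}")
        return "\n".join(lines)
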