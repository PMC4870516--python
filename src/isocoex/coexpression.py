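"""Isoform co-expression statistics.

The central quantity is the isoform co-expression index

    nu = exp(H),    H = -sum_i p_i ln p_i

the exponential of the Shannon entropy (in nats) of the isoform proportion
vector -- the Hill number of order 1, or "effective number of co-expressed
isoforms".  For a two-isoform event quantified by a percent-spliced-in value
psi, p = (psi/100, 1 - psi/100), so nu ranges from 1 (one isoform only) to 2
(a perfect 50/50 blend).

Developmental trends of nu are scored with the Kendall rank correlation
against stage order, with Benjamini-Hochberg adjustment across events, and
the population of trend coefficients is tested for bimodality with the
Hartigan dip statistic against a uniform Monte-Carlo null.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "shannon_entropy",
    "coexpression_index",
    "kendall_tau",
    "bh_adjust",
    "classify_trends",
    "dip_statistic",
    "dip_test",
    "kde_density",
    "NuValue",
    "TrendResult",
    "BimodalityResult",
    "DensityEstimate",
    "CoexpressionTrendModel",
    "CoexpressionTrendResults",
]

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class NuValue:
    """Shannon entropy (nats) and the derived effective isoform number."""

    H: float
    nu: float


@dataclass(frozen=True)
class TrendResult:
    event_id: str
    tau: float
    p: float
    p_adj: float
    trend_class: str
    n_points: int
    tau_defined: bool = True


@dataclass(frozen=True)
class BimodalityResult:
    dip: float
    p: float
    n: int
    n_boot: int
    seed: int


@dataclass(frozen=True)
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


def _validate_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("proportions must be a non-empty 1-D vector")
    if np.any(p < -_PROP_TOL) or np.any(p > 1 + _PROP_TOL):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"proportions sum to {p.sum():.12g}, expected 1")
    return np.clip(p, 0.0, 1.0)


def shannon_entropy(p) -> float:
    """Shannon entropy in nats, with the 0*ln(0) := 0 convention."""
    p = _validate_proportions(p)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def coexpression_index(p) -> NuValue:
    """Effective number of co-expressed isoforms, nu = exp(H).

    For two isoforms pass ``p = (psi/100, 1 - psi/100)``; nu is 2 at a 50/50
    mixture and 1 when a single isoform carries all the expression.
    """
    H = shannon_entropy(p)
    return NuValue(H=H, nu=float(np.exp(H)))


def nu_from_psi(psi: float) -> float:
    """Two-isoform nu directly from a percent-spliced-in value (0..100)."""
    if not 0.0 <= psi <= 100.0:
        raise ValueError(f"psi={psi} outside [0, 100]")
    return coexpression_index([psi / 100.0, 1.0 - psi / 100.0]).nu


def kendall_tau(x, y, exact_max_n: int = 8):
    """Kendall tau-b with a two-sided p value.

    The p value is exact (full permutation null) when n <= ``exact_max_n``
    and there are no ties in x or y; otherwise the tie-corrected normal
    approximation is used.  A constant y has no defined ordering: tau is
    reported as 0.0 with p = 1.0 and ``defined=False``.

    Returns (tau, p, defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend test")
    if np.all(y == y[0]) or np.all(x == x[0]):
        return 0.0, 1.0, False
    ties = (len(np.unique(x)) < x.size) or (len(np.unique(y)) < y.size)
    method = "exact" if (x.size <= exact_max_n and not ties) else "asymptotic"
    res = _sps.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue), True


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_trends(tau, p_adj, tau_threshold: float = 0.4, alpha: float = 0.005):
    """Label each (tau, adjusted p) pair increasing / decreasing / none."""
    tau = np.asarray(tau, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    out = np.full(tau.shape, "none", dtype=object)
    out[(tau > tau_threshold) & (p_adj < alpha)] = "increasing"
    out[(tau < -tau_threshold) & (p_adj < alpha)] = "decreasing"
    return out


# ---------------------------------------------------------------------------
# Hartigan dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(sample) -> float:
    """Hartigan dip statistic of a 1-D sample.

    The dip is the smallest sup-norm distance between the empirical CDF and
    any unimodal CDF (convex below its mode, concave above, with at most one
    atom at the mode).  It is computed with the greatest-convex-minorant /
    least-concave-majorant sweep over a shrinking modal interval; deviations
    are tracked in step units and halved at the end, so the value lies in
    [1/(2n), 0.25] for non-degenerate samples.  A sample of identical values
    is perfectly unimodal and returns 0.
    """
    xs = np.sort(np.asarray(sample, dtype=float))
    n = xs.size
    if n < 2 or xs[0] == xs[-1]:
        return 0.0
    x = np.empty(n + 1)
    x[1:] = xs  # 1-based indexing below

    # prev-knot links of the lower convex hull of (x_j, j), built left to right
    mn = np.zeros(n + 1, dtype=np.intp)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # next-knot links of the upper concave hull, built right to left
    mj = np.zeros(n + 1, dtype=np.intp)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in step units; enforces the 1/(2n) floor
    gcm = np.zeros(n + 2, dtype=np.intp)
    lcm = np.zeros(n + 2, dtype=np.intp)
    while True:
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # largest vertical gap between the two hulls, scanned at interior knots
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # majorant knot below a minorant segment
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - \
                        (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # minorant knot below a majorant segment
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - \
                        (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # ECDF deviation above the minorant between the new and the old low
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # ECDF deviation below the majorant between the new and the old high
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (je - jj + 1) - (x[je] - x[jj]) * C
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t
        if dip < dip_l:
            dip = dip_l
        if dip < dip_u:
            dip = dip_u
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]
    return dip / (2 * n)


@functools.lru_cache(maxsize=16)
def _uniform_null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


def dip_test(sample, n_boot: int = 2000, seed: int = 0) -> BimodalityResult:
    """Monte-Carlo dip test of unimodality against a uniform null.

    p = (b + 1) / (n_boot + 1) where b counts uniform(0,1) samples of the
    same size whose dip is at least the observed one.  Deterministic for a
    given seed; the null table is cached per (n, n_boot, seed).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = dip_statistic(sample)
    null = _uniform_null_dips(sample.size, int(n_boot), int(seed))
    b = null.size - np.searchsorted(null, d, side="left")
    p = (b + 1) / (n_boot + 1)
    return BimodalityResult(dip=d, p=float(p), n=int(sample.size),
                            n_boot=int(n_boot), seed=int(seed))


def kde_density(values, bandwidth_rule: str = "silverman",
                grid_size: int = 512, cut: float = 4.0) -> DensityEstimate:
    """Gaussian kernel density estimate on a regular grid.

    Silverman's rule by default ('scott' also accepted).  A zero-variance
    input has no data-driven bandwidth; a small fallback bandwidth is used
    and the estimate is flagged degenerate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    sd = v.std(ddof=1)
    if sd == 0:
        bw = max(1e-3, 1e-3 * abs(v[0]))
        degenerate = True
    else:
        n = v.size
        if bandwidth_rule == "silverman":
            iqr = np.subtract(*np.percentile(v, [75, 25]))
            a = min(sd, iqr / 1.349) if iqr > 0 else sd
            bw = 0.9 * a * n ** (-1 / 5)
        elif bandwidth_rule == "scott":
            bw = sd * n ** (-1 / 5)
        else:
            raise ValueError(f"unknown bandwidth rule: {bandwidth_rule!r}")
        degenerate = False
    grid = np.linspace(v.min() - cut * bw, v.max() + cut * bw, grid_size)
    z = (grid[:, None] - v[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, density=dens, bandwidth=float(bw),
                           degenerate=degenerate)


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

class CoexpressionTrendModel:
    """Developmental trend model for isoform co-expression.

    Built from a long-format percent-spliced-in table and a sample sheet;
    ``fit`` computes per-event nu trajectories over stage order, Kendall
    tau with BH-adjusted p values, and trend classes.

    Parameters
    ----------
    psi : DataFrame with columns event_id, sample_id, psi (percent; NaN for
        samples where the event had no junction coverage).
    samples : DataFrame with columns sample_id, stage, replicate.  Stage
        order is taken from the categorical order of `stage` if ordered,
        otherwise from order of first appearance.
    """

    def __init__(self, psi: pd.DataFrame, samples: pd.DataFrame):
        need = {"event_id", "sample_id", "psi"}
        if not need.issubset(psi.columns):
            raise ValueError(f"psi table must have columns {sorted(need)}")
        if not {"sample_id", "stage"}.issubset(samples.columns):
            raise ValueError("sample sheet must have columns sample_id, stage")
        self.psi = psi.copy()
        self.samples = samples.copy()
        stages = samples["stage"]
        if isinstance(stages.dtype, pd.CategoricalDtype) and stages.cat.ordered:
            self.stage_order = list(stages.cat.categories)
        else:
            self.stage_order = list(pd.unique(stages))
        unknown = set(samples["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")

    @classmethod
    def from_counts(cls, counts: "pd.DataFrame", samples: pd.DataFrame):
        """Build from a junction count table (event_id, sample_id,
        inclusion, exclusion); psi is NaN where the total is zero."""
        from .quant import compute_psi_frame

        return cls(compute_psi_frame(counts), samples)

    def fit(self, tau_threshold: float = 0.4, alpha: float = 0.005,
            per_replicate: bool = True) -> "CoexpressionTrendResults":
        rank = {s: i + 1 for i, s in enumerate(self.stage_order)}
        meta = self.samples.set_index("sample_id")["stage"].map(rank)
        df = self.psi.dropna(subset=["psi"]).copy()
        df["stage_rank"] = df["sample_id"].map(meta)
        if df["stage_rank"].isna().any():
            bad = df.loc[df["stage_rank"].isna(), "sample_id"].unique()
            raise ValueError(f"samples missing from sample sheet: {list(bad)[:5]}")
        df["nu"] = [nu_from_psi(p) for p in df["psi"]]
        if not per_replicate:
            df = (df.groupby(["event_id", "stage_rank"], as_index=False)
                    .agg(nu=("nu", "mean")))
        rows = []
        for event_id, g in df.groupby("event_id", sort=True):
            if len(g) < 3:
                rows.append((event_id, np.nan, np.nan, 0, False))
                continue
            tau, p, defined = kendall_tau(g["stage_rank"].to_numpy(),
                                          g["nu"].to_numpy())
            rows.append((event_id, tau, p, len(g), defined))
        res = pd.DataFrame(rows, columns=["event_id", "tau", "p",
                                          "n_points", "tau_defined"])
        tested = res["p"].notna()
        res["p_adj"] = np.nan
        res.loc[tested, "p_adj"] = bh_adjust(res.loc[tested, "p"].to_numpy())
        res["trend_class"] = "none"
        res.loc[tested, "trend_class"] = classify_trends(
            res.loc[tested, "tau"].to_numpy(),
            res.loc[tested, "p_adj"].to_numpy(),
            tau_threshold=tau_threshold, alpha=alpha)
        return CoexpressionTrendResults(
            model=self, trends=res, tau_threshold=tau_threshold, alpha=alpha,
            per_replicate=per_replicate, nu_points=df)


@dataclass
class CoexpressionTrendResults:
    """Per-event trend table plus bimodality / density summaries."""

    model: CoexpressionTrendModel
    trends: pd.DataFrame
    tau_threshold: float
    alpha: float
    per_replicate: bool
    nu_points: pd.DataFrame = field(repr=False, default=None)

    @property
    def counts(self) -> dict:
        c = self.trends["trend_class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("increasing", "decreasing", "none")}

    def tau_values(self, events: Sequence[str] | None = None) -> np.ndarray:
        t = self.trends
        if events is not None:
            t = t[t["event_id"].isin(set(events))]
        return t["tau"].dropna().to_numpy()

    def bimodality(self, events: Sequence[str] | None = None,
                   n_boot: int = 2000, seed: int = 0) -> BimodalityResult:
        """Dip test of the tau distribution for a subset of events."""
        return dip_test(self.tau_values(events), n_boot=n_boot, seed=seed)

    def density(self, events: Sequence[str] | None = None,
                **kw) -> DensityEstimate:
        return kde_density(self.tau_values(events), **kw)

    def summary(self) -> str:
        c = self.counts
        tested = int(self.trends["p"].notna().sum())
        lines = [
            "Isoform co-expression trend analysis",
            "=" * 44,
            f"events tested          {tested}",
            f"stages                 {len(self.model.stage_order)}",
            f"points per event       {'replicate-level' if self.per_replicate else 'stage means'}",
            f"tau threshold          {self.tau_threshold}",
            f"alpha (BH-adjusted)    {self.alpha}",
            "-" * 44,
            f"increasing trends      {c['increasing']}",
            f"decreasing trends      {c['decreasing']}",
            f"no trend               {c['none']}",
        ]
        return "\n".join(lines)
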