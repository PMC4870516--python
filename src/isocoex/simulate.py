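"""Synthetic data generators for every stage of the analysis.

The generators emulate the statistical structure the pipeline assumes: an
8-stage neuronal differentiation time course with replicated two-isoform
junction counts (beta-binomial replicate noise), gene models with genuine
UA3E/AIDE topology plus cassette-exon and tandem-APA decoys, splice-site
windows with planted pyrimidine-rich hexamers, knockdown contrasts, and
single-cell marker/isoform profiles.  Every generator is deterministic
given the config seed and returns a ground-truth table covering each
emitted record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import WindowSet
from .quant import JunctionCountTable

__all__ = [
    "SimulationConfig",
    "simulate_gene_models",
    "simulate_timecourse_counts",
    "simulate_knockdown_counts",
    "simulate_windows",
    "simulate_single_cells",
]

DEFAULT_STAGES = ("DIV-8", "DIV-4", "DIV0", "DIV1",
                  "DIV7", "DIV16", "DIV21", "DIV28")


@dataclass
class SimulationConfig:
    """All tunables for the synthetic generators (seed is mandatory)."""

    seed: int

    # time-course counts
    n_events: int = 200
    n_increasing: int = 50
    n_decreasing: int = 0
    stage_names: tuple = DEFAULT_STAGES
    replicates_per_stage: int = 3
    depth_mean: float = 100.0
    overdispersion: float = 0.02       # beta-binomial rho
    psi_start: float = 5.0
    psi_end: float = 45.0
    switch_stage: float | None = None  # default: midpoint of the series
    switch_slope: float = 0.6          # logistic steepness, in stage ranks

    # gene models
    n_true_genes: int = 50
    n_cassette_decoys: int = 25
    n_tandem_decoys: int = 25

    # knockdown contrasts
    n_kd_events: int = 100
    n_dependent: int = 20
    kd1_delta_psi: float = 20.0
    kd12_delta_psi: float = 35.0
    kd_replicates: int = 3
    kd_depth_mean: float = 300.0

    # splice-site windows / motif planting
    n_regulated_windows: int = 100
    n_background_windows: int = 100
    window_width: int = 250
    planted_motif: str = "UCUUCU"
    plant_rate_regulated: float = 0.6
    plant_rate_background: float = 0.1

    # single cells
    n_neurons: int = 72
    n_astrocytes: int = 18
    n_other: int = 33
    psi_neuron: float = 42.8
    psi_astrocyte: float = 4.5
    psi_logit_sd: float = 0.35
    cell_depth: float = 200.0
    marker_dropout: float = 0.0

    def __post_init__(self):
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion rho must lie in [0, 1)")
        for r in (self.plant_rate_regulated, self.plant_rate_background,
                  self.marker_dropout):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_increasing + self.n_decreasing > self.n_events:
            raise ValueError("planted events exceed n_events")
        if self.window_width < len(self.planted_motif):
            raise ValueError("window shorter than the planted motif")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _flip(iv, L):
    s, e = iv
    return (L - e, L - s)


def _gene_layout(rng):
    m = 100
    a = (m, m + int(rng.integers(80, 151)))
    t0 = a[1] + int(rng.integers(150, 301))
    t = (t0, t0 + int(rng.integers(60, 121)))
    w0 = t[1] + int(rng.integers(100, 251))
    w = (w0, w0 + int(rng.integers(80, 151)))
    x0 = w[1] + int(rng.integers(80, 201))
    x = (x0, x0 + int(rng.integers(60, 101)))
    length = x[1] + m
    return a, t, w, x, length


def _gtf_line(chrom, start, end, strand, gene, tx):
    return (f"{chrom}\tisocoex_sim\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";')


def simulate_gene_models(config: SimulationConfig):
    """Two-transcript genes with genuine UA3E/AIDE structure plus decoys.

    Returns (gtf_text, truth, genome) where genome maps each per-gene
    contig to a random DNA sequence, and truth records the planted event
    coordinates (gene_class 'true') or the decoy type.
    """
    rng = config.rng(1)
    lines, truth, genome = [], [], {}
    specs = ([("true", i) for i in range(config.n_true_genes)]
             + [("cassette", i) for i in range(config.n_cassette_decoys)]
             + [("tandem", i) for i in range(config.n_tandem_decoys)])
    for gene_class, i in specs:
        gene = f"{gene_class}_{i:04d}"
        chrom = f"chr_{gene}"
        strand = "+" if rng.random() < 0.5 else "-"
        a, t, w, x, L = _gene_layout(rng)
        if strand == "-":
            a, t, w, x = (_flip(a, L), _flip(t, L), _flip(w, L), _flip(x, L))
        donor = a[1] if strand == "+" else a[0]
        ua3e_3ss = t[0] if strand == "+" else t[1]
        aide_3ss = w[0] if strand == "+" else w[1]
        if gene_class == "true":
            txs = {"short": [a, t], "long": [a, w, x]}
        elif gene_class == "cassette":
            txs = {"short": [a, t], "long": [a, w, x], "mid": [a, t, w]}
        else:  # tandem APA: two terminal exons sharing one acceptor
            if strand == "+":
                t2 = (t[0], t[1] + 50)
            else:
                t2 = (t[0] - 50, t[1])
            txs = {"short": [a, t], "short2": [a, t2]}
        for tx, exons in sorted(txs.items()):
            for (s, e) in sorted(exons):
                lines.append(_gtf_line(chrom, s, e, strand, gene, f"{gene}.{tx}"))
        genome[chrom] = "".join(rng.choice(list("ACGT"), size=L))
        event_id = (f"{gene}|{chrom}:{donor}:{ua3e_3ss}:{aide_3ss}:{strand}"
                    if gene_class == "true" else "")
        truth.append((gene, chrom, strand, gene_class, donor, ua3e_3ss,
                      aide_3ss, event_id))
    truth_df = pd.DataFrame(truth, columns=["gene_id", "chrom", "strand",
                                            "gene_class", "donor", "ua3e_3ss",
                                            "aide_3ss", "event_id"])
    return "\n".join(lines) + "\n", truth_df, genome


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def _logistic_psi(ranks, psi_start, psi_end, mid, slope):
    z = (ranks - mid) / slope
    return psi_start + (psi_end - psi_start) / (1.0 + np.exp(-z))


def _beta_binomial(rng, n, p, rho):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if rho == 0:
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


def simulate_timecourse_counts(config: SimulationConfig, event_ids=None):
    """Replicated junction counts along the differentiation time course.

    Planted 'increasing' events follow a logistic psi trajectory from
    ``psi_start`` to ``psi_end`` (decreasing events the reverse); flat
    events keep a constant baseline psi.  Per sample the junction total is
    Poisson and the inclusion count beta-binomial with overdispersion rho.
    """
    rng = config.rng(2)
    n = config.n_events
    if event_ids is None:
        event_ids = [f"ev{i:04d}" for i in range(n)]
    elif len(event_ids) != n:
        raise ValueError("event_ids length must equal n_events")
    classes = np.array(["increasing"] * config.n_increasing
                       + ["decreasing"] * config.n_decreasing
                       + ["flat"] * (n - config.n_increasing - config.n_decreasing))
    rng.shuffle(classes)
    stages = list(config.stage_names)
    S = len(stages)
    ranks = np.arange(1, S + 1, dtype=float)
    mid = config.switch_stage if config.switch_stage is not None else (S + 1) / 2
    sample_ids, stage_col, rep_col = [], [], []
    for st in stages:
        for r in range(1, config.replicates_per_stage + 1):
            sample_ids.append(f"{st}_r{r}")
            stage_col.append(st)
            rep_col.append(r)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "stage": pd.Categorical(stage_col, categories=stages, ordered=True),
        "replicate": rep_col,
        "condition": "timecourse",
    })
    rows, truth = [], []
    for event_id, cls in zip(event_ids, classes):
        if cls == "increasing":
            psi = _logistic_psi(ranks, config.psi_start, config.psi_end,
                                mid, config.switch_slope)
        elif cls == "decreasing":
            psi = _logistic_psi(ranks, config.psi_end, config.psi_start,
                                mid, config.switch_slope)
        else:
            base = float(rng.uniform(15.0, 85.0))
            psi = np.full(S, base)
        for si, st in enumerate(stages):
            for r in range(1, config.replicates_per_stage + 1):
                total = int(rng.poisson(config.depth_mean))
                inc = int(_beta_binomial(rng, total, psi[si] / 100.0,
                                         config.overdispersion)) if total else 0
                rows.append((event_id, f"{st}_r{r}", inc, total - inc))
        truth.append((event_id, cls, float(psi[0]), float(psi[-1])))
    counts = pd.DataFrame(rows, columns=["event_id", "sample_id",
                                         "inclusion", "exclusion"])
    truth_df = pd.DataFrame(truth, columns=["event_id", "true_class",
                                            "psi_first_stage", "psi_last_stage"])
    return JunctionCountTable(counts, samples), truth_df


def simulate_knockdown_counts(config: SimulationConfig, event_ids=None):
    """Junction counts for control / single- / double-knockdown conditions.

    Dependent events shift psi by ``kd1_delta_psi`` and ``kd12_delta_psi``
    with a common (random) sign; independent events keep their baseline.
    """
    rng = config.rng(5)
    n = config.n_kd_events
    if event_ids is None:
        event_ids = [f"kd{i:04d}" for i in range(n)]
    dependent = np.zeros(n, dtype=bool)
    dependent[:config.n_dependent] = True
    rng.shuffle(dependent)
    conditions = ("control", "kd1", "kd12")
    samples = pd.DataFrame(
        [(f"{c}_r{r}", c, r) for c in conditions
         for r in range(1, config.kd_replicates + 1)],
        columns=["sample_id", "condition", "replicate"])
    rows, truth = [], []
    for event_id, dep in zip(event_ids, dependent):
        base = float(rng.uniform(20.0, 60.0))
        if dep:
            sign = 1.0 if base + config.kd12_delta_psi <= 95.0 else -1.0
            d1, d12 = sign * config.kd1_delta_psi, sign * config.kd12_delta_psi
        else:
            d1 = d12 = 0.0
        psi = {"control": base, "kd1": base + d1, "kd12": base + d12}
        for c in conditions:
            for r in range(1, config.kd_replicates + 1):
                total = int(rng.poisson(config.kd_depth_mean))
                inc = int(_beta_binomial(rng, total, psi[c] / 100.0,
                                         config.overdispersion)) if total else 0
                rows.append((event_id, f"{c}_r{r}", inc, total - inc))
        truth.append((event_id, bool(dep), d1, d12))
    counts = pd.DataFrame(rows, columns=["event_id", "sample_id",
                                         "inclusion", "exclusion"])
    truth_df = pd.DataFrame(truth, columns=["event_id", "dependent",
                                            "delta_psi_kd1", "delta_psi_kd12"])
    return JunctionCountTable(counts, samples), truth_df


# ---------------------------------------------------------------------------
# windows and motif planting
# ---------------------------------------------------------------------------

def simulate_windows(config: SimulationConfig):
    """Random splice-site windows with a hexamer planted at class-specific
    rates.  Returns (regulated, background, truth)."""
    rng = config.rng(3)
    motif = config.planted_motif.upper().replace("T", "U")
    width = config.window_width
    half = width // 2

    def make(prefix, count, rate):
        out, rows = [], []
        for i in range(count):
            seq = "".join(rng.choice(list("ACGU"), size=width))
            planted = bool(rng.random() < rate)
            pos = -1
            if planted:
                pos = int(rng.integers(0, width - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            wid = f"{prefix}{i:04d}"
            out.append(WindowSet(event_id=wid, intronic_seq=seq[:half],
                                 exonic_seq=seq[half:], width=width))
            rows.append((wid, prefix.rstrip("_"), planted, pos))
        return out, rows

    regulated, r_rows = make("reg", config.n_regulated_windows,
                             config.plant_rate_regulated)
    background, b_rows = make("bg", config.n_background_windows,
                              config.plant_rate_background)
    truth = pd.DataFrame(r_rows + b_rows,
                         columns=["window_id", "window_class", "planted",
                                  "position"])
    return regulated, background, truth


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p / (1 - p))


def simulate_single_cells(config: SimulationConfig):
    """Marker/isoform profiles for neurons, astrocytes and other cells.

    psi is class-conditional (Gaussian on the logit scale); markers are
    positive counts with optional dropout; isoform counts are binomial at
    Poisson depth.  Returns (profiles, truth).
    """
    rng = config.rng(4)
    rows, truth = [], []
    spec = ([("neuron", config.psi_neuron)] * config.n_neurons
            + [("astrocyte", config.psi_astrocyte)] * config.n_astrocytes
            + [("other", None)] * config.n_other)
    for i, (cls, psi_mean) in enumerate(spec):
        cell_id = f"cell{i:04d}"
        if psi_mean is None:
            psi_mean = float(rng.uniform(10.0, 70.0))
        z = _logit(psi_mean / 100.0) + rng.normal(0.0, config.psi_logit_sd)
        psi = 100.0 / (1.0 + np.exp(-z))
        gapdh = 1 + int(rng.poisson(8))
        neun = 1 + int(rng.poisson(5)) if cls == "neuron" else 0
        gfap = 1 + int(rng.poisson(5)) if cls == "astrocyte" else 0
        if config.marker_dropout > 0:
            gapdh = 0 if rng.random() < config.marker_dropout else gapdh
            neun = 0 if rng.random() < config.marker_dropout else neun
            gfap = 0 if rng.random() < config.marker_dropout else gfap
        depth = int(rng.poisson(config.cell_depth))
        e6 = int(rng.binomial(depth, psi / 100.0)) if depth else 0
        rows.append((cell_id, gapdh, neun, gfap, e6, depth - e6))
        truth.append((cell_id, cls, float(psi)))
    profiles = pd.DataFrame(rows, columns=["cell_id", "gapdh", "neun",
                                           "gfap", "e6", "e7"])
    truth_df = pd.DataFrame(truth, columns=["cell_id", "true_class", "true_psi"])
    return profiles, truth_df
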