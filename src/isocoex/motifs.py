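"""k-mer motif scanning and enrichment around 3' splice sites.

Polypyrimidine tract-binding proteins (Ptbp1/Ptbp2) recognise short CU-rich
elements; regulated exons are expected to carry such motifs near their
acceptors.  Enrichment compares motif presence in the splice-site windows
of regulated versus non-regulated events with a one-sided Fisher test per
k-mer and BH adjustment across the motif set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotation import WindowSet
from .coexpression import bh_adjust
from .quant import fisher_exact_2x2

__all__ = ["MotifSet", "scan_motif", "default_ptbp_motifs",
           "MotifEnrichmentModel", "MotifEnrichmentResults"]

_RNA = set("ACGU")


@dataclass(frozen=True)
class MotifSet:
    name: str
    kmers: tuple

    def __post_init__(self):
        if not self.kmers:
            raise ValueError("motif set is empty")
        k = len(self.kmers[0])
        for m in self.kmers:
            if len(m) != k:
                raise ValueError("all k-mers must have the same length")
            if not set(m) <= _RNA:
                raise ValueError(f"k-mer {m!r} not over the RNA alphabet")

    @property
    def k(self) -> int:
        return len(self.kmers[0])

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "MotifSet":
        with open(path) as fh:
            kmers = [ln.strip().upper().replace("T", "U")
                     for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(name=name or str(path), kmers=tuple(kmers))


def scan_motif(seq: str, kmer: str) -> list:
    """0-based positions of (possibly overlapping) exact matches.

    N in the sequence never matches.
    """
    seq = seq.upper().replace("T", "U")
    kmer = kmer.upper().replace("T", "U")
    if not kmer:
        raise ValueError("empty k-mer")
    if "N" in kmer:
        return []
    return [i for i in range(len(seq) - len(kmer) + 1)
            if seq[i:i + len(kmer)] == kmer]


def default_ptbp_motifs() -> MotifSet:
    """Built-in CU-rich hexamer set standing in for a Ptbp1/2 consensus.

    All hexamers over {C, U} containing UCUU or CUCU as a substring -- the
    cores of the classic polypyrimidine-tract binding consensus.  The list
    is deterministic and enumerable; supply a custom motif file to use an
    experimentally derived set instead.
    """
    kmers = sorted(
        "".join(m) for m in itertools.product("CU", repeat=6)
        if "UCUU" in "".join(m) or "CUCU" in "".join(m)
    )
    return MotifSet(name="ptbp_cu_hexamers", kmers=tuple(kmers))


def _window_region(w: WindowSet, region: str) -> str:
    if region == "R4":
        return w.intronic_seq
    if region == "R5":
        return w.exonic_seq
    if region == "both":
        return w.sequence
    raise ValueError(f"region must be R4, R5 or both, got {region!r}")


class MotifEnrichmentModel:
    """Per-k-mer enrichment of motif presence in regulated vs background
    splice-site windows.

    Scoring is presence/absence per window (robust to window length); a
    count-based mode is available via ``method='count'`` which uses total
    occurrence counts in a binomial test per k-mer.
    """

    def __init__(self, regulated: Iterable[WindowSet],
                 background: Iterable[WindowSet],
                 motifs: MotifSet, region: str = "both"):
        self.regulated = list(regulated)
        self.background = list(background)
        if not self.regulated or not self.background:
            raise ValueError("both window sets must be non-empty")
        self.motifs = motifs
        self.region = region

    def fit(self, alternative: str = "greater",
            method: str = "presence") -> "MotifEnrichmentResults":
        reg = [_window_region(w, self.region) for w in self.regulated]
        bg = [_window_region(w, self.region) for w in self.background]
        rows = []
        for kmer in self.motifs.kmers:
            if method == "presence":
                rw = sum(1 for s in reg if scan_motif(s, kmer))
                bw = sum(1 for s in bg if scan_motif(s, kmer))
                ro, bo = len(reg) - rw, len(bg) - bw
                orr, p = fisher_exact_2x2(rw, ro, bw, bo,
                                          alternative=alternative)
                rows.append((kmer, rw, ro, bw, bo, orr, p))
            elif method == "count":
                from scipy.stats import binomtest
                rc = sum(len(scan_motif(s, kmer)) for s in reg)
                bc = sum(len(scan_motif(s, kmer)) for s in bg)
                n_r = sum(max(0, len(s) - len(kmer) + 1) for s in reg)
                n_b = sum(max(0, len(s) - len(kmer) + 1) for s in bg)
                if rc + bc == 0:
                    rows.append((kmer, rc, n_r - rc, bc, n_b - bc, 1.0, 1.0))
                    continue
                alt = {"greater": "greater", "two-sided": "two-sided"}[alternative]
                p = binomtest(rc, rc + bc, n_r / (n_r + n_b), alternative=alt).pvalue
                orr, _ = fisher_exact_2x2(rc, max(n_r - rc, 0), bc, max(n_b - bc, 0))
                rows.append((kmer, rc, n_r - rc, bc, n_b - bc, orr, float(p)))
            else:
                raise ValueError(f"unknown method {method!r}")
        df = pd.DataFrame(rows, columns=["kmer", "n_regulated_with",
                                         "n_regulated_without",
                                         "n_background_with",
                                         "n_background_without",
                                         "odds_ratio", "p"])
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["region"] = self.region
        df = df.sort_values(["p_adj", "p", "kmer"], kind="stable",
                            ignore_index=True)
        return MotifEnrichmentResults(table=df, region=self.region,
                                      alternative=alternative, method=method,
                                      n_regulated=len(reg), n_background=len(bg))


@dataclass
class MotifEnrichmentResults:
    table: pd.DataFrame
    region: str
    alternative: str
    method: str
    n_regulated: int
    n_background: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Motif enrichment (regulated vs background windows)",
            "=" * 52,
            f"windows                {self.n_regulated} regulated / "
            f"{self.n_background} background",
            f"region                 {self.region}",
            f"k-mers tested          {len(self.table)}",
            f"significant (BH<0.05)  {len(sig)}",
        ]
        for r in sig.head(10).itertuples(index=False):
            lines.append(f"  {r.kmer}  OR={r.odds_ratio:8.3g}  p_adj={r.p_adj:.3g}")
        return "\n".join(lines)
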