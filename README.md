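# isocoex

Quantitative analysis of **alternative 3′-terminal exon (A3E) usage and
isoform co-expression** during neuronal differentiation, from splice-junction
counts.

Many genes choose between an upstream alternative 3′-terminal exon (**UA3E**)
— the last exon of a short isoform lying inside an intron of a longer isoform
— and the **AIDE** (alternative isoform with downstream exons) that skips it.
During differentiation some genes do not switch completely from one 3′ end to
the other but settle into a *stable blend* of both isoforms in the same cell
(the mouse *Cdc42* E6/E7 pair is the canonical example: neurons hold a nearly
equimolar mixture, astrocytes use almost only E7). `isocoex` provides the
statistical machinery to find and characterise such events:

* **Event cataloging** from gene models (GTF), with cassette-exon and
  tandem-APA configurations filtered out, and strand-aware extraction of
  sequence windows around the UA3E 3′ splice site.
* **ψ quantification** from the two donor-anchored junction counts:
  ψ = 100·*inclusion*/(*inclusion*+*exclusion*).
* The **isoform co-expression index** ν = exp(*H*), where
  *H* = −Σᵢ pᵢ ln pᵢ is the Shannon entropy of the isoform proportions
  (for two isoforms, p = (ψ/100, 1−ψ/100)). ν is the Hill number of order 1 —
  the *effective number of co-expressed isoforms* — ranging from 1 (one
  isoform only) to 2 (a perfect 50/50 blend).
* **Trend statistics**: Kendall τ-b of ν against stage order, exact
  permutation p values for small n, Benjamini–Hochberg adjustment, and trend
  classes (τ > 0.4, BH-adjusted p < 0.005 by default).
* **Bimodality testing** of τ populations with the Hartigan dip statistic
  (own GCM/LCM sweep implementation, Monte-Carlo uniform null).
* **Differential-usage calls** over a time course or knockdown contrasts,
  using dispersion-corrected pooled exact tests with a |Δψ| effect-size gate.
* **Motif enrichment** of pyrimidine-rich (Ptbp1/2-style) hexamers near
  regulated 3′ splice sites.
* **Single-cell classification** (Gapdh/NeuN/Gfap markers) with per-cell ψ,
  group medians and Welch comparison.
* **Synthetic data generators** for every input, with ground-truth tables,
  so the whole pipeline is testable offline.

## Worked example

```python
from isocoex import (SimulationConfig, simulate_timecourse_counts,
                     simulate_single_cells, CoexpressionTrendModel,
                     SingleCellCoexpressionModel, coexpression_index)

coexpression_index([0.5, 0.5])
# NuValue(H=0.6931471805599453, nu=2.0)     # a 50/50 blend: 2 effective isoforms

cfg = SimulationConfig(seed=1)              # 8-stage course, 3 replicates,
table, truth = simulate_timecourse_counts(cfg)  # 200 events, 50 planted 5->45%
res = CoexpressionTrendModel.from_counts(table.counts, table.samples).fit()
print(res.summary())
```

```
Isoform co-expression trend analysis
============================================
events tested          200
stages                 8
points per event       replicate-level
tau threshold          0.4
alpha (BH-adjusted)    0.005
--------------------------------------------
increasing trends      51
decreasing trends      0
no trend               149
```

Of the 50 planted ψ 5 → 45 % switches, all 50 are recovered as increasing-ν
trends (plus one false call among the 150 flat events). The same results
object tests the τ population for bimodality:

```python
res.bimodality(seed=1)
# BimodalityResult(dip=0.0686, p=0.0005, n=200, n_boot=2000, seed=1)
```

Single-cell profiles emulate a newborn-hippocampus dissociation (72 neurons,
18 astrocytes, 33 other cells):

```python
profiles, _ = simulate_single_cells(cfg)
sc = SingleCellCoexpressionModel(profiles).fit()
print(sc.summary())
```

```
Single-cell isoform co-expression
============================================
cells                  123
marker threshold       1
astrocyte               14.63 %
neuron                  58.54 %
other                   26.83 %
median psi neuron        41.7 %  (n=72)
median psi astrocyte      4.5 %  (n=18)
```

`sc.compare()` gives the Welch test between the groups
(t = 30.3, df = 83.1, p ≈ 1.1 × 10⁻⁴⁶): neurons co-express both isoforms at a
near-balanced ratio while astrocytes are essentially single-isoform.

## Command line

Every stage is also exposed as a subcommand of `isocoex`:

```bash
isocoex simulate --preset genes --seed 1 --out sim/
isocoex catalog  --gtf sim/genes.gtf --out sim/events.tsv
isocoex windows  --events sim/events.tsv --fasta sim/genome.fa --width 250 --out sim/windows.fa
isocoex trends   --counts counts.tsv --samples samples.tsv --out trends.tsv
isocoex run      --config run.yaml        # full pipeline with a report
```

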