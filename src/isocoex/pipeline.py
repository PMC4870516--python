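"""End-to-end orchestration with config, logging and machine-readable reports."""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (catalog_ua3e_events, events_to_frame,
                         parse_gene_models)
from .coexpression import CoexpressionTrendModel
from .motifs import MotifEnrichmentModel, MotifSet, default_ptbp_motifs
from .quant import (JunctionCountTable, KnockdownRegulationModel,
                    TimecourseRegulationModel, flag_detectable,
                    overlap_enrichment, psi_matrix)
from .simulate import (SimulationConfig, simulate_gene_models,
                       simulate_knockdown_counts, simulate_single_cells,
                       simulate_timecourse_counts, simulate_windows)
from .single_cell import SingleCellCoexpressionModel

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for a full pipeline run.

    With ``synthetic=True`` all inputs are generated with the built-in
    simulators (using ``seed``) before the analysis stages run; otherwise
    the path fields point at user-supplied TSV/GTF/FASTA inputs.  Every
    threshold is echoed verbatim into the run report.
    """

    out_dir: str
    seed: int
    synthetic: bool = True
    gtf: str | None = None
    counts: str | None = None
    samples: str | None = None
    kd_counts: str | None = None
    kd_samples: str | None = None
    cell_profiles: str | None = None
    motif_file: str | None = None

    min_total_per_sample: int = 20
    min_stages: int = 1
    min_delta_psi: float = 10.0
    regulation_alpha: float = 0.05
    tau_threshold: float = 0.4
    trend_alpha: float = 0.005
    window_width: int = 250
    n_boot: int = 2000
    marker_threshold: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must set a seed")
        if "out_dir" not in data:
            raise ValueError("config must set out_dir")
        return cls(**data)


@dataclass
class RunReport:
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "config": self.config,
                           "counts": self.counts, "timings": self.timings},
                          indent=2, default=str)

    def to_text(self) -> str:
        lines = [f"isocoex {self.version} run report", "=" * 40]
        for k, v in self.counts.items():
            lines.append(f"{k:32s} {v}")
        return "\n".join(lines)


def _log(stage: str, msg: str) -> None:
    print(f"[isocoex:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in dependency order, writing TSV/JSON outputs.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=dataclasses.asdict(config))

    def stage(name, fn):
        t0 = time.perf_counter()
        _log(name, "start")
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        report.timings[name] = round(time.perf_counter() - t0, 3)
        return result

    # ------------------------------------------------------------------ inputs
    sim = SimulationConfig(seed=config.seed) if config.synthetic else None

    def _inputs():
        if config.synthetic:
            gtf, gene_truth, _genome = simulate_gene_models(sim)
            table, tc_truth = simulate_timecourse_counts(sim)
            kd_table, kd_truth = simulate_knockdown_counts(sim)
            reg_w, bg_w, w_truth = simulate_windows(sim)
            profiles, cell_truth = simulate_single_cells(sim)
            (out / "inputs").mkdir(exist_ok=True)
            (out / "inputs" / "genes.gtf").write_text(gtf)
            table.to_tsv(out / "inputs" / "counts.tsv",
                         out / "inputs" / "samples.tsv")
            kd_table.to_tsv(out / "inputs" / "kd_counts.tsv",
                            out / "inputs" / "kd_samples.tsv")
            profiles.to_csv(out / "inputs" / "cells.tsv", sep="\t", index=False)
            return dict(gtf=gtf, table=table, kd_table=kd_table,
                        reg_windows=reg_w, bg_windows=bg_w, profiles=profiles)
        data = {}
        data["gtf"] = Path(config.gtf).read_text() if config.gtf else None
        if config.counts and config.samples:
            data["table"] = JunctionCountTable.from_tsv(config.counts,
                                                        config.samples)
        else:
            raise PipelineError("inputs", "counts and samples are required")
        if config.kd_counts and config.kd_samples:
            data["kd_table"] = JunctionCountTable.from_tsv(config.kd_counts,
                                                           config.kd_samples)
        else:
            data["kd_table"] = None
        data["reg_windows"] = data["bg_windows"] = None
        data["profiles"] = (pd.read_csv(config.cell_profiles, sep="\t")
                            if config.cell_profiles else None)
        return data

    data = stage("inputs", _inputs)

    # ------------------------------------------------------------------ catalog
    def _catalog():
        if data["gtf"] is None:
            return None
        genes = parse_gene_models(data["gtf"])
        events = catalog_ua3e_events(genes)
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
        report.counts["events_cataloged"] = len(events)
        return events

    stage("catalog", _catalog)

    # ------------------------------------------------------------------ quantify
    def _quantify():
        table = data["table"]
        psi = psi_matrix(table)
        psi.to_csv(out / "psi_matrix.tsv", sep="\t")
        det = flag_detectable(table, config.min_total_per_sample,
                              config.min_stages)
        det.to_frame().to_csv(out / "detectable.tsv", sep="\t")
        report.counts["events_quantified"] = int(psi.shape[0])
        report.counts["events_detectable"] = int(det.sum())
        return det

    stage("quantify", _quantify)

    # ------------------------------------------------------------------ regulation
    def _regulate():
        model = TimecourseRegulationModel(data["table"])
        res = model.fit(alpha=config.regulation_alpha,
                        min_delta_psi=config.min_delta_psi)
        res.calls.to_csv(out / "regulation.tsv", sep="\t", index=False)
        report.counts["events_regulated"] = res.n_called
        return res

    regulation = stage("regulate", _regulate)

    # ------------------------------------------------------------------ knockdown
    def _knockdown():
        if data["kd_table"] is None:
            return None
        res = KnockdownRegulationModel(data["kd_table"]).fit(
            alpha=config.regulation_alpha, min_delta_psi=config.min_delta_psi)
        res.calls.to_csv(out / "knockdown.tsv", sep="\t", index=False)
        report.counts["events_kd_dependent"] = res.n_called
        return res

    knockdown = stage("knockdown", _knockdown)

    # ------------------------------------------------------------------ overlap
    def _overlap():
        if knockdown is None:
            return None
        universe = set(regulation.calls["event_id"]) | set(
            knockdown.calls["event_id"])
        enr = overlap_enrichment(set(regulation.called_events),
                                 set(knockdown.called_events), universe)
        (out / "overlap.json").write_text(json.dumps(dataclasses.asdict(enr),
                                                     indent=2))
        report.counts["overlap_a_and_b"] = enr.a_and_b
        return enr

    stage("overlap", _overlap)

    # ------------------------------------------------------------------ trends
    def _trends():
        table = data["table"]
        model = CoexpressionTrendModel.from_counts(table.counts, table.samples)
        res = model.fit(tau_threshold=config.tau_threshold,
                        alpha=config.trend_alpha)
        res.trends.to_csv(out / "trends.tsv", sep="\t", index=False)
        c = res.counts
        report.counts["trend_increasing"] = c["increasing"]
        report.counts["trend_decreasing"] = c["decreasing"]
        report.counts["trend_none"] = c["none"]
        return res

    trends = stage("trends", _trends)

    # ------------------------------------------------------------------ bimodality
    def _bimodality():
        reg_ids = set(regulation.called_events)
        results = {}
        for name, ids in (("regulated", reg_ids),
                          ("all", None)):
            taus = trends.tau_values(ids)
            if len(taus) >= 4:
                r = trends.bimodality(ids, n_boot=config.n_boot,
                                      seed=config.seed)
                results[name] = dataclasses.asdict(r)
        (out / "bimodality.json").write_text(json.dumps(results, indent=2))
        if "regulated" in results:
            report.counts["bimodality_p_regulated"] = results["regulated"]["p"]
        return results

    stage("bimodality", _bimodality)

    # ------------------------------------------------------------------ motifs
    def _motifs():
        if data["reg_windows"] is None:
            return None
        motifs = (MotifSet.from_file(config.motif_file)
                  if config.motif_file else default_ptbp_motifs())
        res = MotifEnrichmentModel(data["reg_windows"], data["bg_windows"],
                                   motifs).fit()
        res.table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        report.counts["motifs_significant"] = int(len(res.significant()))
        return res

    stage("motifs", _motifs)

    # ------------------------------------------------------------------ single cells
    def _single_cell():
        if data["profiles"] is None:
            return None
        res = SingleCellCoexpressionModel(data["profiles"]).fit(
            threshold=config.marker_threshold)
        res.cells.to_csv(out / "cell_classes.tsv", sep="\t", index=False)
        summary = {
            "composition": {k: v[0] for k, v in res.composition.items()},
            "groups": res.group_summary().to_dict(orient="records"),
        }
        try:
            summary["comparison"] = res.compare()
        except ValueError:
            summary["comparison"] = None
        (out / "single_cell.json").write_text(json.dumps(summary, indent=2))
        report.counts["cells_classified"] = int(len(res.cells))
        return res

    stage("single_cell", _single_cell)

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    _log("done", f"report written to {out / 'report.json'}")
    return report
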