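"""End-to-end orchestration: simulate -> assign -> quantify -> classify.

A single YAML-able config drives the whole run; one master seed makes it
byte-for-byte reproducible. Each stage writes its intermediate as the
module's TSV so stages can also be run (and tested) independently, and a
JSON run log records the seed, thresholds and per-stage read totals.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allele_assignment import TranscriptSnpIndex, assign_readset, tabulate_counts, write_assignments
from .classifier import ClassifierConfig, classify_table, results_frame
from .io_formats import (
    STAGES,
    GeneModel,
    read_counts,
    write_counts,
    write_fasta,
    write_results,
    write_snp_table,
)
from .kinetics import KineticsConfig, feasibility_table
from .quantification import SampleQuant, normalize_autosomal
from .synthetic_data import (
    CrossDesign,
    build_diploid_transcriptome,
    example_panel,
    simulate_expression,
    simulate_reads,
)

__all__ = ["default_config", "load_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def default_config() -> dict[str, Any]:
    """The bundled demo configuration: a 200-gene panel, three stages,
    error-bearing 36-nt reads at modest depth."""
    return {
        "seed": 0,
        "stages": list(STAGES),
        "panel": {"n_maternal": 170, "n_zygotic": 30, "transcript_length": 1000},
        "transcriptome": {"mean_snp_spacing": 200.0},
        "reads": {
            "read_length": 36,
            "per_base_error_rate": 0.005,
            "n_reads_per_stage": 50_000,
        },
        "cross": {"maternal_line": "line-A", "paternal_line": "line-B", "reciprocal": False},
        "classifier": {},
        "kinetics": {},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = default_config()
    for key, val in cfg.items():
        if isinstance(val, Mapping) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    return base


def _require(cfg: Mapping[str, Any], key: str, stage: str) -> Any:
    if key not in cfg:
        raise PipelineError(f"[{stage}] config is missing required field {key!r}")
    return cfg[key]


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the full simulate/assign/quantify/classify pipeline.

    Writes all intermediates and results under ``out_dir`` and returns the
    run log (also written as ``run_log.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    log: dict[str, Any] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in config.items()},
        "per_stage": {},
    }

    # --- simulate: panel, diploid transcriptome, reads ---------------------
    try:
        pcfg = config.get("panel", {})
        refs, program = example_panel(
            n_maternal=int(pcfg.get("n_maternal", 170)),
            n_zygotic=int(pcfg.get("n_zygotic", 30)),
            transcript_length=int(pcfg.get("transcript_length", 1000)),
            seed=seed,
        )
        tcfg = config.get("transcriptome", {})
        spacing = float(_require(tcfg, "mean_snp_spacing", "simulate"))
        maternal, paternal, snps = build_diploid_transcriptome(refs, spacing, seed)
        cross = CrossDesign(**config.get("cross", default_config()["cross"]))
        write_fasta(maternal, out / "maternal.fasta")
        write_fasta(paternal, out / "paternal.fasta")
        write_snp_table(snps, out / "snps.tsv")
        program.to_yaml(out / "expression_program.yaml")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[simulate] {exc}") from exc

    gene_models = {
        gid: GeneModel(gene_id=gid, chrom=gid, strand="+", exons=((0, len(seq)),))
        for gid, seq in refs.items()
    }
    lengths = {gid: len(seq) for gid, seq in refs.items()}
    index = TranscriptSnpIndex.from_transcript_snps(snps, lengths, cross=cross)

    rcfg = config.get("reads", {})
    read_length = int(_require(rcfg, "read_length", "simulate"))
    error_rate = float(_require(rcfg, "per_base_error_rate", "simulate"))
    n_reads = int(_require(rcfg, "n_reads_per_stage", "simulate"))

    all_rows = []
    per_stage_counts: dict[str, dict[str, float]] = {}
    for stage in stages:
        try:
            copies = simulate_expression(program, stage)
            readset = simulate_reads(
                maternal, paternal, copies, read_length, error_rate, n_reads,
                seed, stage=stage,
            )
            readset.to_fastq(out / f"reads_{stage}.fastq")
            readset.write_truth_table(out / f"truth_{stage}.tsv")
        except Exception as exc:
            raise PipelineError(f"[simulate:{stage}] {exc}") from exc
        try:
            assignments = assign_readset(readset, index)
            write_assignments(assignments, out / f"assignments_{stage}.tsv")
            rows = tabulate_counts(assignments, stage, known_genes=lengths, cross=cross)
            write_counts(rows, out / f"counts_{stage}.tsv")
        except Exception as exc:
            raise PipelineError(f"[assign:{stage}] {exc}") from exc
        all_rows.extend(rows)
        per_stage_counts[stage] = {
            str(g): float(c) for g, c in assignments["gene_id"].value_counts().items()
        }
        log["per_stage"][stage] = {
            "n_reads": len(readset),
            "n_informative": int(sum(r.informative_total for r in rows)),
        }

    # --- quantify ----------------------------------------------------------
    try:
        samples = [
            SampleQuant.from_counts(stage, per_stage_counts[stage], gene_models)
            for stage in stages
            if per_stage_counts.get(stage)
        ]
        factors = normalize_autosomal(samples, gene_models)
        quant = pd.DataFrame(
            [
                {"stage": s.stage, "gene_id": gid, "rpkm": v, "scale_factor": s.scale_factor}
                for s in samples
                for gid, v in sorted(s.rpkm.items())
            ]
        )
        quant.to_csv(out / "rpkm.tsv", sep="\t", index=False)
        log["normalization_factors"] = dict(zip([s.stage for s in samples], factors))
    except Exception as exc:
        raise PipelineError(f"[quantify] {exc}") from exc

    # --- classify ----------------------------------------------------------
    try:
        clf_cfg = ClassifierConfig(**config.get("classifier", {}))
        results, summary = classify_table(all_rows, clf_cfg)
        write_results(results_frame(results), out / "results.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log["classifier"] = asdict(clf_cfg)
        log["summary"] = summary
    except Exception as exc:
        raise PipelineError(f"[classify] {exc}") from exc

    # --- kinetics ----------------------------------------------------------
    try:
        kin_cfg = KineticsConfig(**config.get("kinetics", {}))
        kin = feasibility_table({gid: float(L) for gid, L in sorted(lengths.items())}, kin_cfg)
        kin.to_csv(out / "kinetics.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"[kinetics] {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
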