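"""End-to-end orchestration: simulate (or load) -> call -> triage -> report.

A single global seed determines every stochastic step; component seeds are
derived from it deterministically, so identical configuration yields
byte-identical output files. Logging goes to standard error, results to
files only. On any stage failure the partial outputs written so far are
removed.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .calling import call_cohort
from .errors import ParameterError, SurfacerError
from .params import (CallParams, CohortConfig, TriageParams,
                     call_params_from_dict, cohort_config_from_dict,
                     triage_params_from_dict)
from .simulate import ARCH_LYMPHOID, generate_cohort
from .tables import ExpressionAtlas
from .triage import TriageResult, dotplot_stats, triage

log = logging.getLogger("surfacer")

_CALL_SEED_OFFSET = 50_000


@dataclass
class PipelineConfig:
    """Composite configuration of one pipeline run."""

    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    call: CallParams = field(default_factory=CallParams)
    triage: TriageParams = field(default_factory=TriageParams)
    seed: int = 0
    input_dir: str | None = None  # load a serialized cohort instead of simulating
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(
            cohort=cohort_config_from_dict(data.get("cohort", {}))
            if data.get("cohort") is not None or "input_dir" not in data else None,
            call=call_params_from_dict(data.get("call", {})),
            triage=triage_params_from_dict(data.get("triage", {})),
            seed=int(data.get("seed", 0)),
            input_dir=data.get("input_dir"),
            top_k=int(data.get("top_k", 10)),
        )
        if seed is not None:
            cfg.seed = seed
        return cfg


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    waterfall: list[tuple[str, int]]
    calls: pd.DataFrame
    report: str
    evaluation: dict | None = None


def _load_cohort(input_dir):
    d = Path(input_dir)
    quant_paths = sorted(d.glob("pdx_*.quant.tsv"),
                         key=lambda p: int(p.stem.split("_")[1].split(".")[0]))
    if not quant_paths:
        raise SurfacerError(f"no pdx_*.quant.tsv files under {d}")
    tables = [sio.read_quant_table(p, f"PDX{i}")
              for i, p in enumerate(quant_paths, start=1)]
    annotations = sio.read_annotations(d / "annotations.tsv")
    truth_path = d / "truth.tsv"
    truth = sio.read_truth(truth_path) if truth_path.exists() else None
    return tables, annotations, truth


def evaluate_against_truth(candidates: pd.DataFrame,
                           truth: pd.DataFrame) -> dict:
    """Sensitivity / FDR of the final candidate list against planted truth.

    A true target is a planted surface protein with the lymphoid-restricted
    tissue archetype (the profile the cascade is designed to recover).
    """
    targets = set(truth.index[(truth["is_surface"])
                              & (truth["tissue_archetype"] == ARCH_LYMPHOID)])
    final = set(candidates.index[candidates["not_excluded"]])
    recovered = targets & final
    false_hits = final - targets
    decoys = set(truth.index[(truth["is_surface"])
                             & (truth["tissue_archetype"] != ARCH_LYMPHOID)])
    ranks = {p: int(candidates.at[p, "rank"]) for p in recovered}
    return {
        "n_targets": len(targets),
        "n_candidates": len(final),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(targets) if targets else float("nan"),
        "fdr": len(false_hits) / len(final) if final else 0.0,
        "n_decoys_in_candidates": len(final & decoys),
        "target_ranks": dict(sorted(ranks.items())),
    }


def _render_report(config: PipelineConfig, result_calls: pd.DataFrame,
                   tri: TriageResult, atlas: ExpressionAtlas | None,
                   evaluation: dict | None) -> str:
    lines = ["# Surfaceome triage report", ""]
    lines.append("## Parameters")
    for name, obj in (("cohort", config.cohort), ("call", config.call),
                      ("triage", config.triage)):
        if obj is None:
            continue
        fields = ", ".join(f"{f.name}={getattr(obj, f.name)!r}"
                           for f in dataclasses.fields(obj))
        lines.append(f"- {name}: {fields}")
    lines.append(f"- seed: {config.seed}")
    lines += ["", "## Stage waterfall", "", "| stage | surviving proteins |",
              "|---|---|"]
    for stage, count in tri.waterfall:
        lines.append(f"| {stage} | {count} |")
    if tri.unannotated:
        lines.append(f"\nDetected but unannotated (treated as non-membrane): "
                     f"{len(tri.unannotated)}")
    if tri.unresolved_genes:
        lines.append(f"Genes unresolved in the tissue matrix: "
                     f"{len(tri.unresolved_genes)}")
    surv = tri.candidates[tri.candidates["not_excluded"]]
    lines += ["", f"## Top candidates (of {len(surv)})", ""]
    if len(surv):
        cols = ["gene_symbol", "n_pdx_detected", "mean_log2fc", "tau",
                "max_excluded_frac", "known_car_target", "rank_score"]
        head = surv.head(config.top_k)
        lines.append("| rank | " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * (len(cols) + 1))
        for pid, row in head.iterrows():
            cells = [str(int(row["rank"]))] + [
                f"{row[c]:.3f}" if isinstance(row[c], float) else str(row[c])
                for c in cols]
            lines.append("| " + " | ".join(cells) + " |")
        if atlas is not None:
            top_gene = head.iloc[0]["gene_symbol"]
            try:
                dp = dotplot_stats(atlas, top_gene)
                lines += ["", f"### Cell-type profile of top candidate "
                              f"{top_gene}", ""]
                lines.append("| celltype | frac_expressing | mean_expr |")
                lines.append("|---|---|---|")
                for ct, row in dp.iterrows():
                    lines.append(f"| {ct} | {row['frac_expressing']:.3f} | "
                                 f"{row['mean_expr']:.3f} |")
            except KeyError:
                pass
    else:
        lines.append("No candidate survived the cascade.")
    if evaluation is not None:
        lines += ["", "## Evaluation against planted truth", ""]
        for key in ("n_targets", "n_candidates", "n_recovered",
                    "sensitivity", "fdr", "n_decoys_in_candidates"):
            v = evaluation[key]
            lines.append(f"- {key}: "
                         f"{v:.3f}" if isinstance(v, float) else f"- {key}: {v}")
        if evaluation["target_ranks"]:
            ranks = ", ".join(f"{p}:{r}"
                              for p, r in evaluation["target_ranks"].items())
            lines.append(f"- recovered target ranks: {ranks}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run simulate/load -> call-surface -> prioritize -> report.

    Writes ``calls.tsv``, ``candidates.tsv``, ``waterfall.tsv`` and
    ``report.md`` into ``outdir``. Any stage failure removes the partial
    outputs and re-raises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if config.input_dir is not None:
            log.info("loading cohort from %s", config.input_dir)
            tables, annotations, truth = _load_cohort(config.input_dir)
            d = Path(config.input_dir)
            atlas = sio.read_atlas(
                d / "tissue_expression.tsv", d / "celltype_expression.tsv",
                config.triage.lymphoid_tissues,
                config.triage.excluded_celltypes)
        else:
            if config.cohort is None:
                raise ParameterError(
                    "cohort: configuration required when no input_dir is given")
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            log.info("simulating cohort (n_pdx=%d, n_proteins=%d, seed=%d)",
                     cohort_cfg.n_pdx, cohort_cfg.n_proteins, config.seed)
            tables, annotations, atlas, truth = generate_cohort(cohort_cfg)
        config.triage.validate(n_pdx=len(tables))
        config.call.validate(n_biot_runs=len(tables[0].biot_runs))

        log.info("calling surface detection on %d PDX samples", len(tables))
        calls = call_cohort(tables, config.call,
                            seed=config.seed + _CALL_SEED_OFFSET)
        p = outdir / "calls.tsv"
        sio.write_calls(calls, p)
        written.append(p)

        log.info("running triage cascade")
        tri = triage(calls, annotations, atlas, config.triage)
        p = outdir / "candidates.tsv"
        sio.write_candidates(tri.candidates, p)
        written.append(p)
        p = outdir / "waterfall.tsv"
        sio.write_waterfall(tri.waterfall, p)
        written.append(p)

        evaluation = (evaluate_against_truth(tri.candidates, truth)
                      if truth is not None else None)
        report = _render_report(config, calls, tri, atlas, evaluation)
        p = outdir / "report.md"
        p.write_text(report, encoding="utf-8")
        written.append(p)
        log.info("done: %d final candidates", tri.waterfall[-1][1])
        return PipelineResult(tri.candidates, tri.waterfall, calls, report,
                              evaluation)
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
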