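"""End-to-end runs: evaluate a score table, plot figures, mine a corpus.

These functions are thin pipeline wrappers over the library: load/validate
inputs, run the computation, and write tabular/markdown/figure outputs.
Each run is atomic — every output is computed in memory before the first
file is written, so a validation failure leaves no partial results — and
idempotent: rerunning with identical inputs rewrites identical tabular
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .pmc import (
    GradeScale,
    PmcResult,
    ScoreMode,
    evaluate_all,
    group_mean,
    improvement_path,
    variable_means,
)
from .schema import EvaluationSchema, builtin_schema, load_schema
from .scores import ScoreTable, builtin_score_table, read_score_table
from .surface import render_radar, render_surface, surface_matrix
from .textmine import Corpus, build_network, export_network, term_frequencies

__all__ = ["RunConfig", "run_evaluation", "run_plots", "run_mining", "results_frame"]


@dataclass
class RunConfig:
    """Inputs and options for an evaluation/plot run.

    With both paths left ``None`` the bundled smart older-adults-care
    schema and 10-policy score table are used.
    """

    schema_path: str | Path | None = None
    scores_path: str | Path | None = None
    dialect: Literal["long", "wide", "compact"] = "long"
    mode: ScoreMode = "rounded2"
    scale: GradeScale = field(default_factory=GradeScale)
    out_dir: str | Path = "pmc_out"
    group_column: str = "level"
    upsample_factor: int = 10
    interpolation: Literal["bilinear", "bicubic"] = "bilinear"
    cmap: str = "viridis"
    figure_format: Literal["png", "svg"] = "png"

    def load_inputs(self) -> tuple[EvaluationSchema, ScoreTable]:
        if self.schema_path is None and self.scores_path is None:
            schema = builtin_schema()
            return schema, builtin_score_table(schema)
        schema = builtin_schema() if self.schema_path is None else load_schema(self.schema_path)
        if self.scores_path is None:
            table = builtin_score_table(schema)
        else:
            table = read_score_table(Path(self.scores_path), schema, dialect=self.dialect)
        return schema, table


def results_frame(results: Sequence[PmcResult]) -> pd.DataFrame:
    """Results as a tidy frame: policy, X1..Xp, pmc_index, grade, rank."""
    rows = []
    for r in results:
        row: dict[str, object] = {"policy": r.policy}
        for i, s in enumerate(r.primary_scores.scores, start=1):
            row[f"X{i}"] = s
        row.update(pmc_index=r.pmc_index, grade=r.grade, rank=r.rank)
        rows.append(row)
    return pd.DataFrame(rows).set_index("policy")


def run_evaluation(config: RunConfig) -> dict[str, Path]:
    """Evaluate every policy and write score/ranking tables and a report.

    Outputs (all UTF-8, under ``config.out_dir``):

    - ``pmc_scores.csv`` — per-policy primary scores, index, grade, rank
    - ``pmc_ranking.csv`` — index/grade/rank sorted by rank
    - ``pmc_results.json`` — the same content plus means, group means and
      improvement paths
    - ``pmc_report.md`` — human-readable summary
    """
    schema, table = config.load_inputs()
    results = evaluate_all(table, mode=config.mode, scale=config.scale)
    means = variable_means(results)
    overall = group_mean(results, [r.policy for r in results])
    frame = results_frame(results)

    group_means: dict[str, float] = {}
    if table.metadata is not None and config.group_column in table.metadata.columns:
        for level, members in table.metadata.groupby(config.group_column).groups.items():
            group_means[str(level)] = group_mean(results, list(members))

    paths = {
        r.policy: [f"X{i}" for i in improvement_path(r, means)] for r in results
    }

    payload = {
        "schema": schema.name,
        "mode": config.mode,
        "results": json.loads(frame.reset_index().to_json(orient="records")),
        "variable_means": {f"X{i}": m for i, m in enumerate(means, start=1)},
        "mean_pmc_index": overall,
        "group_means": group_means,
        "improvement_paths": paths,
    }
    report_md = _markdown_report(payload, results)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {
        "scores_csv": out / "pmc_scores.csv",
        "ranking_csv": out / "pmc_ranking.csv",
        "results_json": out / "pmc_results.json",
        "report_md": out / "pmc_report.md",
    }
    frame.to_csv(written["scores_csv"])
    ranking = frame[["pmc_index", "grade", "rank"]].sort_values("rank")
    ranking.to_csv(written["ranking_csv"])
    written["results_json"].write_text(
        json.dumps(payload, ensure_ascii=False, indent=2) + "\n", encoding="utf-8"
    )
    written["report_md"].write_text(report_md, encoding="utf-8")
    return written


def _markdown_report(payload: dict, results: Sequence[PmcResult]) -> str:
    lines = ["# PMC evaluation report", ""]
    lines.append(f"Mode: `{payload['mode']}` — mean PMC index **{payload['mean_pmc_index']:.2f}**")
    lines.append("")
    lines.append("| Policy | PMC index | Grade | Rank |")
    lines.append("| --- | --- | --- | --- |")
    for r in sorted(results, key=lambda r: r.rank):
        lines.append(f"| {r.policy} | {r.pmc_index:.2f} | {r.grade} | {r.rank} |")
    lines.append("")
    lines.append("## Variable means")
    lines.append("")
    means = payload["variable_means"]
    lines.append("| " + " | ".join(means) + " |")
    lines.append("| " + " | ".join("---" for _ in means) + " |")
    lines.append("| " + " | ".join(f"{v:.2f}" for v in means.values()) + " |")
    if payload["group_means"]:
        lines.append("")
        lines.append("## Group means")
        lines.append("")
        for group, value in sorted(payload["group_means"].items()):
            lines.append(f"- {group}: {value:.2f}")
    lines.append("")
    lines.append("## Improvement paths (below-mean dimensions, largest gap first)")
    lines.append("")
    for policy, path in payload["improvement_paths"].items():
        arrow = " -> ".join(path) if path else "(none: at or above the mean everywhere)"
        lines.append(f"- {policy}: {arrow}")
    lines.append("")
    return "\n".join(lines)


def run_plots(config: RunConfig) -> dict[str, Path]:
    """Render one surface figure per policy plus one radar chart."""
    _, table = config.load_inputs()
    results = evaluate_all(table, mode=config.mode, scale=config.scale)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for r in results:
        target = out / f"surface_{r.policy}.{config.figure_format}"
        render_surface(
            surface_matrix(r.primary_scores),
            target,
            factor=config.upsample_factor,
            method=config.interpolation,
            cmap=config.cmap,
            title=f"{r.policy} (PMC {r.pmc_index:.2f})",
        )
        written[f"surface_{r.policy}"] = target
    radar = out / f"radar.{config.figure_format}"
    render_radar(results, radar)
    written["radar"] = radar
    return written


def run_mining(
    corpus: Corpus,
    out_dir: str | Path,
    stopwords: Iterable[str] = (),
    top_n: int = 50,
) -> dict[str, Path]:
    """Write term-frequency CSV and the co-occurrence network edge list."""
    stopwords = frozenset(stopwords)
    freqs = term_frequencies(corpus, stopwords)
    network = build_network(corpus, stopwords, top_n=top_n)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {
        "term_frequencies": out / "term_frequencies.csv",
        "network_edgelist": out / "network_edgelist.tsv",
        "network_graphml": out / "network.graphml",
    }
    freq_frame = pd.DataFrame(
        sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["term", "count"],
    )
    freq_frame.to_csv(written["term_frequencies"], index=False)
    export_network(network, written["network_edgelist"], format="edge-list")
    export_network(network, written["network_graphml"], format="graphml")
    return written
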