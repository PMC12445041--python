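"""End-to-end pipeline orchestration and run manifests.

Stages run in a fixed order -- preprocess, QC, scaling, essentiality, GI
scoring, context analyses -- each writing its output as TSV under the run's
output directory, with a JSON manifest recording the configuration, seed and
per-stage record counts so that any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .context import anova_by_cancer_type, hit_frequency_analysis, rank_hits_per_line
from .essentiality import call_essentiality
from .gi import HitCallConfig, score_screen, summarize_pairs
from .library import ROLE_SCREEN, read_counts, read_library, read_samples
from .preprocess import PreprocessConfig, preprocess
from .qc import QCThresholds, apply_exclusions, qc_screen
from .scaling import scale_lfc

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_QC_EMPTY = 4


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an exit code."""

    def __init__(self, stage: str, code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    library: str = ""
    counts: str = ""
    samples: str = ""
    expression: str | None = None
    excluded_constructs: str | None = None
    outdir: str = "slscreen_out"
    seed: int = 0
    scaling_per: str = "sample"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    hits: HitCallConfig = field(default_factory=HitCallConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for name, sub in (
            ("preprocess", PreprocessConfig),
            ("qc", QCThresholds),
            ("hits", HitCallConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                if name == "preprocess" and "excluded_constructs" in kwargs[name]:
                    kwargs[name]["excluded_constructs"] = tuple(
                        kwargs[name]["excluded_constructs"]
                    )
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_excluded_constructs(path: str | Path) -> tuple[str, ...]:
    """One construct id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages, writing TSVs and a manifest to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {"slscreen": __version__, "python": platform.python_version()},
        "stages": {},
    }
    results: dict[str, pd.DataFrame] = {}

    try:
        library = read_library(config.library)
        samples = read_samples(config.samples)
        counts = read_counts(config.counts, library, samples)
    except FileNotFoundError as exc:
        raise StageError("load", EXIT_DATA_ERROR, str(exc)) from exc
    except ValueError as exc:
        raise StageError("load", EXIT_DATA_ERROR, str(exc)) from exc

    pre_config = config.preprocess
    if config.excluded_constructs:
        pre_config = dataclasses.replace(
            pre_config, excluded_constructs=read_excluded_constructs(config.excluded_constructs)
        )

    try:
        pre = preprocess(counts, pre_config)
    except ValueError as exc:
        raise StageError("preprocess", EXIT_DATA_ERROR, str(exc)) from exc
    results["lfc"] = pre.lfc
    _write(pre.lfc.rename_axis("construct_id"), outdir / "lfc.tsv", index=True)
    manifest["stages"]["preprocess"] = {
        "constructs_retained": len(pre.retained_constructs),
        "constructs_excluded": len(counts.counts) - len(pre.retained_constructs),
    }

    try:
        report = qc_screen(pre.lfc, counts.counts, library, samples, config.qc)
        retained, dropped_lines = apply_exclusions(report)
    except ValueError as exc:
        raise StageError("qc", EXIT_DATA_ERROR, str(exc)) from exc
    results["qc"] = report
    _write(report, outdir / "qc_report.tsv")
    (outdir / "excluded_samples.txt").write_text(
        "\n".join(sorted(set(report.index) - set(retained))) + "\n"
    )
    manifest["stages"]["qc"] = {
        "samples_retained": len(retained),
        "lines_dropped": dropped_lines,
    }
    if not retained:
        raise StageError("qc", EXIT_QC_EMPTY, "all screen samples excluded by QC")

    try:
        scaled, anchors = scale_lfc(
            pre.lfc[retained], library, samples, per=config.scaling_per
        )
    except ValueError as exc:
        raise StageError("scaling", EXIT_DATA_ERROR, str(exc)) from exc
    results["scaled"] = scaled
    _write(scaled.rename_axis("construct_id"), outdir / "scaled_lfc.tsv", index=True)
    _write(anchors.rename_axis("sample_id"), outdir / "scaling_anchors.tsv", index=True)

    try:
        ess = call_essentiality(scaled, library, samples)
    except ValueError as exc:
        raise StageError("essentiality", EXIT_DATA_ERROR, str(exc)) from exc
    results["essentiality"] = ess
    _write(ess, outdir / "essentiality.tsv")
    manifest["stages"]["essentiality"] = {
        "genes_scored": int(ess["testable"].sum()),
        "essential_calls": int(ess["essential"].sum()),
    }

    try:
        pair_results = score_screen(scaled, library, samples, config.hits, ess)
    except ValueError as exc:
        raise StageError("gi_scoring", EXIT_DATA_ERROR, str(exc)) from exc
    results["pair_results"] = pair_results
    _write(pair_results, outdir / "pair_results.tsv")
    summary = summarize_pairs(pair_results)
    results["pair_summary"] = summary
    _write(summary.rename_axis("gene_pair"), outdir / "pair_summary.tsv", index=True)
    manifest["stages"]["gi_scoring"] = {
        "pair_line_tests": len(pair_results),
        "hits": int(pair_results["hit"].sum()),
    }

    try:
        lineage = samples[samples["role"] == ROLE_SCREEN].drop_duplicates("cell_line")
        lineage = lineage.set_index("cell_line")["lineage"]
        anova = anova_by_cancer_type(pair_results, lineage)
        freq_table, freq_r, freq_p = hit_frequency_analysis(pair_results)
        ranks = rank_hits_per_line(pair_results)
    except ValueError as exc:
        raise StageError("context", EXIT_DATA_ERROR, str(exc)) from exc
    results["anova"] = anova
    results["hit_frequency"] = freq_table
    results["ranks"] = ranks
    _write(anova, outdir / "context_anova.tsv")
    _write(freq_table.rename_axis("gene_pair"), outdir / "hit_frequency.tsv", index=True)
    _write(ranks, outdir / "hit_ranks.tsv")
    manifest["stages"]["context"] = {
        "anova_pairs": len(anova),
        "hit_gi_vs_frequency_r": None if pd.isna(freq_r) else freq_r,
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results


def summarize(results: dict[str, pd.DataFrame]) -> dict[str, Any]:
    """Run-level summary: per-line hit counts and the pair partition."""
    pair_results = results.get("pair_results")
    if pair_results is None or pair_results.empty:
        return {
            "hits_per_line": {},
            "n_pairs": 0,
            "strong_hits": 0,
            "context_dependent": 0,
            "never_hit": 0,
        }
    summary = results.get("pair_summary")
    if summary is None:
        summary = summarize_pairs(pair_results)
    return {
        "hits_per_line": pair_results.groupby("cell_line")["hit"].sum().astype(int).to_dict(),
        "n_pairs": int(len(summary)),
        "strong_hits": int(summary["strong_hit"].sum()),
        "context_dependent": int(summary["context_dependent"].sum()),
        "never_hit": int(summary["never_hit"].sum()),
    }
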