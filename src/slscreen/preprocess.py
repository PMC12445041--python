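"""Counts normalisation, low-count filtering and log2 fold changes.

Normalisation follows the screen's quantification convention: after dropping
any user-flagged artefact constructs, each raw count gets a pseudocount of 5,
is divided by the per-sample total of raw mapped reads (computed after the
exclusion), and multiplied by a 10-million scale factor, i.e. reads per 10M.
Constructs below 20 reads-per-10M in *every* control sample are removed, and
log2 fold changes are taken against the mean normalised count of each screen
sample's mapped control (early-timepoint, Cas9-null) samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import CountsMatrix, ROLE_CONTROL, ROLE_SCREEN


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    pseudocount: int = 5
    scale_factor: float = 1e7
    low_count_threshold: float = 20.0
    excluded_constructs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise PreprocessError("pseudocount must be >= 0")
        if self.scale_factor <= 0:
            raise PreprocessError("scale_factor must be > 0")


@dataclass
class PreprocessResult:
    """Normalised counts, surviving constructs and the LFC matrix."""

    normalised: pd.DataFrame
    retained_constructs: pd.Index
    lfc: pd.DataFrame
    control_map: dict[str, list[str]] = field(repr=False)


def normalize_counts(counts: CountsMatrix, config: PreprocessConfig) -> pd.DataFrame:
    """(raw + pseudocount) / per-sample raw total x scale_factor, exclusions first."""
    raw = counts.counts
    drop = [c for c in config.excluded_constructs if c in raw.index]
    raw = raw.drop(index=drop)
    totals = raw.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise PreprocessError(f"samples with zero total reads: {zero}")
    return (raw + config.pseudocount) / totals * config.scale_factor


def filter_low_counts(
    normalised: pd.DataFrame,
    control_sample_ids: Sequence[str],
    config: PreprocessConfig,
) -> pd.Index:
    """Retain constructs unless below threshold in every control sample."""
    controls = list(control_sample_ids)
    if not controls:
        raise PreprocessError("low-count filter needs at least one control sample")
    removed = (normalised[controls] < config.low_count_threshold).all(axis=1)
    return normalised.index[~removed]


def lineage_control_map(
    samples: pd.DataFrame,
    override: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Map each screen sample to its control samples, lineage-matched by default.

    ``override`` maps cell-line names to explicit control sample-id lists and
    takes precedence over lineage matching for those lines.
    """
    controls = samples[samples["role"] == ROLE_CONTROL]
    out: dict[str, list[str]] = {}
    unresolved = []
    for sid, row in samples[samples["role"] == ROLE_SCREEN].iterrows():
        if override and row["cell_line"] in override:
            mapped = list(override[row["cell_line"]])
        else:
            mapped = controls.index[controls["lineage"] == row["lineage"]].tolist()
        if not mapped:
            unresolved.append(sid)
        out[sid] = mapped
    if unresolved:
        raise PreprocessError(
            f"no control samples resolve for screen sample(s): {unresolved}"
        )
    return out


def log2_fold_change(
    normalised: pd.DataFrame,
    samples: pd.DataFrame,
    control_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """LFC(c, s) = log2(norm(c, s)) - log2(mean over mapped controls of norm(c, .))."""
    cols = {}
    for sid, ctrl_ids in control_map.items():
        if not ctrl_ids:
            raise PreprocessError(f"screen sample {sid!r} has no mapped controls")
        baseline = normalised[list(ctrl_ids)].mean(axis=1)
        cols[sid] = np.log2(normalised[sid]) - np.log2(baseline)
    return pd.DataFrame(cols, index=normalised.index)


def preprocess(
    counts: CountsMatrix,
    config: PreprocessConfig | None = None,
    control_override: Mapping[str, Sequence[str]] | None = None,
) -> PreprocessResult:
    """Normalise, low-count filter, and compute LFCs versus mapped controls."""
    config = config or PreprocessConfig()
    normalised = normalize_counts(counts, config)
    retained = filter_low_counts(normalised, counts.control_sample_ids(), config)
    normalised = normalised.loc[retained]
    cmap = lineage_control_map(counts.samples, control_override)
    lfc = log2_fold_change(normalised, counts.samples, cmap)
    return PreprocessResult(
        normalised=normalised, retained_constructs=retained, lfc=lfc, control_map=cmap
    )
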