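"""Per-replicate screen quality control and sample exclusion.

Replicate quality is gated on two metrics computed on unscaled LFCs:

* NNMD, the null-normalised mean difference (muE - muNE) / sigmaNE between the
  essential-control and non-essential-control single constructs -- more
  negative means better separation of true depletion from the null;
* the mean Spearman rank correlation of a replicate against its sibling
  replicates of the same cell line.

A replicate is excluded iff NNMD > -2 or R < 0.55 (strict inequalities).
The Gini index of raw counts is reported descriptively (library skew).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library import (
    CLASS_ESSENTIAL,
    CLASS_NON_ESSENTIAL,
    LibraryAnnotation,
    ROLE_SCREEN,
)


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    nnmd_max: float = -2.0
    min_spearman: float = 0.55


def nnmd(
    lfc_sample: pd.Series,
    essential_single_ids: Sequence[str],
    nonessential_single_ids: Sequence[str],
) -> float:
    """(muE - muNE) / sigmaNE with sample (n-1) standard deviation."""
    ess = lfc_sample.reindex(essential_single_ids).dropna()
    non = lfc_sample.reindex(nonessential_single_ids).dropna()
    if ess.empty or non.empty:
        raise QCError("NNMD needs non-empty essential and non-essential control sets")
    sigma = non.std(ddof=1)
    if not np.isfinite(sigma) or sigma == 0:
        raise QCError("degenerate controls: sigma of non-essential singles is zero")
    return float((ess.mean() - non.mean()) / sigma)


def replicate_correlation(lfc: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Per screen sample, mean Spearman rho against sibling replicates.

    Samples from single-replicate lines get NaN (undefined, not failed).
    """
    screen = samples[samples["role"] == ROLE_SCREEN]
    out = {}
    for sid in lfc.columns:
        line = screen.loc[sid, "cell_line"]
        siblings = [
            s for s in screen.index[screen["cell_line"] == line] if s != sid and s in lfc
        ]
        if not siblings:
            out[sid] = np.nan
            continue
        rhos = [stats.spearmanr(lfc[sid], lfc[s]).statistic for s in siblings]
        out[sid] = float(np.mean(rhos))
    return pd.Series(out, name="spearman_r")


def gini_index(raw_counts_sample: pd.Series | np.ndarray) -> float:
    """Gini coefficient of the count distribution: 0 = uniform, (n-1)/n = one spike."""
    x = np.sort(np.asarray(raw_counts_sample, dtype=float))
    if (x < 0).any():
        raise QCError("Gini index requires non-negative counts")
    total = x.sum()
    if total == 0:
        raise QCError("Gini index undefined for an all-zero sample")
    n = len(x)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def qc_screen(
    lfc: pd.DataFrame,
    raw_counts: pd.DataFrame,
    library: LibraryAnnotation,
    samples: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-screen-sample QC report: nnmd, spearman_r, gini, pass flag, reason."""
    thresholds = thresholds or QCThresholds()
    ess_ids = library.control_single_ids(CLASS_ESSENTIAL)
    non_ids = library.control_single_ids(CLASS_NON_ESSENTIAL)
    spearman = replicate_correlation(lfc, samples)

    rows = []
    for sid in lfc.columns:
        sample_nnmd = nnmd(lfc[sid], ess_ids, non_ids)
        r = spearman[sid]
        gini = gini_index(raw_counts[sid]) if sid in raw_counts else np.nan
        reasons = []
        if sample_nnmd > thresholds.nnmd_max:
            reasons.append(f"NNMD {sample_nnmd:.3f} > {thresholds.nnmd_max}")
        if not np.isnan(r) and r < thresholds.min_spearman:
            reasons.append(f"R {r:.3f} < {thresholds.min_spearman}")
        rows.append(
            {
                "sample_id": sid,
                "cell_line": samples.loc[sid, "cell_line"],
                "nnmd": sample_nnmd,
                "spearman_r": r,
                "gini": gini,
                "passed": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id", drop=False)
    report.index.name = None
    return report


def apply_exclusions(qc_report: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Retained screen sample ids and cell lines dropped entirely.

    Idempotent: re-running on the already-filtered report changes nothing.
    """
    retained = qc_report.index[qc_report["passed"]].tolist()
    by_line = qc_report.groupby("cell_line")["passed"].any()
    dropped_lines = by_line.index[~by_line].tolist()
    return retained, dropped_lines
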