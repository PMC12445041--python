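"""Control-anchored scaling of log2 fold changes.

Each sample's LFC vector is mapped by the affine transform that puts the
median of the safe|safe constructs at 0 and the median of the essential-control
single constructs at -1, giving every screen a common, interpretable axis
(0 = cutting-only toxicity, -1 = essential-gene depletion magnitude).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .library import CLASS_ESSENTIAL, LibraryAnnotation


class ScalingError(ValueError):
    pass


def scale_sample(
    lfc_sample: pd.Series,
    safe_safe_ids: Sequence[str],
    essential_single_ids: Sequence[str],
) -> tuple[pd.Series, float, float]:
    """Anchor one sample: returns (scaled vector, median_safe_safe, median_essential).

    scaled(x) = (x - m_ss) / (m_ss - m_se); order-preserving and affine, so
    rank statistics are unchanged.
    """
    ss = lfc_sample.reindex(safe_safe_ids).dropna()
    se = lfc_sample.reindex(essential_single_ids).dropna()
    if ss.empty or se.empty:
        raise ScalingError("both anchor sets (safe|safe, essential singles) required")
    m_ss = float(ss.median())
    m_se = float(se.median())
    if m_se >= m_ss:
        raise ScalingError(
            f"inverted or null screen signal: median essential singles ({m_se:.3f}) "
            f">= median safe|safe ({m_ss:.3f})"
        )
    return (lfc_sample - m_ss) / (m_ss - m_se), m_ss, m_se


def scale_lfc(
    lfc: pd.DataFrame,
    library: LibraryAnnotation,
    samples: pd.DataFrame | None = None,
    per: str = "sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale every screen sample; returns (scaled matrix, per-sample anchors).

    ``per='sample'`` (default) anchors each replicate on its own medians;
    ``per='line'`` pools a cell line's replicates to estimate shared anchors
    and applies the same affine map to each of its samples.
    """
    safe_ids = [c for c in library.safe_safes().index if c in lfc.index]
    ess_ids = [
        c for c in library.control_single_ids(CLASS_ESSENTIAL) if c in lfc.index
    ]
    scaled = {}
    anchors = []
    if per == "sample":
        for sid in lfc.columns:
            scaled[sid], m_ss, m_se = scale_sample(lfc[sid], safe_ids, ess_ids)
            anchors.append((sid, m_ss, m_se))
    elif per == "line":
        if samples is None:
            raise ScalingError("per='line' scaling needs sample metadata")
        for line, group in samples.loc[list(lfc.columns)].groupby("cell_line"):
            sids = [s for s in group.index if s in lfc.columns]
            pooled_ss = lfc.loc[safe_ids, sids].to_numpy().ravel()
            pooled_se = lfc.loc[ess_ids, sids].to_numpy().ravel()
            m_ss = float(pd.Series(pooled_ss).median())
            m_se = float(pd.Series(pooled_se).median())
            if m_se >= m_ss:
                raise ScalingError(f"inverted anchors for cell line {line!r}")
            for sid in sids:
                scaled[sid] = (lfc[sid] - m_ss) / (m_ss - m_se)
                anchors.append((sid, m_ss, m_se))
    else:
        raise ScalingError("per must be 'sample' or 'line'")
    anchor_df = pd.DataFrame(
        anchors, columns=["sample_id", "median_safe_safe", "median_single_essential"]
    ).set_index("sample_id")
    return pd.DataFrame(scaled, index=lfc.index)[list(lfc.columns)], anchor_df
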