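"""Data model and I/O for dual-guide CRISPR libraries, counts and sample metadata.

A dual-guide library is a catalogue of constructs, each expressing two gRNAs
from tandem promoters (position A = first promoter, position B = second).
Constructs fall into three categories:

* ``dual`` -- both guides target genes; these measure the combined knockout.
* ``single`` -- one gene-targeting guide paired with a safe-targeting control;
  these measure single-gene knockout fitness.
* ``safe_safe`` -- both guides safe-targeting; these control for the fitness
  cost of double-strand breaks alone.

Safe-targeting guides cut intergenic sites with no known function and are
encoded in the gene columns by the reserved token ``SAFE`` (case-insensitive;
extra aliases may be supplied for libraries that use named safe guides).

All tables are tab-separated UTF-8 text with a header row; the construct order
of the library file is authoritative for every downstream matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SAFE = "SAFE"
DEFAULT_SAFE_ALIASES: tuple[str, ...] = ("SAFE", "SAFE_TARGETING", "SAFETARGETING")

POSITION_A = "A"
POSITION_B = "B"

CATEGORY_DUAL = "dual"
CATEGORY_SINGLE = "single"
CATEGORY_SAFE_SAFE = "safe_safe"
CATEGORIES = (CATEGORY_DUAL, CATEGORY_SINGLE, CATEGORY_SAFE_SAFE)

CLASS_ESSENTIAL = "essential"
CLASS_NON_ESSENTIAL = "non_essential"
CLASS_LIBRARY = "library"
CLASS_SAFE = "safe"
CONTROL_CLASSES = frozenset(
    {CLASS_ESSENTIAL, CLASS_NON_ESSENTIAL, CLASS_LIBRARY, CLASS_SAFE}
)

ROLE_CONTROL = "CONTROL"
ROLE_SCREEN = "SCREEN"
LINEAGES = frozenset({"melanoma", "lung", "pancreas", "other"})

LIBRARY_COLUMNS = [
    "construct_id",
    "guide_a_id",
    "gene_a",
    "guide_b_id",
    "gene_b",
    "control_class",
]
SAMPLE_COLUMNS = ["sample_id", "cell_line", "lineage", "replicate", "role", "day"]


class LibraryError(ValueError):
    """Raised for malformed library, counts or sample-metadata inputs."""


@dataclass(frozen=True)
class GuideRef:
    """A single gRNA with its target gene (or ``SAFE``) and promoter position."""

    guide_id: str
    gene: str
    position: str

    @property
    def is_safe(self) -> bool:
        return self.gene == SAFE


@dataclass(frozen=True)
class Construct:
    construct_id: str
    guide_a: GuideRef
    guide_b: GuideRef
    category: str
    control_class: str


def normalise_gene(gene: object, safe_aliases: Iterable[str] = DEFAULT_SAFE_ALIASES) -> str:
    """Map any safe-token alias to the canonical ``SAFE`` sentinel."""
    text = str(gene).strip()
    if text.upper() in {a.upper() for a in safe_aliases}:
        return SAFE
    return text


def derive_category(gene_a: str, gene_b: str) -> str:
    a_safe = gene_a == SAFE
    b_safe = gene_b == SAFE
    if a_safe and b_safe:
        return CATEGORY_SAFE_SAFE
    if a_safe or b_safe:
        return CATEGORY_SINGLE
    return CATEGORY_DUAL


def pair_id(gene_x: str, gene_y: str) -> str:
    """Canonical unordered gene-pair key (sorted, pipe-joined)."""
    return "|".join(sorted((gene_x, gene_y)))


class LibraryAnnotation:
    """The construct catalogue with derived categories and gene-pair index.

    Parameters
    ----------
    frame
        DataFrame with :data:`LIBRARY_COLUMNS`; gene columns must already use
        the ``SAFE`` sentinel. Row order is preserved and authoritative.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
        if missing:
            raise LibraryError(f"library table missing columns: {missing}")
        frame = frame.loc[:, LIBRARY_COLUMNS].copy()
        frame = frame.astype(str)

        dup = frame["construct_id"][frame["construct_id"].duplicated()]
        if len(dup):
            raise LibraryError(
                f"duplicate construct_id values: {sorted(dup.unique())[:10]}"
            )
        bad = ~frame["control_class"].isin(CONTROL_CLASSES)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = line 1
            token = frame.loc[bad, "control_class"].iloc[0]
            raise LibraryError(
                f"unknown control_class {token!r} at line {line} of library table"
            )

        frame["category"] = [
            derive_category(a, b) for a, b in zip(frame["gene_a"], frame["gene_b"])
        ]
        ctrl_on_non_single = frame["control_class"].isin(
            [CLASS_ESSENTIAL, CLASS_NON_ESSENTIAL]
        ) & (frame["category"] != CATEGORY_SINGLE)
        if ctrl_on_non_single.any():
            offenders = frame.loc[ctrl_on_non_single, "construct_id"].tolist()[:5]
            raise LibraryError(
                "essential/non_essential control classes are only valid on single "
                f"constructs; offenders: {offenders}"
            )
        frame = frame.set_index("construct_id", drop=False)
        frame.index.name = None
        self.frame = frame
        self.gene_pairs = self._build_gene_pairs()
        self._warn_duals_without_singles()

    # -- derived views ----------------------------------------------------

    def _build_gene_pairs(self) -> dict[str, list[str]]:
        pairs: dict[str, list[str]] = {}
        duals = self.frame[self.frame["category"] == CATEGORY_DUAL]
        for cid, ga, gb in zip(duals["construct_id"], duals["gene_a"], duals["gene_b"]):
            pairs.setdefault(pair_id(ga, gb), []).append(cid)
        return pairs

    def _warn_duals_without_singles(self) -> None:
        single_genes = set(self.single_gene_of(self.singles().index))
        dual_genes = set(self.dual_genes())
        orphans = sorted(dual_genes - single_genes)
        if orphans:
            warnings.warn(
                f"{len(orphans)} dual-construct gene(s) have no single construct: "
                f"{orphans[:10]}",
                stacklevel=2,
            )

    def duals(self) -> pd.DataFrame:
        return self.frame[self.frame["category"] == CATEGORY_DUAL]

    def singles(self) -> pd.DataFrame:
        return self.frame[self.frame["category"] == CATEGORY_SINGLE]

    def safe_safes(self) -> pd.DataFrame:
        return self.frame[self.frame["category"] == CATEGORY_SAFE_SAFE]

    def dual_genes(self) -> list[str]:
        duals = self.duals()
        return sorted(set(duals["gene_a"]) | set(duals["gene_b"]))

    def single_gene_of(self, construct_ids: Sequence[str]) -> pd.Series:
        """For single constructs, the gene-targeting member's gene symbol."""
        sub = self.frame.loc[list(construct_ids)]
        return sub["gene_a"].where(sub["gene_a"] != SAFE, sub["gene_b"])

    def singles_for_gene(self, gene: str) -> pd.DataFrame:
        singles = self.singles()
        mask = (singles["gene_a"] == gene) | (singles["gene_b"] == gene)
        return singles[mask]

    def control_single_ids(self, control_class: str) -> list[str]:
        singles = self.singles()
        return singles.index[singles["control_class"] == control_class].tolist()

    def construct(self, construct_id: str) -> Construct:
        row = self.frame.loc[construct_id]
        return Construct(
            construct_id=construct_id,
            guide_a=GuideRef(row["guide_a_id"], row["gene_a"], POSITION_A),
            guide_b=GuideRef(row["guide_b_id"], row["gene_b"], POSITION_B),
            category=row["category"],
            control_class=row["control_class"],
        )

    def classify_pair_constructs(self, gene_x: str, gene_y: str) -> dict[str, list[str]]:
        """Partition the library's constructs relevant to an unordered gene pair.

        Returns dual constructs in both orientations, the position-annotated
        single constructs of each member, and all safe|safe constructs. A gene
        absent from the library yields empty partitions with a warning.
        """
        if gene_x == gene_y:
            raise LibraryError("gene pair members must differ")
        out = {
            "duals": self.gene_pairs.get(pair_id(gene_x, gene_y), []),
            "singles_x": self.singles_for_gene(gene_x).index.tolist(),
            "singles_y": self.singles_for_gene(gene_y).index.tolist(),
            "safe_safes": self.safe_safes().index.tolist(),
        }
        known = set(self.frame["gene_a"]) | set(self.frame["gene_b"])
        for gene in (gene_x, gene_y):
            if gene not in known:
                warnings.warn(f"gene {gene!r} not present in library", stacklevel=2)
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def write(self, path: str | Path) -> None:
        self.frame.loc[:, LIBRARY_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class CountsMatrix:
    """Raw integer read counts (constructs x samples) with annotations."""

    counts: pd.DataFrame
    library: LibraryAnnotation
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise LibraryError("counts matrix contains negative entries")

    def screen_sample_ids(self) -> list[str]:
        return self.samples.index[self.samples["role"] == ROLE_SCREEN].tolist()

    def control_sample_ids(self) -> list[str]:
        return self.samples.index[self.samples["role"] == ROLE_CONTROL].tolist()


# -- I/O ------------------------------------------------------------------


def read_library(
    path: str | Path, safe_aliases: Iterable[str] = DEFAULT_SAFE_ALIASES
) -> LibraryAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise LibraryError(f"{path}: missing columns {missing}")
    for col in ("gene_a", "gene_b"):
        frame[col] = [normalise_gene(g, safe_aliases) for g in frame[col]]
    return LibraryAnnotation(frame)


def read_samples(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise LibraryError(f"{path}: sample metadata missing columns {missing}")
    meta = meta.loc[:, SAMPLE_COLUMNS].copy()
    meta["role"] = meta["role"].str.upper()
    meta["lineage"] = meta["lineage"].str.lower()
    meta["replicate"] = meta["replicate"].astype(int)
    meta["day"] = meta["day"].astype(int)
    return validate_samples(meta)


def validate_samples(meta: pd.DataFrame) -> pd.DataFrame:
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise LibraryError(f"duplicate sample_id values: {sorted(dup.unique())}")
    bad_role = ~meta["role"].isin([ROLE_CONTROL, ROLE_SCREEN])
    if bad_role.any():
        raise LibraryError(
            f"unknown sample role(s): {sorted(meta.loc[bad_role, 'role'].unique())}"
        )
    bad_lin = ~meta["lineage"].isin(LINEAGES)
    if bad_lin.any():
        raise LibraryError(
            f"unknown lineage(s): {sorted(meta.loc[bad_lin, 'lineage'].unique())}"
        )
    if (meta["replicate"] < 1).any():
        raise LibraryError("replicate numbers must be >= 1")
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    return meta


def read_counts(
    path: str | Path,
    library: LibraryAnnotation,
    samples: pd.DataFrame | str | Path,
) -> CountsMatrix:
    """Load a constructs x samples counts TSV, validated against library and metadata.

    The first column must be ``construct_id``; remaining columns must match the
    sample metadata ids exactly. Counts must be non-negative integers; missing
    cells are an error (never silently zero-filled).
    """
    if not isinstance(samples, pd.DataFrame):
        samples = read_samples(samples)
    raw = pd.read_csv(path, sep="\t", index_col=0)

    extra = sorted(set(raw.columns) - set(samples.index))
    absent = sorted(set(samples.index) - set(raw.columns))
    if extra or absent:
        raise LibraryError(
            f"{path}: sample mismatch; in counts but not metadata: {extra}; "
            f"in metadata but not counts: {absent}"
        )
    missing_rows = sorted(set(library.frame.index) - set(raw.index))
    extra_rows = sorted(set(raw.index) - set(library.frame.index))
    if missing_rows or extra_rows:
        raise LibraryError(
            f"{path}: construct mismatch with library; missing: {missing_rows[:5]}; "
            f"unknown: {extra_rows[:5]}"
        )
    if raw.isna().to_numpy().any():
        raise LibraryError(f"{path}: counts matrix contains missing cells")
    values = raw.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise LibraryError(f"{path}: counts must be integers")
    counts = raw.loc[library.frame.index, list(samples.index)].astype(np.int64)
    return CountsMatrix(counts=counts, library=library, samples=samples)


def write_counts(counts: CountsMatrix, path: str | Path) -> None:
    out = counts.counts.copy()
    out.insert(0, "construct_id", out.index)
    out.to_csv(path, sep="\t", index=False)
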