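"""Tabular I/O and validation for replicated time-course expression data.

All files are plain TSV with a header row and '.' as the decimal separator:

* expression matrix — probe IDs in the first column, one column per array;
* design table — ``sample_id``, ``timepoint`` (0-based, contiguous
  integers), ``replicate`` (1-based within a time point);
* annotation table — ``probe_id``, ``gene_symbol``; an empty symbol marks a
  probe that cannot be annotated to a gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseDesign",
    "read_expression",
    "read_design",
    "read_annotation",
    "write_expression",
    "write_design",
    "write_annotation",
]


@dataclass(frozen=True)
class TimeCourseDesign:
    """Sample layout of a replicated time course.

    ``frame`` is indexed by sample ID and carries integer columns
    ``timepoint`` and ``replicate``.  Time points must form a contiguous
    ordered set of integers (e.g. weeks 0..5); replication per time point is
    what later makes the per-probe significance filter possible.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("timepoint", "replicate"):
            if col not in f.columns:
                raise ValueError(f"design table lacks required column {col!r}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in design: {dups}")
        tps = np.sort(pd.unique(f["timepoint"].to_numpy()))
        if not np.issubdtype(np.asarray(tps).dtype, np.integer):
            raise ValueError("timepoint column must be integer-coded")
        if not np.array_equal(tps, np.arange(tps.min(), tps.min() + tps.size)):
            raise ValueError(
                f"time points must form a contiguous ordered set, got {tps.tolist()}"
            )

    @classmethod
    def from_layout(
        cls, n_timepoints: int, n_replicates: int, prefix: str = "wk"
    ) -> "TimeCourseDesign":
        """Balanced design with samples named ``<prefix><t>_r<r>``."""
        rows = [
            (f"{prefix}{t}_r{r}", t, r)
            for t in range(n_timepoints)
            for r in range(1, n_replicates + 1)
        ]
        frame = pd.DataFrame(rows, columns=["sample_id", "timepoint", "replicate"])
        return cls(frame.set_index("sample_id"))

    # -- introspection -----------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(pd.unique(self.frame["timepoint"].to_numpy()))

    @property
    def n_timepoints(self) -> int:
        return int(self.timepoints.size)

    @property
    def min_replicates(self) -> int:
        return int(self.frame.groupby("timepoint").size().min())

    def samples_at(self, timepoint: int) -> list[str]:
        mask = self.frame["timepoint"] == timepoint
        return self.frame.index[mask].tolist()

    def timepoint_of(self) -> pd.Series:
        """Series mapping sample ID -> time point."""
        return self.frame["timepoint"]

    def validate_matrix(self, em: pd.DataFrame) -> None:
        """Check that matrix columns and design samples coincide exactly."""
        matrix_samples = set(em.columns)
        design_samples = set(self.frame.index)
        missing = sorted(design_samples - matrix_samples)
        if missing:
            raise ValueError(
                f"design sample(s) absent from expression matrix: {missing}"
            )
        extra = sorted(matrix_samples - design_samples)
        if extra:
            raise ValueError(
                f"expression matrix column(s) absent from design: {extra}"
            )


def _validate_expression(em: pd.DataFrame, name: str = "expression matrix") -> None:
    if em.index.has_duplicates:
        dups = em.index[em.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate probe IDs {dups}")
    if em.columns.has_duplicates:
        dups = em.columns[em.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample IDs {dups}")
    try:
        values = em.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: non-numeric values ({exc})") from exc
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{name}: missing or non-finite value at probe "
            f"{em.index[r]!r}, sample {em.columns[c]!r}"
        )


def read_expression(path) -> pd.DataFrame:
    """Read and validate a probes x samples log2 intensity matrix."""
    em = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    em.index.name = "probe_id"
    _validate_expression(em, name=str(path))
    return em.astype(float)


def read_design(path) -> TimeCourseDesign:
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: design table lacks a sample_id column")
    return TimeCourseDesign(frame.set_index("sample_id"))


def read_annotation(path) -> pd.Series:
    """Read a probe -> gene symbol map; empty symbols become <NA>."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.columns.tolist()[:2] != ["probe_id", "gene_symbol"]:
        raise ValueError(
            f"{path}: annotation table must have columns probe_id, gene_symbol"
        )
    if frame["probe_id"].duplicated().any():
        dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"{path}: duplicate probe IDs {dups}")
    symbols = frame.set_index("probe_id")["gene_symbol"].str.strip()
    return symbols.mask(symbols == "", pd.NA)


def write_expression(em: pd.DataFrame, path) -> None:
    _validate_expression(em)
    em.rename_axis("probe_id").to_csv(path, sep="\t")


def write_design(design: TimeCourseDesign, path) -> None:
    design.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def write_annotation(annotation: pd.Series, path) -> None:
    out = annotation.rename("gene_symbol").rename_axis("probe_id").fillna("")
    out.to_csv(path, sep="\t")
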