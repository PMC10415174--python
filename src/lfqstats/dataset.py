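"""Canonical dataset model: samples x proteins matrix joined to metadata.

The :class:`DataSet` holds the intensity matrix in statistical orientation
(rows = samples, columns = protein groups), the sample metadata aligned to
it, an immutable snapshot of the matrix taken at creation (``raw``) and an
append-only log of preprocessing steps.  Every preprocessing operation
records its complete parameters (including seeds), so that
``reset_preprocessing`` followed by replaying the log reproduces the current
matrix bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import fmt_float
from .exceptions import JoinError, LfqstatsError
from .io_import import RawProteinTable

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessStep",
    "DataSet",
    "read_metadata",
    "create_dataset",
    "reset_preprocessing",
    "subset",
    "summarize",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PreprocessStep:
    """One logged preprocessing operation.

    ``params`` holds every parameter needed to replay the step
    deterministically (seeds included); ``shape_after`` is
    ``(n_samples, n_proteins)`` after the step ran.
    """

    name: str
    params: dict
    shape_after: tuple[int, int]
    n_removed_or_imputed: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params,
            "shape_after": list(self.shape_after),
            "n_removed_or_imputed": self.n_removed_or_imputed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessStep":
        return cls(
            name=d["name"],
            params=dict(d["params"]),
            shape_after=tuple(d["shape_after"]),
            n_removed_or_imputed=int(d["n_removed_or_imputed"]),
        )


@dataclass(frozen=True)
class DataSet:
    """Samples x proteins intensity matrix with metadata and provenance.

    Attributes
    ----------
    matrix:
        Current (possibly preprocessed) intensities, samples as rows.
    metadata:
        Sample metadata indexed by sample id, aligned row-for-row with
        ``matrix``.
    raw:
        Immutable snapshot of ``matrix`` at creation (re-based on
        :func:`subset`); the anchor of provenance replay.
    log:
        Ordered preprocessing steps applied since ``raw``.
    annotations, contaminant:
        Per-protein annotation columns and contaminant flags carried over
        from the imported table, indexed like ``matrix.columns``.
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame
    raw: pd.DataFrame
    log: tuple[PreprocessStep, ...] = ()
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    contaminant: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[1]

    def with_step(
        self,
        matrix: pd.DataFrame,
        step: PreprocessStep,
        contaminant: pd.Series | None = None,
        annotations: pd.DataFrame | None = None,
    ) -> "DataSet":
        """Return a copy with a new matrix and one appended log entry."""
        return replace(
            self,
            matrix=matrix,
            log=self.log + (step,),
            contaminant=self.contaminant if contaminant is None else contaminant,
            annotations=self.annotations if annotations is None else annotations,
        )


def read_metadata(path: str | os.PathLike, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-metadata table from CSV/TSV (separator sniffed)."""
    if sep is None:
        sep = "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, encoding="utf-8")


def create_dataset(
    table: RawProteinTable,
    metadata: pd.DataFrame,
    sample_column: str,
) -> DataSet:
    """Join an imported protein table to sample metadata.

    Samples are matched by exact string equality after stripping surrounding
    whitespace (no fuzzy matching).  Table samples absent from the metadata
    are dropped with a warning; zero overlap is an error.
    """
    if metadata.empty:
        raise LfqstatsError("metadata table is empty")
    if sample_column not in metadata.columns:
        raise LfqstatsError(
            f"sample column {sample_column!r} not in metadata columns "
            f"{list(metadata.columns)}"
        )
    meta = metadata.copy()
    meta[sample_column] = meta[sample_column].astype(str).str.strip()
    if meta[sample_column].duplicated().any():
        dups = meta[sample_column][meta[sample_column].duplicated()].tolist()
        raise LfqstatsError(f"duplicated metadata sample ids: {dups}")
    if (meta[sample_column] == "").any():
        raise LfqstatsError("empty sample id in metadata")
    meta = meta.set_index(sample_column)
    meta.index.name = "sample_id"

    table_samples = [str(s).strip() for s in table.sample_names]
    overlap = [s for s in table_samples if s in set(meta.index)]
    if not overlap:
        raise JoinError(
            f"no overlapping sample names; table has {table_samples[:10]}, "
            f"metadata has {list(meta.index)[:10]}"
        )
    dropped = [s for s in table_samples if s not in set(overlap)]
    if dropped:
        logger.warning(
            "dropping %d samples absent from metadata: %s", len(dropped), dropped
        )

    intensities = table.intensities.copy()
    intensities.columns = table_samples
    matrix = intensities[overlap].T.astype(float)
    matrix.index.name = "sample_id"
    meta = meta.loc[overlap]

    return DataSet(
        matrix=matrix,
        metadata=meta,
        raw=matrix.copy(),
        log=(),
        annotations=table.annotations.copy(),
        contaminant=table.contaminant.copy(),
    )


def reset_preprocessing(ds: DataSet) -> DataSet:
    """Restore the raw snapshot and empty the log (metadata unchanged).

    Because the raw snapshot is re-based when samples are subset, reset
    undoes preprocessing but not subsetting.
    """
    return replace(ds, matrix=ds.raw.copy(), log=())


def subset(
    ds: DataSet,
    keep: "list[str] | None" = None,
    where: "dict[str, object] | None" = None,
) -> DataSet:
    """Keep a subset of samples, by explicit id list or metadata equality.

    ``where`` maps metadata columns to a required value (or list of allowed
    values).  The raw snapshot is re-based to the subset and a ``subset``
    step with the resolved sample ids is logged, so replaying the log on the
    re-based dataset is a no-op for this step.
    """
    if (keep is None) == (where is None):
        raise LfqstatsError("pass exactly one of `keep` or `where`")
    if where is not None:
        mask = pd.Series(True, index=ds.metadata.index)
        for col, val in where.items():
            if col not in ds.metadata.columns:
                raise LfqstatsError(f"unknown metadata column {col!r}")
            allowed = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= ds.metadata[col].isin(list(allowed))
        ids = list(ds.metadata.index[mask])
    else:
        missing = [s for s in keep if s not in set(ds.matrix.index)]
        if missing:
            raise LfqstatsError(f"unknown sample ids: {missing}")
        ids = [s for s in ds.matrix.index if s in set(keep)]
    if not ids:
        raise LfqstatsError("subset would produce a dataset with zero samples")

    matrix = ds.matrix.loc[ids].copy()
    step = PreprocessStep(
        name="subset",
        params={"sample_ids": list(ids)},
        shape_after=matrix.shape,
        n_removed_or_imputed=ds.n_samples - len(ids),
    )
    return replace(
        ds,
        matrix=matrix,
        metadata=ds.metadata.loc[ids].copy(),
        raw=ds.raw.loc[ids].copy(),
        log=ds.log + (step,),
    )


def summarize(ds: DataSet) -> dict:
    """Basic dataset summary: sizes, missingness, contaminant count."""
    vals = ds.matrix.to_numpy(dtype=float)
    missing = np.isnan(vals)
    per_sample = {
        s: float(m) for s, m in zip(ds.matrix.index, missing.mean(axis=1))
    }
    n_cont = int(
        ds.contaminant.reindex(ds.matrix.columns, fill_value=False)
        .astype(bool)
        .sum()
    )
    return {
        "n_samples": ds.n_samples,
        "n_proteins": ds.n_proteins,
        "missing_fraction": float(missing.mean()) if vals.size else 0.0,
        "missing_fraction_per_sample": per_sample,
        "n_contaminants": n_cont,
        "n_steps": len(ds.log),
    }


# ---------------------------------------------------------------------------
# serialization (directory of plain-text files)


def save_dataset(ds: DataSet, directory: str | os.PathLike) -> None:
    """Serialize to a directory: matrix/raw/metadata TSV + JSON log."""
    os.makedirs(directory, exist_ok=True)
    d = os.fspath(directory)
    # repr-style float formatting keeps the round-trip bit-exact
    ds.matrix.to_csv(os.path.join(d, "matrix.tsv"), sep="\t", float_format=fmt_float)
    ds.raw.to_csv(os.path.join(d, "raw.tsv"), sep="\t", float_format=fmt_float)
    ds.metadata.to_csv(os.path.join(d, "metadata.tsv"), sep="\t")
    ds.annotations.to_csv(os.path.join(d, "annotations.tsv"), sep="\t")
    ds.contaminant.rename("contaminant").to_csv(
        os.path.join(d, "contaminant.tsv"), sep="\t"
    )
    with open(os.path.join(d, "log.json"), "w", encoding="utf-8") as fh:
        json.dump([s.to_dict() for s in ds.log], fh, indent=1)


def load_dataset(directory: str | os.PathLike) -> DataSet:
    """Load a dataset serialized by :func:`save_dataset`."""
    d = os.fspath(directory)
    matrix = pd.read_csv(
        os.path.join(d, "matrix.tsv"), sep="\t", index_col=0,
        float_precision="round_trip",
    )
    raw = pd.read_csv(
        os.path.join(d, "raw.tsv"), sep="\t", index_col=0,
        float_precision="round_trip",
    )
    metadata = pd.read_csv(os.path.join(d, "metadata.tsv"), sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    annotations = pd.read_csv(
        os.path.join(d, "annotations.tsv"), sep="\t", index_col=0
    )
    contaminant = pd.read_csv(
        os.path.join(d, "contaminant.tsv"), sep="\t", index_col=0
    )["contaminant"].astype(bool)
    matrix.index = matrix.index.astype(str)
    raw.index = raw.index.astype(str)
    with open(os.path.join(d, "log.json"), encoding="utf-8") as fh:
        log = tuple(PreprocessStep.from_dict(x) for x in json.load(fh))
    return DataSet(
        matrix=matrix.astype(float),
        metadata=metadata,
        raw=raw.astype(float),
        log=log,
        annotations=annotations,
        contaminant=contaminant,
    )
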