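"""Import of search-engine protein tables into a canonical protein table.

Each supported quantification software writes protein-group level output in
its own layout (wide MaxQuant ``proteinGroups.txt``, DIA-NN ``pg_matrix``,
FragPipe ``combined_protein``, long Spectronaut reports, AlphaPept CSV) plus
the mzTab exchange format.  This module detects the dialect from the header,
parses the file into a :class:`RawProteinTable` (proteins x samples intensity
matrix plus annotations) and flags laboratory contaminants / decoy entries.

A seeded fixture generator (:func:`make_fixture_file`) emits a syntactically
valid file in every dialect together with a manifest of the exact values
written, so each loader can be verified cell-by-cell.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from pyteomics import mztab as _pyteomics_mztab

from .exceptions import (
    AmbiguousFormatError,
    FormatError,
    ParseError,
    UnrecognizedFormatError,
)

__all__ = [
    "EngineDialect",
    "RawProteinTable",
    "DIALECTS",
    "detect_dialect",
    "load_table",
    "load_mztab",
    "flag_contaminants",
    "make_fixture_file",
]


@dataclass(frozen=True)
class EngineDialect:
    """Parsing rules for one search-engine output format.

    Parameters
    ----------
    name:
        Dialect identifier (``maxquant``, ``diann``, ...).
    sep:
        Field separator of the text file.
    id_column:
        Column holding the protein-group identifier. ``id_column_fallbacks``
        are tried in order when the primary column is absent.
    orientation:
        ``wide`` (one column per sample) or ``long`` (one row per
        protein/sample observation).
    intensity_families:
        Ordered column families; each is ``(prefix, suffix)`` stripped from a
        matching column header to obtain the sample name.  The first family
        with at least one matching column is used.  An empty list means
        "every non-annotation column is a sample".
    annotation_columns:
        Known non-intensity columns (kept as per-protein annotations).
    marker_columns:
        ``(column, marker)`` pairs: a protein whose annotation cell equals the
        marker is a contaminant/decoy.
    contaminant_prefixes:
        Identifier prefixes marking contaminant or reversed-decoy entries.
    """

    name: str
    sep: str = "\t"
    id_column: str = "id"
    id_column_fallbacks: tuple[str, ...] = ()
    orientation: str = "wide"
    intensity_families: tuple[tuple[str, str], ...] = ()
    annotation_columns: tuple[str, ...] = ()
    marker_columns: tuple[tuple[str, str], ...] = ()
    contaminant_prefixes: tuple[str, ...] = ("CON__", "REV__")
    # long-format specifics
    long_sample_column: str = ""
    long_quantity_column: str = ""
    sample_from_basename: bool = False


DIALECTS: dict[str, EngineDialect] = {
    "maxquant": EngineDialect(
        name="maxquant",
        sep="\t",
        id_column="Majority protein IDs",
        id_column_fallbacks=("Protein IDs",),
        intensity_families=(("LFQ intensity ", ""), ("Intensity ", "")),
        annotation_columns=(
            "Protein IDs",
            "Majority protein IDs",
            "Gene names",
            "Protein names",
            "Fasta headers",
            "Potential contaminant",
            "Contaminant",
            "Reverse",
            "Only identified by site",
        ),
        marker_columns=(
            ("Potential contaminant", "+"),
            ("Contaminant", "+"),
            ("Reverse", "+"),
            ("Only identified by site", "+"),
        ),
    ),
    "diann": EngineDialect(
        name="diann",
        sep="\t",
        id_column="Protein.Group",
        annotation_columns=(
            "Protein.Group",
            "Protein.Ids",
            "Protein.Names",
            "Genes",
            "First.Protein.Description",
        ),
        sample_from_basename=True,
    ),
    "fragpipe": EngineDialect(
        name="fragpipe",
        sep="\t",
        id_column="Protein",
        intensity_families=(("", " MaxLFQ Intensity"), ("", " Intensity")),
        annotation_columns=(
            "Protein",
            "Protein ID",
            "Entry Name",
            "Gene",
            "Description",
            "Protein Probability",
            "Combined Total Peptides",
        ),
        contaminant_prefixes=("CON__", "REV__", "contam_"),
    ),
    "spectronaut": EngineDialect(
        name="spectronaut",
        sep="\t",
        orientation="long",
        id_column="PG.ProteinGroups",
        long_sample_column="R.FileName",
        long_quantity_column="PG.Quantity",
        annotation_columns=("PG.Genes",),
    ),
    "alphapept": EngineDialect(
        name="alphapept",
        sep=",",
        id_column="protein_group",
    ),
    "mztab": EngineDialect(
        name="mztab",
        id_column="accession",
    ),
    "generic": EngineDialect(
        name="generic",
        sep=",",
        id_column="",  # first column
    ),
}


@dataclass(frozen=True)
class RawProteinTable:
    """Canonical parsed protein table: proteins x samples intensities.

    ``intensities`` is indexed by protein-group id with one column per
    sample; missing observations are NaN.  ``annotations`` carries the
    per-protein text columns of the source file and ``contaminant`` the
    boolean contaminant/decoy flag.
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame
    contaminant: pd.Series
    source_dialect: str = "generic"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.intensities.columns)

    def validate(self) -> None:
        """Raise ``FormatError`` if the structural invariants are violated."""
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dups[:5]}")
        cols = self.intensities.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample names: {dups[:5]}")
        if len(cols) == 0:
            raise FormatError("table has no intensity columns")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative intensity values present")
        if not self.annotations.index.equals(idx):
            raise FormatError("annotations not aligned to protein ids")
        if not self.contaminant.index.equals(idx):
            raise FormatError("contaminant flags not aligned to protein ids")


# ---------------------------------------------------------------------------
# dialect detection


def _split_header(line: str) -> list[str]:
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) == 1:
        fields = line.rstrip("\r\n").split(",")
    return fields


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def detect_dialect(header_lines: list[str]) -> EngineDialect:
    """Identify the engine dialect from the first lines of a file.

    Signature columns unique to each engine are matched against the header.
    A file matching two or more dialects raises
    :class:`AmbiguousFormatError`; a file matching none is accepted as
    ``generic`` when it has one leading id-like column followed by at least
    one numeric column, and rejected otherwise.
    """
    lines = [ln for ln in header_lines if ln.strip()]
    if not lines:
        raise UnrecognizedFormatError("no nonempty header lines")

    if lines[0].split("\t")[0] == "MTD":
        return DIALECTS["mztab"]

    fields = _split_header(lines[0])
    fieldset = set(fields)
    matches = []
    if "Majority protein IDs" in fieldset or (
        "Protein IDs" in fieldset
        and any(f.startswith(("LFQ intensity ", "Intensity ")) for f in fields)
    ):
        matches.append("maxquant")
    if "Protein.Group" in fieldset:
        matches.append("diann")
    if "Protein" in fieldset and any(f.endswith(" Intensity") for f in fields):
        matches.append("fragpipe")
    if "PG.ProteinGroups" in fieldset:
        matches.append("spectronaut")
    if "protein_group" in fieldset:
        matches.append("alphapept")

    if len(matches) > 1:
        raise AmbiguousFormatError(matches)
    if len(matches) == 1:
        return DIALECTS[matches[0]]

    # generic fallback: id-like first column, numeric body columns
    if len(fields) >= 2 and len(lines) >= 2:
        body = _split_header(lines[1])
        if len(body) == len(fields) and all(
            _is_number(tok) or tok == "" for tok in body[1:]
        ):
            return DIALECTS["generic"]
    raise UnrecognizedFormatError(
        "header does not match any supported dialect: " + lines[0][:120]
    )


# ---------------------------------------------------------------------------
# loading


def _coerce_numeric(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Parse intensity columns as floats; name the offending cell on failure."""
    out = {}
    for col in columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric intensity cell {raw.iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
        out[col] = num.astype(float)
    return pd.DataFrame(out, index=df.index)


def _select_intensity_columns(
    columns: list[str],
    dialect: EngineDialect,
    intensity_preference: list[tuple[str, str]] | None,
) -> tuple[dict[str, str], tuple[str, str]]:
    """Map intensity column -> sample name for the first matching family."""
    families = (
        [tuple(f) for f in intensity_preference]
        if intensity_preference
        else list(dialect.intensity_families)
    )
    for prefix, suffix in families:
        mapping = {}
        for col in columns:
            if (
                col.startswith(prefix)
                and col.endswith(suffix)
                and len(col) > len(prefix) + len(suffix)
            ):
                name = col[len(prefix): len(col) - len(suffix)]
                mapping[col] = name.strip()
        if mapping:
            return mapping, (prefix, suffix)
    raise FormatError(
        f"no intensity columns found for families {families} "
        f"in dialect {dialect.name!r}"
    )


def _find_id_column(df: pd.DataFrame, dialect: EngineDialect) -> str:
    if dialect.id_column == "":  # generic: first column is the id
        return str(df.columns[0])
    for cand in (dialect.id_column, *dialect.id_column_fallbacks):
        if cand in df.columns:
            return cand
    raise FormatError(
        f"missing id column {dialect.id_column!r} for dialect {dialect.name!r}"
    )


def _finalize(
    ids: pd.Index,
    intensities: pd.DataFrame,
    annotations: pd.DataFrame,
    dialect: EngineDialect,
) -> RawProteinTable:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate protein-group rows: {dups[:5]}")
    if intensities.columns.has_duplicates:
        dups = intensities.columns[intensities.columns.duplicated()]
        raise FormatError(
            f"sample name collision after stripping family affixes: "
            f"{dups.unique().tolist()[:5]}"
        )
    table = RawProteinTable(
        intensities=intensities,
        annotations=annotations,
        contaminant=pd.Series(False, index=ids, name="contaminant"),
        source_dialect=dialect.name,
    )
    table.validate()
    return table


def load_table(
    path: str | os.PathLike,
    dialect: EngineDialect | str | None = None,
    intensity_preference: list[tuple[str, str]] | None = None,
) -> RawProteinTable:
    """Load a wide or long search-engine protein table.

    Parameters
    ----------
    path:
        Text file in one of the supported dialects.
    dialect:
        Dialect object or name; auto-detected from the header when omitted.
    intensity_preference:
        Ordered ``(prefix, suffix)`` column families overriding the dialect
        default (e.g. prefer raw ``Intensity`` over ``LFQ intensity`` for
        MaxQuant output).
    """
    if dialect is None:
        with open(path, encoding="utf-8") as fh:
            head = [fh.readline() for _ in range(5)]
        dialect = detect_dialect(head)
    elif isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    if dialect.name == "mztab":
        return load_mztab(path)

    df = pd.read_csv(path, sep=dialect.sep, dtype=str, encoding="utf-8")
    id_col = _find_id_column(df, dialect)
    ids = pd.Index(df[id_col].astype(str).str.strip(), name="protein_id")

    if dialect.orientation == "long":
        return _pivot_long(df, ids, dialect)

    if dialect.intensity_families or intensity_preference:
        mapping, _family = _select_intensity_columns(
            list(df.columns), dialect, intensity_preference
        )
    elif dialect.name == "diann":
        runs = [c for c in df.columns if c not in dialect.annotation_columns]
        mapping = {
            c: os.path.splitext(os.path.basename(c))[0].strip() for c in runs
        }
    else:  # alphapept, generic: remaining numeric columns are samples
        candidates = [
            c
            for c in df.columns
            if c != id_col and c not in dialect.annotation_columns
        ]
        mapping = {}
        for c in candidates:
            num = pd.to_numeric(df[c], errors="coerce")
            if num.notna().any() or df[c].isna().all():
                mapping[c] = c.strip()
        if not mapping:
            raise FormatError("no numeric intensity columns found")

    numeric = _coerce_numeric(df, list(mapping))
    intensities = numeric.rename(columns=mapping)
    intensities.index = ids
    ann_cols = [c for c in df.columns if c not in mapping and c != id_col]
    annotations = df[ann_cols].copy()
    annotations.index = ids
    return _finalize(ids, intensities, annotations, dialect)


def _pivot_long(
    df: pd.DataFrame, ids: pd.Index, dialect: EngineDialect
) -> RawProteinTable:
    """Pivot a long (one observation per row) report to a wide matrix."""
    for col in (dialect.long_sample_column, dialect.long_quantity_column):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in long-format file")
    samples = df[dialect.long_sample_column].astype(str).str.strip()
    pairs = pd.MultiIndex.from_arrays([ids, samples])
    if pairs.has_duplicates:
        dup = pairs[pairs.duplicated()][0]
        raise FormatError(
            f"duplicate (protein, sample) observation {tuple(dup)!r} "
            "in long-format file"
        )
    quantity = _coerce_numeric(
        df, [dialect.long_quantity_column]
    )[dialect.long_quantity_column]
    wide = pd.DataFrame(
        {"protein_id": ids.to_numpy(), "sample": samples.to_numpy(),
         "quantity": quantity.to_numpy()}
    ).pivot(index="protein_id", columns="sample", values="quantity")
    # preserve first-appearance order of proteins and samples
    wide = wide.reindex(index=ids.unique(), columns=samples.unique())
    wide.columns.name = None

    ann_cols = [c for c in dialect.annotation_columns if c in df.columns]
    annotations = (
        df.assign(protein_id=ids.to_numpy())
        .groupby("protein_id", sort=False)[ann_cols]
        .first()
        .reindex(wide.index)
    )
    return _finalize(wide.index, wide, annotations, dialect)


_ABUNDANCE_RE = re.compile(r"^protein_abundance_assay\[(\d+)\]$")


def load_mztab(path: str | os.PathLike) -> RawProteinTable:
    """Load the protein section of an mzTab file.

    PRT rows become proteins and ``protein_abundance_assay[n]`` columns
    become samples, named from the ``assay[n]`` metadata entry when present
    and ``assay[n]`` otherwise.  ``null`` cells are treated as missing.
    PSM/peptide sections are ignored.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    prefixes = {ln.split("\t", 1)[0] for ln in lines if ln.strip()}
    if "PRT" not in prefixes or "PRH" not in prefixes:
        raise FormatError("mzTab file has no protein (PRH/PRT) section")
    n_header = next(
        len(ln.rstrip("\r\n").split("\t"))
        for ln in lines
        if ln.startswith("PRH\t")
    )
    for i, ln in enumerate(lines):
        if ln.startswith("PRT\t"):
            n = len(ln.rstrip("\r\n").split("\t"))
            if n != n_header:
                raise FormatError(
                    f"PRT line {i + 1} has {n} columns, PRH has {n_header}"
                )

    parsed = _pyteomics_mztab.MzTab(os.fspath(path))
    prot = parsed.protein_table
    if "accession" not in prot.columns:
        raise FormatError("mzTab protein section lacks an accession column")
    ids = pd.Index(prot["accession"].astype(str).str.strip(), name="protein_id")

    abundance = {}
    for col in prot.columns:
        m = _ABUNDANCE_RE.match(str(col))
        if m:
            n = int(m.group(1))
            meta_name = parsed.metadata.get(f"assay[{n}]")
            name = (
                str(meta_name).strip()
                if isinstance(meta_name, str) and meta_name.strip()
                else f"assay[{n}]"
            )
            abundance[col] = name
    if not abundance:
        raise FormatError(
            "mzTab protein section has no protein_abundance_assay columns; "
            "use the generic loader for plain matrices"
        )
    intensities = (
        prot[list(abundance)]
        .apply(pd.to_numeric, errors="coerce")
        .astype(float)
        .rename(columns=abundance)
    )
    intensities.index = ids
    ann_cols = [c for c in prot.columns if c not in abundance and c != "accession"]
    annotations = prot[ann_cols].copy()
    annotations.index = ids
    return _finalize(ids, intensities, annotations, DIALECTS["mztab"])


# ---------------------------------------------------------------------------
# contaminant flagging


def flag_contaminants(
    table: RawProteinTable,
    extra_accessions: set[str] | None = None,
) -> RawProteinTable:
    """Flag contaminant/decoy proteins; returns a new table.

    A protein is flagged when a dialect marker column fires (e.g. ``+`` in
    MaxQuant's ``Potential contaminant``), when its identifier or any
    ``;``-separated member accession starts with a contaminant prefix
    (``CON__``, ``REV__``, ...), or when a member accession is listed in
    ``extra_accessions``.  Existing flags are preserved, so the operation is
    idempotent and monotone.
    """
    dialect = DIALECTS.get(table.source_dialect, DIALECTS["generic"])
    flags = table.contaminant.to_numpy().copy()

    for col, marker in dialect.marker_columns:
        if col in table.annotations.columns:
            hit = table.annotations[col].astype(str).str.strip() == marker
            flags |= hit.to_numpy()

    extra = {str(a) for a in (extra_accessions or set())}
    for i, pid in enumerate(table.intensities.index):
        members = [m.strip() for m in str(pid).split(";")]
        if any(
            m.startswith(dialect.contaminant_prefixes) for m in members
        ) or (extra and (str(pid) in extra or any(m in extra for m in members))):
            flags[i] = True

    return replace(
        table,
        contaminant=pd.Series(
            flags, index=table.intensities.index, name="contaminant"
        ),
    )


# ---------------------------------------------------------------------------
# fixture generation


def _fixture_values(
    n_proteins: int, n_samples: int, seed: int
) -> tuple[list[str], list[str], np.ndarray]:
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    if n_proteins >= 2:
        ids[1] = "CON__" + ids[1]
    samples = [f"sample_{chr(ord('A') + i % 26)}{i // 26}" for i in range(n_samples)]
    values = np.round(rng.uniform(1e4, 1e8, size=(n_proteins, n_samples)), 1)
    return ids, samples, values


def make_fixture_file(
    dialect: EngineDialect | str,
    n_proteins: int,
    n_samples: int,
    seed: int,
    path: str | os.PathLike,
) -> dict:
    """Write a small, valid file in the given dialect and return its manifest.

    The manifest records the protein ids, sample names and the exact
    intensity matrix written (row-major list of lists), so that loaders can
    be validated cell-by-cell.  When ``n_proteins >= 2`` the second protein
    is a contaminant (``CON__`` prefix, plus the dialect's marker column
    where one exists).  Equal seeds produce byte-identical files.  A JSON
    manifest is written next to the file.
    """
    if isinstance(dialect, EngineDialect):
        dialect = dialect.name
    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}")
    if n_proteins < 1 or n_samples < 1:
        raise ValueError("n_proteins and n_samples must be >= 1")

    ids, samples, values = _fixture_values(n_proteins, n_samples, seed)
    fmt = np.vectorize(repr)
    cells = fmt(values)

    lines: list[str] = []
    if dialect == "maxquant":
        header = (
            ["Protein IDs", "Majority protein IDs", "Gene names"]
            + [f"LFQ intensity {s}" for s in samples]
            + [f"Intensity {s}" for s in samples]
            + ["Potential contaminant", "Reverse", "Only identified by site"]
        )
        lines.append("\t".join(header))
        for i, pid in enumerate(ids):
            con = "+" if pid.startswith("CON__") else ""
            row = (
                [pid, pid, f"GENE{i}"]
                + list(cells[i])
                + list(cells[i])  # raw Intensity mirrors LFQ in fixtures
                + [con, "", ""]
            )
            lines.append("\t".join(row))
    elif dialect == "diann":
        header = [
            "Protein.Group", "Protein.Ids", "Protein.Names", "Genes",
            "First.Protein.Description",
        ] + [f"runs/{s}.raw" for s in samples]
        lines.append("\t".join(header))
        for i, pid in enumerate(ids):
            lines.append(
                "\t".join(
                    [pid, pid, f"{pid}_HUMAN", f"GENE{i}", f"protein {i}"]
                    + list(cells[i])
                )
            )
    elif dialect == "fragpipe":
        header = (
            ["Protein", "Protein ID", "Gene", "Description"]
            + [f"{s} Intensity" for s in samples]
            + [f"{s} MaxLFQ Intensity" for s in samples]
        )
        lines.append("\t".join(header))
        for i, pid in enumerate(ids):
            lines.append(
                "\t".join(
                    [pid, pid, f"GENE{i}", f"protein {i}"]
                    + list(cells[i])
                    + list(cells[i])
                )
            )
    elif dialect == "spectronaut":
        lines.append("\t".join(
            ["R.FileName", "PG.ProteinGroups", "PG.Genes", "PG.Quantity"]
        ))
        for i, pid in enumerate(ids):
            for j, s in enumerate(samples):
                lines.append("\t".join([s, pid, f"GENE{i}", cells[i][j]]))
    elif dialect == "alphapept":
        lines.append(",".join(["protein_group"] + samples))
        for i, pid in enumerate(ids):
            lines.append(",".join([pid] + list(cells[i])))
    elif dialect == "generic":
        lines.append(",".join(["id"] + samples))
        for i, pid in enumerate(ids):
            lines.append(",".join([pid] + list(cells[i])))
    elif dialect == "mztab":
        lines.append("MTD\tmzTab-version\t1.0.0")
        lines.append("MTD\tmzTab-mode\tSummary")
        lines.append("MTD\tmzTab-type\tQuantification")
        lines.append("MTD\tdescription\tsynthetic fixture")
        for j, s in enumerate(samples, start=1):
            lines.append(f"MTD\tassay[{j}]\t{s}")
        lines.append("\t".join(
            ["PRH", "accession", "description"]
            + [f"protein_abundance_assay[{j}]" for j in range(1, n_samples + 1)]
        ))
        for i, pid in enumerate(ids):
            lines.append(
                "\t".join(["PRT", pid, f"protein {i}"] + list(cells[i]))
            )
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")

    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)

    manifest = {
        "dialect": dialect,
        "protein_ids": ids,
        "sample_names": samples,
        "values": values.tolist(),
        "contaminant_ids": [p for p in ids if p.startswith("CON__")],
        "seed": seed,
    }
    with open(
        os.fspath(path) + ".manifest.json", "w", encoding="utf-8"
    ) as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
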