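"""Core data containers and standard-format I/O.

``OtuTable`` holds a samples x OTUs integer count matrix with per-OTU
Greengenes-style taxonomy strings.  Tables are read and written as plain
tab-delimited text (rows = OTUs, columns = samples, trailing ``taxonomy``
column) and, for interoperability, as classic BIOM 1.0 JSON
(observations x samples, sparse or dense).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """Malformed table or metadata input."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableFormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Integer count matrix, samples x OTUs, with ids and taxonomy."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise TableFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise TableFormatError("counts must be non-negative")
        n_samples, n_otus = self.counts.shape
        if len(self.sample_ids) != n_samples:
            raise TableFormatError(
                f"{len(self.sample_ids)} sample ids for {n_samples} rows"
            )
        if len(self.otu_ids) != n_otus:
            raise TableFormatError(f"{len(self.otu_ids)} OTU ids for {n_otus} columns")
        if not self.taxonomy:
            self.taxonomy = [""] * n_otus
        if len(self.taxonomy) != n_otus:
            raise TableFormatError("taxonomy length must match number of OTUs")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def select_otus(self, keep: np.ndarray) -> "OtuTable":
        """New table restricted to the OTU columns flagged in boolean *keep*."""
        keep = np.asarray(keep, dtype=bool)
        return OtuTable(
            counts=self.counts[:, keep].copy(),
            sample_ids=list(self.sample_ids),
            otu_ids=[o for o, k in zip(self.otu_ids, keep) if k],
            taxonomy=[t for t, k in zip(self.taxonomy, keep) if k],
        )

    def select_samples(self, keep_ids: Iterable[str]) -> "OtuTable":
        """New table restricted to *keep_ids*, in the given order."""
        idx = self.sample_index()
        rows = [idx[s] for s in keep_ids]
        return OtuTable(
            counts=self.counts[rows, :].copy(),
            sample_ids=[self.sample_ids[r] for r in rows],
            otu_ids=list(self.otu_ids),
            taxonomy=list(self.taxonomy),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and self.taxonomy == other.taxonomy
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class FeatureMatrix:
    """Real-valued model-ready matrix with provenance flags."""

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    transformed: bool = False
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise TableFormatError("values shape does not match ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "FeatureMatrix":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [pos[o] for o in otu_ids]
        return FeatureMatrix(
            values=self.values[:, cols].copy(),
            sample_ids=list(self.sample_ids),
            otu_ids=list(otu_ids),
            transformed=self.transformed,
            centered=self.centered,
        )


# ---------------------------------------------------------------------------
# tab-delimited OTU tables (rows = OTUs, columns = samples, last col taxonomy)
# ---------------------------------------------------------------------------

TAXONOMY_COLUMN = "taxonomy"


def write_otu_table_tsv(table: OtuTable, path: str | Path) -> None:
    df = pd.DataFrame(
        table.counts.T, index=pd.Index(table.otu_ids, name="otu_id"),
        columns=table.sample_ids,
    )
    df[TAXONOMY_COLUMN] = table.taxonomy
    df.to_csv(path, sep="\t")


def read_otu_table_tsv(path: str | Path) -> OtuTable:
    """Read a tab-delimited OTU table; rejects malformed rows with line numbers."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableFormatError(f"{path}: header has fewer than 2 columns")
        has_tax = header[-1] == TAXONOMY_COLUMN
        sample_ids = header[1 : -1 if has_tax else len(header)]
        _check_unique(sample_ids, "sample")
        otu_ids: list[str] = []
        taxonomy: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            otu_ids.append(parts[0])
            tax = parts[-1] if has_tax else ""
            taxonomy.append(tax)
            vals = parts[1 : -1 if has_tax else len(parts)]
            try:
                row = [int(float(v)) if float(v) == int(float(v)) else None for v in vals]
            except ValueError as e:
                raise TableFormatError(f"{path}:{lineno}: non-numeric count: {e}")
            if any(v is None for v in row):
                raise TableFormatError(f"{path}:{lineno}: non-integer count")
            if any(v < 0 for v in row):  # type: ignore[operator]
                raise TableFormatError(f"{path}:{lineno}: negative count")
            rows.append(row)  # type: ignore[arg-type]
    _check_unique(otu_ids, "OTU")
    counts = (
        np.asarray(rows, dtype=np.int64).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int64)
    )
    return OtuTable(counts=counts, sample_ids=sample_ids, otu_ids=otu_ids, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# classic BIOM 1.0 JSON (observations x samples)
# ---------------------------------------------------------------------------

def read_otu_table_biom_json(path: str | Path) -> OtuTable:
    """Read a classic BIOM 1.0 JSON table (sparse or dense matrix_type)."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        taxonomy = []
        for r in doc["rows"]:
            meta = r.get("metadata") or {}
            tax = meta.get("taxonomy", "")
            if isinstance(tax, list):
                tax = ";".join(tax)
            taxonomy.append(tax)
        sample_ids = [c["id"] for c in doc["columns"]]
        n_obs, n_samp = doc["shape"]
        matrix_type = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as e:
        raise TableFormatError(f"{path}: not a classic BIOM JSON table ({e})")
    if len(otu_ids) != n_obs or len(sample_ids) != n_samp:
        raise TableFormatError(f"{path}: shape does not match row/column lists")
    mat = np.zeros((n_obs, n_samp), dtype=np.int64)
    if matrix_type == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = int(v)
    elif matrix_type == "dense":
        mat[:, :] = np.asarray(data, dtype=np.int64)
    else:
        raise TableFormatError(f"{path}: unknown matrix_type {matrix_type!r}")
    return OtuTable(
        counts=mat.T, sample_ids=sample_ids, otu_ids=otu_ids, taxonomy=taxonomy
    )


def write_otu_table_biom_json(table: OtuTable, path: str | Path) -> None:
    obs_mat = table.counts.T
    nz = np.nonzero(obs_mat)
    data = [[int(i), int(j), int(obs_mat[i, j])] for i, j in zip(*nz)]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microrf",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [
            {"id": o, "metadata": {"taxonomy": t}}
            for o, t in zip(table.otu_ids, table.taxonomy)
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh)


def read_otu_table(path: str | Path) -> OtuTable:
    """Dispatch on extension: ``.json``/``.biom`` -> BIOM JSON, else TSV."""
    p = Path(path)
    if p.suffix.lower() in {".json", ".biom"}:
        return read_otu_table_biom_json(p)
    return read_otu_table_tsv(p)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

METADATA_REQUIRED = ("sample_id", "subject_id", "hbi", "crp", "fc")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the clinical metadata TSV; validates required columns and ids."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise TableFormatError(
            f"{path}: duplicate sample id: {dup.iloc[0]!r}"
        )
    for col in ("hbi", "crp", "fc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            bad = df.index[vals < 0][0] + 2  # header line + 1-based
            raise TableFormatError(f"{path}:{bad}: negative value in {col!r}")
        df[col] = vals
    if "days_since_antibiotics" in df.columns:
        df["days_since_antibiotics"] = pd.to_numeric(
            df["days_since_antibiotics"], errors="coerce"
        )
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def subject_map_from_metadata(meta: pd.DataFrame) -> dict[str, str]:
    return dict(zip(meta["sample_id"], meta["subject_id"]))
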