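"""Reading and writing abundance tables, sample metadata and ranked-feature output.

Abundance data arrive as BIOM tables (the Biological Observation Matrix
standard: JSON in v1.0, HDF5 in v2.1), feature-by-sample count matrices with
optional per-observation taxonomy and per-sample metadata.  Phenotype labels
come either from a QIIME-style tab-delimited mapping file keyed by sample ID
or from metadata embedded in the BIOM file itself.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_MISSING_VALUES = {"", "NA", "N/A", "nan", "NaN", "None"}


class BiomParseError(ValueError):
    """Raised when a BIOM file is malformed; the message names the offending field."""


@dataclass
class AbundanceTable:
    """A K-feature x M-sample matrix of nonnegative counts.

    Rows are features (OTUs or functional units) identified by
    ``feature_ids`` and optionally annotated with a joined taxonomy lineage
    string; columns are samples identified by ``sample_ids``.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D feature-by-sample matrix")
        k, m = self.counts.shape
        if k < 1 or m < 2:
            raise ValueError(f"need at least 1 feature and 2 samples, got {k}x{m}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.feature_ids) != k:
            raise ValueError("feature_ids length does not match counts rows")
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.feature_ids)) != k:
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample IDs")
        if not self.taxonomy:
            self.taxonomy = [""] * k
        if len(self.taxonomy) != k:
            raise ValueError("taxonomy length does not match counts rows")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, indices: list[int]) -> "AbundanceTable":
        """Return a copy restricted to the given sample columns, order preserved."""
        return AbundanceTable(
            counts=self.counts[:, indices].copy(),
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
            taxonomy=list(self.taxonomy),
        )


@dataclass
class SampleMetadata:
    """Per-sample metadata: sample ID -> {column name -> raw string value}."""

    records: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        cols = None
        for sid, rec in self.records.items():
            if cols is None:
                cols = set(rec)
            elif set(rec) != cols:
                raise ValueError(f"sample {sid!r} has a different column set")

    @property
    def columns(self) -> list[str]:
        for rec in self.records.values():
            return list(rec)
        return []


@dataclass
class LabelVector:
    """Discrete phenotype labels aligned to an AbundanceTable's samples."""

    values: list[str]
    classes: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("fewer than two classes")
        if len(self.values) != len(self.sample_ids):
            raise ValueError("values and sample_ids lengths differ")
        bad = set(self.values) - set(self.classes)
        if bad:
            raise ValueError(f"labels {sorted(bad)} not in declared classes")

    @classmethod
    def from_values(cls, values: list[str], sample_ids: list[str]) -> "LabelVector":
        return cls(list(values), sorted(set(values)), list(sample_ids))

    def as_states(self) -> np.ndarray:
        """Integer class codes in the (sorted) order of ``classes``."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[v] for v in self.values], dtype=np.int64)


def _join_taxonomy(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (list, tuple)):
        return "; ".join(str(v) for v in value)
    if isinstance(value, bytes):
        return value.decode()
    return str(value)


def _read_biom_json(path: str) -> tuple[AbundanceTable, SampleMetadata | None]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BiomParseError(f"not valid JSON: {exc}") from exc
    for fld in ("matrix_type", "shape", "data", "rows", "columns"):
        if fld not in doc:
            raise BiomParseError(f"missing required BIOM field {fld!r}")
    k, m = doc["shape"]
    if len(doc["rows"]) != k:
        raise BiomParseError("field 'rows' length disagrees with 'shape'")
    if len(doc["columns"]) != m:
        raise BiomParseError("field 'columns' length disagrees with 'shape'")
    matrix_type = doc["matrix_type"]
    if matrix_type == "dense":
        counts = np.asarray(doc["data"], dtype=float)
        if counts.shape != (k, m):
            raise BiomParseError("field 'data' shape disagrees with 'shape'")
    elif matrix_type == "sparse":
        counts = np.zeros((k, m), dtype=float)
        for triplet in doc["data"]:
            r, c, v = triplet
            counts[int(r), int(c)] = v
    else:
        raise BiomParseError(f"unknown matrix_type {matrix_type!r}")

    feature_ids = [row["id"] for row in doc["rows"]]
    taxonomy = [
        _join_taxonomy((row.get("metadata") or {}).get("taxonomy"))
        for row in doc["rows"]
    ]
    sample_ids = [col["id"] for col in doc["columns"]]

    table = AbundanceTable(counts, feature_ids, sample_ids, taxonomy)

    col_meta = [col.get("metadata") or {} for col in doc["columns"]]
    metadata = None
    keys = sorted({key for meta in col_meta for key in meta})
    if keys:
        metadata = SampleMetadata(
            {
                sid: {key: str(meta.get(key, "")) for key in keys}
                for sid, meta in zip(sample_ids, col_meta)
            }
        )
    return table, metadata


def _read_biom_hdf5(path: str) -> tuple[AbundanceTable, SampleMetadata | None]:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        try:
            shape = tuple(fh.attrs["shape"])
            feature_ids = [x.decode() for x in fh["observation/ids"][:]]
            sample_ids = [x.decode() for x in fh["sample/ids"][:]]
            data = fh["observation/matrix/data"][:]
            indices = fh["observation/matrix/indices"][:]
            indptr = fh["observation/matrix/indptr"][:]
        except KeyError as exc:
            raise BiomParseError(f"missing required BIOM 2.1 dataset: {exc}") from exc
        counts = csr_matrix((data, indices, indptr), shape=shape).toarray()
        taxonomy = []
        if "observation/metadata/taxonomy" in fh:
            tax = fh["observation/metadata/taxonomy"][:]
            taxonomy = [_join_taxonomy([t.decode() if isinstance(t, bytes) else t
                                        for t in np.atleast_1d(row)]) for row in tax]
        metadata = None
        if "sample/metadata" in fh:
            group = fh["sample/metadata"]
            keys = sorted(group.keys())
            if keys:
                cols = {key: group[key][:] for key in keys}
                metadata = SampleMetadata(
                    {
                        sid: {
                            key: (v[i].decode() if isinstance(v[i], bytes) else str(v[i]))
                            for key, v in cols.items()
                        }
                        for i, sid in enumerate(sample_ids)
                    }
                )
    return AbundanceTable(counts, feature_ids, sample_ids, taxonomy), metadata


def _is_hdf5(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(8) == b"\x89HDF\r\n\x1a\n"


def read_biom(path: str) -> AbundanceTable:
    """Read a BIOM 1.0 JSON (dense or sparse) or BIOM 2.1 HDF5 table."""
    if _is_hdf5(path):
        return _read_biom_hdf5(path)[0]
    return _read_biom_json(path)[0]


def read_biom_sample_metadata(path: str) -> SampleMetadata | None:
    """Return sample metadata embedded in a BIOM file, or None if there is none."""
    if _is_hdf5(path):
        return _read_biom_hdf5(path)[1]
    return _read_biom_json(path)[1]


def write_biom(table: AbundanceTable, path: str, matrix_type: str = "sparse") -> None:
    """Write a BIOM 1.0 JSON file (round-trip support)."""
    if matrix_type not in ("sparse", "dense"):
        raise ValueError("matrix_type must be 'sparse' or 'dense'")
    counts = table.counts
    if matrix_type == "dense":
        data = counts.tolist()
    else:
        rr, cc = np.nonzero(counts)
        data = [[int(r), int(c), float(counts[r, c])] for r, c in zip(rr, cc)]
    is_int = bool(np.all(counts == np.floor(counts)))
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "otufs",
        "date": "",
        "matrix_type": matrix_type,
        "matrix_element_type": "int" if is_int else "float",
        "shape": [table.n_features, table.n_samples],
        "data": data,
        "rows": [
            {"id": fid, "metadata": ({"taxonomy": tax} if tax else None)}
            for fid, tax in zip(table.feature_ids, table.taxonomy)
        ],
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_map(path: str) -> SampleMetadata:
    """Read a QIIME-style tab-delimited mapping file.

    The first header column is the sample-ID column; a leading ``#`` on the
    header (the ``#SampleID`` dialect) is accepted and stripped.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty mapping file") from None
        header[0] = header[0].lstrip("#")
        columns = header[1:]
        records: dict[str, dict[str, str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            sid = row[0]
            if sid in records:
                raise ValueError(f"duplicate sample ID {sid!r}")
            records[sid] = dict(zip(columns, row[1:]))
    return SampleMetadata(records)


def extract_labels(
    table: AbundanceTable, metadata: SampleMetadata, column: str
) -> tuple[AbundanceTable, LabelVector]:
    """Align a phenotype column to a table.

    Samples absent from the metadata, or with an empty / NA value in
    ``column``, are dropped; the surviving samples keep the table's order.
    """
    if column not in metadata.columns:
        raise ValueError(
            f"column {column!r} not in metadata (have: {metadata.columns})"
        )
    keep: list[int] = []
    values: list[str] = []
    for i, sid in enumerate(table.sample_ids):
        rec = metadata.records.get(sid)
        if rec is None:
            continue
        value = rec[column].strip()
        if value in _MISSING_VALUES:
            continue
        keep.append(i)
        values.append(value)
    if not keep:
        raise ValueError("no samples overlap between table and metadata")
    if len(set(values)) < 2:
        raise ValueError("fewer than two classes in phenotype column")
    sub = table.select_samples(keep)
    labels = LabelVector.from_values(values, sub.sample_ids)
    return sub, labels


def write_results(result, table: AbundanceTable, path: str) -> None:
    """Write a ranked-feature TSV: rank, feature_id, taxonomy, score."""
    k = table.n_features
    for idx in result.feature_indices:
        if not 0 <= idx < k:
            raise ValueError(f"selected feature index {idx} out of range for table")
    with open(path, "w") as fh:
        fh.write("rank\tfeature_id\ttaxonomy\tscore\n")
        for rank, (idx, score) in enumerate(
            zip(result.feature_indices, result.scores), start=1
        ):
            fh.write(
                f"{rank}\t{table.feature_ids[idx]}\t{table.taxonomy[idx]}\t{score:.10g}\n"
            )
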