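"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: OTU table as TSV (either orientation) or BIOM 1.0 JSON,
taxonomy and metadata as TSV, phylogeny as newick (via scikit-bio).
Round-trips (write then read) reproduce each object exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    RANKS,
    UNCLASSIFIED,
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
    validate_tree,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
]


def read_otu_table(path, format: str = "tsv", orientation: str = "samples") -> OtuTable:
    """Read an OTU table.

    Parameters
    ----------
    format
        ``"tsv"`` (tab-separated with a header row and an id column) or
        ``"biom-json"`` (BIOM 1.0 JSON, dense or sparse).
    orientation
        For TSV only: ``"samples"`` if rows are samples, ``"otus"`` if rows
        are OTUs (the table is transposed on read). BIOM files carry their
        own orientation (rows are observations/OTUs by convention).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if frame.columns.size == 0:
            raise ValidationError(f"{path}: no data columns found")
        try:
            frame = frame.apply(pd.to_numeric)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric count ({exc})") from exc
        if orientation == "otus":
            frame = frame.T
        elif orientation != "samples":
            raise ValueError("orientation must be 'samples' or 'otus'")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return OtuTable(frame)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise ValidationError(f"{path}: BIOM document missing key {key!r}")
    otu_ids = [r["id"] for r in doc["rows"]]       # rows = observations (OTUs)
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValidationError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    frame = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return OtuTable(frame)


def _write_biom_json(table: OtuTable, path: Path) -> None:
    mat = table.counts.to_numpy().T  # observations x samples
    rows, cols = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "digestnet",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [int(mat.shape[0]), int(mat.shape[1])],
        "rows": [{"id": str(o), "metadata": None} for o in table.otu_ids],
        "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(mat[i, j])] for i, j in zip(rows, cols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path, sep: str = ";") -> TaxonomyMap:
    """Read a two-column TSV: OTU id, lineage string.

    The lineage is split on *sep*; QIIME-style rank prefixes (``g__`` etc.)
    are tolerated and stripped. Lineages shorter than five ranks are padded
    with ``unclassified``.
    """
    lineages: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected two tab-separated fields")
            otu, lineage = parts[0], parts[1]
            labels = [tok.strip() for tok in lineage.split(sep)]
            labels = [_strip_prefix(tok) for tok in labels]
            entry = {}
            for k, rank in enumerate(RANKS):
                entry[rank] = labels[k] if k < len(labels) and labels[k] else UNCLASSIFIED
            lineages[otu] = entry
    return TaxonomyMap(lineages)


def _strip_prefix(token: str) -> str:
    if len(token) >= 3 and token[1:3] == "__":
        return token[3:]
    return token


def write_taxonomy(tax: TaxonomyMap, path, sep: str = ";") -> None:
    with open(path, "w") as fh:
        for otu, lin in tax.lineages.items():
            fh.write(otu + "\t" + sep.join(lin[r] for r in RANKS) + "\n")


def read_tree(path, table: OtuTable | None = None) -> TreeNode:
    """Read a rooted newick tree; validate leaves against *table* if given."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"{path}: malformed newick ({exc})") from exc
    return validate_tree(tree, table)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
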