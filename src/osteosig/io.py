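"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: TSV expression matrices (first column header ``gene``),
GCT 1.2, GMT gene-set collections, one-symbol-per-line signatures, clinical
TSVs, and JSON manifests for report bundles.  All readers reject non-numeric
or NaN-bearing cells with an error naming the offending location.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .types import ClinicalTable, ExpressionMatrix, GeneSetCollection, GeneSignature, warn

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_clinical",
    "write_clinical",
    "harmonize_symbols",
    "write_report_bundle",
]


class ParseError(ValueError):
    pass


def _parse_cell(token: str, path, line_no: int, col: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric cell {token!r} at line {line_no}, sample {col!r}"
        ) from None
    if not np.isfinite(v):
        raise ParseError(f"{path}: non-finite cell {token!r} at line {line_no}, sample {col!r}")
    return v


def _read_matrix_lines(lines, path, first_data_line, sample_ids, n_label_cols):
    genes, rows = [], []
    for offset, line in enumerate(lines):
        line_no = first_data_line + offset
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != n_label_cols + len(sample_ids):
            raise ParseError(
                f"{path}: line {line_no} has {len(parts)} fields, expected "
                f"{n_label_cols + len(sample_ids)}"
            )
        genes.append(parts[0])
        rows.append(
            [
                _parse_cell(tok, path, line_no, sample_ids[j])
                for j, tok in enumerate(parts[n_label_cols:])
            ]
        )
    return genes, np.asarray(rows, dtype=float)


def read_expression(path, format: str = "tsv", scale: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    Duplicate gene symbols are preserved as-is; collapsing them is an
    explicit preprocessing step.
    """
    path = Path(path)
    text = path.read_text().splitlines(keepends=True)
    if format == "tsv":
        if not text:
            raise ParseError(f"{path}: empty file")
        header = text[0].rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: malformed header at line 1 (need gene column + samples)")
        sample_ids = header[1:]
        genes, values = _read_matrix_lines(text[1:], path, 2, sample_ids, 1)
    elif format == "gct":
        if len(text) < 3 or not text[0].startswith("#1.2"):
            raise ParseError(f"{path}: line 1 must be the GCT version tag '#1.2'")
        try:
            n_genes, n_samples = (int(x) for x in text[1].split("\t")[:2])
        except ValueError:
            raise ParseError(f"{path}: malformed dimensions row at line 2") from None
        header = text[2].rstrip("\n").split("\t")
        if len(header) != n_samples + 2:
            raise ParseError(
                f"{path}: header at line 3 has {len(header)} fields, expected {n_samples + 2}"
            )
        sample_ids = header[2:]
        genes, values = _read_matrix_lines(text[3:], path, 4, sample_ids, 2)
        if len(genes) != n_genes:
            raise ParseError(f"{path}: dimensions row says {n_genes} rows, found {len(genes)}")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'gct'")
    mat = ExpressionMatrix(genes, sample_ids, values, scale)
    log.info("read %s: %d genes x %d samples (%s)", path, mat.n_genes, mat.n_samples, scale)
    return mat


def write_expression(mat: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    df = mat.to_frame()
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(mat.sample_ids) + "\n")
            for g, row in zip(mat.gene_ids, mat.values):
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{mat.n_genes}\t{mat.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(mat.sample_ids) + "\n")
            for g, row in zip(mat.gene_ids, mat.values):
                fh.write(g + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    del df


def read_gmt(path, name: Optional[str] = None) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then gene symbols."""
    path = Path(path)
    sets = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {line_no} has {len(parts)} fields, need >= 3")
        set_name = parts[0]
        if set_name in sets:
            raise ParseError(f"{path}: duplicate gene-set name {set_name!r} at line {line_no}")
        sets[set_name] = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not sets[set_name]:
            raise ParseError(f"{path}: gene set {set_name!r} at line {line_no} has no genes")
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name in sorted(collection.sets):
            genes = sorted(collection.sets[set_name])
            fh.write(set_name + "\tna\t" + "\t".join(genes) + "\n")


def read_signature(path, name: Optional[str] = None) -> GeneSignature:
    """Read a plain-text signature: one gene symbol per line."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSignature(name or path.stem, frozenset(genes))


def write_signature(sig: GeneSignature, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(sig.genes):
            fh.write(g + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def harmonize_symbols(
    signature: GeneSignature, target_genes: Iterable[str]
) -> Tuple[GeneSignature, list]:
    """Intersect a signature with a target gene universe after uppercasing.

    Returns the mapped signature and the sorted list of symbols that did not
    match.  Used to carry signatures across cohorts and species where gene
    identity is shared symbols; an empty intersection is reported as a
    warning and an empty ``mapped.genes`` is never constructed — the caller
    receives ``(None, dropped)`` in that case and decides how to proceed.
    """
    target = {str(g).upper() for g in target_genes}
    mapped = signature.genes & target
    dropped = sorted(signature.genes - target)
    if not mapped:
        warn(f"signature {signature.name!r}: no genes matched the target universe")
        return None, dropped
    return GeneSignature(signature.name, mapped), dropped


def _write_tsv(obj, path: Path) -> None:
    if isinstance(obj, ExpressionMatrix):
        write_expression(obj, path)
    elif isinstance(obj, ClinicalTable):
        obj.data.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} to TSV")


def write_report_bundle(results: dict, out_dir, params: Optional[dict] = None) -> dict:
    """Write tabular results plus a JSON manifest and return the manifest.

    ``results`` maps a short name to a DataFrame/Series/ExpressionMatrix/
    ClinicalTable (written as ``<name>.tsv``) or to a JSON-serializable
    object (written as ``<name>.json``).  The manifest lists every emitted
    file with the parameters and RNG seeds the caller supplies, so a rerun
    with the same seed and config is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for key in sorted(results):
        obj = results[key]
        if isinstance(obj, (ExpressionMatrix, ClinicalTable, pd.DataFrame, pd.Series)):
            fname = f"{key}.tsv"
            _write_tsv(obj, out_dir / fname)
        else:
            fname = f"{key}.json"
            with open(out_dir / fname, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        files.append(fname)
    manifest = {"files": files, "parameters": params or {}}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj).__name__}")
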