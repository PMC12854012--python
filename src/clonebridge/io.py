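"""Readers and writers for all external formats.

TCR contigs arrive either as AIRR Rearrangement TSV or as the 10x
``filtered_contig_annotations.csv`` dialect; both are mapped onto the same
:class:`~clonebridge.datamodel.ContigRecord` so downstream code never sees
the dialect.  Expression comes as an MTX triplet, gene sets as GMT, spatial
cells as a plain TSV.  Readers validate and count what they drop; writers
emit TSV only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    CellMeta,
    ChainProfile,
    ContigRecord,
    ExpressionMatrix,
    GeneSignature,
)

log = logging.getLogger(__name__)

AIRR_REQUIRED = ["cell_id", "locus", "junction", "junction_aa", "v_call", "j_call", "productive"]
TENX_REQUIRED = [
    "barcode",
    "chain",
    "cdr3_nt",
    "cdr3",
    "v_gene",
    "j_gene",
    "productive",
    "umis",
    "high_confidence",
]

_TRUE_STRINGS = {"t", "true", "1", "yes"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUE_STRINGS


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def read_airr(path, return_report: bool = False):
    """Read an AIRR Rearrangement TSV into contig records.

    Rows with loci other than TRA/TRB, or without a junction, are dropped
    and counted.  An empty file yields an empty list with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("AIRR file %s is empty", path)
        return ([], {"total": 0}) if return_report else []
    _require_columns(df, AIRR_REQUIRED, f"AIRR file {path}")
    report = {"total": len(df), "non_trab_locus": 0, "missing_junction": 0, "retained": 0}
    records: list[ContigRecord] = []
    umi_col = "duplicate_count" if "duplicate_count" in df.columns else None
    for row in df.itertuples(index=False):
        locus = getattr(row, "locus").strip()
        if locus not in ("TRA", "TRB"):
            report["non_trab_locus"] += 1
            continue
        junction = getattr(row, "junction").strip()
        if not junction:
            report["missing_junction"] += 1
            continue
        umis = 0
        if umi_col:
            raw = getattr(row, umi_col)
            umis = int(raw) if str(raw).strip() else 0
        records.append(
            ContigRecord(
                barcode=getattr(row, "cell_id"),
                locus=locus,
                cdr3_nt=junction,
                cdr3_aa=getattr(row, "junction_aa").strip(),
                v_call=getattr(row, "v_call").strip(),
                j_call=getattr(row, "j_call").strip(),
                productive=_parse_bool(getattr(row, "productive")),
                umis=umis,
            )
        )
    report["retained"] = len(records)
    if report["non_trab_locus"]:
        log.info("%s: dropped %d non-TRA/TRB rows", path, report["non_trab_locus"])
    if df.empty:
        log.warning("AIRR file %s has no rows", path)
    return (records, report) if return_report else records


def write_airr(records: Iterable[ContigRecord], path) -> None:
    """Write contig records as AIRR Rearrangement TSV (retained fields only)."""
    rows = [
        {
            "cell_id": r.barcode,
            "locus": r.locus,
            "junction": r.cdr3_nt,
            "junction_aa": r.cdr3_aa,
            "v_call": r.v_call,
            "j_call": r.j_call,
            "productive": "T" if r.productive else "F",
            "duplicate_count": r.umis,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=AIRR_REQUIRED + ["duplicate_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_10x_contigs(path, return_report: bool = False):
    """Read a 10x ``filtered_contig_annotations`` CSV.

    Only ``high_confidence`` rows are kept; ``chain`` maps to locus and
    ``cdr3`` to the amino-acid CDR3, so records compare equal to their AIRR
    encodings of the same cells.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("10x contig file %s is empty", path)
        return ([], {"total": 0}) if return_report else []
    _require_columns(df, TENX_REQUIRED, f"10x contig file {path}")
    report = {
        "total": len(df),
        "low_confidence": 0,
        "non_trab_locus": 0,
        "missing_junction": 0,
        "retained": 0,
    }
    records: list[ContigRecord] = []
    for row in df.itertuples(index=False):
        if not _parse_bool(row.high_confidence):
            report["low_confidence"] += 1
            continue
        chain = row.chain.strip()
        if chain not in ("TRA", "TRB"):
            report["non_trab_locus"] += 1
            continue
        if not row.cdr3_nt.strip():
            report["missing_junction"] += 1
            continue
        records.append(
            ContigRecord(
                barcode=row.barcode,
                locus=chain,
                cdr3_nt=row.cdr3_nt.strip(),
                cdr3_aa=row.cdr3.strip(),
                v_call=row.v_gene.strip(),
                j_call=row.j_gene.strip(),
                productive=_parse_bool(row.productive),
                umis=int(row.umis) if str(row.umis).strip() else 0,
            )
        )
    report["retained"] = len(records)
    return (records, report) if return_report else records


def build_chain_profiles(records: Iterable[ContigRecord]) -> dict[str, ChainProfile]:
    """Group productive contigs per barcode into canonical chain profiles.

    Chains within a locus are ordered by (cdr3_nt, v_call, j_call) then
    descending UMIs; cells whose chains are all non-productive get an empty
    profile.
    """
    by_bc: dict[str, dict[str, list[ContigRecord]]] = {}
    for r in records:
        slot = by_bc.setdefault(r.barcode, {"TRA": [], "TRB": []})
        if r.productive:
            slot[r.locus].append(r)
    order = lambda r: (r.cdr3_nt, r.v_call, r.j_call, -r.umis)
    return {
        bc: ChainProfile(
            barcode=bc,
            tra=tuple(sorted(slots["TRA"], key=order)),
            trb=tuple(sorted(slots["TRB"], key=order)),
        )
        for bc, slots in by_bc.items()
    }


# ---------------------------------------------------------------------------
# Cell metadata

_COMPARTMENT_ALIASES = {
    "blood": "blood",
    "pb": "blood",
    "skin": "skin",
    "st": "ST",
    "sf": "SF",
    "joint": "joint",
}

META_COLUMNS = ["barcode", "patient", "compartment", "lineage", "cluster_id"]


def normalize_compartment(value: str) -> str:
    try:
        return _COMPARTMENT_ALIASES[value.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown compartment {value!r}") from None


def read_cell_meta(path) -> list[CellMeta]:
    """Read the per-cell metadata TSV (barcode, patient, compartment, lineage,
    cluster_id); compartment strings are normalized case-insensitively."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, META_COLUMNS, f"cell metadata {path}")
    bad = sorted(
        {v for v in df["compartment"] if v.strip().lower() not in _COMPARTMENT_ALIASES}
    )
    if bad:
        raise ValueError(f"unknown compartment value(s) in {path}: {bad}")
    dup = df.duplicated(subset=["barcode", "patient"])
    if dup.any():
        raise ValueError(f"{path}: duplicated (barcode, patient) keys: {dup.sum()} rows")
    return [
        CellMeta(
            barcode=row.barcode,
            patient=row.patient,
            compartment=normalize_compartment(row.compartment),
            lineage=row.lineage.strip(),
            cluster_id=row.cluster_id.strip() or None,
        )
        for row in df.itertuples(index=False)
    ]


def write_cell_meta(meta: Iterable[CellMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "barcode": m.barcode,
                "patient": m.patient,
                "compartment": m.compartment,
                "lineage": m.lineage,
                "cluster_id": m.cluster_id or "",
            }
            for m in meta
        ],
        columns=META_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression


def read_expression(mtx_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read an MTX triplet (genes x cells) of normalized expression.

    Gene symbols are uppercased; duplicate symbols are collapsed by summing
    their rows (with a log message).
    """
    mat = scipy.io.mmread(str(mtx_path))
    mat = scipy.sparse.csr_matrix(mat) if scipy.sparse.issparse(mat) else scipy.sparse.csr_matrix(mat)
    genes = [
        line.split("\t")[0].strip().upper()
        for line in Path(features_path).read_text().splitlines()
        if line.strip()
    ]
    cells = [line.strip() for line in Path(barcodes_path).read_text().splitlines() if line.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX shape {mat.shape} inconsistent with {len(genes)} features x {len(cells)} barcodes"
        )
    dense = np.asarray(mat.todense(), dtype=float)
    if len(set(genes)) != len(genes):
        uniq = sorted(set(genes))
        idx = {g: i for i, g in enumerate(uniq)}
        collapsed = np.zeros((len(uniq), dense.shape[1]))
        for g, row in zip(genes, dense):
            collapsed[idx[g]] += row
        log.info("collapsed %d duplicate gene symbols by summation", len(genes) - len(uniq))
        genes, dense = uniq, collapsed
    return ExpressionMatrix(genes=genes, cells=cells, values=dense)


def write_expression(matrix: ExpressionMatrix, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(matrix.values))
    Path(features_path).write_text("\n".join(matrix.genes) + "\n")
    Path(barcodes_path).write_text("\n".join(matrix.cells) + "\n")


# ---------------------------------------------------------------------------
# Gene sets

DOWN_SUFFIX = "_DN"


def read_gmt(path) -> list[GeneSignature]:
    """Read GMT gene sets; a ``NAME_DN`` line supplies NAME's down-set."""
    ups: dict[str, frozenset[str]] = {}
    downs: dict[str, frozenset[str]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields in {path}: {line!r}")
        name, _desc, genes = parts[0], parts[1], frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if name.endswith(DOWN_SUFFIX):
            downs[name[: -len(DOWN_SUFFIX)]] = genes
        else:
            ups[name] = genes
            order.append(name)
    sigs = [
        GeneSignature(name=n, up=ups[n], down=downs.get(n, frozenset())) for n in order
    ]
    # down-only sets with no matching up line
    for n in downs:
        if n not in ups:
            sigs.append(GeneSignature(name=n, up=frozenset(), down=downs[n]))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path) -> None:
    lines = []
    for s in signatures:
        if s.up:
            lines.append("\t".join([s.name, "na", *sorted(s.up)]))
        if s.down:
            lines.append("\t".join([s.name + DOWN_SUFFIX, "na", *sorted(s.down)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spatial

SPATIAL_COLUMNS = ["cell_id", "x_um", "y_um", "fov", "cell_type"]


def read_spatial(path) -> pd.DataFrame:
    """Read a spatial cell table (cell_id, x_um, y_um, fov, cell_type)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "fov": str, "cell_type": str})
    _require_columns(df, SPATIAL_COLUMNS, f"spatial table {path}")
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return df[SPATIAL_COLUMNS].copy()


def write_spatial(cells: pd.DataFrame, path) -> None:
    cells[SPATIAL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Meta-cluster mapping TSV


def read_meta_cluster_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["cluster_id", "meta_cluster"], f"meta-cluster map {path}")
    return dict(zip(df["cluster_id"], df["meta_cluster"]))


def write_meta_cluster_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"cluster_id": list(mapping), "meta_cluster": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
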