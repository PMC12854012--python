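"""Shared data model for the cross-compartment repertoire pipeline.

Cells carry three layers of annotation that the analysis joins on barcode:
TCR chains (from contig tables), sample metadata (patient / anatomical
compartment / lineage / expression cluster), and optionally a normalized
gene-expression profile.  The types below are deliberately plain containers;
all behaviour lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Anatomical compartments sampled per patient.  "joint" only appears after
#: pooling synovial tissue (ST) and synovial fluid (SF).
COMPARTMENTS = ("blood", "skin", "ST", "SF")
POOLED_JOINT = "joint"
KNOWN_COMPARTMENTS = COMPARTMENTS + (POOLED_JOINT,)

LINEAGES = ("CD4", "CD8")

#: Meta-cluster vocabularies per lineage; coarse phenotype groupings used for
#: shared-clone concordance calls.
CD8_META_LABELS = ("Trm", "GZMK+", "CTL", "ANXA1+", "Tcm", "other")
CD4_META_LABELS = ("Trm", "Trm-like Treg", "Treg", "other")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled TCR contig for one cell.

    Only alpha/beta loci are modeled; readers drop other loci with a count.
    Out-of-frame CDR3s are allowed (they arrive flagged non-productive).
    """

    barcode: str
    locus: str  # "TRA" | "TRB"
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    productive: bool
    umis: int = 0

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ValueError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.umis < 0:
            raise ValueError("umis must be non-negative")


@dataclass(frozen=True)
class ChainProfile:
    """Productive chains of one cell, in canonical order.

    Chains are sorted by (cdr3_nt, v_call, j_call) then descending UMIs, so
    that profiles built from differently ordered inputs compare equal.
    """

    barcode: str
    tra: tuple[ContigRecord, ...] = ()
    trb: tuple[ContigRecord, ...] = ()

    @property
    def n_tra(self) -> int:
        return len(self.tra)

    @property
    def n_trb(self) -> int:
        return len(self.trb)

    @property
    def is_empty(self) -> bool:
        return not self.tra and not self.trb


@dataclass(frozen=True)
class CellMeta:
    """Per-cell sample annotation. (patient, barcode) is the unique cell key."""

    barcode: str
    patient: str
    compartment: str
    lineage: str
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.compartment not in KNOWN_COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")


@dataclass
class ExpressionMatrix:
    """Dense genes x cells matrix of upstream-normalized (log-scale) values.

    The pipeline never normalizes; values are taken as-is.  Gene symbols are
    uppercased on read and duplicates collapsed by summation.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # shape (n_genes, n_cells)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}
        if len(self._gene_index) != len(self.genes):
            raise ValueError("duplicate gene symbols after collapsing")

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def cell_columns(self, barcodes) -> np.ndarray:
        idx = [self._cell_index[b] for b in barcodes]
        return self.values[:, idx]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with expected directions (up / down)."""

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.name}: up and down sets overlap")
        if not (self.up or self.down):
            raise ValueError(f"{self.name}: empty signature")


# ---------------------------------------------------------------------------
# Clone calling


@dataclass(frozen=True)
class CloneKey:
    """Identity of a clone: canonicalized alpha and beta chain key lists.

    Each chain key is (cdr3, v_call, j_call) at the chosen resolution
    (nucleotide or amino acid).  Lists are sorted so equality is insensitive
    to chain order.  ``patient_scope`` is "public" for cross-patient keys.
    """

    patient_scope: str
    lineage: str
    tra_keys: tuple[tuple[str, str, str], ...]
    trb_keys: tuple[tuple[str, str, str], ...]
    resolution: str  # "nt" | "aa"

    @property
    def chain_key(self) -> tuple:
        """Patient-agnostic key used for public-clone matching."""
        return (self.lineage, self.tra_keys, self.trb_keys, self.resolution)

    def serialize(self) -> str:
        tra = "+".join("|".join(k) for k in self.tra_keys)
        trb = "+".join("|".join(k) for k in self.trb_keys)
        return f"{self.lineage};TRA={tra};TRB={trb};{self.resolution}"


@dataclass
class CloneRecord:
    clone_id: str
    key: CloneKey
    patient: str
    lineage: str
    counts: dict[str, int]  # compartment -> cell count
    barcodes: tuple[str, ...]
    beta_only: bool = False

    @property
    def size(self) -> int:
        return len(self.barcodes)


@dataclass
class ClonotypeTable:
    """Partition of clone-assigned cells into clones for one cohort."""

    resolution: str
    pairing: str
    clones: list[CloneRecord]
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return sum(c.size for c in self.clones)

    def patients(self) -> list[str]:
        return sorted({c.patient for c in self.clones})

    def compartments(self) -> list[str]:
        out: set[str] = set()
        for c in self.clones:
            out.update(k for k, v in c.counts.items() if v > 0)
        return sorted(out)

    def subset(self, lineage: Optional[str] = None, patient: Optional[str] = None) -> "ClonotypeTable":
        sel = [
            c
            for c in self.clones
            if (lineage is None or c.lineage == lineage)
            and (patient is None or c.patient == patient)
        ]
        return ClonotypeTable(self.resolution, self.pairing, sel, list(self.unassigned))

    def to_frame(self) -> pd.DataFrame:
        comps = self.compartments()
        rows = []
        for c in self.clones:
            row = {
                "clone_id": c.clone_id,
                "patient": c.patient,
                "lineage": c.lineage,
                "clone_key": c.key.serialize(),
                "n_cells": c.size,
                "beta_only": c.beta_only,
            }
            for comp in comps:
                row[f"n_{comp}"] = c.counts.get(comp, 0)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SharedClone:
    clone_id: str
    patient: str
    sizes: dict[str, int]
    triple: bool = False


@dataclass
class SharedCloneSet:
    """Clones detected in both compartments of ``pair`` (per patient)."""

    pair: tuple[str, str]
    clones: list[SharedClone]
    triple_with: Optional[str] = None

    @property
    def clone_ids(self) -> set[str]:
        return {c.clone_id for c in self.clones}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            row = {"clone_id": c.clone_id, "patient": c.patient, "triple": c.triple}
            for comp, n in sorted(c.sizes.items()):
                row[f"n_{comp}"] = n
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class OccupancySummary:
    """Percent of a compartment's clone-assigned repertoire in a clone set."""

    compartment: str
    per_patient: dict[str, float]  # patient -> percent in [0, 100]
    median: float


# ---------------------------------------------------------------------------
# Phenotype


@dataclass
class TrmDecision:
    """Decision trail of the two-stage Trm cluster classifier."""

    cluster_id: str
    marker_hits_up: frozenset[str] = frozenset()
    marker_hits_down: frozenset[str] = frozenset()
    potential: bool = False
    es: float = float("nan")
    nes: float = float("nan")
    gsea_p: float = float("nan")
    confirmed: bool = False

    @property
    def n_hits(self) -> int:
        return len(self.marker_hits_up) + len(self.marker_hits_down)


@dataclass
class MetaClusterMap:
    """User-supplied mapping of fine clusters to coarse meta-clusters."""

    lineage: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set(CD8_META_LABELS if self.lineage == "CD8" else CD4_META_LABELS)
        bad = sorted(set(self.mapping.values()) - allowed)
        if bad:
            raise ValueError(
                f"meta-cluster labels {bad} not in the {self.lineage} vocabulary {sorted(allowed)}"
            )

    def label(self, cluster_id: str) -> str:
        try:
            return self.mapping[cluster_id]
        except KeyError:
            raise KeyError(f"cluster {cluster_id!r} has no meta-cluster assignment") from None


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    n_hits: int


# ---------------------------------------------------------------------------
# Spatial


@dataclass
class SpatialCellMap:
    """Cells with coordinates and a within-fov contact graph.

    ``cells`` columns: cell_id, x_um, y_um, fov, cell_type.
    ``edges`` is an (n_edges, 2) integer array of row indices into ``cells``;
    edges never cross fov boundaries and contain no self-loops.
    """

    cells: pd.DataFrame
    edges: np.ndarray
    method: str = ""
    param: float = float("nan")

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(self.edges):
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("contact graph contains self-edges")
            fov = self.cells["fov"].to_numpy()
            if (fov[self.edges[:, 0]] != fov[self.edges[:, 1]]).any():
                raise ValueError("contact graph contains cross-fov edges")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cells["cell_type"].unique())
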