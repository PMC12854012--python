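"""Synthetic cohort generator with ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes for a
paired-compartment psoriatic-arthritis cohort: six patients each sampled in
blood and lesional skin, five with synovial tissue (ST) and five with
synovial fluid (SF); heavy-tailed clone-size distributions within each
compartment; planted skin-joint shared clones (optionally filling a target
occupancy), a subset also planted in blood ("triple shared"), and public
clones planted across patients as amino-acid-level key collisions with
distinct nucleotide sequences (so nucleotide- vs amino-acid-resolution
behavior is testable); cluster-structured log-scale expression with
directional Trm signature genes; and multi-type spatial point patterns with
planted pairwise attraction.

Everything is a pure function of (config, seed) and the returned ground
truth is sufficient to score each downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .datamodel import (
    CellMeta,
    ContigRecord,
    ExpressionMatrix,
    GeneSignature,
    MetaClusterMap,
)
from .phenotype import TRM_MARKERS_DOWN, TRM_MARKERS_UP, trm_marker_signature

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)
_AA_OF = {c: str(Seq(c).translate()) for c in _SENSE_CODONS}
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for codon, aa in _AA_OF.items():
    _SYNONYMS.setdefault(aa, ())
    _SYNONYMS[aa] = _SYNONYMS[aa] + (codon,)

TRAV = ("TRAV1-2", "TRAV8-4", "TRAV12-1", "TRAV17", "TRAV21", "TRAV29")
TRAJ = ("TRAJ12", "TRAJ23", "TRAJ33", "TRAJ42", "TRAJ49")
TRBV = ("TRBV2", "TRBV6-5", "TRBV7-9", "TRBV19", "TRBV20-1", "TRBV28")
TRBJ = ("TRBJ1-1", "TRBJ1-5", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7")

#: Fine expression clusters per lineage and the default meta-cluster map,
#: mirroring a typical memory T cell clustering of these tissues.
CD8_CLUSTER_META = {
    "c1": "Trm",
    "c2": "Trm",
    "c4": "Trm",
    "c8": "Trm",
    "c14": "Trm",
    "c15": "Trm",
    "c0": "GZMK+",
    "c11": "GZMK+",
    "c3": "CTL",
    "c6": "CTL",
    "c12": "CTL",
    "c5": "Tcm",
    "c7": "Tcm",
    "c9": "Tcm",
    "c10": "ANXA1+",
    "c16": "ANXA1+",
    "c13": "other",
    "c17": "other",
    "c18": "other",
}
CD4_CLUSTER_META = {
    "d6": "Trm",
    "d9": "Trm",
    "d10": "Trm",
    "d15": "Trm",
    "d11": "Trm-like Treg",
    "d13": "Trm-like Treg",
    "d2": "Treg",
    "d12": "Treg",
    "d0": "other",
    "d1": "other",
    "d3": "other",
}

CONCORDANCE_CLASSES = ("same", "similar", "different")

#: Cytotoxicity genes up-shifted in shared-clone cells when requested.
SHARED_EFFECT_GENES = ("GZMB", "GZMH", "GNLY", "PRF1", "NKG7")

#: Synthetic stand-in for a core tissue-residency gene signature
#: (plausible residency-associated genes; replace with a real GMT when one
#: is available).
CORE_TRM_GENES = (
    "ZNF683",
    "PRDM1",
    "RUNX3",
    "CRTAM",
    "CXCL13",
    "DUSP6",
    "RGS1",
    "CD101",
    "TNFRSF9",
    "IL2RB",
    "CCR8",
    "SPRY1",
    "PDE4A",
    "NR4A1",
    "NR4A2",
    "VIM",
    "CAPG",
    "LGALS3",
    "FABP5",
    "PTGER4",
)


def core_trm_signature() -> GeneSignature:
    """Synthetic core Trm up-signature used by the stage-two GSEA."""
    return GeneSignature(name="TRM_CORE_SYNTHETIC", up=frozenset(CORE_TRM_GENES))


def default_meta_cluster_map(lineage: str = "CD8") -> MetaClusterMap:
    mapping = CD8_CLUSTER_META if lineage == "CD8" else CD4_CLUSTER_META
    return MetaClusterMap(lineage=lineage, mapping=dict(mapping))


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated cohort design: 6 patients, skin and blood
    for all, ST for patients 1-5, SF for patients 2-6, and a power-law
    clone-size distribution (alpha = 2.5) reflecting heavy-tailed clonal
    expansion.  Planted counts are cohort totals allocated round-robin over
    the patients that have both skin and a joint compartment.
    """

    n_patients: int = 6
    cells_per_compartment: int = 500
    clone_size_law: str = "powerlaw"  # powerlaw | logseries | uniform
    powerlaw_alpha: float = 2.5
    logseries_theta: float = 0.9
    uniform_max: int = 10
    n_planted_shared: int = 10
    n_planted_triple: int = 3
    n_planted_public: int = 2
    shared_occupancy: Optional[float] = None  # target fraction of skin & joint repertoires
    concordance_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)
    cd8_fraction: float = 0.7
    beta_only_fraction: float = 0.0  # cells emitted without a TRA chain
    # expression
    n_trm_clusters: int = 3
    n_other_clusters: int = 5
    cells_per_cluster: int = 200
    trm_delta: float = 1.0  # log-unit shift of signature genes in true-Trm clusters
    noise_sd: float = 0.5
    baseline_mean: float = 1.0
    n_background_genes: int = 90
    shared_effect_delta: float = 1.0
    # spatial
    n_fovs: int = 4
    fov_size_um: float = 510.0
    type_intensities: dict[str, float] = field(
        default_factory=lambda: {"CD8_Trm": 40.0, "Macrophage": 40.0, "Fibroblast": 80.0}
    )
    attraction: dict[tuple[str, str], float] = field(default_factory=dict)
    attraction_radius_um: float = 15.0
    seed: int = 0

    def compartments_of(self, patient_index: int) -> tuple[str, ...]:
        comps = ["blood", "skin"]
        if patient_index < self.n_patients - 1:
            comps.append("ST")
        if patient_index > 0 or self.n_patients == 1:
            comps.append("SF")
        return tuple(comps)

    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def validate(self) -> None:
        if abs(sum(self.concordance_probs) - 1.0) > 1e-9:
            raise ValueError("concordance class probabilities must sum to 1")
        if self.clone_size_law not in ("powerlaw", "logseries", "uniform"):
            raise ValueError(f"unknown clone-size law {self.clone_size_law!r}")
        if self.shared_occupancy is not None and not (0 < self.shared_occupancy < 1):
            raise ValueError("shared_occupancy must be a fraction in (0, 1)")
        hosts = [i for i in range(self.n_patients) if len(self.compartments_of(i)) > 2]
        if self.n_planted_shared and not hosts:
            raise ValueError("no patient has both skin and a joint compartment")
        if self.n_planted_triple > self.n_planted_shared:
            raise ValueError("triple-shared clones are a subset of shared clones")
        if self.n_planted_public and self.n_patients < 2:
            raise ValueError("public clones require at least 2 patients")
        # rough feasibility: planted shared cells must fit in each compartment
        per_host = -(-self.n_planted_shared // max(1, len(hosts)))
        if per_host * 4 > self.cells_per_compartment:
            raise ValueError("planted shared clones do not fit in cells_per_compartment")


@dataclass
class GroundTruth:
    """Planted structure, keyed so pipeline outputs can be scored exactly."""

    shared_nt_keys: set = field(default_factory=set)
    triple_nt_keys: set = field(default_factory=set)
    public_aa_keys: set = field(default_factory=set)
    concordance_by_key: dict = field(default_factory=dict)
    planted_occupancy: Optional[float] = None
    trm_clusters: set = field(default_factory=set)
    attraction_pairs: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# TCR sequence machinery


def _random_cdr3(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in codons)


def _recode_synonymous(nt: str, rng: np.random.Generator) -> str:
    """Return a distinct nucleotide sequence with identical translation."""
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    out = list(codons)
    changeable = [i for i, c in enumerate(codons) if len(_SYNONYMS[_AA_OF[c]]) > 1]
    if not changeable:  # all Met/Trp: practically impossible at CDR3 lengths
        raise ValueError("sequence cannot be synonymously recoded")
    # change at least one codon, each with probability 1/2
    flips = [i for i in changeable if rng.random() < 0.5] or [changeable[0]]
    for i in flips:
        options = [c for c in _SYNONYMS[_AA_OF[codons[i]]] if c != codons[i]]
        out[i] = options[rng.integers(len(options))]
    return "".join(out)


@dataclass(frozen=True)
class _Tcr:
    tra_nt: str
    trb_nt: str
    tra_v: str
    tra_j: str
    trb_v: str
    trb_j: str

    @property
    def tra_aa(self) -> str:
        return str(Seq(self.tra_nt).translate())

    @property
    def trb_aa(self) -> str:
        return str(Seq(self.trb_nt).translate())

    def key(self, resolution: str) -> tuple:
        if resolution == "nt":
            return (
                ((self.tra_nt, self.tra_v, self.tra_j),),
                ((self.trb_nt, self.trb_v, self.trb_j),),
            )
        return (
            ((self.tra_aa, self.tra_v, self.tra_j),),
            ((self.trb_aa, self.trb_v, self.trb_j),),
        )


def _new_tcr(rng: np.random.Generator, used_nt: set) -> _Tcr:
    while True:
        tcr = _Tcr(
            tra_nt=_random_cdr3(rng, int(rng.integers(10, 19))),
            trb_nt=_random_cdr3(rng, int(rng.integers(10, 19))),
            tra_v=TRAV[rng.integers(len(TRAV))],
            tra_j=TRAJ[rng.integers(len(TRAJ))],
            trb_v=TRBV[rng.integers(len(TRBV))],
            trb_j=TRBJ[rng.integers(len(TRBJ))],
        )
        if (tcr.tra_nt, tcr.trb_nt) not in used_nt:
            used_nt.add((tcr.tra_nt, tcr.trb_nt))
            return tcr


def _clone_sizes(config: SimConfig, rng: np.random.Generator, n_cells: int) -> list[int]:
    """Draw clone sizes from the configured law until ``n_cells`` are filled."""
    sizes: list[int] = []
    left = n_cells
    while left > 0:
        if config.clone_size_law == "powerlaw":
            s = int(rng.zipf(config.powerlaw_alpha))
        elif config.clone_size_law == "logseries":
            s = int(rng.logseries(config.logseries_theta))
        else:
            s = int(rng.integers(1, config.uniform_max + 1))
        s = min(s, 50, left)
        sizes.append(s)
        left -= s
    return sizes


def _split_budget(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` into ``parts`` integers, each >= minimum."""
    if total < parts * minimum:
        raise ValueError("budget too small for planted clones")
    sizes = [minimum] * parts
    for _ in range(total - parts * minimum):
        sizes[rng.integers(parts)] += 1
    return sizes


# ---------------------------------------------------------------------------
# Repertoire simulation


def simulate_repertoire(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ContigRecord], list[CellMeta], GroundTruth]:
    """Generate contigs and metadata for the full multi-compartment cohort.

    Planted skin-joint shared clones get cells in both skin and a joint
    compartment of their host patient; the first ``n_planted_triple`` of
    them also get blood cells; public clones are planted in two patients
    with synonymously recoded (distinct-nucleotide, identical-amino-acid)
    chains.  Background clones are confined to a single compartment.  When
    ``shared_occupancy`` is set, the planted shared cells fill that fraction
    of each host patient's skin and joint repertoires.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    used_nt: set = set()
    truth = GroundTruth(planted_occupancy=config.shared_occupancy)

    patients = config.patients()
    meta_rows: list[CellMeta] = []
    contigs: list[ContigRecord] = []
    counter = {"cell": 0}
    cd8_map = default_meta_cluster_map("CD8")
    label_clusters: dict[str, list[str]] = {}
    for cl, lab in CD8_CLUSTER_META.items():
        label_clusters.setdefault(lab, []).append(cl)
    meta_labels = sorted(label_clusters)

    def emit_cell(patient: str, compartment: str, lineage: str, tcr: _Tcr, cluster: Optional[str]) -> None:
        counter["cell"] += 1
        bc = f"{patient}_{compartment}_{counter['cell']:06d}"
        meta_rows.append(
            CellMeta(barcode=bc, patient=patient, compartment=compartment, lineage=lineage, cluster_id=cluster)
        )
        beta_only = rng.random() < config.beta_only_fraction
        if not beta_only:
            contigs.append(
                ContigRecord(
                    barcode=bc,
                    locus="TRA",
                    cdr3_nt=tcr.tra_nt,
                    cdr3_aa=tcr.tra_aa,
                    v_call=tcr.tra_v,
                    j_call=tcr.tra_j,
                    productive=True,
                    umis=int(rng.integers(1, 21)),
                )
            )
        contigs.append(
            ContigRecord(
                barcode=bc,
                locus="TRB",
                cdr3_nt=tcr.trb_nt,
                cdr3_aa=tcr.trb_aa,
                v_call=tcr.trb_v,
                j_call=tcr.trb_j,
                productive=True,
                umis=int(rng.integers(1, 21)),
            )
        )

    def random_cluster() -> str:
        cl = sorted(CD8_CLUSTER_META)
        return cl[rng.integers(len(cl))]

    def concordance_clusters(cls: str) -> tuple[list[str], list[str]]:
        """(skin label pool, joint label pool) realizing a concordance class."""
        labels = meta_labels
        if cls == "same":
            lab = labels[rng.integers(len(labels))]
            return [lab], [lab]
        i, j = rng.choice(len(labels), size=2, replace=False)
        a, b = labels[int(i)], labels[int(j)]
        if cls == "similar":
            return [a, b], [a]
        return [a], [b]

    # --- planted skin-joint shared clones, allocated round-robin over hosts
    hosts = [i for i in range(config.n_patients) if len(config.compartments_of(i)) > 2]
    planted: list[dict] = []
    for s in range(config.n_planted_shared):
        host = hosts[s % len(hosts)]
        cls = CONCORDANCE_CLASSES[
            rng.choice(3, p=np.asarray(config.concordance_probs))
        ]
        planted.append(
            {
                "patient_index": host,
                "tcr": _new_tcr(rng, used_nt),
                "class": cls,
                "triple": s < config.n_planted_triple,
            }
        )

    planted_cells: dict[tuple[str, str], int] = {}  # (patient, compartment) -> planted count
    for host in hosts:
        mine = [p for p in planted if p["patient_index"] == host]
        if not mine:
            continue
        patient = patients[host]
        joint_comps = [c for c in config.compartments_of(host) if c in ("ST", "SF")]
        if config.shared_occupancy is not None:
            # the target is a fraction of the CD8 repertoire: planted cells are
            # CD8, background cells split cd8_fraction/1-cd8_fraction, so solve
            # P = occ * (P + cd8_fraction * (total - P)) for the planted count P
            occ, f = config.shared_occupancy, config.cd8_fraction

            def budget(n_total: int) -> int:
                return round(occ * f * n_total / (1.0 - (1.0 - f) * occ))

            skin_budget = budget(config.cells_per_compartment)
            joint_budget = budget(config.cells_per_compartment * len(joint_comps))
            skin_sizes = _split_budget(skin_budget, len(mine), 2, rng)
            joint_sizes = _split_budget(joint_budget, len(mine), 1, rng)
        else:
            skin_sizes = [
                int(rng.integers(2 if p["class"] == "similar" else 1, 5)) for p in mine
            ]
            joint_sizes = [int(rng.integers(1, 5)) for p in mine]
        for p, n_skin, n_joint in zip(mine, skin_sizes, joint_sizes):
            if p["class"] == "similar":
                n_skin = max(n_skin, 2)
            skin_pool, joint_pool = concordance_clusters(p["class"])
            nt_key = ("CD8",) + p["tcr"].key("nt")
            truth.shared_nt_keys.add(nt_key)
            truth.concordance_by_key[nt_key] = p["class"]
            if p["triple"]:
                truth.triple_nt_keys.add(nt_key)
            # skin cells: 'similar' clones must realize both labels in skin
            for i in range(n_skin):
                lab = skin_pool[i % len(skin_pool)]
                cluster = label_clusters[lab][rng.integers(len(label_clusters[lab]))]
                emit_cell(patient, "skin", "CD8", p["tcr"], cluster)
            planted_cells[(patient, "skin")] = planted_cells.get((patient, "skin"), 0) + n_skin
            for i in range(n_joint):
                comp = joint_comps[int(rng.integers(len(joint_comps)))]
                lab = joint_pool[i % len(joint_pool)]
                cluster = label_clusters[lab][rng.integers(len(label_clusters[lab]))]
                emit_cell(patient, comp, "CD8", p["tcr"], cluster)
                planted_cells[(patient, comp)] = planted_cells.get((patient, comp), 0) + 1
            if p["triple"]:
                n_blood = int(rng.integers(1, 4))
                for _ in range(n_blood):
                    emit_cell(patient, "blood", "CD8", p["tcr"], random_cluster())
                planted_cells[(patient, "blood")] = (
                    planted_cells.get((patient, "blood"), 0) + n_blood
                )

    # --- planted public clones: same amino acids, distinct nucleotides
    for _ in range(config.n_planted_public):
        base = _new_tcr(rng, used_nt)
        i, j = rng.choice(config.n_patients, size=2, replace=False)
        donors = [patients[int(i)], patients[int(j)]]
        truth.public_aa_keys.add(("CD8",) + base.key("aa"))
        for rank, donor in enumerate(donors):
            if rank == 0:
                tcr = base
            else:
                while True:
                    tcr = _Tcr(
                        tra_nt=_recode_synonymous(base.tra_nt, rng),
                        trb_nt=_recode_synonymous(base.trb_nt, rng),
                        tra_v=base.tra_v,
                        tra_j=base.tra_j,
                        trb_v=base.trb_v,
                        trb_j=base.trb_j,
                    )
                    if (tcr.tra_nt, tcr.trb_nt) not in used_nt:
                        used_nt.add((tcr.tra_nt, tcr.trb_nt))
                        break
            n = int(rng.integers(1, 4))
            for _ in range(n):
                emit_cell(donor, "blood", "CD8", tcr, random_cluster())
            planted_cells[(donor, "blood")] = planted_cells.get((donor, "blood"), 0) + n

    # --- background clones, confined to one compartment each
    for pi, patient in enumerate(patients):
        for comp in config.compartments_of(pi):
            remaining = config.cells_per_compartment - planted_cells.get((patient, comp), 0)
            if remaining <= 0:
                continue
            n_cd8 = round(config.cd8_fraction * remaining)
            for lineage, n_lin in (("CD8", n_cd8), ("CD4", remaining - n_cd8)):
                for size in _clone_sizes(config, rng, n_lin):
                    tcr = _new_tcr(rng, used_nt)
                    for _ in range(size):
                        emit_cell(patient, comp, lineage, tcr, random_cluster())
    return contigs, meta_rows, truth


# ---------------------------------------------------------------------------
# Expression simulation


def _gene_universe(config: SimConfig) -> list[str]:
    sig = trm_marker_signature()
    genes = list(TRM_MARKERS_UP) + list(TRM_MARKERS_DOWN) + list(CORE_TRM_GENES)
    genes += list(SHARED_EFFECT_GENES)
    genes += [f"BG{i:03d}" for i in range(1, config.n_background_genes + 1)]
    assert len(set(genes)) == len(genes)
    return genes


def simulate_expression(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    meta: Optional[list[CellMeta]] = None,
    shared_barcodes: Optional[set] = None,
) -> tuple[ExpressionMatrix, dict[str, str], GroundTruth]:
    """Cluster-structured Gaussian log-expression with planted Trm shifts.

    Without ``meta``, a standalone design of ``n_trm_clusters`` true-Trm and
    ``n_other_clusters`` other clusters with ``cells_per_cluster`` cells each
    is generated (used for classifier calibration).  With ``meta``, one
    expression profile per metadata cell is generated and a cell is treated
    as Trm-cluster resident when its cluster maps to the Trm meta-cluster.

    True-Trm clusters shift the residency markers by +/- ``trm_delta`` (up
    markers and the core signature up, down markers down); every other
    cluster gets its own archetype shift on three background genes so
    clusters are distinguishable.  ``shared_barcodes`` cells additionally
    get the cytotoxicity genes up-shifted by ``shared_effect_delta``.
    Values are clipped at zero (normalized log-scale data is non-negative).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = _gene_universe(config)
    gidx = {g: i for i, g in enumerate(genes)}
    truth = GroundTruth()

    if meta is None:
        cluster_names = [f"trm{i + 1}" for i in range(config.n_trm_clusters)] + [
            f"oth{i + 1}" for i in range(config.n_other_clusters)
        ]
        cells = []
        clusters: dict[str, str] = {}
        for cl in cluster_names:
            for i in range(config.cells_per_cluster):
                bc = f"{cl}_{i:04d}"
                cells.append(bc)
                clusters[bc] = cl
        is_trm = {cl: cl.startswith("trm") for cl in cluster_names}
    else:
        cells = [m.barcode for m in meta]
        clusters = {m.barcode: (m.cluster_id or "unknown") for m in meta}
        cluster_names = sorted(set(clusters.values()))
        trm_cl = {cl for cl, lab in CD8_CLUSTER_META.items() if lab == "Trm"} | {
            cl for cl, lab in CD4_CLUSTER_META.items() if lab == "Trm"
        }
        is_trm = {cl: cl in trm_cl for cl in cluster_names}
    truth.trm_clusters = {cl for cl, t in is_trm.items() if t}

    mean = np.full((len(cluster_names), len(genes)), config.baseline_mean)
    cl_index = {cl: i for i, cl in enumerate(cluster_names)}
    for cl in cluster_names:
        i = cl_index[cl]
        if is_trm[cl]:
            for g in list(TRM_MARKERS_UP) + list(CORE_TRM_GENES):
                mean[i, gidx[g]] += config.trm_delta
            for g in TRM_MARKERS_DOWN:
                mean[i, gidx[g]] = max(0.0, mean[i, gidx[g]] - config.trm_delta)
        else:
            # cluster identity: archetype shift on three dedicated bg genes
            picks = rng.choice(config.n_background_genes, size=3, replace=False)
            for p in picks:
                mean[i, gidx[f"BG{p + 1:03d}"]] += 1.0

    col_means = np.stack([mean[cl_index[clusters[bc]]] for bc in cells], axis=1)
    values = col_means + rng.normal(0.0, config.noise_sd, size=col_means.shape)
    if shared_barcodes:
        sh = [k for k, bc in enumerate(cells) if bc in shared_barcodes]
        for g in SHARED_EFFECT_GENES:
            values[gidx[g], sh] += config.shared_effect_delta
    values = np.clip(values, 0.0, None)
    matrix = ExpressionMatrix(genes=genes, cells=list(cells), values=values)
    return matrix, clusters, truth


# ---------------------------------------------------------------------------
# Spatial simulation


def simulate_spatial(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-type spatial point pattern with optional pairwise attraction.

    Each fov draws Poisson counts per type at the configured intensities and
    places cells uniformly; for an attraction entry ``(A, B): f``, a
    fraction ``f`` of A cells is instead placed within
    ``attraction_radius_um`` of a randomly chosen B cell of the same fov.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    truth = GroundTruth(attraction_pairs=set(config.attraction))
    attracted = {a: (b, f) for (a, b), f in config.attraction.items()}
    order = sorted(config.type_intensities, key=lambda t: (t in attracted, t))
    size = config.fov_size_um
    rows = []
    cid = 0
    for fov in range(1, config.n_fovs + 1):
        placed: dict[str, list[tuple[float, float]]] = {}
        for ctype in order:
            n = int(rng.poisson(config.type_intensities[ctype]))
            pts = []
            partner = attracted.get(ctype)
            for _ in range(n):
                if partner and placed.get(partner[0]) and rng.random() < partner[1]:
                    bx, by = placed[partner[0]][rng.integers(len(placed[partner[0]]))]
                    r = config.attraction_radius_um * np.sqrt(rng.random())
                    theta = rng.random() * 2 * np.pi
                    x = min(max(bx + r * np.cos(theta), 0.0), size)
                    y = min(max(by + r * np.sin(theta), 0.0), size)
                else:
                    x, y = rng.random() * size, rng.random() * size
                pts.append((x, y))
            placed[ctype] = pts
            for x, y in pts:
                cid += 1
                rows.append(
                    {
                        "cell_id": f"sp{cid:05d}",
                        "x_um": x,
                        "y_um": y,
                        "fov": f"F{fov}",
                        "cell_type": ctype,
                    }
                )
    return pd.DataFrame(rows), truth
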