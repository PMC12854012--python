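"""Clone calling: partition cells into clonotypes by paired TCRa/b identity.

A clone is a group of T cells expressing identical alpha and beta chains.
Identity is evaluated on the full canonical chain key-lists (so cells with
two productive alpha chains only merge when both match), within one
(patient, lineage) repertoire, at nucleotide or amino-acid resolution.
Because random V(D)J recombination essentially never produces the same
nucleotide junction twice independently, matching chains imply common
clonal descent.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Optional

from .datamodel import (
    COMPARTMENTS,
    POOLED_JOINT,
    CellMeta,
    ChainProfile,
    CloneKey,
    CloneRecord,
    ClonotypeTable,
)

log = logging.getLogger(__name__)

RESOLUTIONS = ("nt", "aa")
PAIRINGS = ("strict", "beta_fallback")


def _chain_keys(chains, resolution: str, use_vj: bool) -> tuple[tuple[str, str, str], ...]:
    keys = [
        (
            c.cdr3_nt if resolution == "nt" else c.cdr3_aa,
            c.v_call if use_vj else "",
            c.j_call if use_vj else "",
        )
        for c in chains
    ]
    return tuple(sorted(keys))


def call_clones(
    profiles: Mapping[str, ChainProfile],
    meta: Iterable[CellMeta],
    resolution: str = "nt",
    pairing: str = "strict",
    use_vj: bool = True,
) -> ClonotypeTable:
    """Partition cells into clones by identical paired chain keys.

    Parameters
    ----------
    profiles : mapping barcode -> ChainProfile
        Productive chains per cell.
    meta : iterable of CellMeta
        Every barcode in ``profiles`` must have metadata.
    resolution : "nt" or "aa"
        Whether CDR3 identity is read at nucleotide or amino-acid level.
    pairing : "strict" or "beta_fallback"
        Strict mode leaves cells lacking a productive TRA or TRB unassigned;
        beta_fallback additionally groups TRB-only cells by their beta keys
        into flagged clones.
    use_vj : bool
        Require V and J gene identity in addition to CDR3 identity.

    Clone ids are deterministic: within each (patient, lineage) the clones
    are numbered by lexicographic rank of their serialized key.
    """
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be one of {RESOLUTIONS}")
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {PAIRINGS}")
    meta_by_bc = {m.barcode: m for m in meta}
    missing = sorted(b for b in profiles if b not in meta_by_bc)
    if missing:
        raise ValueError(f"{len(missing)} barcode(s) lack metadata, e.g. {missing[:5]}")

    groups: dict[tuple, list[str]] = defaultdict(list)
    unassigned: list[str] = []
    for bc, prof in profiles.items():
        m = meta_by_bc[bc]
        tra = _chain_keys(prof.tra, resolution, use_vj)
        trb = _chain_keys(prof.trb, resolution, use_vj)
        if trb and tra:
            groups[(m.patient, m.lineage, tra, trb, False)].append(bc)
        elif trb and pairing == "beta_fallback":
            groups[(m.patient, m.lineage, (), trb, True)].append(bc)
        else:
            unassigned.append(bc)

    clones: list[CloneRecord] = []
    by_scope: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for gkey in groups:
        by_scope[(gkey[0], gkey[1])].append(gkey)
    for (patient, lineage), gkeys in sorted(by_scope.items()):
        keyed = []
        for gkey in gkeys:
            _, _, tra, trb, beta_only = gkey
            ck = CloneKey(
                patient_scope=patient,
                lineage=lineage,
                tra_keys=tra,
                trb_keys=trb,
                resolution=resolution,
            )
            keyed.append((ck.serialize(), ck, gkey, beta_only))
        keyed.sort(key=lambda t: t[0])
        for rank, (_, ck, gkey, beta_only) in enumerate(keyed):
            barcodes = tuple(sorted(groups[gkey]))
            counts: dict[str, int] = defaultdict(int)
            for bc in barcodes:
                counts[meta_by_bc[bc].compartment] += 1
            clones.append(
                CloneRecord(
                    clone_id=f"{patient}:{lineage}:{rank:05d}",
                    key=ck,
                    patient=patient,
                    lineage=lineage,
                    counts=dict(counts),
                    barcodes=barcodes,
                    beta_only=beta_only,
                )
            )
    if unassigned:
        log.info("%d cells left unassigned (missing paired productive chains)", len(unassigned))
    return ClonotypeTable(
        resolution=resolution, pairing=pairing, clones=clones, unassigned=sorted(unassigned)
    )


def pool_joint(table: ClonotypeTable) -> ClonotypeTable:
    """Merge ST and SF counts into one "joint" compartment.

    Synovial tissue and synovial fluid repertoires are highly similar, so
    pooling them increases power to detect clones shared between the skin
    and the joint; blood and skin counts are unchanged.
    """
    pooled = []
    for c in table.clones:
        counts: dict[str, int] = {}
        for comp, n in c.counts.items():
            target = POOLED_JOINT if comp in ("ST", "SF") else comp
            counts[target] = counts.get(target, 0) + n
        pooled.append(
            CloneRecord(
                clone_id=c.clone_id,
                key=c.key,
                patient=c.patient,
                lineage=c.lineage,
                counts=counts,
                barcodes=c.barcodes,
                beta_only=c.beta_only,
            )
        )
    return ClonotypeTable(table.resolution, table.pairing, pooled, list(table.unassigned))


def pooled_compartment(compartment: str) -> str:
    """Map a raw compartment to its post-pooling name (ST/SF -> joint)."""
    return POOLED_JOINT if compartment in ("ST", "SF") else compartment


def find_public_clones(
    tables: Iterable[ClonotypeTable],
) -> list[tuple[CloneKey, tuple[str, ...]]]:
    """Find clone keys present in two or more patients ("public" clones).

    Matching ignores patient scope and compares (lineage, alpha keys, beta
    keys) at the tables' resolution.  Beta-only fallback clones are excluded
    (a lone beta chain is weak evidence of shared ancestry across donors).
    Public clones are reported independently of within-patient sharing.
    """
    tables = list(tables)
    if len({t.resolution for t in tables}) > 1:
        raise ValueError("all tables must share one resolution for public matching")
    patients_by_key: dict[tuple, set[str]] = defaultdict(set)
    key_obj: dict[tuple, CloneKey] = {}
    for t in tables:
        for c in t.clones:
            if c.beta_only:
                continue
            k = c.key.chain_key
            patients_by_key[k].add(c.patient)
            key_obj[k] = c.key
    out = []
    for k, patients in patients_by_key.items():
        if len(patients) >= 2:
            ck = key_obj[k]
            public = CloneKey(
                patient_scope="public",
                lineage=ck.lineage,
                tra_keys=ck.tra_keys,
                trb_keys=ck.trb_keys,
                resolution=ck.resolution,
            )
            out.append((public, tuple(sorted(patients))))
    out.sort(key=lambda t: t[0].serialize())
    return out
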