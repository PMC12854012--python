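"""Shared-clone detection, repertoire occupancy, and clonality statistics.

A shared clone is a clonotype with member cells in both compartments of a
named pair (canonically skin and the pooled joint); a triple-shared clone
is a skin-joint shared clone also seen in blood.  Occupancy measures what
fraction of a compartment's clone-assigned repertoire those clones take up,
and the inverse Pielou score summarizes clonal expansion (0 = perfectly
polyclonal, 1 = monoclonal).
"""

from __future__ import annotations

import logging
from statistics import median as _median
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    KNOWN_COMPARTMENTS,
    ClonotypeTable,
    OccupancySummary,
    SharedClone,
    SharedCloneSet,
)

log = logging.getLogger(__name__)


def find_shared_clones(
    table: ClonotypeTable,
    pair: tuple[str, str] = ("skin", "joint"),
    triple_with: Optional[str] = "blood",
) -> SharedCloneSet:
    """Return clones with at least one cell in each compartment of ``pair``.

    When ``triple_with`` is given, shared clones also present in that third
    compartment are flagged (for the skin-joint pair this marks the
    "triple shared" clones seen in blood as well).  Apply
    :func:`clonebridge.clones.pool_joint` first when the pair involves the
    pooled joint.
    """
    a, b = pair
    for comp in (a, b, *((triple_with,) if triple_with else ())):
        if comp not in KNOWN_COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r}")
    if a == b:
        raise ValueError("pair must name two distinct compartments")
    shared = []
    for c in table.clones:
        na, nb = c.counts.get(a, 0), c.counts.get(b, 0)
        if na > 0 and nb > 0:
            triple = bool(triple_with) and c.counts.get(triple_with, 0) > 0
            shared.append(
                SharedClone(clone_id=c.clone_id, patient=c.patient, sizes=dict(c.counts), triple=triple)
            )
    return SharedCloneSet(pair=(a, b), clones=shared, triple_with=triple_with)


def occupancy(
    table: ClonotypeTable,
    shared: SharedCloneSet,
    compartment: str,
) -> OccupancySummary:
    """Percent of each patient's ``compartment`` repertoire in shared clones.

    The denominator is the clone-assigned cells of that patient in the focal
    compartment; cells of shared clones residing in other compartments do
    not count toward the numerator.  Patients without cells in the
    compartment are omitted (with a warning) and the cohort median is taken
    over the remaining patients.
    """
    if compartment not in KNOWN_COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    shared_ids = shared.clone_ids
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    for c in table.clones:
        n = c.counts.get(compartment, 0)
        den[c.patient] = den.get(c.patient, 0) + n
        if c.clone_id in shared_ids:
            num[c.patient] = num.get(c.patient, 0) + n
    per_patient: dict[str, float] = {}
    for patient, d in sorted(den.items()):
        if d == 0:
            log.warning("patient %s has no %s cells; omitted from occupancy", patient, compartment)
            continue
        per_patient[patient] = 100.0 * num.get(patient, 0) / d
    med = float(_median(per_patient.values())) if per_patient else float("nan")
    return OccupancySummary(compartment=compartment, per_patient=per_patient, median=med)


def inverse_pielou(clone_sizes: Sequence[int]) -> float:
    """Inverse Pielou clonality of a clone-size distribution.

    ``1 - H/ln(S)`` where H is the Shannon entropy (natural log) of the
    clone-size proportions and S the number of clones.  Ranges from 0
    (all clones equal, polyclonal) to 1 (a single clone, monoclonal); the
    S=1 case is defined as 1 by continuity.
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("clone_sizes must be non-empty")
    if (sizes < 1).any():
        raise ValueError("clone sizes must be >= 1")
    s = sizes.size
    if s == 1:
        return 1.0
    if np.all(sizes == sizes[0]):
        return 0.0
    p = sizes / sizes.sum()
    h = float(-(p * np.log(p)).sum())
    return float(min(1.0, max(0.0, 1.0 - h / np.log(s))))


def diversity_table(table: ClonotypeTable) -> pd.DataFrame:
    """Inverse Pielou score per (patient, lineage, compartment).

    Clonality is never pooled across patients; each row is one sample's
    repertoire restricted to the focal compartment.
    """
    rows = []
    groups: dict[tuple[str, str, str], list[int]] = {}
    for c in table.clones:
        for comp, n in c.counts.items():
            if n > 0:
                groups.setdefault((c.patient, c.lineage, comp), []).append(n)
    for (patient, lineage, comp), sizes in sorted(groups.items()):
        rows.append(
            {
                "patient": patient,
                "lineage": lineage,
                "compartment": comp,
                "n_clones": len(sizes),
                "n_cells": int(sum(sizes)),
                "inverse_pielou": inverse_pielou(sizes),
            }
        )
    return pd.DataFrame(rows)


def sharing_summary(
    table: ClonotypeTable,
    shared_sets: Iterable[SharedCloneSet],
) -> dict[str, pd.DataFrame]:
    """Plot-ready sharing tables.

    Returns three frames:

    ``blocks``
        Per (patient, lineage, compartment, clone) repertoire fraction in
        percent -- the alluvial block heights; heights per compartment sum
        to 100 when every clone is drawn.
    ``links``
        One row per shared clone per pair -- the alluvial/circle links.
    ``bars``
        Shared clones ordered by patient then descending size, with per-
        compartment cell counts (the clone-size bar chart layout).
    """
    shared_sets = list(shared_sets)
    totals: dict[tuple[str, str, str], int] = {}
    for c in table.clones:
        for comp, n in c.counts.items():
            key = (c.patient, c.lineage, comp)
            totals[key] = totals.get(key, 0) + n
    block_rows = []
    for c in table.clones:
        for comp, n in c.counts.items():
            if n > 0:
                block_rows.append(
                    {
                        "patient": c.patient,
                        "lineage": c.lineage,
                        "compartment": comp,
                        "clone_id": c.clone_id,
                        "n_cells": n,
                        "height_pct": 100.0 * n / totals[(c.patient, c.lineage, comp)],
                    }
                )
    blocks = pd.DataFrame(block_rows)

    link_rows = []
    clone_by_id = {c.clone_id: c for c in table.clones}
    for ss in shared_sets:
        a, b = ss.pair
        for sc in ss.clones:
            link_rows.append(
                {
                    "pair": f"{a}-{b}",
                    "patient": sc.patient,
                    "clone_id": sc.clone_id,
                    "lineage": clone_by_id[sc.clone_id].lineage,
                    f"n_a": sc.sizes.get(a, 0),
                    f"n_b": sc.sizes.get(b, 0),
                    "triple": sc.triple,
                }
            )
    links = pd.DataFrame(link_rows)

    bar_rows = []
    for ss in shared_sets:
        for sc in ss.clones:
            total = sum(sc.sizes.values())
            bar_rows.append(
                {
                    "pair": f"{ss.pair[0]}-{ss.pair[1]}",
                    "patient": sc.patient,
                    "clone_id": sc.clone_id,
                    "total_cells": total,
                    **{f"n_{comp}": n for comp, n in sorted(sc.sizes.items())},
                }
            )
    bars = pd.DataFrame(bar_rows)
    if not bars.empty:
        bars = (
            bars.sort_values(["pair", "patient", "total_cells", "clone_id"], ascending=[True, True, False, True])
            .reset_index(drop=True)
        )
        bars.insert(0, "order", range(len(bars)))
    return {"blocks": blocks, "links": links, "bars": bars}
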