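"""Spatial neighborhood analysis on imaged tissue sections.

Cells carry micron coordinates within disjoint fields of view (fov).  A
contact graph links physically adjacent cells (Delaunay edges capped at a
contact distance by default); pairwise cell-type adjacency is then tested
against a label-permutation null that shuffles type labels within each fov
while keeping the graph fixed, reporting upper-tail one-sided p-values for
types that are neighbors more often than chance.  Directed
neighborhood-composition edges (A -> B when A makes up at least 5% of B's
pooled neighbors) summarize the same graph.
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .datamodel import SpatialCellMap

log = logging.getLogger(__name__)

GRAPH_METHODS = ("delaunay_capped", "knn", "radius")

#: Default Delaunay edge-length cap in microns -- a proxy for membrane
#: contact at single-cell resolution.
DEFAULT_CAP_UM = 30.0


def _edges_delaunay(xy: np.ndarray, cap: float) -> np.ndarray:
    tri = Delaunay(xy)
    pairs = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            pairs.add((min(a, b), max(a, b)))
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    if cap is not None and len(edges):
        d = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
        edges = edges[d <= cap]
    return edges


def _edges_radius(xy: np.ndarray, r: float) -> np.ndarray:
    pairs = cKDTree(xy).query_pairs(r, output_type="ndarray")
    return np.sort(pairs, axis=1) if len(pairs) else np.empty((0, 2), int)


def _edges_knn(xy: np.ndarray, k: int) -> np.ndarray:
    n = len(xy)
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return np.empty((0, 2), int)
    tree = cKDTree(xy)
    _, nbr = tree.query(xy, k=k_eff + 1)
    nbr = np.atleast_2d(nbr)[:, 1:]
    neigh_sets = [set(row) for row in nbr]
    pairs = set()
    for i in range(n):
        for j in neigh_sets[i]:
            if i in neigh_sets[j]:  # mutualized
                pairs.add((min(i, j), max(i, j)))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def build_contact_graph(
    cells: pd.DataFrame,
    method: str = "delaunay_capped",
    cap_um: float = DEFAULT_CAP_UM,
    k: int = 6,
    radius_um: float = DEFAULT_CAP_UM,
) -> SpatialCellMap:
    """Build the per-fov cell contact graph.

    ``delaunay_capped`` keeps Delaunay triangulation edges no longer than
    ``cap_um``; ``knn`` keeps mutual k-nearest-neighbor pairs; ``radius``
    links all pairs within ``radius_um``.  Fovs with fewer than 3 cells or
    degenerate (collinear) geometry fall back to the radius rule with a
    warning.  Edges never cross fovs.
    """
    if method not in GRAPH_METHODS:
        raise ValueError(f"method must be one of {GRAPH_METHODS}")
    cells = cells.reset_index(drop=True)
    all_edges = []
    for fov, sub in cells.groupby("fov", sort=True):
        idx = sub.index.to_numpy()
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if method == "delaunay_capped":
            if len(xy) < 3:
                warnings.warn(f"fov {fov}: <3 cells, falling back to radius graph")
                local = _edges_radius(xy, radius_um)
            else:
                try:
                    local = _edges_delaunay(xy, cap_um)
                except QhullError:
                    warnings.warn(f"fov {fov}: degenerate geometry, falling back to radius graph")
                    local = _edges_radius(xy, radius_um)
        elif method == "knn":
            local = _edges_knn(xy, k)
        else:
            local = _edges_radius(xy, radius_um)
        if len(local):
            all_edges.append(idx[local])
    edges = np.concatenate(all_edges) if all_edges else np.empty((0, 2), int)
    param = {"delaunay_capped": cap_um, "knn": float(k), "radius": radius_um}[method]
    return SpatialCellMap(cells=cells, edges=edges, method=method, param=param)


# ---------------------------------------------------------------------------
# Pairwise adjacency enrichment


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray, n_types: int) -> np.ndarray:
    """Symmetric pair-count matrix for one labeling (unordered pairs)."""
    lo = np.minimum(codes_a, codes_b)
    hi = np.maximum(codes_a, codes_b)
    flat = lo * n_types + hi
    counts = np.bincount(flat, minlength=n_types * n_types).reshape(n_types, n_types)
    return counts


def _fov_labelings(labels: tuple) -> list[tuple]:
    """Distinct multiset permutations of one fov's labels."""
    return sorted(set(permutations(labels)))


def contact_enrichment(
    smap: SpatialCellMap,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    exhaustive: bool = False,
    exhaustive_limit: int = 200_000,
) -> pd.DataFrame:
    """Test pairwise cell-type adjacency against a within-fov label shuffle.

    The observed statistic is the number of contact-graph edges joining each
    unordered type pair.  Under the null, type labels are permuted uniformly
    within each fov with the graph held fixed; the upper-tail one-sided
    p-value uses +1 smoothing, ``p = (1 + #{perm >= obs}) / (1 + n_perm)``,
    so it is never zero.  With ``exhaustive=True`` all distinct labelings
    are enumerated instead of sampled (feasible for small maps only), and
    the identity labeling counts as one of the enumerated permutations.

    Returns a frame (type_a, type_b, observed, null_mean, p, neglog10_p)
    over unordered pairs of the present types.
    """
    types = smap.cell_types
    if len(types) < 2:
        log.warning("fewer than 2 cell types present; enrichment is degenerate")
    code_of = {t: i for i, t in enumerate(types)}
    codes = smap.cells["cell_type"].map(code_of).to_numpy()
    n_types = len(types)
    e0, e1 = (smap.edges[:, 0], smap.edges[:, 1]) if len(smap.edges) else (np.array([], int),) * 2
    obs = _pair_counts(codes[e0], codes[e1], n_types)

    fovs = smap.cells["fov"].to_numpy()
    fov_idx = [np.flatnonzero(fovs == f) for f in pd.unique(fovs)]

    if exhaustive:
        per_fov = [_fov_labelings(tuple(codes[idx])) for idx in fov_idx]
        total = math.prod(len(p) for p in per_fov)
        if total > exhaustive_limit:
            raise ValueError(
                f"{total} labelings exceed the exhaustive limit ({exhaustive_limit})"
            )
        from itertools import product

        ge = np.zeros((n_types, n_types), dtype=int)
        null_sum = np.zeros((n_types, n_types))
        for combo in product(*per_fov):
            lab = codes.copy()
            for idx, labeling in zip(fov_idx, combo):
                lab[idx] = labeling
            cnt = _pair_counts(lab[e0], lab[e1], n_types)
            ge += cnt >= obs
            null_sum += cnt
        p_mat = (1 + ge) / (1 + total)
        null_mean = null_sum / total
    else:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} below 100; p-values will be coarse")
        rng = rng if rng is not None else np.random.default_rng()
        ge = np.zeros((n_types, n_types), dtype=int)
        null_sum = np.zeros((n_types, n_types))
        lab = codes.copy()
        for _ in range(n_perm):
            for idx in fov_idx:
                lab[idx] = codes[idx][rng.permutation(idx.size)]
            cnt = _pair_counts(lab[e0], lab[e1], n_types)
            ge += cnt >= obs
            null_sum += cnt
        p_mat = (1 + ge) / (1 + n_perm)
        null_mean = null_sum / n_perm

    rows = []
    for i in range(n_types):
        for j in range(i, n_types):
            p = float(p_mat[i, j])
            rows.append(
                {
                    "type_a": types[i],
                    "type_b": types[j],
                    "observed": int(obs[i, j]),
                    "null_mean": float(null_mean[i, j]),
                    "p": p,
                    "neglog10_p": max(0.0, -math.log10(p)),
                }
            )
    return pd.DataFrame(rows)


def composition_edges(
    smap: SpatialCellMap,
    threshold: float = 0.05,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Directed neighborhood-composition edges between cell types.

    For an ordered pair (A -> B), the composition fraction is the share of
    B cells' neighbor slots occupied by A cells, pooled over all B cells
    (each contact-graph edge contributes one slot in each direction).  An
    edge is emitted when the fraction meets the inclusive ``threshold``
    (default 5%).  ``per_cell=True`` averages per-B-cell fractions instead
    of pooling slots; isolated cells contribute nothing either way.
    """
    types = smap.cell_types
    code_of = {t: i for i, t in enumerate(types)}
    codes = smap.cells["cell_type"].map(code_of).to_numpy()
    n = len(codes)
    n_types = len(types)
    if len(smap.edges) == 0:
        return pd.DataFrame(columns=["src", "dst", "fraction"])
    # neighbor slots: both directions of every edge
    center = np.concatenate([smap.edges[:, 0], smap.edges[:, 1]])
    neighbor = np.concatenate([smap.edges[:, 1], smap.edges[:, 0]])
    rows = []
    if per_cell:
        frac_by_cell = np.zeros((n, n_types))
        deg = np.bincount(center, minlength=n).astype(float)
        np.add.at(frac_by_cell, (center, codes[neighbor]), 1.0)
        has = deg > 0
        frac_by_cell[has] /= deg[has, None]
        for bt in range(n_types):
            members = has & (codes == bt)
            if not members.any():
                continue
            mean_frac = frac_by_cell[members].mean(axis=0)
            for at in range(n_types):
                if mean_frac[at] >= threshold:
                    rows.append({"src": types[at], "dst": types[bt], "fraction": float(mean_frac[at])})
    else:
        flat = codes[center] * n_types + codes[neighbor]
        slot = np.bincount(flat, minlength=n_types * n_types).reshape(n_types, n_types)
        # slot[bt, at] = neighbor slots of B-type cells occupied by A-type
        totals = slot.sum(axis=1)
        for bt in range(n_types):
            if totals[bt] == 0:
                continue
            for at in range(n_types):
                frac = slot[bt, at] / totals[bt]
                if frac >= threshold:
                    rows.append({"src": types[at], "dst": types[bt], "fraction": float(frac)})
    return pd.DataFrame(rows, columns=["src", "dst", "fraction"])
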