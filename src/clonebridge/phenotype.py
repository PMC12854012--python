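"""Trm phenotyping: differential expression, the two-stage Trm cluster
classifier, preranked gene-set enrichment, and shared-clone concordance.

The classifier works in two stages.  Stage one flags "potential Trm"
clusters from cluster-vs-rest differential expression of the canonical
residency markers (up: ITGAE/CD103, CD69, CXCR6, ITGA1/CD49a, PDCD1;
down: S1PR1, SELL, KLF2): a cluster qualifies when three or more markers
move significantly in the expected direction with at least one up and one
down.  Stage two confirms each potential cluster by preranked GSEA of a
core Trm signature against cells pooled from the non-potential clusters;
confirmation requires a positive enrichment score at the permutation-test
significance level.

Marker tests use the two-sample Wilcoxon rank-sum (Mann-Whitney) test.
Cluster-vs-rest marker calls in single-cell practice compare two unpaired
cell groups, for which the signed-rank variant is undefined; the rank-sum
test is the unpaired analogue and is what cluster-vs-rest tools compute.
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, GeneSignature, GseaResult, MetaClusterMap, TrmDecision

log = logging.getLogger(__name__)

#: Canonical human Trm residency markers used by the stage-one rule.
TRM_MARKERS_UP = ("ITGAE", "CD69", "CXCR6", "ITGA1", "PDCD1")
TRM_MARKERS_DOWN = ("S1PR1", "SELL", "KLF2")


def trm_marker_signature() -> GeneSignature:
    """The directional residency-marker signature for stage one."""
    return GeneSignature(
        name="TRM_MARKERS", up=frozenset(TRM_MARKERS_UP), down=frozenset(TRM_MARKERS_DOWN)
    )


# ---------------------------------------------------------------------------
# Rank-sum testing

#: Use exact enumeration of group assignments when both groups are this
#: small; C(16, 8) = 12870 assignments is the worst case.
EXACT_MAX_GROUP = 8


def _exact_ranksum_p(pooled: np.ndarray, na: int) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Uses midranks; the p-value is the fraction of the C(n, na) equally
    likely assignments whose rank-sum deviates from its null mean at least
    as much as the observed one.
    """
    n = pooled.size
    ranks = rankdata(pooled)
    mu = na * (n + 1) / 2.0
    w_obs = ranks[:na].sum()
    d_obs = abs(w_obs - mu)
    count = 0
    for idx in combinations(range(n), na):
        w = sum(ranks[i] for i in idx)
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
    return count / math.comb(n, na)


def ranksum_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample rank-sum z statistics and two-sided p-values.

    ``a`` (genes x n_a) and ``b`` (genes x n_b) hold the two groups; ties are
    midranked and the normal approximation uses tie-corrected variance and a
    continuity correction.  Rows with zero variance (all values tied) get
    z = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    pooled = np.concatenate([a, b], axis=1)
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :na].sum(axis=1)
    mu = na * (n + 1) / 2.0
    # tie correction: sum(t^3 - t) over tie groups, per row
    s = np.sort(pooled, axis=1)
    g = s.shape[0]
    new_group = np.concatenate([np.ones((g, 1), bool), s[:, 1:] != s[:, :-1]], axis=1)
    grp = np.cumsum(new_group, axis=1)  # 1..n per row
    flat = grp + (np.arange(g)[:, None]) * (n + 1)
    cnt = np.bincount(flat.ravel(), minlength=g * (n + 1) + 1)[: g * (n + 1)].reshape(g, n + 1)
    tie_sum = (cnt**3 - cnt).sum(axis=1)
    var = na * nb / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    diff = w - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (diff - 0.5 * np.sign(diff)) / np.where(sd > 0, sd, 1.0), 0.0)
        # continuity correction must not flip the sign
        z = np.where(np.sign(z) * np.sign(diff) < 0, 0.0, z)
    p = np.minimum(1.0, 2.0 * norm.sf(np.abs(z)))
    p = np.where(sd > 0, p, 1.0)
    return z, p


def rank_sum_de(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_pct: float = 0.1,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression between two cell groups.

    Genes are prefiltered to those expressed (>0) in at least ``min_pct`` of
    one group with |log2 fold change| >= ``min_lfc``; BH correction is
    applied over the tested genes only.  For small groups (both sizes <=
    ``EXACT_MAX_GROUP``) the p-value is computed by exact enumeration of
    group assignments; groups smaller than 3 additionally trigger a warning.

    Returns a frame with columns gene, lfc (log2, A over B with pseudocount),
    z, p, adj_p, pct_a, pct_b, sorted by p then gene.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    xa = matrix.cell_columns(group_a)
    xb = matrix.cell_columns(group_b)
    na, nb = xa.shape[1], xb.shape[1]
    if min(na, nb) < 3:
        warnings.warn(
            f"group sizes ({na}, {nb}) below 3; exact enumeration used", stacklevel=2
        )
    pct_a = (xa > 0).mean(axis=1)
    pct_b = (xb > 0).mean(axis=1)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    lfc = np.log2((ma + pseudocount) / (mb + pseudocount))
    keep = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (np.abs(lfc) >= min_lfc)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return pd.DataFrame(columns=["gene", "lfc", "z", "p", "adj_p", "pct_a", "pct_b"])
    xa_k, xb_k = xa[idx], xb[idx]
    if max(na, nb) <= EXACT_MAX_GROUP:
        pooled = np.concatenate([xa_k, xb_k], axis=1)
        p = np.array([_exact_ranksum_p(row, na) for row in pooled])
        z, _ = ranksum_vectorized(xa_k, xb_k)
    else:
        z, p = ranksum_vectorized(xa_k, xb_k)
    adj_p = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": [matrix.genes[i] for i in idx],
            "lfc": lfc[idx],
            "z": z,
            "p": p,
            "adj_p": adj_p,
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
        }
    )
    return out.sort_values(["p", "gene"]).reset_index(drop=True)


def robust_marker_filter(
    per_patient_de: Sequence[pd.DataFrame],
    k: int = 3,
    alpha: float = 0.05,
    method: str = "count",
) -> pd.DataFrame:
    """Keep genes robust across per-patient differential expression runs.

    ``method="count"`` (default) keeps genes significantly changed in the
    same direction in at least ``k`` of the patients.  ``method="fisher"``
    is the combined-p alternative standing in for a conserved-marker
    meta-analysis: per-patient p-values are combined with Fisher's method,
    BH-corrected across genes, and a gene is kept when the combined adj. p
    is below ``alpha``, no patient is significant in the opposing direction,
    and the median fold change sets the direction.

    Returns a frame (gene, direction, n_up, n_down[, combined_p, adj_p]).
    """
    n = len(per_patient_de)
    if method == "count" and k > n:
        raise ValueError(f"k={k} exceeds number of patients ({n})")
    genes = sorted(set().union(*[set(df["gene"]) for df in per_patient_de]))
    rows = []
    for gene in genes:
        pvals, lfcs, sig_dirs = [], [], []
        for df in per_patient_de:
            hit = df[df["gene"] == gene]
            if hit.empty:
                continue
            r = hit.iloc[0]
            pvals.append(float(r["p"]))
            lfcs.append(float(r["lfc"]))
            if r["adj_p"] < alpha:
                sig_dirs.append(1 if r["lfc"] > 0 else -1)
        n_up = sum(1 for d in sig_dirs if d > 0)
        n_down = sum(1 for d in sig_dirs if d < 0)
        if method == "count":
            if n_up >= k and n_down == 0:
                rows.append({"gene": gene, "direction": "up", "n_up": n_up, "n_down": n_down})
            elif n_down >= k and n_up == 0:
                rows.append({"gene": gene, "direction": "down", "n_up": n_up, "n_down": n_down})
        elif method == "fisher":
            if not pvals or (n_up and n_down):
                continue
            from scipy.stats import combine_pvalues

            stat = combine_pvalues(np.clip(pvals, 1e-300, 1.0), method="fisher")
            rows.append(
                {
                    "gene": gene,
                    "direction": "up" if float(np.median(lfcs)) > 0 else "down",
                    "n_up": n_up,
                    "n_down": n_down,
                    "combined_p": float(stat.pvalue),
                }
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(rows)
    if method == "fisher" and not out.empty:
        out["adj_p"] = multipletests(out["combined_p"], method="fdr_bh")[1]
        out = out[out["adj_p"] < alpha].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Stage one: potential-Trm rule


def classify_potential_trm(
    de_vs_rest: pd.DataFrame,
    signature: Optional[GeneSignature] = None,
    alpha: float = 0.05,
    cluster_id: str = "",
) -> TrmDecision:
    """Apply the directional marker rule to a cluster-vs-rest DE table.

    A cluster is "potential Trm" when >= 3 signature markers are
    significantly changed in the expected direction, with at least one
    increased and one decreased marker.  Signature genes absent from the DE
    table count as non-hits (logged).
    """
    sig = signature or trm_marker_signature()
    present = set(de_vs_rest["gene"])
    absent = (sig.up | sig.down) - present
    if absent:
        log.info("cluster %s: signature genes not tested: %s", cluster_id, sorted(absent))
    idx = de_vs_rest.set_index("gene")
    hits_up = frozenset(
        g for g in sig.up if g in present and idx.at[g, "adj_p"] < alpha and idx.at[g, "lfc"] > 0
    )
    hits_down = frozenset(
        g for g in sig.down if g in present and idx.at[g, "adj_p"] < alpha and idx.at[g, "lfc"] < 0
    )
    potential = (len(hits_up) + len(hits_down) >= 3) and bool(hits_up) and bool(hits_down)
    return TrmDecision(
        cluster_id=cluster_id,
        marker_hits_up=hits_up,
        marker_hits_down=hits_down,
        potential=potential,
    )


# ---------------------------------------------------------------------------
# Preranked GSEA


def _running_es(hit: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = hit.size
    n_hit = int(hit.sum())
    hw = weights * hit
    total = hw.sum()
    if total <= 0:
        # all-zero stats at the hit positions: fall back to equal hit weights
        hw = hit.astype(float)
        total = hw.sum()
    inc = hw / total
    dec = (~hit.astype(bool)).astype(float) / (n - n_hit)
    walk = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(walk)))
    # the walk is analytically within [-1, 1]; guard against float drift
    return float(np.clip(walk[i], -1.0, 1.0))


def preranked_gsea(
    genes: Sequence[str],
    stats: Sequence[float],
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> GseaResult:
    """Preranked GSEA with the weighted Kolmogorov-Smirnov running sum.

    Genes are ranked by ``stats`` (descending).  Walking down the ranking,
    hits increment the running sum proportionally to |stat|^weight and
    misses decrement it by 1/(N - N_hit); the enrichment score (ES) is the
    signed maximum deviation.  Significance is assessed by gene-label
    permutation (random hit sets of the same size) with +1 smoothing on the
    same-sign tail, and NES normalizes ES by the mean |permuted ES| of the
    same sign.
    """
    genes = list(genes)
    stats_arr = np.asarray(stats, dtype=float)
    if stats_arr.size != len(genes):
        raise ValueError("genes and stats must align")
    if not np.isfinite(stats_arr).all():
        raise ValueError("ranking statistics must be finite")
    gene_set = set(gene_set)
    order = np.argsort(-stats_arr, kind="stable")
    ranked_genes = [genes[i] for i in order]
    ranked_stats = stats_arr[order]
    hit = np.array([g in gene_set for g in ranked_genes])
    n_hit = int(hit.sum())
    n = hit.size
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked genes")
    if n_hit == n:
        raise ValueError("gene set equals the ranked universe; ES is degenerate")
    weights = np.abs(ranked_stats) ** weight
    es = _running_es(hit, weights)

    rng = rng if rng is not None else np.random.default_rng()
    # vectorized permutation: random hit sets of size n_hit
    mask = np.zeros(n, dtype=bool)
    mask[:n_hit] = True
    perms = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perms[i] = mask[rng.permutation(n)]
    hw = perms * weights
    totals = hw.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        hw[zero] = perms[zero].astype(float)
        totals = hw.sum(axis=1)
    inc = hw / totals[:, None]
    dec = (~perms).astype(float) / (n - n_hit)
    walks = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(walks), axis=1)
    perm_es = np.clip(walks[np.arange(n_perm), idx], -1.0, 1.0)

    if es >= 0:
        tail = perm_es[perm_es >= 0]
        p = (1 + int((perm_es >= es).sum())) / (1 + n_perm)
    else:
        tail = perm_es[perm_es < 0]
        p = (1 + int((perm_es <= es).sum())) / (1 + n_perm)
    nes = es / float(np.mean(np.abs(tail))) if tail.size else float("nan")
    return GseaResult(es=es, nes=nes, p=p, n_hits=n_hit)


def confirm_trm(
    matrix: ExpressionMatrix,
    cluster_cells: Sequence[str],
    pool_cells: Sequence[str],
    core_set: GeneSignature,
    decision: TrmDecision,
    alpha: float = 0.05,
    n_perm: int = 1000,
    weight: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> TrmDecision:
    """Stage two: confirm a potential-Trm cluster by preranked GSEA.

    Genes are ranked by the signed rank-sum z statistic of cluster vs the
    pooled non-potential cells, and the core Trm up-set is tested;
    confirmation requires ES > 0 with permutation p below ``alpha``.
    Calling this on a cluster that did not pass stage one is a stage-order
    violation and raises.
    """
    if not decision.potential:
        raise ValueError(
            f"cluster {decision.cluster_id}: stage order violated (not flagged potential)"
        )
    xa = matrix.cell_columns(cluster_cells)
    xb = matrix.cell_columns(pool_cells)
    z, _ = ranksum_vectorized(xa, xb)
    res = preranked_gsea(matrix.genes, z, core_set.up, weight=weight, n_perm=n_perm, rng=rng)
    return TrmDecision(
        cluster_id=decision.cluster_id,
        marker_hits_up=decision.marker_hits_up,
        marker_hits_down=decision.marker_hits_down,
        potential=True,
        es=res.es,
        nes=res.nes,
        gsea_p=res.p,
        confirmed=bool(res.es > 0 and res.p < alpha),
    )


def classify_trm_clusters(
    matrix: ExpressionMatrix,
    clusters: Mapping[str, str],
    core_set: GeneSignature,
    signature: Optional[GeneSignature] = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, TrmDecision]:
    """Run the full two-stage Trm classification over all clusters.

    ``clusters`` maps barcode -> cluster id.  Stage one tests each cluster
    against all other cells with unfiltered DE (so every marker is tested);
    stage two confirms potential clusters against the pooled cells of the
    non-potential clusters.
    """
    by_cluster: dict[str, list[str]] = {}
    for bc, cl in clusters.items():
        by_cluster.setdefault(cl, []).append(bc)
    all_cells = [bc for bc in matrix.cells if bc in clusters]
    decisions: dict[str, TrmDecision] = {}
    for cl, cells in sorted(by_cluster.items()):
        rest = [bc for bc in all_cells if clusters[bc] != cl]
        de = rank_sum_de(matrix, cells, rest, min_pct=0.0, min_lfc=0.0)
        decisions[cl] = classify_potential_trm(de, signature, alpha=alpha, cluster_id=cl)
    pool = [bc for bc in all_cells if not decisions[clusters[bc]].potential]
    for cl, dec in decisions.items():
        if dec.potential:
            if not pool:
                log.warning("no non-potential pool cells; cluster %s left unconfirmed", cl)
                continue
            decisions[cl] = confirm_trm(
                matrix, by_cluster[cl], pool, core_set, dec, alpha=alpha, n_perm=n_perm, rng=rng
            )
    return decisions


def trm_decision_frame(decisions: Mapping[str, TrmDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": d.cluster_id,
                "hits_up": ",".join(sorted(d.marker_hits_up)),
                "hits_down": ",".join(sorted(d.marker_hits_down)),
                "n_hits": d.n_hits,
                "potential": d.potential,
                "es": d.es,
                "nes": d.nes,
                "gsea_p": d.gsea_p,
                "confirmed": d.confirmed,
            }
            for _, d in sorted(decisions.items())
        ]
    )


# ---------------------------------------------------------------------------
# Shared-clone concordance


def classify_concordance(labels_a: Iterable[str], labels_b: Iterable[str]) -> str:
    """Classify a shared clone's phenotype concordance between compartments.

    ``same`` when all cells from both compartments fall in a single
    meta-cluster, ``similar`` when at least one cell from each compartment
    shares a meta-cluster, otherwise ``different``.  Precedence is
    same > similar > different; the call is invariant to cell order and
    duplication.
    """
    sa, sb = set(labels_a), set(labels_b)
    if not sa or not sb:
        raise ValueError("both compartments must contribute at least one cell")
    if len(sa | sb) == 1:
        return "same"
    if sa & sb:
        return "similar"
    return "different"


def concordance_table(
    table,
    shared,
    cell_clusters: Mapping[str, str],
    meta_map: MetaClusterMap,
    cell_compartments: Mapping[str, str],
) -> pd.DataFrame:
    """Classify every shared clone's concordance between the pair compartments.

    ``cell_clusters`` maps barcode -> fine cluster; ``cell_compartments``
    maps barcode -> (post-pooling) compartment.  Unmapped clusters raise.
    """
    a, b = shared.pair
    clone_by_id = {c.clone_id: c for c in table.clones}
    rows = []
    for sc in shared.clones:
        clone = clone_by_id[sc.clone_id]
        la, lb = [], []
        for bc in clone.barcodes:
            comp = cell_compartments[bc]
            if comp not in (a, b):
                continue
            cl = cell_clusters.get(bc)
            if cl is None:
                raise KeyError(f"cell {bc} of shared clone {sc.clone_id} has no cluster")
            (la if comp == a else lb).append(meta_map.label(cl))
        rows.append(
            {
                "clone_id": sc.clone_id,
                "patient": sc.patient,
                "labels_a": ",".join(sorted(set(la))),
                "labels_b": ",".join(sorted(set(lb))),
                "concordance": classify_concordance(la, lb),
            }
        )
    return pd.DataFrame(rows)


def concordance_summary(classes: Iterable[str]) -> dict[str, float]:
    """Fractions of same / similar / different over classified shared clones."""
    classes = list(classes)
    if not classes:
        raise ValueError("no classified clones")
    bad = set(classes) - {"same", "similar", "different"}
    if bad:
        raise ValueError(f"unknown concordance classes {sorted(bad)}")
    n = len(classes)
    return {
        "same": classes.count("same") / n,
        "similar": classes.count("similar") / n,
        "different": classes.count("different") / n,
    }


def shared_vs_nonshared_de(
    matrix: ExpressionMatrix,
    shared_cells: Sequence[str],
    nonshared_cells: Sequence[str],
    **de_kwargs,
) -> pd.DataFrame:
    """DE between cells of shared clones and cells of non-shared clones.

    Run within one compartment at a time; both groups must be non-empty.
    """
    if not list(shared_cells):
        raise ValueError("shared-cell group is empty")
    if not list(nonshared_cells):
        raise ValueError("non-shared-cell group is empty")
    return rank_sum_de(matrix, list(shared_cells), list(nonshared_cells), **de_kwargs)
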