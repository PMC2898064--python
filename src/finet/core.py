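"""Core-subnetwork discovery: recurrence curves, average shortest path
(ASP) permutation statistics, shortest-path gene clustering, and minimal
linker subnetworks.

Recurrently altered genes in a cohort tend to sit closer together in the
FI network than random gene sets do.  The machinery here quantifies that:
ASP is the mean unweighted shortest-path length over all gene pairs
co-resident in the network's largest connected component; its
significance comes from permutation nulls that draw either uniformly
from the component or stratified by degree (to control for the hub bias
of well-studied genes).  A compact connected "core" is then built by
adding a near-minimal set of linker genes between candidate clusters.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import shortest_path as csgraph_shortest_path
from scipy.spatial.distance import squareform

from .cancer import SampleAlterationTable
from .network import largest_component

__all__ = [
    "RecurrenceCurve",
    "ASPResult",
    "CoreSubnetwork",
    "component_distances",
    "average_shortest_path",
    "asp_permutation_test",
    "degree_bins",
    "recurrence_curve",
    "cluster_genes_shortest_path",
    "build_linker_subnetwork",
]

logger = logging.getLogger(__name__)


def component_distances(g: nx.Graph) -> Tuple[List[str], np.ndarray]:
    """All-pairs unweighted shortest-path matrix of the largest component.

    Returns (sorted node list, integer distance matrix).
    """
    comp = largest_component(g)
    nodes = sorted(comp.nodes)
    adj = nx.to_scipy_sparse_array(comp, nodelist=nodes, format="csr")
    dist = csgraph_shortest_path(adj, method="D", unweighted=True)
    return nodes, dist


def average_shortest_path(
    g: nx.Graph,
    genes: Iterable[str],
    _cache: Optional[Tuple[List[str], np.ndarray]] = None,
) -> float:
    """Mean shortest-path length over all unordered in-component pairs.

    Genes outside the largest connected component are excluded (their
    count is logged).  Raises if fewer than two genes are usable.
    """
    nodes, dist = _cache if _cache is not None else component_distances(g)
    pos = {n: i for i, n in enumerate(nodes)}
    genes = sorted(set(genes))
    idx = [pos[x] for x in genes if x in pos]
    excluded = len(genes) - len(idx)
    if excluded:
        logger.info("%d genes outside the largest component", excluded)
    if len(idx) < 2:
        raise ValueError("need >=2 genes inside the largest component")
    sub = dist[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def degree_bins(
    candidate_degrees: Sequence[int],
    pool_degrees: np.ndarray,
    min_pool: int = 5,
) -> List[Tuple[int, int, int]]:
    """Greedy degree bins over the sorted candidate degrees.

    Returns (lo, hi, count) triples: each bin covers the closed degree
    range [lo, hi], holds ``count`` candidates, and is grown until the
    network pool inside the range holds at least max(min_pool, count)
    nodes; a trailing short bin is merged into its predecessor.
    """
    degs = sorted(candidate_degrees)
    bins: List[Tuple[int, int, int]] = []
    i = 0
    while i < len(degs):
        lo = degs[i]
        j = i
        while True:
            hi = degs[j]
            count = j - i + 1
            pool = int(((pool_degrees >= lo) & (pool_degrees <= hi)).sum())
            if pool >= max(min_pool, count) or j == len(degs) - 1:
                break
            j += 1
        # widen the final bin if its pool is still short
        while pool < max(min_pool, count) and (lo > 0 or hi < pool_degrees.max()):
            lo = max(0, lo - 1)
            hi = hi + 1
            pool = int(((pool_degrees >= lo) & (pool_degrees <= hi)).sum())
        bins.append((lo, hi, count))
        i = j + 1
    # merge a trailing bin whose pool cannot cover it
    merged: List[Tuple[int, int, int]] = []
    for lo, hi, count in bins:
        if merged and merged[-1][1] >= lo:
            plo, phi, pcount = merged.pop()
            merged.append((plo, max(phi, hi), pcount + count))
        else:
            merged.append((lo, hi, count))
    return merged


@dataclass(frozen=True)
class ASPResult:
    """Observed ASP against a permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_as_short: int
    n_perm: int
    mode: str

    @property
    def p_str(self) -> str:
        if self.n_as_short == 0:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def asp_permutation_test(
    g: nx.Graph,
    genes: Iterable[str],
    mode: str = "uniform",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_pool: int = 5,
    _cache: Optional[Tuple[List[str], np.ndarray]] = None,
) -> ASPResult:
    """Permutation significance of a gene set's ASP.

    ``uniform`` draws the same number of genes uniformly from the largest
    component; ``degree_stratified`` draws bin-matched counts from degree
    bins built over the sorted candidate degrees, so each null set
    reproduces the candidates' degree histogram bin by bin.  p is the
    fraction of permutations with null ASP <= observed ("< 1/n_perm"
    when none).
    """
    if mode not in ("uniform", "degree_stratified"):
        raise ValueError(f"unknown mode {mode!r}")
    nodes, dist = _cache if _cache is not None else component_distances(g)
    pos = {n: i for i, n in enumerate(nodes)}
    idx = np.array(sorted(pos[x] for x in set(genes) if x in pos))
    if len(idx) < 2:
        raise ValueError("need >=2 genes inside the largest component")
    iu = np.triu_indices(len(idx), k=1)
    observed = float(dist[np.ix_(idx, idx)][iu].mean())

    rng = np.random.default_rng(seed)
    n_nodes = len(nodes)
    node_degrees = np.array([g.degree(n) for n in nodes])
    if mode == "degree_stratified":
        cand_degrees = node_degrees[idx]
        bins = degree_bins(cand_degrees.tolist(), node_degrees, min_pool)
        bin_pools = [
            np.where((node_degrees >= lo) & (node_degrees <= hi))[0]
            for lo, hi, _ in bins
        ]
        bin_counts = [count for _, _, count in bins]

    null = np.empty(n_perm)
    for p_i in range(n_perm):
        if mode == "uniform":
            draw = rng.choice(n_nodes, size=len(idx), replace=False)
        else:
            parts = [
                rng.choice(pool, size=count, replace=False)
                for pool, count in zip(bin_pools, bin_counts)
            ]
            draw = np.unique(np.concatenate(parts))
            # overlapping pools can yield duplicates; top up uniformly
            while len(draw) < len(idx):
                extra = rng.choice(n_nodes, size=len(idx) - len(draw))
                draw = np.unique(np.concatenate([draw, extra]))
        sub = dist[np.ix_(draw, draw)]
        null[p_i] = sub[np.triu_indices(len(draw), k=1)].mean()

    n_as_short = int((null <= observed + 1e-12).sum())
    p = n_as_short / n_perm if n_as_short else 1.0 / n_perm
    return ASPResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=p,
        n_as_short=n_as_short,
        n_perm=n_perm,
        mode=mode,
    )


@dataclass
class RecurrenceCurve:
    """Observed vs null fraction of altered genes at each recurrence level.

    ``observed[s]`` is the fraction of all altered genes occurring in at
    least ``s`` samples; the null redraws per-sample gene sets uniformly
    from the universe preserving per-sample counts.  ``asp`` holds the
    average shortest path of each >=s gene set in the FI network (NaN
    where fewer than two genes are usable or no network was given).
    """

    s_values: List[int]
    observed: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    asp: np.ndarray
    null_asp_mean: np.ndarray


def recurrence_curve(
    cohort: SampleAlterationTable,
    universe: Iterable[str],
    net: Optional[nx.Graph] = None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> RecurrenceCurve:
    """Recurrence distribution of altered genes with a permutation null."""
    universe = sorted({g.upper() for g in universe})
    upos = {g: i for i, g in enumerate(universe)}
    altered = cohort.all_genes
    if not altered <= set(universe):
        raise ValueError("universe must contain every altered gene")
    counts = np.zeros(len(universe), dtype=np.int64)
    sample_sizes = []
    for genes in cohort.samples.values():
        sample_sizes.append(len(genes))
        for gname in genes:
            counts[upos[gname]] += 1
    max_s = int(counts.max())
    s_values = list(range(1, max_s + 1))
    n_altered = int((counts > 0).sum())
    observed = np.array(
        [(counts >= s).sum() / n_altered for s in s_values]
    )

    cache = component_distances(net) if net is not None else None

    def asp_of(level_counts: np.ndarray) -> np.ndarray:
        out = np.full(len(s_values), np.nan)
        if cache is None:
            return out
        for k, s in enumerate(s_values):
            genes_s = [universe[i] for i in np.where(level_counts >= s)[0]]
            try:
                out[k] = average_shortest_path(net, genes_s, _cache=cache)
            except ValueError:
                pass
        return out

    asp = asp_of(counts)

    rng = np.random.default_rng(seed)
    u = len(universe)
    null_fracs = np.zeros((n_perm, len(s_values)))
    null_asps = np.full((min(n_perm, 50), len(s_values)), np.nan)
    for p_i in range(n_perm):
        ncounts = np.zeros(u, dtype=np.int64)
        for k in sample_sizes:
            ncounts[rng.choice(u, size=min(k, u), replace=False)] += 1
        n_alt = max(int((ncounts > 0).sum()), 1)
        null_fracs[p_i] = [(ncounts >= s).sum() / n_alt for s in s_values]
        if p_i < null_asps.shape[0]:
            null_asps[p_i] = asp_of(ncounts)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_asp_mean = np.nanmean(null_asps, axis=0)
    return RecurrenceCurve(
        s_values=s_values,
        observed=observed,
        null_mean=null_fracs.mean(axis=0),
        null_lo=np.quantile(null_fracs, 0.025, axis=0),
        null_hi=np.quantile(null_fracs, 0.975, axis=0),
        asp=asp,
        null_asp_mean=null_asp_mean,
    )


def cluster_genes_shortest_path(
    g: nx.Graph,
    genes: Iterable[str],
    coverage: float = 0.70,
    _cache: Optional[Tuple[List[str], np.ndarray]] = None,
) -> Set[str]:
    """Average-linkage clustering on shortest-path distances; returns the
    smallest cluster holding more than ``coverage`` of the usable genes.

    Usable genes are those inside the largest connected component.  Merge
    heights are scanned in ascending order; if no cluster below the root
    qualifies, the root (all usable genes) is returned with a warning.
    """
    nodes, dist = _cache if _cache is not None else component_distances(g)
    pos = {n: i for i, n in enumerate(nodes)}
    usable = sorted(x for x in set(genes) if x in pos)
    if len(usable) < 2:
        raise ValueError("need >=2 genes inside the largest component")
    idx = [pos[x] for x in usable]
    sub = dist[np.ix_(idx, idx)]
    z = linkage(squareform(sub, checks=False), method="average")
    n = len(usable)
    members: Dict[int, Set[str]] = {i: {usable[i]} for i in range(n)}
    alive: Set[int] = set(range(n))
    target = coverage * n
    # merges at equal heights form together: evaluate candidate clusters
    # only once a height level is complete, so flat ties (e.g. cliques)
    # yield their full cluster rather than an arbitrary sub-merge
    row_i = 0
    while row_i < len(z):
        h = z[row_i, 2]
        level_new: List[int] = []
        while row_i < len(z) and abs(z[row_i, 2] - h) <= 1e-12:
            a, b = int(z[row_i, 0]), int(z[row_i, 1])
            merged = members[a] | members[b]
            node = n + row_i
            members[node] = merged
            alive -= {a, b}
            alive.add(node)
            level_new.append(node)
            row_i += 1
        qualifying = [
            members[c] for c in level_new
            if c in alive and len(members[c]) > target
        ]
        if qualifying:
            return min(qualifying, key=len)
    warnings.warn("no cluster below the root met the coverage; returning root")
    return set(usable)


@dataclass
class CoreSubnetwork:
    """A connected subnetwork spanning candidate genes via linker genes."""

    candidates: Set[str]
    linkers: Set[str]
    graph: nx.Graph
    coverage: float  # fraction of requested candidates included

    @property
    def genes(self) -> Set[str]:
        return self.candidates | self.linkers


def _lexi_shortest_path(
    g: nx.Graph, u: str, v: str, dist_from_v: Dict[str, int]
) -> List[str]:
    """Lexicographically smallest shortest u->v path, guided by BFS
    distances from v."""
    path = [u]
    cur = u
    while cur != v:
        step = dist_from_v[cur] - 1
        nxt = min(
            w for w in g.neighbors(cur) if dist_from_v.get(w, -1) == step
        )
        path.append(nxt)
        cur = nxt
    return path


def build_linker_subnetwork(g: nx.Graph, genes: Iterable[str]) -> CoreSubnetwork:
    """Greedy Steiner-style core subnetwork over the candidate genes.

    Starting from each in-component candidate as a singleton cluster, the
    two clusters at the smallest shortest-path distance are repeatedly
    joined along one such path (lexicographically smallest node sequence
    among ties), the path's interior nodes becoming linkers, until a
    single connected cluster remains.  A final pruning pass removes any
    linker whose removal leaves the candidates connected.
    """
    requested = set(genes)
    comp = largest_component(g)
    cands = sorted(requested & set(comp.nodes))
    if len(cands) < 2:
        raise ValueError("need >=2 candidates inside the largest component")

    nodes, dist = component_distances(g)
    pos = {n: i for i, n in enumerate(nodes)}
    clusters: List[Set[str]] = [{c} for c in cands]
    linkers: Set[str] = set()

    while len(clusters) > 1:
        best = None  # (d, u, v, a_idx, b_idx)
        for a_i, b_i in itertools.combinations(range(len(clusters)), 2):
            for u in sorted(clusters[a_i]):
                du = dist[pos[u]]
                for v in sorted(clusters[b_i]):
                    d = du[pos[v]]
                    key = (d, min(u, v), max(u, v))
                    if best is None or key < best[0]:
                        best = (key, u, v, a_i, b_i)
        (_d, _lo, _hi), u, v, a_i, b_i = best
        dist_from_v = nx.single_source_shortest_path_length(comp, v)
        path = _lexi_shortest_path(comp, u, v, dist_from_v)
        interior = set(path[1:-1])
        linkers |= interior - requested
        merged = clusters[a_i] | clusters[b_i] | set(path)
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a_i, b_i)
        ]
        # absorb clusters that the new path touched
        untouched = []
        for c in clusters:
            if c & merged:
                merged |= c
            else:
                untouched.append(c)
        clusters = untouched + [merged]

    linkers = _minimize_linkers(comp, set(cands), linkers)
    sub = comp.subgraph(set(cands) | linkers).copy()
    return CoreSubnetwork(
        candidates=set(cands),
        linkers=linkers,
        graph=sub,
        coverage=len(cands) / len(requested),
    )


def _connects(comp: nx.Graph, nodes: Set[str]) -> bool:
    h = comp.subgraph(nodes)
    return h.number_of_nodes() > 0 and nx.is_connected(h)


def _minimize_linkers(
    comp: nx.Graph, cands: Set[str], linkers: Set[str]
) -> Set[str]:
    """Shrink the linker set while the candidates stay connected.

    Two moves, applied until a fixed point: drop any single redundant
    linker, and replace any linker pair by one substitute node (a hub
    the greedy merge missed because it joined clusters pairwise).
    """
    linkers = set(linkers)
    spare = sorted(set(comp.nodes) - cands)
    changed = True
    while changed:
        changed = False
        for l in sorted(linkers):
            if _connects(comp, (cands | linkers) - {l}):
                linkers.discard(l)
                changed = True
        if changed:
            continue
        for l1, l2 in itertools.combinations(sorted(linkers), 2):
            base = (cands | linkers) - {l1, l2}
            sub = next(
                (v for v in spare if v not in base
                 and _connects(comp, base | {v})),
                None,
            )
            if sub is not None:
                linkers -= {l1, l2}
                linkers.add(sub)
                changed = True
                break
    return linkers
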