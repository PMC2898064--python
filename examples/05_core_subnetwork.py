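"""Core-subnetwork discovery from recurrently altered genes.

Takes the recurrently altered genes of a simulated cohort, shows that
their average shortest path (ASP) in the FI network is far below both a
uniform and a degree-matched permutation null, clusters them by
shortest-path distance, and connects the selected cluster with a
minimal set of linker genes.
"""

import networkx as nx

from finet import (
    asp_permutation_test,
    build_linker_subnetwork,
    cluster_genes_shortest_path,
)
from finet.network import build_network, largest_component
from finet.synthetic import (
    CohortSpec,
    WorldSpec,
    gen_cohort,
    gen_pathway_world,
)

world = gen_pathway_world(WorldSpec(seed=1))
net = build_network(world.fis)
comp = largest_component(net)
nodes = sorted(comp.nodes)

hub = max(nodes, key=lambda n: (comp.degree(n), n))
ordered = sorted(
    nx.single_source_shortest_path_length(comp, hub).items(),
    key=lambda kv: (kv[1], kv[0]),
)
modules = (
    frozenset(n for n, _ in ordered[:8]),
    frozenset(n for n, _ in ordered[8:16]),
)
cohort = gen_cohort(
    nodes,
    CohortSpec(
        modules=modules,
        hit_probabilities=(0.85, 0.85),
        passenger_rate=1.0,
        n_samples=91,
        seed=5,
    ),
)

counts = {}
for genes in cohort.samples.values():
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
recurrent = sorted(g for g, c in counts.items() if c >= 2 and g in comp)
print(f"genes altered in >=2 samples and in the network: {len(recurrent)}")

cluster = cluster_genes_shortest_path(net, recurrent, coverage=0.70)
print(
    f"shortest-path cluster: {len(cluster)} genes"
    f" ({len(cluster) / len(recurrent):.0%} of recurrent genes)"
)

uni = asp_permutation_test(net, cluster, "uniform", n_perm=1000, seed=7)
deg = asp_permutation_test(
    net, cluster, "degree_stratified", n_perm=1000, seed=7
)
print(
    f"cluster ASP {uni.observed:.2f} vs uniform null {uni.null_mean:.2f}"
    f" (p {uni.p_str}) and degree-matched null {deg.null_mean:.2f}"
    f" (p {deg.p_str})"
)
core = build_linker_subnetwork(net, cluster)
print(
    f"core subnetwork: {len(core.genes)} genes,"
    f" {len(core.linkers)} linkers, connected="
    f"{nx.is_connected(core.graph)}"
)
# Recurrently altered genes huddle in one corner of the network: their
# ASP is several hops below chance even after matching the null on
# degree, and a handful of linker genes suffices to join them into one
# connected core.
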