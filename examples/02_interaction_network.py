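"""Unify four validated-interaction source tables into the bipartite
miRNA-mRNA network and quantify its scale-free character.

The four synthetic exports emulate curated databases: names vary in case
and whitespace, ~45% of pairs are listed redundantly across sources, and
decoy records for non-differential miRNAs are present. Unification
canonicalizes names, de-duplicates on the (miRNA, gene) key, and
restriction to the 179 differential miRNAs removes the decoys.
"""

import mirnetkit as mk

config = mk.FixtureConfig()
raw, truth = mk.generate_expression_fixture(config)
differential = mk.screen(raw, mk.CELL_LINES)
sources = mk.generate_interaction_db(config, truth)

total_records = sum(len(df) for df in sources.values())
pairs = mk.unify_interactions(list(sources.values()))
print(f"{total_records} source records -> {len(pairs)} unique pairs after de-duplication")

net = mk.build_network(pairs, differential)
print(f"restricted network: {net.n_edges} edges between "
      f"{len(net.mirnas)} differential miRNAs and {len(net.genes)} target genes")

dist = mk.degree_distribution(net, side="both")
fit = mk.scale_free_fit(dist)
print(f"log-log degree fit: slope {fit.slope:.2f}, R^2 {fit.r_squared:.2f} "
      f"over {fit.n_points} degree values")

# 5,092 edges / 62 miRNAs / 4,362 genes are the planted database
# cardinalities; the negative slope says high-degree regulator hubs are
# rare and low-degree nodes dominate, the heavy-tailed signature the R^2
# quantifies.
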