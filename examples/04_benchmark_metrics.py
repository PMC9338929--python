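"""Evaluate an inferred interaction the way the benchmark module does.

For a predicted ligand-receptor interaction: (1) the one-sided rank-sum
test asks whether ligand+ sender to receptor+ receiver distances are
shorter than distances between all cell pairs; (2) the co-expression
percent measures how many sender->receiver graph edges carry the pair;
(3) Fisher's exact test checks whether inferred target genes enrich a
pathway gene set.
"""

import numpy as np
import spacomm as sp
from spacomm.communication import build_knn_graph

scenario = sp.SyntheticScenario(seed=0)
st, coords, labels = sp.generate_spatial(scenario)
lig, rec, sender, receiver = scenario.planted_lri

xy = coords.xy(st.units)
types = labels.loc[st.units].to_numpy(dtype=object)
rng = np.random.default_rng(0)

p, flags = sp.spatial_proximity_test(xy, types, st, lig, rec, sender,
                                     receiver, rng=rng)
print(f"spatial proximity one-sided P: {p:.3e} (flags: {flags})")

graph = build_knn_graph(xy, types, cells=st.units, K=10)
pct = sp.coexpression_percent(graph, st, sender, receiver, lig, rec)
print(f"co-expression percent on {sender}->{receiver} edges: {pct:.1f}%")

receptor, tf, targets = scenario.planted_chain
prior = sp.generate_prior(scenario)
table = sp.fisher_pathway_enrichment(
    [tf, *targets], prior.pathway_sets, universe=st.genes)
print(table.round(6).to_string(index=False))
# a small P for the planted pathway says the inferred targets match it far
# beyond chance overlap with the gene universe.
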