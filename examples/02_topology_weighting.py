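"""Exact topology weighting across local genealogies.

Simulates 200 window genealogies for three populations plus an outgroup
(three tips each) under incomplete lineage sorting only, computes the exact
weight of each rooted population topology per window, and summarizes
genome-wide weights with 95% bootstrap confidence intervals.
"""
import admixscan as ax

trees = ax.simulate_window_trees(n_windows=200, tips_per_group=3,
                                 t1=1.0, t2=2.0, t3=3.0, seed=7)
groups = {tip: tip.rsplit("_", 1)[0] for tip in trees[0].tip_labels}
topologies = ax.enumerate_rooted_topologies(["P1", "P2", "P3"], "O")

records = [ax.topology_weights(t, groups, topologies) for t in trees]
totals, lo, hi = ax.weight_summary(records, n_boot=1000, seed=1)

for topo, w, a, b in zip(topologies, totals, lo, hi):
    print(f"{topo.newick:<22} weight = {w:.3f}  95% CI [{a:.3f}, {b:.3f}]")

# The species topology (((P1,P2),P3),O) dominates; the two discordant
# topologies receive equal weight within CI - the symmetric signature of
# incomplete lineage sorting without gene flow.
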