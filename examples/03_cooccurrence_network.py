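"""Co-occurrence network with planted correlated blocks and Zi/Pi roles.

Two 10-taxon blocks share latent abundance factors, so their members
rise and fall together across 40 samples. The network keeps taxa above
0.1% mean relative abundance and draws an edge for |Spearman rho| >= 0.6
at BH q <= 0.05; greedy modularity should rediscover the planted blocks.
"""

from collections import Counter

import microstand as ms

cfg = ms.SimulationConfig(n_features=100, n_groups=1, replicates_per_group=40,
                          effect_features=0,
                          correlation_blocks=((10, 1.5), (10, 1.5)), seed=31)
table, _, truth = ms.generate_community(cfg)
rel = ms.to_relative(table)

net = ms.build_cooccurrence(rel, min_abund=0.001, rho_min=0.6, q_max=0.05)
modules = ms.assign_modules(net, seed=0)
topo = ms.topology_summary(net, modules)
print("topology:", {k: round(v, 3) if isinstance(v, float) else v
                    for k, v in topo.items()})

bm = truth.block_membership
for b in (0, 1):
    members = [f for f in bm.index[bm == b] if f in modules]
    found = Counter(modules[f] for f in members)
    print(f"planted block {b}: {len(members)} taxa in the network, "
          f"detected modules {dict(found)}")

roles = ms.classify_roles(ms.zi_pi(net, modules))
print("\nrole counts:", roles["role"].value_counts().to_dict())
print("module/network hubs and connectors knit modules together; "
      "peripherals dominate sparse microbial networks.")
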