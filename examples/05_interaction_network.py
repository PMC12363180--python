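"""Screen phage-host interaction predictions and build the network.

Multimer confidences combine as 0.8*ipTM + 0.2*pTM; pairs above 0.5 enter
the network, pairs above 0.7 make the stringent candidate list.  Phage
nodes are sized by the number of proteins their cluster represents, host
nodes by how many phage proteins target them.
"""

from scsh.interactions import build_network, edge_list, screen_interactions
from scsh.types import InteractionRecord

records = [
    InteractionRecord("phageA_gp5", "host_RecA", 0.86, 0.78),
    InteractionRecord("phageA_gp5", "host_LexA", 0.55, 0.60),
    InteractionRecord("phageB_gp2", "host_RecA", 0.74, 0.70),
    InteractionRecord("phageB_gp9", "host_GyrA", 0.31, 0.45),  # low confidence
]

for threshold in (0.5, 0.7):
    screened = screen_interactions(records, threshold)
    print(f"score > {threshold}: {len(screened)} of {len(records)} pairs")

network = build_network(
    screen_interactions(records, 0.5),
    phage_rep_sizes={"phageA_gp5": 12, "phageB_gp2": 3},
)
print("host degrees:", {
    n: d["degree"] for n, d in network.nodes(data=True) if d["kind"] == "host"
})
print("edges (phage, host, weight):")
for row in edge_list(network):
    print("  %s -- %s  %.3f" % row)
# host_RecA is targeted by proteins from two phage clusters (degree 2);
# the weak gp9-GyrA prediction never enters the network.
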