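"""Identify dominant senders, receivers, mediators and influencers.

Weighted out-/in-degree mark the dominant signal sources and targets;
flow betweenness marks gatekeepers of flow between other groups;
information centrality marks groups with the most control over
information flow in the (symmetrized) network.
"""

import numpy as np

import commscape as cs
from commscape.inference import SignalingNetwork

# a relay topology: FIB sends to MYL, MYL forwards to TCELL
A = np.zeros((3, 3))
A[0, 1] = 0.5   # FIB -> MYL
A[1, 2] = 0.4   # MYL -> TCELL
net = SignalingNetwork("TGFb", A, ["FIB", "MYL", "TCELL"])

scores = cs.centrality_scores(net)
print(scores[["out_degree", "in_degree", "flow_betweenness",
              "information_centrality"]].round(3))
print()
for role, groups in cs.role_summary(scores).items():
    print(f"dominant {role}: {', '.join(groups)}")

# MYL both receives and forwards signal, so it is the network's mediator
# (max flow betweenness) and influencer (max information centrality).
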