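"""Discover global communication patterns with NMF.

The probability tensor is collapsed into a groups x pathways role matrix
(outgoing: who sends how much on each pathway).  NMF factorizes it into R
latent patterns; the rank is chosen where consensus stability (cophenetic
correlation + silhouette) first drops.
"""

import numpy as np

import commscape as cs
from commscape.patterns import SignalRoleMatrix

# role matrix with three planted sender programs
rng = np.random.default_rng(0)
Pj = np.zeros((12, 15))
for b in range(3):
    Pj[b * 4:(b + 1) * 4, b * 5:(b + 1) * 5] = 1.0
Pj += 0.05 * rng.random(Pj.shape)
role = SignalRoleMatrix(Pj, [f"G{i}" for i in range(12)],
                        [f"PW{i}" for i in range(15)], "outgoing")

R, diagnostics = cs.select_pattern_number(role, candidate_R=range(2, 7), seed=0)
print(diagnostics.round(3).to_string(index=False))
print(f"selected number of patterns: {R}")

dec = cs.nmf_factorize(role, R, seed=0)
assignment = np.argmax(dec.W, axis=1)
print("group -> pattern:", dict(zip(role.group_names, assignment.tolist())))

scores = cs.contribution_scores(dec)
print("contribution of G0 to PW0..PW4:", np.round(scores[0, :5], 2))

# Groups sharing a pattern coordinate their outgoing signaling through
# the same set of pathways; the contribution matrix links each group to
# the pathways its pattern is enriched for.
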