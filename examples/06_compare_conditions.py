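"""Compare communication between two conditions and evaluate robustness.

Ranks shared pathways by their change in overall information flow
(on/off/up/down), scores the multi-subunit false-positive metric for
single-gene-pair predictions, and measures how stable the inferred
communications are under cell subsampling.
"""

import numpy as np

import commscape as cs
from commscape.inference import SignalingNetwork


def _net(pathway, w):
    A = np.zeros((2, 2))
    A[0, 1] = w
    return SignalingNetwork(pathway, A, ["FIB", "MYL"])


condition_A = [_net("TGFb", 0.5), _net("WNT", 0.3), _net("BMP", 0.2)]
condition_B = [_net("TGFb", 0.1), _net("WNT", 0.3), _net("NOTCH", 0.4)]
flows = cs.compare_information_flow(condition_A, condition_B)
print(flows.to_string(index=False))

db = cs.LRDatabase(
    [
        cs.LRInteraction(id="tgfb1", ligand_subunits=["Tgfb1"],
                         receptor_subunits=["Tgfbr1", "Tgfbr2"],
                         pathway="TGFb", annotation="secreted_signaling")
    ]
)
frac, _ = cs.partial_complex_fpr(
    [cs.Prediction("FIB", "MYL", "Tgfb1", "Tgfbr1")], db
)
print(f"\npartial-complex false positive rate: {frac:.0%}")

spec = cs.plant_edges(cs.SyntheticSpec(seed=1), 10, effect_size=10.0)
sdb = cs.make_database(spec)
expr, grouping, _ = cs.make_expression(spec, sdb)
robust = cs.subsample_robustness(expr, grouping, sdb,
                                 cs.InferenceParams(M=100, seed=1),
                                 fractions=[0.9, 0.8], seed=1)
print("\nsubsampling robustness:")
print(robust.round(3).to_string(index=False))

# BMP turns off and NOTCH turns on between conditions; a prediction that
# names only one subunit of the Tgfbr1/Tgfbr2 complex is a false positive;
# the inferred communications are stable down to 80% of the cells.
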