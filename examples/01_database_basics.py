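"""Build, validate and summarize a ligand-receptor interaction database.

Interactions couple a (possibly multimeric) ligand with a (possibly
multimeric) receptor and may carry agonist/antagonist and co-stimulatory/
co-inhibitory cofactor gene sets, grouped into signaling pathways.
"""

import tempfile
from pathlib import Path

import commscape as cs
from commscape.database import write_database

db = cs.LRDatabase(
    [
        cs.LRInteraction(
            id="tgfb1",
            ligand_subunits=["Tgfb1"],
            receptor_subunits=["Tgfbr1", "Tgfbr2"],  # heteromeric receptor
            pathway="TGFb",
            annotation="secreted_signaling",
        ),
        cs.LRInteraction(
            id="wnt1",
            ligand_subunits=["Wnt1"],
            receptor_subunits=["Fzd1"],
            agonists=frozenset({"Rspo1"}),
            antagonists=frozenset({"Dkk1"}),
            pathway="WNT",
            annotation="secreted_signaling",
        ),
    ]
)

print("receptor complex name:", db["tgfb1"].receptor_name)
print("stats:", cs.database_stats(db))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "db.tsv"
    write_database(db, path)
    back = cs.load_database(path)
    print("round-trip identical:", back.interactions == db.interactions)

# The stats show 50% of interactions use a multi-subunit complex; such
# complexes are inactive whenever any subunit is unexpressed.
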