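"""Rank a drug library against a target pathway cloud in all three modes.

Uses hand-written PAS signatures: a faithful mimic, a double-strength
version, a reversed drug, and an unrelated decoy, scored against a
two-pathway target cloud.
"""

import pandas as pd

from pascloud import DrugSignature, rank_drugs
from pascloud.pas_engine import CloudEntry, PathwayCloud

target = PathwayCloud(entries=(
    CloudEntry("P1", +2.0, "activated"),
    CloudEntry("P2", -1.0, "repressed"),
))

library = [
    DrugSignature("faithful", pd.Series({"P1": +2.0, "P2": -1.0})),
    DrugSignature("amplifier", pd.Series({"P1": +4.0, "P2": -2.0})),
    DrugSignature("reverser", pd.Series({"P1": -2.0, "P2": +1.0})),
    DrugSignature("unrelated", pd.Series({"P1": +0.1, "P2": +0.2})),
]

for mode in ("mimic", "minimize", "exaggerate"):
    ranking = rank_drugs(library, target, mode)
    print(f"\n--- {mode} ---")
    for r in ranking.records:
        print(f"  {r.rank}. {r.drug_id:10} score={r.score:+.3f}")

# mimic: faithful and amplifier tie at cosine 1 (ties break alphabetically);
# minimize: the reverser wins with cosine 1 against the negated target;
# exaggerate: the amplifier's projection ratio of 2 certifies a
# beyond-target response, while the reverser scores -1.
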