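"""Build the shipped synthetic-accessibility fragment frequency table.

Counts radius-0..2 circular substructure identifiers over a seeded synthetic
molecule library and stores a log-relative-frequency score per fragment:
common fragments score high (easy), rare ones low, unseen ones lower still.
Deterministic; rerunning reproduces src/nullelab/data/sa_fragments.json.
"""

import json
import math
from collections import Counter
from pathlib import Path

from rdkit.Chem import rdMolDescriptors

from nullelab.synthetic import gen_molecule_library

SEED = 97
N_MOLECULES = 400
WALK_LENGTH = 8
MAX_FRAGMENTS = 2000

def main() -> None:
    library = gen_molecule_library(SEED, N_MOLECULES, walk_length=WALK_LENGTH)
    counts: Counter[int] = Counter()
    for st in library:
        fp = rdMolDescriptors.GetMorganFingerprint(st.mol, 2)
        counts.update(fp.GetNonzeroElements())
    top = dict(counts.most_common(MAX_FRAGMENTS))
    median = sorted(top.values())[len(top) // 2]
    scores = {str(k): round(math.log10(v / median), 4) for k, v in top.items()}
    unknown = min(scores.values()) - 0.5
    out = {
        "seed": SEED,
        "n_molecules": N_MOLECULES,
        "walk_length": WALK_LENGTH,
        "unknown_score": round(unknown, 4),
        "scores": scores,
    }
    path = Path(__file__).resolve().parent.parent / "src" / "nullelab" / "data" / "sa_fragments.json"
    path.write_text(json.dumps(out, indent=1))
    print(f"wrote {path} ({len(scores)} fragments, unknown_score={unknown:.3f})")

if __name__ == "__main__":
    main()
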