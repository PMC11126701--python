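"""Generate the clade-like synthetic datasets every later stage consumes.

One fixture per clade (fern, angiosperm, ant): an ultrametric birth-death
tree scaled to a realistic crown age, a rare clustered binary trait
(common for ants), taxonomy and habit columns, and a truth ledger with
the exact simulated gain ages.  Writes newick + TSV + JSON under
results/fixtures/.
"""

import json
import sys
from pathlib import Path

from nectarevo.synth import make_fixture
from nectarevo.traits import write_trait_table
from nectarevo.treeio import write_newick_file

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main(seed: int = 0):
    OUT.mkdir(parents=True, exist_ok=True)
    for clade in ("fern", "angiosperm", "ant"):
        fx = make_fixture(clade, seed=seed)
        write_newick_file(fx.tree, OUT / f"{clade}.nwk")
        write_trait_table(fx.table, OUT / f"{clade}_traits.tsv")
        (OUT / f"{clade}_truth.json").write_text(json.dumps(fx.truth, indent=1))
        print(f"{clade}: {fx.tree.n_tips} tips, height {fx.tree.height:.0f} My, "
              f"prevalence {fx.table['trait'].mean():.3f}, "
              f"true first gain {fx.truth['first_gain_age']:.1f} My BP")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
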