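"""Expression mapping: footprints, reporter overlap, left-right symmetry.

Maps the two synthetic reporters onto the lineage and computes the
quantities reported for real reporters: the number of terminal cells with
an expressing progenitor, the per-cell overlap classes between the two
reporters (simultaneous vs sequential), and the fraction of lateral
expressing cells with a mirror-expressed contralateral partner (>90% in
the real data).  Output: results/05_expression.json.
"""

import json
from collections import Counter
from pathlib import Path

from lineascope.experiments import synthetic_reporter_patterns
from lineascope.expression import (lr_symmetry_fraction, overlap_classify,
                                   terminal_footprint)
from lineascope.simulate import Template

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    tpl = Template.packaged()
    tree = tpl.tree
    a, b = synthetic_reporter_patterns(tpl)
    foot_a = terminal_footprint(a, tree)
    foot_b = terminal_footprint(b, tree)
    overlap = overlap_classify(a, b, tree)
    counts = Counter(v for v in overlap.values() if v != "none")
    out = {
        "reporterA_expressing_cells": len(a.cells),
        "reporterA_terminal_footprint": len(foot_a),
        "reporterA_footprint_fraction_of_leaves": len(foot_a) / len(tree.leaves),
        "reporterB_terminal_footprint": len(foot_b),
        "footprint_overlap": len(foot_a & foot_b),
        "overlap_classes": dict(counts),
        "reporterA_lr_symmetry": lr_symmetry_fraction(a),
        "reporterB_lr_symmetry": lr_symmetry_fraction(b),
    }
    (RESULTS / "05_expression.json").write_text(json.dumps(out, indent=2))
    print(f"reporter A: {len(a.cells)} expressing cells -> "
          f"{len(foot_a)} terminal cells "
          f"({out['reporterA_footprint_fraction_of_leaves']:.0%} of leaves); "
          f"L/R symmetry {out['reporterA_lr_symmetry']:.3f}; "
          f"overlap classes {dict(counts)}")


if __name__ == "__main__":
    main()
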