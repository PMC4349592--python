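"""Downstream statistics over the defect tables.

Computes, per mutant embryo, the sister-pair co-occurrence bootstrap
(100,000 iterations, inclusive exceedance p) and the defect-trio count;
aggregates per-cell penetrance with ABpxp and expression-set group
columns; and evaluates the published contingency statistics on the
printed counts (mutant-vs-wild-type defect rates, expression enrichment
of cycle-defective cells).  Outputs: results/04_statistics.json,
results/04_penetrance_per_cell.csv.
"""

import json
from pathlib import Path

import pandas as pd

from lineascope.config import AnalysisConfig
from lineascope.experiments import synthetic_reporter_patterns
from lineascope.lineage import matches_pattern
from lineascope.simulate import Template
from lineascope.stats import (category_association, count_defect_trios,
                              enrichment_2x2, enrichment_gof, penetrance_table,
                              sister_pair_bootstrap)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cfg = AnalysisConfig()
    tpl = Template.packaged()
    tree = tpl.tree
    mutants = pd.read_csv(RESULTS / "03_defects_mutants.csv")
    reporter_a, _ = synthetic_reporter_patterns(tpl)
    expressing = {c for c in tree.cells()
                  if any(c == e or c.startswith(e) for e in reporter_a.cells)}

    groups = {"ABpxp": "ABpxp", "expressing": expressing}
    tables = [g for _, g in mutants.groupby("embryo_id")]
    summary = penetrance_table(tables, groups)
    summary.per_cell.to_csv(RESULTS / "04_penetrance_per_cell.csv", index=False)

    per_embryo = {}
    all_cells = set(tree.cells())
    for sub in tables:
        eid = str(sub["embryo_id"].iloc[0])
        defective = set(sub["cell"]) & all_cells
        res = sister_pair_bootstrap(defective, all_cells,
                                    n_iter=cfg.n_bootstrap, seed=cfg.rng_seed)
        abpxp_def = {c for c in defective if matches_pattern(c, "ABpxp")}
        abpxp_sub = {c for c in all_cells if matches_pattern(c, "ABpxp")}
        res_abpxp = sister_pair_bootstrap(abpxp_def, abpxp_sub,
                                          n_iter=cfg.n_bootstrap,
                                          seed=cfg.rng_seed)
        per_embryo[eid] = {
            "defective_cells": res.X,
            "sister_pairs": res.Y,
            "bootstrap_p": res.p_value,
            "null_mean_pairs": res.null_mean,
            "abpxp_defective": res_abpxp.X,
            "abpxp_sister_pairs": res_abpxp.Y,
            "abpxp_bootstrap_p": res_abpxp.p_value,
            "defect_trios": count_defect_trios(set(sub["cell"]), tree),
        }

    assoc = category_association(tables, universe=sorted(all_cells))

    # the published contingency tables, re-tested with the log-space tails
    chi2_rate, p_rate, lg_rate = enrichment_2x2(495, 9636 - 495, 85, 26171 - 85)
    chi2_expr, p_expr, lg_expr = enrichment_gof(33, 49, 0.30)

    out = {
        "per_embryo": per_embryo,
        "mean_defects_per_embryo": float(pd.Series(
            [len(t) for t in tables]).mean()),
        "mean_sister_pairs_per_embryo": float(pd.Series(
            [per_embryo[e]["sister_pairs"] for e in per_embryo]).mean()),
        "mean_defect_trios_per_embryo": float(pd.Series(
            [per_embryo[e]["defect_trios"] for e in per_embryo]).mean()),
        "cycle_position_association": assoc,
        "published_defect_rate_test": {
            "table": [[495, 9636 - 495], [85, 26171 - 85]],
            "chi2": chi2_rate, "log10_p": lg_rate,
            "bound_satisfied_p_le_1e-220": lg_rate <= -220,
        },
        "published_expression_enrichment": {
            "observed": [33, 49], "expected_fraction": 0.30,
            "chi2": chi2_expr, "p": p_expr,
            "bound_satisfied_p_le_2e-6": p_expr <= 2e-6,
        },
    }
    (RESULTS / "04_statistics.json").write_text(json.dumps(out, indent=2))
    print(f"defect-rate chi2 {chi2_rate:.0f} (log10 p {lg_rate:.0f}); "
          f"expression enrichment p {p_expr:.2e}; "
          f"mean trios/embryo {out['mean_defect_trios_per_embryo']:.1f}")


if __name__ == "__main__":
    main()
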