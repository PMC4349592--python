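"""Simulate the study cohorts.

Generates the synthetic recordings the downstream analyses run on, at the
study's sample sizes: 18 wild-type embryos for the reference build, 22
held-out wild-type controls, and 8 'mutant' embryos each carrying the
standard supra-threshold injection program (timing shifts, displacements,
a midline crossing, a skipped death, an extra division) with its ground
truth.  Embryo CSVs go to scratch/cohorts/ (bulky); a summary lands in
results/01_cohorts_summary.json.
"""

import json
from pathlib import Path

from lineascope.experiments import standard_injection_program
from lineascope.simulate import (SimulationSpec, Template, generate_wildtype,
                                 inject_defects)
from lineascope.tracks import write_embryo_csv

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

N_WT_REF, N_WT_HELD, N_MUT = 18, 22, 8
SEED_REF, SEED_HELD, SEED_MUT = 100, 9000, 5000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    tpl = Template.packaged()
    summary = {"n_wt_reference": N_WT_REF, "n_wt_heldout": N_WT_HELD,
               "n_mutant": N_MUT, "template_cells": len(tpl.tree),
               "injections_per_mutant": None}
    for i in range(N_WT_REF):
        emb = generate_wildtype(SimulationSpec(template=tpl, seed=SEED_REF + i),
                                f"wt{i:02d}")
        write_embryo_csv(emb, OUT / f"wt{i:02d}.csv")
    for i in range(N_WT_HELD):
        emb = generate_wildtype(SimulationSpec(template=tpl, seed=SEED_HELD + i),
                                f"held{i:02d}")
        write_embryo_csv(emb, OUT / f"held{i:02d}.csv")
    n_inj = 0
    for i in range(N_MUT):
        seed = SEED_MUT + i
        emb = generate_wildtype(SimulationSpec(template=tpl, seed=seed),
                                f"mut{i:02d}", genotype="synthetic-mutant")
        spec = standard_injection_program(tpl, emb, seed)
        mut, truth = inject_defects(emb, spec, seed, tpl)
        write_embryo_csv(mut, OUT / f"mut{i:02d}.csv")
        truth.to_csv(OUT / f"mut{i:02d}.truth.csv", index=False)
        n_inj += len(truth)
    summary["injections_per_mutant"] = n_inj / N_MUT
    (RESULTS / "01_cohorts_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {N_WT_REF}+{N_WT_HELD} wild-type and {N_MUT} mutant embryos "
          f"to {OUT} ({n_inj} injected defects total)")


if __name__ == "__main__":
    main()
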