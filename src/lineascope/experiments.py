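"""Self-contained closure experiments on synthetic embryos.

These parameter-recovery experiments quantify the pipeline end to end:
specificity on held-out wild-type embryos, sensitivity to injected
supra-threshold defects, rigid-alignment recovery, per-cell timing-SD
recovery, and bootstrap-vs-enumeration agreement.  They are used both by
the test suite and by the reproduction script.

Injected timing shifts are max(12 min, 8 SD) and displacements 15 µm --
comfortably above the calling thresholds (3 SD and 5 min; 3.5 SD), since
an injection sitting exactly on a threshold is recovered only ~50-85% of
the time by construction (the observed magnitude carries one SD of
sampling noise, and the reference's SD estimate its own sampling error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .defects import call_all_defects
from .lineage import split_name
from .reference import ReferenceModel, build_reference, kabsch, spatial_align, temporal_align
from .simulate import (DefectSpec, Injection, SimulationSpec, Template,
                       generate_wildtype, inject_defects)
from .stats import sister_pair_bootstrap, sister_pair_null_exact
from .tracks import EmbryoRecord

#: category each injection kind must be recovered as
EXPECTED_CATEGORY = {
    "delay": "cycle_late",
    "advance": "cycle_early",
    "displace": "position",
    "mirror_cross": "position",
    "skip_death": "missed_death",
    "extra_division": "extra_division",
}


def wt_cohort(template: Template, n: int, seed0: int,
              prefix: str = "wt") -> list[EmbryoRecord]:
    return [generate_wildtype(SimulationSpec(template=template, seed=seed0 + i),
                              f"{prefix}{i}") for i in range(n)]


def _disjoint_pick(rng: np.random.Generator, candidates: list[str],
                   k: int, taken: set[str]) -> list[str]:
    """Pick k cells no two of which are in an ancestor/descendant relation
    with each other or with already-taken cells."""
    picked: list[str] = []
    for c in rng.permutation(candidates):
        related = any(c.startswith(t) or t.startswith(c) for t in taken)
        if not related:
            picked.append(c)
            taken.add(c)
            if len(picked) == k:
                break
    return picked


def standard_injection_program(template: Template, embryo: EmbryoRecord,
                               seed: int, timing_cv: float = 0.03,
                               ) -> DefectSpec:
    """A representative supra-threshold defect program for one embryo:
    two delays, one advance, two 15-µm displacements, one midline cross,
    one skipped death, one extra division."""
    rng = np.random.default_rng(seed)
    tree = template.tree
    dividing = [c for c in tree.cells()
                if tree.fates[c] == "divides" and 4 <= len(split_name(c)[1]) <= 6
                and c in embryo.cells]
    leaves = [c for c in tree.terminals if c in embryo.cells]
    # midline crossing is only detectable where the contralateral side is
    # genuinely distant: lateral AB-derived cells in dense neighborhoods
    lateral = [c for c in leaves
               if abs(template.pos_end[c][1]) >= 4.5 and split_name(c)[0] == "AB"]
    deaths = [c for c in sorted(tree.deaths) if c in embryo.cells]

    taken: set[str] = set()
    delays = _disjoint_pick(rng, dividing, 2, taken)
    advances = _disjoint_pick(rng, dividing, 1, taken)
    displaced = _disjoint_pick(rng, leaves, 2, taken)
    mirrors = _disjoint_pick(rng, lateral, 1, taken)
    skipped = _disjoint_pick(rng, deaths, 1, taken)
    extra = _disjoint_pick(rng, leaves, 1, taken)
    # one progenitor "trio": a delayed mother whose daughters are both
    # displaced -- defects propagating through a division, the signature the
    # sister-pair and trio statistics are built to detect
    trio_mothers = [c for c in dividing if len(split_name(c)[1]) == 6
                    and all(k in embryo.cells for k in tree.children(c))]
    trio = _disjoint_pick(rng, trio_mothers, 1, taken)
    trio_kids = [k for m in trio for k in tree.children(m)]
    taken.update(trio_kids)

    def timing_mag(cell: str) -> float:
        # well above the max(5 min, 3 SD) calling rule even when the
        # reference overestimates a cell's SD at small n
        return max(12.0, 8.0 * timing_cv * template.cycle(cell))

    inj = ([Injection(c, "delay", timing_mag(c)) for c in delays + trio]
           + [Injection(c, "advance", timing_mag(c)) for c in advances]
           + [Injection(c, "displace", 15.0) for c in displaced + trio_kids]
           + [Injection(c, "mirror_cross") for c in mirrors]
           + [Injection(c, "skip_death") for c in skipped]
           + [Injection(c, "extra_division") for c in extra])
    return DefectSpec(inj)


@dataclass
class SensitivityResult:
    n_injected: int
    n_recovered: int
    n_false_cells: int
    n_clean_cells: int
    missed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_injected

    @property
    def false_call_rate(self) -> float:
        return self.n_false_cells / self.n_clean_cells


def sensitivity_experiment(reference: ReferenceModel, template: Template,
                           n_seeds: int = 20, seed0: int = 5000,
                           config: AnalysisConfig | None = None,
                           ) -> SensitivityResult:
    """Inject the standard program into `n_seeds` fresh embryos and measure
    recovery of each injection as its expected category, plus the fraction
    of uninjected cells with any call."""
    config = config or AnalysisConfig()
    n_inj = n_rec = n_false = n_clean = 0
    missed: list[tuple[str, str]] = []
    for k in range(n_seeds):
        seed = seed0 + k
        emb = generate_wildtype(SimulationSpec(template=template, seed=seed),
                                f"mut{k}", genotype="synthetic-mutant")
        spec = standard_injection_program(template, emb, seed)
        mut, truth = inject_defects(emb, spec, seed, template)
        table, _, _ = call_all_defects(mut, reference, config)
        called = {(r.cell, r.category) for r in table.itertuples()}
        injected_cells = set(truth["cell"])
        for row in truth.itertuples():
            n_inj += 1
            if (row.cell, EXPECTED_CATEGORY[row.kind]) in called:
                n_rec += 1
            else:
                missed.append((row.cell, row.kind))
        # collateral: ignore descendants of injected cells (their timing or
        # identity legitimately changed with the injection)
        affected = {c for c in mut.cells
                    if any(c.startswith(i) for i in injected_cells)}
        false_cells = {c for c, _ in called} - affected
        n_false += len(false_cells)
        n_clean += len(set(mut.cells) - affected)
    return SensitivityResult(n_inj, n_rec, n_false, n_clean, missed)


def false_positive_experiment(reference: ReferenceModel, template: Template,
                              n_embryos: int = 8, seed0: int = 9000,
                              config: AnalysisConfig | None = None,
                              ) -> tuple[float, int, int]:
    """Fraction of cells called defective in held-out wild-type embryos
    (drawn from the generating distribution, not used in the reference)."""
    config = config or AnalysisConfig()
    n_def = n_tot = 0
    for k in range(n_embryos):
        emb = generate_wildtype(SimulationSpec(template=template, seed=seed0 + k),
                                f"held{k}")
        table, _, _ = call_all_defects(emb, reference, config)
        n_def += table["cell"].nunique()
        n_tot += emb.n_cells
    return n_def / n_tot, n_def, n_tot


def rigid_recovery_experiment(template: Template, seed: int = 42) -> float:
    """Residual RMS (µm) of aligning a noiseless randomly-placed embryo to a
    reference built from noiseless embryos: should be at numerical zero."""
    cfg = AnalysisConfig()
    quiet = dict(timing_cv=0.0, pos_noise_um=0.0, walk_um=0.0)
    e0 = generate_wildtype(SimulationSpec(template=template, seed=0,
                                          rigid_placement="fixed", **quiet), "a")
    e1 = generate_wildtype(SimulationSpec(template=template, seed=1,
                                          rigid_placement="fixed", **quiet), "b")
    ref = build_reference([e0, e1], cfg)
    probe = generate_wildtype(SimulationSpec(template=template, seed=seed,
                                             rigid_placement="random", **quiet),
                              "probe")
    tmap = temporal_align(probe, ref)
    tf = spatial_align(probe, ref, tmap, cfg)
    return tf.residual_rms


def sd_recovery_experiment(template: Template, n_embryos: int = 10,
                           seed0: int = 7000, timing_cv: float = 0.03,
                           ) -> float:
    """Median over cells of the relative error of the recovered per-cell
    cycle SD against the generating SD (cv x template cycle)."""
    cfg = AnalysisConfig()
    embs = wt_cohort(template, n_embryos, seed0)
    ref = build_reference(embs, cfg)
    rel = []
    for c, r in ref.cells.items():
        if r.n_obs >= n_embryos - 2 and np.isfinite(r.cycle_sd):
            true_sd = timing_cv * template.cycle(c)
            rel.append(abs(r.cycle_sd - true_sd) / true_sd)
    return float(np.median(rel))


def synthetic_reporter_patterns(template: Template):
    """Two synthetic reporter patterns on the template lineage.

    Reporter A emulates a broad, transient progenitor factor: bilaterally
    symmetric expression in the ABpxp progenitors (2-3 cell cycles from
    mid-lineage) plus the MSaa/MSpa sublineages, with one unpaired lateral
    cell.  Reporter B is a later factor overlapping A spatially in part of
    ABpxp but switched on only after A switches off (sequential overlap).
    """
    from .expression import ExpressionPattern
    from .lineage import matches_pattern

    a = ExpressionPattern("reporterA")
    b = ExpressionPattern("reporterB")
    tree = template.tree
    for cell in tree.cells():
        depth = len(split_name(cell)[1])
        birth, end = template.birth[cell], template.end[cell]
        span = end - birth
        in_abpxp = matches_pattern(cell, "ABpxp")
        in_ms = matches_pattern(cell, "MSaa") or matches_pattern(cell, "MSpa")
        if (in_abpxp or in_ms) and 3 <= depth <= 5:
            a.add(cell, birth, end)
        if in_abpxp and depth == 6:
            # spatial overlap without temporal overlap: A early, B late
            a.add(cell, birth, birth + 0.4 * span)
            b.add(cell, birth + 0.6 * span, end)
        if in_abpxp and depth == 7:
            b.add(cell, birth + 0.25 * span, end)
    # one unpaired lateral expressing cell (breaks perfect L/R symmetry)
    a.add("ABalapppp", template.birth["ABalapppp"], template.end["ABalapppp"])
    # one shared cell where both reporters are on simultaneously
    shared = "ABplpapa"
    b.add(shared, template.birth[shared], template.end[shared])
    return a, b


def bootstrap_enumeration_gap(n_iter: int = 100_000, seed: int = 11,
                              ) -> tuple[float, float]:
    """Compare the bootstrap p-value against exact enumeration on all
    sister-pair configurations of subgroups up to 8 cells.

    Returns (max absolute gap, max allowed gap 3*sqrt(p(1-p)/n_iter)).
    """
    cases = []
    # subgroups assembled from sister pairs and singletons (a leaf and an
    # internal cell can never be sisters of each other's names)
    pairs = [("ABplpappaa", "ABplpappap"), ("ABprpappaa", "ABprpappap"),
             ("MSpaapa", "MSpaapp"), ("Caaaaa", "Caaaap")]
    singles = ["ABalaaaaaa", "Eprpp", "Dpppa", "Cpllll"[:5]]
    for n_pairs in (1, 2, 3):
        for n_single in (0, 1, 2):
            grp = [c for p in pairs[:n_pairs] for c in p] + singles[:n_single]
            if len(grp) > 8:
                continue
            for x in range(2, min(len(grp), 6) + 1):
                cases.append((grp, x))
    worst_gap, worst_tol, worst_ratio = 0.0, 1.0, -np.inf
    for grp, x in cases:
        # deterministic choice of the defective set: first x cells
        defective = set(sorted(grp)[:x])
        res = sister_pair_bootstrap(defective, set(grp), n_iter=n_iter, seed=seed)
        exact = sister_pair_null_exact(x, grp, res.Y)
        gap = abs(res.p_value - exact)
        tol = 3.0 * np.sqrt(max(exact * (1 - exact), 1e-12) / n_iter) + 1.0 / n_iter
        if gap / tol > worst_ratio:
            worst_gap, worst_tol, worst_ratio = gap, tol, gap / tol
    return worst_gap, worst_tol
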