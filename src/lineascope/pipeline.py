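"""End-to-end pipeline: reference -> defect calls -> statistics -> report.

`run_pipeline` composes the library stages over in-memory records; the CLI
wraps it over files and adds a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .defects import call_all_defects
from .lineage import LineageTree
from .reference import ReferenceModel, build_reference
from .stats import count_defect_trios, penetrance_table, sister_pair_bootstrap
from .tracks import EmbryoRecord


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    seeds: dict[str, int]
    software_version: str
    started: str
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class ReportBundle:
    reference: ReferenceModel
    defect_tables: dict[str, pd.DataFrame]      # embryo_id -> calls
    summary: "object"                           # DefectSummary
    bootstrap: dict[str, dict]                  # embryo_id -> bootstrap stats
    trios: dict[str, int]
    manifest: RunManifest | None = None


def run_pipeline(config: AnalysisConfig,
                 wt_embryos: list[EmbryoRecord],
                 mutant_embryos: list[EmbryoRecord],
                 groups: dict | None = None,
                 tree: LineageTree | None = None,
                 reference: ReferenceModel | None = None) -> ReportBundle:
    """Build (or reuse) the reference, call defects per mutant, and compute
    penetrance, per-embryo sister-pair bootstraps and defect-trio counts."""
    if reference is None:
        if len(wt_embryos) < 2:
            raise ValueError("need >= 2 wild-type embryos (or a prebuilt reference)")
        reference = build_reference(wt_embryos, config)
    if not mutant_embryos:
        raise ValueError("need >= 1 mutant embryo")
    tree = tree or LineageTree.packaged()
    groups = groups or {}

    tables: dict[str, pd.DataFrame] = {}
    for emb in mutant_embryos:
        table, _, _ = call_all_defects(emb, reference, config)
        tables[emb.embryo_id] = table

    summary = penetrance_table(list(tables.values()), groups,
                               n_embryos=len(mutant_embryos))

    subgroup = set(tree.cells())
    boot: dict[str, dict] = {}
    trios: dict[str, int] = {}
    for eid, table in tables.items():
        defective = set(table["cell"]) & subgroup
        res = sister_pair_bootstrap(defective, subgroup,
                                    n_iter=config.n_bootstrap,
                                    seed=config.rng_seed)
        boot[eid] = {"X": res.X, "Y": res.Y, "p_value": res.p_value,
                     "null_mean": res.null_mean, "n_iter": res.n_iter}
        trios[eid] = count_defect_trios(set(table["cell"]), tree)

    return ReportBundle(reference=reference, defect_tables=tables,
                        summary=summary, bootstrap=boot, trios=trios)
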