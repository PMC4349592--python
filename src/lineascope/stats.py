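"""Downstream statistics over defect tables.

Implements the sister-pair co-occurrence bootstrap, defect-trio counting,
chi-squared enrichment tests with log-space tails (finite p down to
1e-300), and per-cell penetrance / lineage-group aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lineage import LineageTree, matches_pattern, sister_pairs


# ---------------------------------------------------------------------------
# sister-pair bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    X: int               # defective cells drawn per iteration
    Y: int               # observed defective sister pairs
    n_iter: int
    p_value: float       # (#iterations with count >= Y) / n_iter, inclusive
    seed: int
    null_mean: float
    exceedances: int

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def _pair_indices(subgroup: list[str]) -> np.ndarray:
    """(n_pairs, 2) integer indices of sister pairs within the subgroup."""
    index = {c: i for i, c in enumerate(subgroup)}
    pairs = sister_pairs(subgroup)
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.array([[index[a], index[b]] for a, b in pairs], dtype=np.intp)


def count_sister_pairs(defective: set[str]) -> int:
    """Sister pairs (by name) fully contained in the defective set."""
    return len(sister_pairs(defective))


def sister_pair_bootstrap(defective: set[str], subgroup: set[str],
                          n_iter: int = 100_000, seed: int = 0,
                          chunk: int = 4096) -> BootstrapResult:
    """Bootstrap null for the number of co-defective sister pairs.

    Null: draw |defective| cells uniformly without replacement from the
    subgroup, count sister pairs among them; repeat ``n_iter`` times.  The
    p-value is the inclusive exceedance fraction (#counts >= observed Y) /
    n_iter; when no iteration reaches Y it is reported conservatively as
    1/n_iter.
    """
    defective = set(defective)
    subgroup_sorted = sorted(set(subgroup))
    if not defective <= set(subgroup_sorted):
        raise ValueError("defective cells must be a subset of the subgroup")
    X = len(defective)
    n = len(subgroup_sorted)
    if X > n:
        raise ValueError("more defective cells than subgroup members")
    Y = count_sister_pairs(defective)
    pairs = _pair_indices(subgroup_sorted)
    rng = np.random.default_rng(seed)
    exceed = 0
    total_pairs = 0.0
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        u = rng.random((m, n))
        # take the X smallest uniforms per row: a uniform draw w/o replacement
        picked = np.argpartition(u, X - 1, axis=1)[:, :X] if X else np.empty((m, 0), int)
        member = np.zeros((m, n), dtype=bool)
        np.put_along_axis(member, picked, True, axis=1)
        if pairs.size:
            counts = (member[:, pairs[:, 0]] & member[:, pairs[:, 1]]).sum(axis=1)
        else:
            counts = np.zeros(m, dtype=int)
        exceed += int(np.count_nonzero(counts >= Y))
        total_pairs += float(counts.sum())
        done += m
    p = exceed / n_iter if exceed else 1.0 / n_iter
    return BootstrapResult(X=X, Y=Y, n_iter=n_iter, p_value=p, seed=seed,
                           null_mean=total_pairs / n_iter, exceedances=exceed)


def sister_pair_null_exact(X: int, subgroup: set[str] | list[str],
                           y_min: int) -> float:
    """Exact P(pairs >= y_min) by enumerating all C(n, X) draws.

    Independent brute-force check of the bootstrap; only feasible for
    small subgroups.
    """
    from itertools import combinations
    subgroup = sorted(set(subgroup))
    hits = total = 0
    for draw in combinations(subgroup, X):
        total += 1
        if count_sister_pairs(set(draw)) >= y_min:
            hits += 1
    return hits / total if total else 1.0


# ---------------------------------------------------------------------------
# defect trios
# ---------------------------------------------------------------------------

def count_defect_trios(defective: set[str], tree: LineageTree) -> int:
    """Internal cells where the cell and both daughters each carry a defect."""
    trios = 0
    for cell in defective:
        if cell not in tree:
            continue
        kids = tree.children(cell)
        if len(kids) == 2 and all(k in defective for k in kids):
            trios += 1
    return trios


# ---------------------------------------------------------------------------
# chi-squared enrichment with log-space tails
# ---------------------------------------------------------------------------

def chi2_sf_log10(chi2: float, df: int = 1) -> float:
    """log10 of the chi-squared upper tail, finite far beyond float underflow.

    For df=1 the tail is 2*P(Z > sqrt(chi2)); going through the asymptotic
    log-normal-tail keeps it finite where the plain survival function
    underflows (chi2 beyond ~1400).
    """
    from scipy.special import log_ndtr
    if df == 1:
        log_p = np.log(2.0) + log_ndtr(-np.sqrt(chi2))
    else:
        log_p = sps.chi2.logsf(chi2, df)
    return float(log_p / np.log(10.0))


def enrichment_gof(n_in: int, n_total: int, expected_fraction: float,
                   ) -> tuple[float, float, float]:
    """1-df goodness-of-fit chi-squared of an observed split vs an expected
    fraction (no continuity correction).  Returns (chi2, p, log10_p)."""
    if not (0 < n_in <= n_total):
        raise ValueError("need 0 < n_in <= n_total")
    if not (0.0 < expected_fraction < 1.0):
        raise ValueError("expected_fraction must be in (0, 1)")
    exp_in = n_total * expected_fraction
    exp_out = n_total - exp_in
    if min(exp_in, exp_out) < 1:
        import warnings
        warnings.warn("expected count below 1; chi-squared approximation is poor")
    chi2 = (n_in - exp_in) ** 2 / exp_in + ((n_total - n_in) - exp_out) ** 2 / exp_out
    lg = chi2_sf_log10(chi2)
    return float(chi2), float(10.0 ** max(lg, -308.0)), lg


def enrichment_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Pearson 1-df chi-squared on a 2x2 table [[a, b], [c, d]], no
    continuity correction; log-space tail.  Returns (chi2, p, log10_p)."""
    a, b, c, d = (float(x) for x in (a, b, c, d))
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
    lg = chi2_sf_log10(chi2)
    return float(chi2), float(10.0 ** max(lg, -308.0)), lg


# ---------------------------------------------------------------------------
# penetrance and group aggregation
# ---------------------------------------------------------------------------

@dataclass
class DefectSummary:
    per_cell: pd.DataFrame       # cell, category counts, n_defective, penetrance
    per_embryo: pd.DataFrame     # embryo_id x category counts (+ per-group)
    groups: dict[str, list[str]]
    n_embryos: int


def _group_members(cells: list[str], pattern_or_set) -> list[str]:
    if isinstance(pattern_or_set, str):
        return [c for c in cells if matches_pattern(c, pattern_or_set)]
    members = set(pattern_or_set)
    return [c for c in cells if c in members]


def penetrance_table(defect_tables: list[pd.DataFrame],
                     groups: dict | None = None,
                     n_embryos: int | None = None) -> DefectSummary:
    """Aggregate defect tables from several embryos.

    ``groups`` maps a name to a wildcard pattern (e.g. ``"ABpxp"``) or an
    explicit cell set (e.g. an expression footprint).  Penetrance of a
    cell is the fraction of assayed embryos in which it carries >= 1
    defect of any category.
    """
    groups = groups or {}
    frames = [t for t in defect_tables]
    all_df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["embryo_id", "cell", "category"]))
    embryos = sorted(set().union(*[set(t["embryo_id"]) for t in frames])
                     if frames else set())
    n_embryos = n_embryos if n_embryos is not None else len(embryos)

    cells = sorted(set(all_df["cell"]))
    rows = []
    for cell in cells:
        sub = all_df[all_df["cell"] == cell]
        by_cat = sub.groupby("category")["embryo_id"].nunique().to_dict()
        n_def = sub["embryo_id"].nunique()
        rows.append({
            "cell": cell,
            **{cat: by_cat.get(cat, 0) for cat in
               ("cycle_early", "cycle_late", "missed_division", "extra_division",
                "missed_death", "position")},
            "n_embryos_defective": n_def,
            "n_embryos_assayed": n_embryos,
            "penetrance": n_def / n_embryos if n_embryos else float("nan"),
        })
        for gname, gdef in groups.items():
            rows[-1][f"in_{gname}"] = bool(_group_members([cell], gdef))
    per_cell = pd.DataFrame(rows)

    erows = []
    for eid in embryos:
        sub = all_df[all_df["embryo_id"] == eid]
        row = {"embryo_id": eid, "n_defects": len(sub),
               "n_defective_cells": sub["cell"].nunique()}
        for cat in ("cycle_early", "cycle_late", "missed_division",
                    "extra_division", "missed_death", "position"):
            row[cat] = int((sub["category"] == cat).sum())
        for gname, gdef in groups.items():
            in_cells = set(_group_members(sorted(set(sub["cell"])), gdef))
            row[f"defective_cells_in_{gname}"] = len(in_cells)
            row[f"sister_pairs_in_{gname}"] = count_sister_pairs(in_cells)
        erows.append(row)
    per_embryo = pd.DataFrame(erows)

    resolved = {g: (d if isinstance(d, str) else sorted(d))
                for g, d in groups.items()}
    return DefectSummary(per_cell=per_cell, per_embryo=per_embryo,
                         groups=resolved, n_embryos=n_embryos)


def cells_defective_in_at_least(summary: DefectSummary, k: int) -> int:
    return int((summary.per_cell["n_embryos_defective"] >= k).sum())


def category_association(defect_tables: list[pd.DataFrame],
                         cat_a: str = "position",
                         cats_b: tuple = ("cycle_early", "cycle_late"),
                         universe: list[str] | None = None) -> dict:
    """Risk ratio for carrying `cat_a` given a defect in `cats_b`, with its
    2x2 chi-squared (simple conditional-frequency ratio, nothing more)."""
    all_df = pd.concat(defect_tables, ignore_index=True)
    has_a = set(all_df.loc[all_df["category"] == cat_a, "cell"])
    has_b = set(all_df.loc[all_df["category"].isin(cats_b), "cell"])
    cells = set(universe) if universe is not None else set(all_df["cell"])
    a_and_b = len(has_a & has_b)
    b_only = len(has_b - has_a)
    a_not_b = len(has_a - has_b)
    rest = len(cells - has_a - has_b)
    p_a_given_b = a_and_b / max(len(has_b & cells), 1)
    p_a_given_not_b = a_not_b / max(len(cells - has_b), 1)
    ratio = p_a_given_b / p_a_given_not_b if p_a_given_not_b else float("inf")
    chi2, p, lg = enrichment_2x2(a_and_b, b_only, a_not_b, rest)
    return {"risk_ratio": ratio, "chi2": chi2, "p": p, "log10_p": lg,
            "table": (a_and_b, b_only, a_not_b, rest)}
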