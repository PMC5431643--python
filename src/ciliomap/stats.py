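"""Zebrafish rescue-assay and cilia-morphometry statistics.

Embryo grade tables (grades 0 = normal to 4 = severe/dead) are collapsed to
normal-vs-morphant 2x2 tables and compared with a two-tailed Fisher exact
test computed by full hypergeometric enumeration.  Cilium samples are
summarised as incidence (percent, SEM across fields of view) and length
(mean +- SEM over ciliated cells), and compared between conditions with a
Welch test on log lengths or a rank-based alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GRADE_COLUMNS = ("normal", "grade1", "grade2", "grade3", "grade4")

#: A grade table is a pandas DataFrame with condition rows and the five
#: grade columns; :func:`ciliomap.simulate.gen_embryo_grades` produces one.
GradeTable = pd.DataFrame


@dataclass
class CiliaSample:
    """Per-cell ciliation records for one condition.

    ``cells`` columns: ``cell_id``, ``field_id``, ``ciliated`` (bool),
    ``length_um`` (positive float for ciliated cells, NaN otherwise).
    """

    condition: str
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "field_id", "ciliated", "length_um"}
        if not required.issubset(self.cells.columns):
            raise ValueError(f"cells table needs columns {sorted(required)}")
        cil = self.cells["ciliated"].astype(bool)
        lengths = self.cells["length_um"]
        if cil.any() and not (lengths[cil] > 0).all():
            raise ValueError("ciliated cells must have positive lengths")
        if (~cil).any() and lengths[~cil].notna().any():
            raise ValueError("non-ciliated cells must have no length")

    @property
    def lengths(self) -> np.ndarray:
        cil = self.cells["ciliated"].astype(bool)
        return self.cells.loc[cil, "length_um"].to_numpy(float)


def collapse_grades(
    table: GradeTable, condition_pair: tuple[str, str]
) -> np.ndarray:
    """Collapse two grade rows to a 2x2 (condition x normal/morphant) table.

    Grades 1-4 (including grade-4 deaths) count as morphant; grade 0 is
    normal.  Counts are conserved: normal + morphant = embryos injected.
    """
    rows = []
    for cond in condition_pair:
        if cond not in table.index:
            raise KeyError(f"condition {cond!r} missing from grade table")
        row = table.loc[cond, list(GRADE_COLUMNS)].to_numpy(int)
        rows.append([row[0], int(row[1:].sum())])
    return np.array(rows, dtype=int)


def fisher_exact_two_tailed(table: np.ndarray) -> float:
    """Two-tailed Fisher exact p for a 2x2 table by full enumeration.

    All tables with the observed margins are enumerated under the
    hypergeometric null and the probabilities of those no more likely than
    the observed table are summed ("small-p" two-tail rule), with a 1e-7
    relative tolerance for probability ties.  A zero row or column margin
    carries no information: p = 1 by convention, with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if 0 in (r1, n - r1, c1, n - c1):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    mask = pmf <= p_obs * (1 + 1e-7)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


def rescue_comparison(
    table: GradeTable,
    mo_condition: str = "MO",
    rescue_conditions: tuple[str, ...] = ("MO+WT", "MO+MT"),
    alpha: float = 0.05,
) -> dict:
    """Morpholino-alone vs rescue contrasts on collapsed grade tables.

    For each rescue condition present, reports the 2x2 table against the
    morpholino-alone row, the two-tailed Fisher exact p, a significance
    verdict at ``alpha``, and per-condition morphant fractions.
    """
    if mo_condition not in table.index:
        raise KeyError(f"condition {mo_condition!r} missing from grade table")
    report: dict = {"alpha": alpha, "contrasts": {}, "morphant_fraction": {}}
    for cond in table.index:
        row = table.loc[cond, list(GRADE_COLUMNS)].to_numpy(int)
        total = int(row.sum())
        report["morphant_fraction"][cond] = (
            float(row[1:].sum() / total) if total else float("nan"))
    for cond in rescue_conditions:
        if cond not in table.index:
            continue
        t22 = collapse_grades(table, (mo_condition, cond))
        p = fisher_exact_two_tailed(t22)
        report["contrasts"][f"{mo_condition} vs {cond}"] = {
            "table": t22,
            "p_value": p,
            "significant": bool(p < alpha),
        }
    return report


def cilia_summary(sample: CiliaSample) -> dict:
    """Incidence and length summary for one condition.

    Incidence is ciliated cells / total cells in percent, with its SEM
    taken across fields of view; length is mean +- SEM over ciliated
    cells.  An empty or cilium-free sample yields a defined n = 0 summary
    with NaN means.
    """
    cells = sample.cells
    n_cells = len(cells)
    lengths = sample.lengths
    n_cilia = len(lengths)
    if n_cells:
        incidence = 100.0 * n_cilia / n_cells
        by_field = cells.groupby("field_id")["ciliated"].mean() * 100.0
        inc_sem = (float(by_field.std(ddof=1) / np.sqrt(len(by_field)))
                   if len(by_field) > 1 else float("nan"))
    else:
        incidence, inc_sem = float("nan"), float("nan")
    if n_cilia:
        mean_len = float(lengths.mean())
        sem_len = (float(lengths.std(ddof=1) / np.sqrt(n_cilia))
                   if n_cilia > 1 else 0.0)
    else:
        mean_len, sem_len = float("nan"), float("nan")
    return {
        "condition": sample.condition,
        "n_cells": n_cells,
        "n_cilia": n_cilia,
        "incidence_pct": incidence,
        "incidence_sem_pct": inc_sem,
        "mean_length_um": mean_len,
        "sem_length_um": sem_len,
    }


def cilia_length_test(
    affected: CiliaSample,
    unaffected: CiliaSample,
    method: str = "welch",
) -> float:
    """Two-sided comparison of cilium lengths between two conditions.

    ``"welch"`` (default) is an unequal-variance t test on log lengths --
    lengths are positive and right-skewed, so the log scale is the natural
    one.  ``"rank"`` is a Mann-Whitney U test on the raw lengths.
    """
    x = affected.lengths
    y = unaffected.lengths
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 cilium lengths")
    if method == "welch":
        lx, ly = np.log(x), np.log(y)
        if np.ptp(lx) == 0 and np.ptp(ly) == 0:
            return 1.0 if lx[0] == ly[0] else 0.0
        t = sps.ttest_ind(lx, ly, equal_var=False)
        return float(t.pvalue)
    if method == "rank":
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            return 1.0
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               use_continuity=False, method="asymptotic")
        return float(res.pvalue)
    raise ValueError("method must be 'welch' or 'rank'")
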