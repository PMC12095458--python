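"""Cohort-level aggregation and non-parametric testing.

Per-patient fit results (one row per patient x lobe, where lobe "ALL" is
the fit of the mean TAC over all five lobes, not an average of lobe fits)
are summarised as mean / sd / median per parameter, and blood-flow (K1)
differences between demographic subgroups are tested with the
Mann-Whitney U test.  Associations with continuous covariates use
Spearman's rank correlation with a t-test p-value.  No multiple-comparison
correction is applied by default; Holm correction is available as an
option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOBE_LABELS",
    "PARAMETER_COLUMNS",
    "summarize",
    "mann_whitney",
    "spearman",
    "subgroup_analysis",
    "SUBGROUP_COMPARISONS",
]

logger = logging.getLogger(__name__)

LOBE_LABELS: tuple[str, ...] = ("LLL", "RLL", "RML", "LUL", "RUL", "ALL")
PARAMETER_COLUMNS: tuple[str, ...] = (
    "K1_mL_min_cm3", "k2_per_min", "partition", "V_A", "V_B", "j_s",
)

#: The subgroup battery: blood flow compared between women/men and
#: under/over the age cut, in all seven pairings.
SUBGROUP_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("women_under", "women_over"),
    ("men_under", "men_over"),
    ("all_under", "all_over"),
    ("women_under", "men_under"),
    ("women_over", "men_over"),
    ("women_under", "men_over"),
    ("women", "men"),
)

#: Combined sample size at or below which the exact U distribution is used
#: (ties force the normal approximation regardless).
EXACT_SWITCH_N = 20


def summarize(
    table: pd.DataFrame,
    by: str | Sequence[str] = "lobe",
    parameters: Sequence[str] = PARAMETER_COLUMNS,
) -> pd.DataFrame:
    """Mean, sample sd (n-1 denominator) and median per group and parameter.

    Single-row groups report sd = 0 with ``sd_defined = False``.  Empty
    groups are omitted with a warning.  Row order within groups does not
    affect the result.
    """
    parameters = [p for p in parameters if p in table.columns]
    if not parameters:
        raise ValueError("no parameter columns found in the table")
    rows = []
    for key, group in table.groupby(by, sort=True, dropna=False):
        if len(group) == 0:
            warnings.warn(f"empty group {key!r} omitted from the summary")
            continue
        row: dict = {"group": key, "n": len(group)}
        for p in parameters:
            vals = group[p].to_numpy(dtype=float)
            row[f"{p}_mean"] = vals.mean()
            row[f"{p}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"{p}_median"] = float(np.median(vals))
        row["sd_defined"] = len(group) > 1
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact U distribution is used for combined samples of at most 20
    values without ties; otherwise the normal approximation with tie
    correction.  The reported U is the statistic of the first group;
    swapping the groups leaves the p-value unchanged and the two U
    statistics add to n_a * n_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if a.size + b.size <= EXACT_SWITCH_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a t-test p-value.

    Ties receive average ranks; the two-sided p comes from
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom.
    Constant input has no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), int(x.size))


def _subgroups(table: pd.DataFrame, age_cut: float) -> dict[str, pd.DataFrame]:
    women = table[table["sex"] == "female"]
    men = table[table["sex"] == "male"]
    # "under" = age < cut, "over" = age >= cut: the two groups are exhaustive
    return {
        "women": women,
        "men": men,
        "women_under": women[women["age"] < age_cut],
        "women_over": women[women["age"] >= age_cut],
        "men_under": men[men["age"] < age_cut],
        "men_over": men[men["age"] >= age_cut],
        "all_under": table[table["age"] < age_cut],
        "all_over": table[table["age"] >= age_cut],
    }


def subgroup_analysis(
    table: pd.DataFrame,
    value_column: str = "K1_mL_min_cm3",
    age_cut: float = 65.0,
    holm: bool = False,
) -> pd.DataFrame:
    """Blood-flow comparisons between the seven demographic subgroup pairs.

    ``table`` must hold one row per patient (the all-lobes fit) with
    ``sex`` ("female"/"male"), ``age`` and the value column.  P-values are
    reported without multiple-comparison correction unless ``holm`` is
    set.  Comparisons with an empty side are skipped with a warning.
    """
    for col in ("sex", "age", value_column):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    groups = _subgroups(table, age_cut)
    rows = []
    for name_a, name_b in SUBGROUP_COMPARISONS:
        ga = groups[name_a][value_column].to_numpy(dtype=float)
        gb = groups[name_b][value_column].to_numpy(dtype=float)
        if ga.size == 0 or gb.size == 0:
            warnings.warn(
                f"comparison {name_a} vs {name_b} skipped: empty subgroup"
            )
            continue
        res = mann_whitney(ga, gb)
        rows.append(
            {
                "group_1": name_a,
                "group_2": name_b,
                "n_1": ga.size,
                "n_2": gb.size,
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adjusted[idx] = min(1.0, running)
        out["p_value_holm"] = adjusted
    return out
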