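"""Per-metabolite fold changes and significance testing.

Reproduces the printed-table analysis: for each metabolite, the fold change is
the ratio of arithmetic group means of raw (not log) relative abundances, and
significance comes from a two-sided Student's t-test (equal-variance by
default, Welch optional) or Tukey's HSD over the four cultivar x temperature
cells. Normality (Shapiro-Wilk) and variance homogeneity (Bartlett) are
reported as gate checks; the pipeline proceeds on failure with a logged
warning, matching the validate-then-test workflow it emulates.

The replicate unit is the vine: by default abundances are averaged over
sampling days within each (cultivar, temperature, replicate) before testing.
On cohorts where each sample already carries a unique replicate id the
averaging is an identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable

logger = logging.getLogger(__name__)

Group = Mapping[str, str]  # metadata column -> value filters defining a group


@dataclass(frozen=True)
class FoldChangeRecord:
    metabolite: str
    contrast: tuple[str, str]  # (numerator label, denominator label)
    fold_change: float
    p_value: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"{self.metabolite}: fold change must be > 0")


@dataclass(frozen=True)
class ShiftSummary:
    """How many metabolites moved, and by how much on average.

    ``mean_abs_percent_change`` is the mean of |fold change - 1| x 100 over
    the significant metabolites — the formalization of an 'average change in
    relative abundance' percentage; ``mean_abs_log2_fc`` is the symmetric
    alternative on the log2 scale.
    """

    n_significant: int
    mean_abs_percent_change: float
    mean_abs_log2_fc: float


def average_days(table: AbundanceTable) -> AbundanceTable:
    """Collapse repeated days: one averaged profile per cultivar/temp/vine."""
    wide = table.to_wide_frame()
    grouped = (
        wide.drop(columns=["day"])
        .groupby(["cultivar", "temperature", "replicate"], sort=True)
        .mean(numeric_only=True)
        .reset_index()
    )
    grouped["day"] = "avg"
    samples = grouped[["cultivar", "temperature", "day", "replicate"]]
    data = grouped[table.metabolites]
    return AbundanceTable(samples.reset_index(drop=True), data.reset_index(drop=True))


def _group_label(group: Group) -> str:
    return "/".join(f"{v}" for v in group.values())


def fold_change(
    table: AbundanceTable, metabolite: str, numerator: Group, denominator: Group
) -> FoldChangeRecord:
    """Ratio of arithmetic group means of raw abundances (numerator/denominator)."""
    num = table.group_values(metabolite, **numerator)
    den = table.group_values(metabolite, **denominator)
    if len(num) == 0 or len(den) == 0:
        raise ValueError(
            f"{metabolite}: empty group in contrast "
            f"({_group_label(numerator)} vs {_group_label(denominator)})"
        )
    return FoldChangeRecord(
        metabolite=metabolite,
        contrast=(_group_label(numerator), _group_label(denominator)),
        fold_change=float(num.mean() / den.mean()),
    )


def percent_change(fc: float) -> int:
    """Signed percent change for report prose: (FC - 1) x 100, nearest integer."""
    if fc <= 0:
        raise ValueError("fold change must be > 0")
    return int(round((fc - 1.0) * 100.0))


def ratio_consistency(
    ratio_at_control: float, fc_numerator: float, fc_denominator: float
) -> float:
    """Treatment-side ratio implied by a control ratio and two fold changes.

    E.g. an ascorbate/DHA ratio at 25 degC combined with the two metabolites'
    35/25 fold changes yields the implied ratio at 35 degC.
    """
    if min(ratio_at_control, fc_numerator, fc_denominator) <= 0:
        raise ValueError("all inputs must be > 0")
    return ratio_at_control * fc_numerator / fc_denominator


def significance_test(
    table: AbundanceTable,
    metabolite: str,
    groups: Sequence[Group],
    method: str = "student_t",
    equal_var: bool = True,
):
    """Two-sided p-value(s) for group mean differences of one metabolite.

    ``student_t`` expects exactly two groups and returns a float;
    ``tukey_hsd`` accepts >= 2 groups (typically the four cultivar x
    temperature cells) and returns {(i, j): adjusted p} over group-index pairs.
    All-zero within-group variance yields NaN with a warning.
    """
    values = [np.asarray(table.group_values(metabolite, **g), float) for g in groups]
    if any(len(v) < 2 for v in values):
        raise ValueError(f"{metabolite}: need >= 2 observations per group")
    if all(np.ptp(v) == 0 for v in values):
        warnings.warn(
            f"{metabolite}: zero within-group variance in all groups; p undefined",
            stacklevel=2,
        )
        if method == "student_t":
            return float("nan")
        return {
            (i, j): float("nan")
            for i in range(len(values))
            for j in range(i + 1, len(values))
        }
    if method == "student_t":
        if len(values) != 2:
            raise ValueError("student_t requires exactly two groups")
        res = stats.ttest_ind(values[0], values[1], equal_var=equal_var)
        return float(res.pvalue)
    if method == "tukey_hsd":
        res = stats.tukey_hsd(*values)
        return {
            (i, j): float(res.pvalue[i, j])
            for i in range(len(values))
            for j in range(i + 1, len(values))
        }
    raise ValueError(f"unknown method {method!r}")


def distribution_checks(
    table: AbundanceTable, metabolite: str, groups: Sequence[Group]
) -> dict:
    """Shapiro-Wilk p per group and Bartlett p across groups (gate checks).

    Groups with n < 3 are skipped for Shapiro-Wilk with a notice. Failures do
    not halt the pipeline; callers log and proceed.
    """
    out: dict = {"shapiro_wilk": {}, "bartlett": None, "notices": []}
    values = []
    for g in groups:
        v = np.asarray(table.group_values(metabolite, **g), float)
        values.append(v)
        label = _group_label(g)
        if len(v) < 3:
            out["notices"].append(f"{label}: n={len(v)} < 3, Shapiro-Wilk skipped")
            out["shapiro_wilk"][label] = None
        elif np.ptp(v) == 0:
            out["notices"].append(f"{label}: constant sample, Shapiro-Wilk skipped")
            out["shapiro_wilk"][label] = None
        else:
            out["shapiro_wilk"][label] = float(stats.shapiro(v).pvalue)
    usable = [v for v in values if len(v) >= 2 and np.ptp(v) > 0]
    if len(usable) >= 2:
        out["bartlett"] = float(stats.bartlett(*usable).pvalue)
    else:
        out["notices"].append("fewer than two variable groups; Bartlett skipped")
    return out


def diff_report(
    table: AbundanceTable,
    numerator: Group,
    denominator: Group,
    alpha: float = 0.05,
    method: str = "student_t",
    equal_var: bool = True,
    collapse_days: bool = True,
    fdr: bool = False,
) -> tuple[pd.DataFrame, ShiftSummary]:
    """Fold change + significance for every metabolite under one contrast.

    Returns a DataFrame (metabolite, fold_change, p_value, significant) in
    panel order and a :class:`ShiftSummary` over the significant metabolites.
    ``fdr=True`` applies Benjamini-Hochberg across the panel before calling
    significance (off by default: the emulated analysis reports per-metabolite
    p < alpha).
    """
    if collapse_days:
        table = average_days(table)
    if method == "tukey_hsd":
        # adjusted p over all four cultivar x temperature cells, then extract
        # the requested pair
        cells = [
            {"cultivar": c, "temperature": t}
            for c in sorted(table.samples["cultivar"].unique())
            for t in sorted(table.samples["temperature"].unique())
        ]
        try:
            i_num = cells.index(dict(numerator))
            i_den = cells.index(dict(denominator))
        except ValueError as exc:
            raise ValueError(
                "tukey_hsd contrasts must be single cultivar x temperature cells"
            ) from exc
    records = []
    for metabolite in table.metabolites:
        rec = fold_change(table, metabolite, numerator, denominator)
        if method == "tukey_hsd":
            pairwise = significance_test(table, metabolite, cells, method="tukey_hsd")
            p = pairwise[(min(i_num, i_den), max(i_num, i_den))]
        else:
            p = significance_test(
                table, metabolite, [numerator, denominator],
                method="student_t", equal_var=equal_var,
            )
        records.append((metabolite, rec.fold_change, p))
    frame = pd.DataFrame(records, columns=["metabolite", "fold_change", "p_value"])
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = frame["p_value"].notna()
        adjusted = frame["p_value"].copy()
        adjusted[ok] = multipletests(frame.loc[ok, "p_value"], method="fdr_bh")[1]
        frame["p_value"] = adjusted
    frame["significant"] = frame["p_value"] < alpha
    sig = frame.loc[frame["significant"]]
    n_sig = int(len(sig))
    if n_sig:
        mean_pct = float(np.mean(np.abs(sig["fold_change"] - 1.0) * 100.0))
        mean_l2 = float(np.mean(np.abs(np.log2(sig["fold_change"]))))
    else:
        mean_pct = 0.0
        mean_l2 = 0.0
    return frame, ShiftSummary(n_sig, mean_pct, mean_l2)
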