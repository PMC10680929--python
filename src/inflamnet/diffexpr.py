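"""Two-group differential expression on log2-scale expression matrices.

Each disease cohort is a genes x samples matrix with a case/control label per
sample.  Differential expression is a per-gene Welch t-test on the log2 values
with Benjamini-Hochberg adjustment across all genes of the cohort; a gene is
called differentially expressed when |log2FC| >= 1 (inclusive) and FDR < 0.05
(strict).  log2FC is case mean minus control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

CASE = "case"
CONTROL = "control"

#: default thresholds for calling a gene differentially expressed
LFC_MIN = 1.0
FDR_MAX = 0.05


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for one cohort.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    groups
        Mapping of sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise InputError("duplicate gene ids in expression matrix")
        if cols.has_duplicates:
            raise InputError("duplicate sample ids in expression matrix")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        bad = {g for g in self.groups.values()} - {CASE, CONTROL}
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        if not self.case_samples or not self.control_samples:
            raise InputError("both case and control groups must be non-empty")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == CONTROL]


def differential_expression(
    mat: ExpressionMatrix, lfc_min: float = LFC_MIN, fdr_max: float = FDR_MAX
) -> pd.DataFrame:
    """Per-gene Welch test with BH adjustment.

    Returns a DataFrame indexed by gene id with columns ``log2fc``,
    ``p_value``, ``fdr`` and ``direction`` (``up``/``down``/``ns``).

    Conventions for degenerate genes: a gene constant across *all* samples has
    p = 1; a gene with zero variance in both groups but different means has
    p = 0 (the groups separate perfectly on the log2 scale).
    """
    case = mat.values[mat.case_samples].to_numpy(float)
    ctrl = mat.values[mat.control_samples].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InputError("each group needs at least 2 samples for the Welch test")

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)

    var_case = case.var(axis=1, ddof=1)
    var_ctrl = ctrl.var(axis=1, ddof=1)
    degenerate = (var_case == 0) & (var_ctrl == 0)
    pvals[degenerate & (log2fc == 0)] = 1.0
    pvals[degenerate & (log2fc != 0)] = 0.0
    pvals = np.nan_to_num(pvals, nan=1.0)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(
        (log2fc >= lfc_min) & (fdr < fdr_max),
        "up",
        np.where((log2fc <= -lfc_min) & (fdr < fdr_max), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "fdr": fdr, "direction": direction},
        index=mat.values.index.rename("gene_id"),
    )


def threshold_degs(
    table: pd.DataFrame, lfc_min: float = LFC_MIN, fdr_max: float = FDR_MAX
) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) gene sets at the given thresholds.

    The fold threshold is inclusive (>= lfc_min) and the FDR threshold strict
    (< fdr_max).
    """
    if lfc_min < 0:
        raise ConfigurationError("lfc_min must be non-negative")
    sig = table["fdr"] < fdr_max
    up = set(table.index[sig & (table["log2fc"] >= lfc_min)])
    down = set(table.index[sig & (table["log2fc"] <= -lfc_min)])
    return up, down


def shared_degs(
    per_disease: Mapping[str, set[str]], exclude: Iterable[str] = ()
) -> set[str]:
    """Genes differentially expressed in every non-excluded disease."""
    exclude = set(exclude)
    kept = [s for d, s in per_disease.items() if d not in exclude]
    if len(kept) < 2:
        raise InputError("need at least 2 diseases after exclusion")
    return reduce(set.intersection, (set(s) for s in kept))


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")
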