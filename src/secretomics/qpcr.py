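"""Relative expression by the ddCt (Livak) method.

For a target gene, dCt = mean target Ct - mean reference Ct within each
condition (multiple reference genes are combined by the arithmetic mean of
their per-condition mean Cts, equivalent to a geometric mean of relative
quantities); ddCt = dCt(condition) - dCt(control) and the fold change is
2^(-ddCt).  Replicates are averaged on the Ct scale before differencing;
replicate spread is propagated as the root-sum-square of the standard errors
of the four mean terms.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "role", "condition", "replicate", "ct")


@dataclasses.dataclass
class ExpressionResult:
    gene: str
    condition: str
    control: str
    delta_delta_ct: float
    fold_change: float  # 2^(-ddCt)
    se: float  # propagated replicate spread on the Ct scale
    references: tuple[str, ...]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    dup = table.duplicated(subset=["gene", "condition", "replicate"])
    if dup.any():
        raise ValueError("replicate indices must be unique per gene x condition")
    return table


def _mean_se(table: pd.DataFrame, gene: str, condition: str) -> tuple[float, float]:
    sel = table[(table["gene"] == gene) & (table["condition"] == condition)]["ct"]
    if sel.empty:
        raise ValueError(f"gene {gene!r} missing in condition {condition!r}")
    n = len(sel)
    se = float(sel.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(sel.mean()), se


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    condition: str,
    control: str,
    references: list[str] | None = None,
) -> ExpressionResult:
    """ddCt relative expression of ``target`` in ``condition`` vs ``control``.

    ``references`` defaults to all genes with role ``"reference"`` in the
    table.  A reference gene missing from either condition raises
    ``ValueError`` naming the gene and condition.
    """
    table = _validate_table(table)
    if references is None:
        references = sorted(table.loc[table["role"] == "reference", "gene"].unique())
    if not references:
        raise ValueError("no reference genes supplied or found in the table")

    def dct(cond: str) -> tuple[float, float]:
        t_mean, t_se = _mean_se(table, target, cond)
        ref_means, ref_vars = [], []
        for ref in references:
            m, se = _mean_se(table, ref, cond)
            ref_means.append(m)
            ref_vars.append(se**2)
        k = len(references)
        ref_se2 = sum(ref_vars) / k**2
        return t_mean - float(np.mean(ref_means)), t_se**2 + ref_se2

    d_cond, var_cond = dct(condition)
    d_ctrl, var_ctrl = dct(control)
    ddct = d_cond - d_ctrl
    return ExpressionResult(
        gene=target,
        condition=condition,
        control=control,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
        se=math.sqrt(var_cond + var_ctrl),
        references=tuple(references),
    )


def expression_table(results: list[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "condition": [r.condition for r in results],
            "control": [r.control for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "fold_change": [r.fold_change for r in results],
            "se": [r.se for r in results],
        }
    )
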