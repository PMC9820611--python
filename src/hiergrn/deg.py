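"""Differential-expression calls per stress time point versus the 0 h control.

Each non-control time point is tested against the control on log2
values; genes pass at a time point when BH-adjusted FDR < 0.05 and the
fold change exceeds 1.5 (up) or falls below 0.66 (down), both strict.
The union of per-time-point DEGs is the gene universe entering network
construction.

The default per-gene test is a two-sided Welch t-test on log2 values —
a deliberately simple, self-contained stand-in for a count-based
negative-binomial GLM.  Callers working from count data can inject
externally computed p-values instead (``p_values=`` in
:func:`call_degs`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["fold_change", "de_test", "bh_adjust", "call_degs", "deg_union"]


def fold_change(treated: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """(fold_change, log2_fold_change) from per-replicate log2 values.

    log2 fold change is mean(treated) - mean(control); the fold change is
    2 raised to that difference.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("fold_change requires at least one replicate per group")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
        raise ValueError("fold_change requires finite log2 values")
    lfc = float(t.mean() - c.mean())
    return float(2.0 ** lfc), lfc


def de_test(treated: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on log2 values.

    Groups that are both constant return p = 1 when their means agree
    (no evidence of change) and p = 0 when they differ exactly.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError(
            "Welch test needs >= 2 replicates per group; supply external "
            "p-values via call_degs(p_values=...) for unreplicated designs"
        )
    if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
        return 1.0 if t.mean() == c.mean() else 0.0
    res = stats.ttest_ind(t, c, equal_var=False)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def call_degs(
    matrix: ExpressionMatrix,
    control_time: float = 0.0,
    fdr_max: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.66,
    p_values: pd.DataFrame | None = None,
    drop_all_zero: bool = True,
) -> pd.DataFrame:
    """One row per (gene, non-control time point) with DEG calls.

    BH adjustment is performed within each time point across all tested
    genes.  ``is_deg`` is True when fdr < ``fdr_max`` and the fold change
    is > ``fc_up`` or < ``fc_down`` (both strict).

    Parameters
    ----------
    p_values
        Optional externally computed raw p-values (genes x time points;
        index = gene IDs, columns = non-control time points as floats).
        When given, the built-in Welch test is bypassed.
    drop_all_zero
        Drop genes whose expression is exactly zero in every sample
        before testing (count logged).
    """
    if control_time not in matrix.time_points:
        raise ValueError(
            f"control time {control_time} not among time points {matrix.time_points}"
        )
    treat_times = [t for t in matrix.time_points if t != control_time]
    if not treat_times:
        raise ValueError("need at least one non-control time point")

    values = matrix.values
    if drop_all_zero:
        zero_mask = (values == 0).all(axis=1)
        n_zero = int(zero_mask.sum())
        if n_zero:
            logger.info("dropping %d genes with zero expression everywhere", n_zero)
            values = values.loc[~zero_mask]
    genes = list(values.index)

    ctrl_cols = matrix.columns_at_time(control_time)
    ctrl = values[ctrl_cols].to_numpy()

    rows = []
    for t in treat_times:
        cols = matrix.columns_at_time(t)
        trt = values[cols].to_numpy()
        lfc = trt.mean(axis=1) - ctrl.mean(axis=1)
        fc = 2.0 ** lfc
        if p_values is not None:
            try:
                p = p_values.loc[genes, t].to_numpy(dtype=float)
            except KeyError as exc:
                raise ValueError(f"external p-values missing entries: {exc}") from exc
        else:
            p = np.array([de_test(trt[i], ctrl[i]) for i in range(len(genes))])
        fdr = bh_adjust(p)
        is_deg = (fdr < fdr_max) & ((fc > fc_up) | (fc < fc_down))
        for i, g in enumerate(genes):
            rows.append((g, t, lfc[i], fc[i], p[i], fdr[i], bool(is_deg[i])))

    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "time_point", "log2_fold_change", "fold_change",
            "p_value", "fdr", "is_deg",
        ],
    )
    n_deg = table.loc[table.is_deg, "gene_id"].nunique()
    logger.info("DEG calling: %d genes tested, %d DEGs (union over %d time points)",
                len(genes), n_deg, len(treat_times))
    return table


def deg_union(deg_table: pd.DataFrame) -> set[str]:
    """Genes that are differentially expressed at >= 1 time point."""
    return set(deg_table.loc[deg_table.is_deg, "gene_id"])
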