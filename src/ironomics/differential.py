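"""Differential and dynamic intron retention between cell types.

The significance engine is the Audic-Claverie test for two digital count
observations x and y with library sizes N1 and N2: conditional on x, the
posterior predictive distribution of y is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1+N2/N1)^(x+y+1) ),

a negative binomial with r = x+1 successes and success probability
N1/(N1+N2).  The two-sided p-value doubles the smaller of the two tail
probabilities (including the observed value) and caps at 1.  Everything is
computed in log space by direct summation, so counts up to ~1e5 are exact to
floating precision without overflow.

A differentially retained intron has p <= 0.05 and |deltaIR| >= 0.1 and meets
the retention criteria in at least one of the two cell types; a dynamic
intron is retained in >=1 cell type and non-retained in >=1 other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DomainError

__all__ = [
    "DifferentialCall",
    "audic_claverie_pvalue",
    "call_differential",
    "find_dynamic_introns",
    "differential_table",
    "P_THRESHOLD",
    "DELTA_IR_THRESHOLD",
]

P_THRESHOLD = 0.05
DELTA_IR_THRESHOLD = 0.1


@dataclass(frozen=True)
class DifferentialCall:
    intron_id: str
    cell_type_a: str
    cell_type_b: str
    x_a: int
    x_b: int
    n_a: float
    n_b: float
    delta_ir: float
    p_value: float
    significant: bool


def _ac_logpmf(y: np.ndarray, x: int, log_ratio: float) -> np.ndarray:
    """log p(y|x) for the Audic-Claverie posterior predictive."""
    y = np.asarray(y, dtype=float)
    return (y * log_ratio + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * np.log1p(np.exp(log_ratio)))


def _ac_upper_tail(x: int, y: int, log_ratio: float) -> float:
    """P(Y >= y | x) by direct log-space summation from y upward.

    The posterior predictive has mean (x+1)*N2/N1; summation runs until the
    terms have decayed ~25 orders of magnitude below the running total.
    """
    if y == 0:
        return 1.0
    mean = (x + 1) * np.exp(log_ratio)
    sd = np.sqrt((x + 1) * np.exp(log_ratio) * (1 + np.exp(log_ratio)))
    hi = int(max(y + 64, mean + 20 * sd + 64))
    total = -np.inf
    k = y
    while True:
        ks = np.arange(k, hi + 1)
        lp = _ac_logpmf(ks, x, log_ratio)
        total = np.logaddexp(total, logsumexp(lp))
        if lp[-1] < total - 60.0:  # remaining geometric tail is negligible
            break
        k, hi = hi + 1, 2 * hi + 64
    return float(min(1.0, np.exp(total)))


def audic_claverie_pvalue(x: int, y: int, n1: float, n2: float,
                          sided: str = "two") -> float:
    """Audic-Claverie tail probability for counts x, y with library sizes n1, n2.

    ``sided="two"`` (default) doubles the smaller of the two one-sided
    enrichment tails, each evaluated in its natural conditioning direction —
    min(1, 2*min(P(Y>=y | x), P(X>=x | y))) — and is exactly symmetric under
    (x, n1) <-> (y, n2).  ``sided="greater"`` tests enrichment of y relative
    to x (P(Y>=y | x)); ``sided="less"`` the reverse.
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise DomainError("counts must be non-negative integers")
    if not (np.isfinite(n1) and np.isfinite(n2)) or n1 <= 0 or n2 <= 0:
        raise DomainError("library sizes must be positive and finite")
    x, y = int(x), int(y)
    log_ratio = float(np.log(n2) - np.log(n1))
    if sided == "greater":
        return _ac_upper_tail(x, y, log_ratio)
    if sided == "less":
        return _ac_upper_tail(y, x, -log_ratio)
    up = _ac_upper_tail(x, y, log_ratio)
    down = _ac_upper_tail(y, x, -log_ratio)
    return min(1.0, 2.0 * min(up, down))


def call_differential(ir_a: Mapping, ir_b: Mapping, n_a: float, n_b: float,
                      cell_type_a: str = "A", cell_type_b: str = "B",
                      sided: str = "two") -> DifferentialCall:
    """Pairwise Audic-Claverie comparison of one intron between two cell types.

    ``ir_a``/``ir_b`` are row-like mappings with ``irratio``, ``intron_depth``
    and ``retention_call``.  Counts are the rounded trimmed intronic depths
    (replicate-pooled upstream, so replicated cell types contribute summed
    evidence through their pooled coverage).
    """
    x_a = int(round(float(ir_a["intron_depth"])))
    x_b = int(round(float(ir_b["intron_depth"])))
    p = audic_claverie_pvalue(x_a, x_b, n_a, n_b, sided=sided)
    delta = float(ir_a["irratio"]) - float(ir_b["irratio"])
    retained_somewhere = (ir_a.get("retention_call") == "retained"
                          or ir_b.get("retention_call") == "retained")
    significant = (p <= P_THRESHOLD and abs(delta) >= DELTA_IR_THRESHOLD
                   and retained_somewhere)
    return DifferentialCall(str(ir_a.get("intron_id", "")), cell_type_a,
                            cell_type_b, x_a, x_b, float(n_a), float(n_b),
                            delta, p, significant)


def differential_table(ir_table: pd.DataFrame, cell_type_a: str,
                       cell_type_b: str, library_sizes: Mapping[str, float]
                       | None = None) -> pd.DataFrame:
    """All-introns differential calls for one cell-type pair.

    ``ir_table`` is the replicate-pooled output of
    :func:`ironomics.irquant.quantify_cell_types`.  Introns ineligible in both
    cell types (ambiguous host expression or length) are skipped.  Library
    sizes default to the summed intronic depths per cell type.
    """
    a = ir_table[ir_table["cell_type"] == cell_type_a].set_index("intron_id")
    b = ir_table[ir_table["cell_type"] == cell_type_b].set_index("intron_id")
    shared = a.index.intersection(b.index)
    if library_sizes is None:
        library_sizes = {
            cell_type_a: max(float(a["intron_depth"].sum()), 1.0),
            cell_type_b: max(float(b["intron_depth"].sum()), 1.0),
        }
    rows = []
    for iid in shared:
        ra, rb = a.loc[iid], b.loc[iid]
        eligible = (ra["host_fpkm"] >= 1.0 or rb["host_fpkm"] >= 1.0)
        if not eligible:
            continue
        call = call_differential(
            dict(ra, intron_id=iid), dict(rb, intron_id=iid),
            library_sizes[cell_type_a], library_sizes[cell_type_b],
            cell_type_a, cell_type_b)
        rows.append(dict(intron_id=iid, pair=f"{cell_type_a}_vs_{cell_type_b}",
                         x_a=call.x_a, x_b=call.x_b,
                         delta_ir=round(call.delta_ir, 6),
                         p_value=call.p_value, significant=call.significant))
    return pd.DataFrame(rows)


def find_dynamic_introns(ir_table: pd.DataFrame) -> set[str]:
    """Introns retained in >=1 cell type and non-retained in >=1 other.

    Ambiguous states count for neither side.  Expects the pooled per-cell-type
    IR table with columns ``intron_id``, ``cell_type``, ``retention_call``.
    """
    if ir_table["cell_type"].nunique() < 2:
        raise ValueError("dynamic introns require at least two cell types")
    piv = ir_table.pivot_table(index="intron_id", columns="cell_type",
                               values="retention_call", aggfunc="first")
    ret = (piv == "retained").any(axis=1)
    non = (piv == "non_retained").any(axis=1)
    return set(piv.index[ret & non])
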