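"""Position-resolved GCH methylation profiles around splice sites.

Builds introns x position-bins matrices of %GCH methylation over the ±200 bp
window around a chosen anchor (5' splice site, 3' splice site or intron
midpoint), clusters them by complete-linkage hierarchical clustering
(Euclidean distance, tree cut at k=5 by default), aggregates group mean
curves (retained vs non-retained states, with length/GC-matched controls),
and deconfounds H3K36me3 from nucleosome occupancy with a log-link count
regression of the mark on %GCH methylation followed by a residual group
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from .errors import DomainError

__all__ = [
    "ProfileMatrix",
    "build_profile_matrix",
    "cluster_profiles",
    "aggregate_group_profiles",
    "match_controls",
    "h3k36me3_glm_adjust",
    "first_vs_internal_stratify",
    "WINDOW",
]

WINDOW = 200  # bp each side of the anchor


@dataclass
class ProfileMatrix:
    """Rows = introns, columns = position bins, values = %GCH methylation."""

    values: pd.DataFrame          # index intron ids, columns bin start offsets
    bin_size: int
    anchor: str
    clusters: pd.Series | None = None

    @property
    def offsets(self) -> np.ndarray:
        return self.values.columns.to_numpy(int)

    def imputed(self) -> pd.DataFrame:
        """Column-mean imputation of missing bins (used for clustering only)."""
        return self.values.apply(lambda c: c.fillna(c.mean()), axis=0)


def _anchor_position(intron, anchor: str) -> int:
    start, end, strand = intron.start, intron.end, intron.strand
    if anchor == "5ss":
        return start if strand == "+" else end - 1
    if anchor == "3ss":
        return end - 1 if strand == "+" else start
    if anchor == "mid":
        return (start + end) // 2
    raise ValueError(f"unknown anchor {anchor!r}")


def build_profile_matrix(introns, gch_calls: pd.DataFrame, anchor: str = "5ss",
                         bin_size: int = 10) -> ProfileMatrix:
    """Pooled %GCH methylation per intron per offset bin over ±200 bp.

    Offsets are transcription-oriented: negative is upstream of the anchor
    for both strands.  Bins without GCH sites are missing (NaN); introns with
    all bins missing are dropped.
    """
    if 2 * WINDOW % bin_size:
        raise ValueError("bin_size must divide 400")
    edges = np.arange(-WINDOW, WINDOW + 1, bin_size)
    cols = edges[:-1]
    pos = gch_calls["pos"].to_numpy()
    meth = gch_calls["count_methylated"].to_numpy(float)
    total = meth + gch_calls["count_unmethylated"].to_numpy(float)
    order = np.argsort(pos)
    pos, meth, total = pos[order], meth[order], total[order]

    rows, index = [], []
    for intron in introns:
        centre = _anchor_position(intron, anchor)
        lo, hi = centre - WINDOW, centre + WINDOW + 1
        a, b = np.searchsorted(pos, [lo, hi])
        if a == b:
            continue
        p, m, t = pos[a:b], meth[a:b], total[a:b]
        off = (p - centre) if intron.strand == "+" else (centre - p)
        keep = (off >= -WINDOW) & (off < WINDOW)
        off, m, t = off[keep], m[keep], t[keep]
        if len(off) == 0:
            continue
        bin_idx = (off + WINDOW) // bin_size
        msum = np.bincount(bin_idx, weights=m, minlength=len(cols))
        tsum = np.bincount(bin_idx, weights=t, minlength=len(cols))
        with np.errstate(invalid="ignore"):
            row = np.where(tsum > 0, 100.0 * msum / tsum, np.nan)
        if np.all(np.isnan(row)):
            continue
        rows.append(row)
        index.append(intron.intron_id)
    values = pd.DataFrame(rows, index=index, columns=cols)
    return ProfileMatrix(values=values, bin_size=bin_size, anchor=anchor)


def cluster_profiles(matrix: ProfileMatrix, k: int = 5) -> pd.Series:
    """Complete-linkage hierarchical clustering of profile rows, cut at k.

    Euclidean distance on column-mean-imputed rows; deterministic with ties
    broken by row order.  Cluster labels are 1..k.
    """
    X = matrix.imputed().to_numpy(float)
    if len(X) < k:
        raise ValueError(f"need >= {k} rows to form {k} clusters, got {len(X)}")
    if k == 1:
        labels = np.ones(len(X), dtype=int)
    else:
        Z = linkage(X, method="complete", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=matrix.values.index, name="cluster")
    matrix.clusters = assignments
    return assignments


def aggregate_group_profiles(matrices: dict[str, ProfileMatrix]) -> pd.DataFrame:
    """Per-column mean curve per named group, missing values excluded."""
    rows = {}
    for name, m in matrices.items():
        if not len(m.values):
            raise ValueError(f"group {name!r} is empty")
        rows[name] = m.values.mean(axis=0, skipna=True)
    return pd.DataFrame(rows).T


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame,
                   max_gc_delta: float = 0.05,
                   max_length_ratio: float = 2.0) -> pd.DataFrame:
    """Nearest-neighbour (length, GC) matching of control introns to cases.

    ``cases`` and ``pool`` need columns ``intron_id``, ``length``,
    ``gc_content``.  Each case takes its closest unused pool intron within
    the caliper (|dGC| <= 0.05 and length ratio <= 2); unmatched cases are
    dropped.  Returns matched pool rows with a ``case_id`` column.
    """
    used: set[int] = set()
    out = []
    pool = pool.reset_index(drop=True)
    log_len_pool = np.log(pool["length"].to_numpy(float))
    gc_pool = pool["gc_content"].to_numpy(float)
    for case in cases.itertuples():
        d = (np.abs(log_len_pool - np.log(case.length)) / np.log(max_length_ratio)
             + np.abs(gc_pool - case.gc_content) / max_gc_delta)
        ok = ((np.abs(gc_pool - case.gc_content) <= max_gc_delta)
              & (np.abs(log_len_pool - np.log(case.length)) <= np.log(max_length_ratio)))
        for i in used:
            ok[i] = False
        if not ok.any():
            continue
        cand = np.flatnonzero(ok)
        best = int(cand[np.argmin(d[cand])])
        used.add(best)
        row = pool.iloc[best].to_dict()
        row["case_id"] = case.intron_id
        out.append(row)
    return pd.DataFrame(out)


def h3k36me3_glm_adjust(counts: np.ndarray, gch_meth: np.ndarray,
                        groups: np.ndarray) -> dict:
    """Remove the GCH-accessibility component from H3K36me3 counts.

    Fits a Poisson log-link regression of the mark counts on %GCH
    methylation, reports the overdispersion scale (Pearson chi-square / df),
    and contrasts the Pearson residuals between retained and non-retained
    groups with a two-sample t-test.  When the group difference in counts is
    entirely mediated by accessibility, the adjusted contrast is null.
    """
    import statsmodels.api as sm

    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise DomainError("H3K36me3 counts must be integers")
        counts = counts.astype(int)
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    gch_meth = np.asarray(gch_meth, dtype=float)
    groups = np.asarray(groups)

    exog = sm.add_constant(gch_meth)
    model = sm.GLM(counts, exog, family=sm.families.Poisson())
    fit = model.fit()
    resid = fit.resid_pearson
    scale = float(fit.pearson_chi2 / fit.df_resid) if fit.df_resid > 0 else np.nan

    r = resid[groups == "retained"]
    n = resid[groups == "non_retained"]
    stat, p = ttest_ind(r, n, equal_var=False)
    ci = fit.conf_int()[1]  # slope row: [low, high]
    return {
        "slope": float(fit.params[1]),
        "slope_ci": (float(ci[0]), float(ci[1])),
        "overdispersion_scale": scale,
        "residual_difference": float(r.mean() - n.mean()),
        "t_statistic": float(stat),
        "p_value": float(p),
    }


def first_vs_internal_stratify(introns, annotation: pd.DataFrame | None = None,
                               tx_position: dict[str, int] | None = None
                               ) -> tuple[list, list]:
    """Split introns into first-in-transcript vs internal.

    An intron counts as *first* when it is the first intron of any transcript
    of its gene (promoter-proximal chromatin is the concern, so any-transcript
    is the inclusive rule).  Position is taken from ``tx_position`` (intron id
    -> 1-based position) when given, otherwise derived from the annotation's
    transcript exon chains.
    """
    if tx_position is None:
        tx_position = {}
        exons = annotation[annotation["Feature"] == "exon"]
        for (_, tid), tx in exons.groupby(["gene_id", "transcript_id"], sort=False):
            tx = tx.sort_values("Start")
            strand = str(tx["Strand"].iloc[0])
            rows = list(tx.itertuples())
            n_introns = len(rows) - 1
            for j, (a, b) in enumerate(zip(rows[:-1], rows[1:])):
                iid = f"{a.Chromosome}:{int(a.End)}-{int(b.Start)}:{strand}"
                order = j + 1 if strand == "+" else n_introns - j
                prev = tx_position.get(iid)
                tx_position[iid] = min(prev, order) if prev else order
    first, internal = [], []
    for intron in introns:
        iid = getattr(intron, "intron_id", None) or str(intron)
        (first if tx_position.get(iid, 2) == 1 else internal).append(intron)
    return first, internal
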