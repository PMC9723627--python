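"""NOMe-seq chromatin-state calling from GCH methylation.

In NOMe-seq the exogenous M.CviPI methyltransferase methylates GpC sites that
are not protected by nucleosomes, so the per-site GCH methylation level reads
out chromatin accessibility.  This module:

* filters CpG calls to sites with coverage > 5 reads;
* segments candidate regions by chaining consecutive GCH sites whose signal
  exceeds the chromosome-wide mean, breaking on inter-site gaps (150 bp for
  NFRs on methylation, 20 bp for nucleosomes on occupancy = 1 - methylation);
* tests each candidate with a one-sided Fisher exact test of summed read
  counts against the local background (4000 bp flanks for NFRs, 1000 bp for
  nucleosomes) and keeps calls with p <= 0.05 that exceed the minimum length
  (> 40 bp NFR, > 140 bp nucleosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import InputIntegrityError

__all__ = [
    "ChromatinRegionCall",
    "filter_cpg_coverage",
    "segment_candidates",
    "fisher_region_test",
    "call_nfrs",
    "call_nucleosomes",
    "region_methylation",
    "NFR_PARAMS",
    "NUCLEOSOME_PARAMS",
]

CPG_MIN_COVERAGE = 5  # keep sites with coverage strictly greater than this
P_THRESHOLD = 0.05

#: Candidate-seeding and testing parameters per mode.  The threshold
#: multiplier scales the chromosome-wide mean signal that a site must exceed
#: to seed a candidate: at shallow NOMe coverage roughly half the background
#: sites exceed the plain mean by sampling noise alone, chaining candidates
#: across background, so the NFR default demands 1.5x the mean; occupancy
#: runs near saturation (background ~0.9), so its default is a gentler 1.2x.
NFR_PARAMS = dict(max_gap=150, min_len=40, background_flank=4000,
                  signal="methylation", threshold_multiplier=1.5)
NUCLEOSOME_PARAMS = dict(max_gap=20, min_len=140, background_flank=1000,
                         signal="occupancy", threshold_multiplier=1.2)


@dataclass(frozen=True)
class ChromatinRegionCall:
    chrom: str
    start: int
    end: int
    kind: Literal["NFR", "nucleosome"]
    p_value: float
    region_meth: float
    background_meth: float
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_cpg_coverage(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep CpG sites covered by more than 5 reads."""
    total = calls["count_methylated"] + calls["count_unmethylated"]
    return calls[total > CPG_MIN_COVERAGE].reset_index(drop=True)


def _site_signal(calls: pd.DataFrame, signal: str) -> np.ndarray:
    total = (calls["count_methylated"] + calls["count_unmethylated"]).to_numpy(float)
    meth = calls["count_methylated"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, meth / total, np.nan)
    return 1.0 - frac if signal == "occupancy" else frac


def segment_candidates(calls: pd.DataFrame, max_gap: int, min_len: int,
                       signal: str = "methylation",
                       threshold_multiplier: float = 1.0) -> list[tuple[int, int]]:
    """Chain elevated GCH sites into candidate intervals.

    A site is *elevated* when its signal exceeds ``threshold_multiplier``
    times the chromosome-wide mean signal.  Chains break when consecutive
    elevated sites are more than ``max_gap`` apart; the emitted interval spans
    first to last chained site (inclusive of the last cytosine, so length =
    last - first + 1) and intervals of length <= ``min_len`` are dropped.
    """
    pos = calls["pos"].to_numpy()
    if len(pos) > 1 and np.any(np.diff(pos) < 0):
        raise InputIntegrityError("GCH calls must be sorted by position")
    sig = _site_signal(calls, signal)
    valid = ~np.isnan(sig)
    mean_sig = np.nanmean(sig) if valid.any() else 0.0
    elevated = valid & (sig > threshold_multiplier * mean_sig)
    epos = pos[elevated]
    if len(epos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(epos) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(epos) - 1]])
    out = []
    for s, e in zip(starts, ends):
        a, b = int(epos[s]), int(epos[e]) + 1
        if b - a > min_len:
            out.append((a, b))
    return out


def fisher_region_test(candidate: tuple[int, int], calls: pd.DataFrame,
                       background_flank: int, signal: str = "methylation",
                       kind: str = "NFR",
                       chrom: str | None = None) -> ChromatinRegionCall | None:
    """One-sided Fisher exact test of a candidate against its local background.

    Builds the 2x2 table [methylated, unmethylated] x [region, background]
    from summed read counts over GCH sites (occupancy mode swaps the
    methylated/unmethylated roles) and tests for enrichment in the region.
    Returns None when the background flanks contain no sites.
    """
    a, b = candidate
    pos = calls["pos"].to_numpy()
    in_region = (pos >= a) & (pos < b)
    in_bg = (((pos >= a - background_flank) & (pos < a))
             | ((pos >= b) & (pos < b + background_flank)))
    if not in_region.any() or not in_bg.any():
        return None
    meth = calls["count_methylated"].to_numpy(int)
    unmeth = calls["count_unmethylated"].to_numpy(int)
    rm, ru = int(meth[in_region].sum()), int(unmeth[in_region].sum())
    bm, bu = int(meth[in_bg].sum()), int(unmeth[in_bg].sum())
    if signal == "occupancy":
        rm, ru, bm, bu = ru, rm, bu, bm
    table = [[rm, ru], [bm, bu]]
    _, p = fisher_exact(table, alternative="greater")
    region_meth = rm / (rm + ru) if rm + ru else float("nan")
    bg_meth = bm / (bm + bu) if bm + bu else float("nan")
    if chrom is None:
        chrom = str(calls["chrom"].iloc[0]) if len(calls) else "."
    return ChromatinRegionCall(chrom, a, b, kind, float(p),
                               region_meth, bg_meth, int(in_region.sum()))


def _call_regions(calls: pd.DataFrame, kind: str, params: dict,
                  threshold_multiplier: float | None = None
                  ) -> list[ChromatinRegionCall]:
    calls = calls.sort_values("pos").reset_index(drop=True)
    mult = params["threshold_multiplier"] if threshold_multiplier is None \
        else threshold_multiplier
    out = []
    for cand in segment_candidates(calls, params["max_gap"], params["min_len"],
                                   params["signal"], mult):
        call = fisher_region_test(cand, calls, params["background_flank"],
                                  params["signal"], kind)
        if call is not None and call.p_value <= P_THRESHOLD:
            out.append(call)
    return out


def call_nfrs(calls: pd.DataFrame,
              threshold_multiplier: float | None = None) -> list[ChromatinRegionCall]:
    """Nucleosome-free regions: gap 150 bp, length > 40 bp, 4 kb background."""
    return _call_regions(calls, "NFR", NFR_PARAMS, threshold_multiplier)


def call_nucleosomes(calls: pd.DataFrame,
                     threshold_multiplier: float | None = None
                     ) -> list[ChromatinRegionCall]:
    """Nucleosomes from GCH occupancy: gap 20 bp, length > 140 bp, 1 kb background."""
    return _call_regions(calls, "nucleosome", NUCLEOSOME_PARAMS,
                         threshold_multiplier)


def region_methylation(interval: tuple[int, int], calls: pd.DataFrame,
                       context: str | None = None) -> float | None:
    """Pooled methylation (summed meth / summed total) over sites in interval.

    Returns None when the interval contains no (context-matching) sites.
    """
    sub = calls
    if context is not None and "context" in calls.columns:
        sub = sub[sub["context"] == context]
    a, b = interval
    sub = sub[(sub["pos"] >= a) & (sub["pos"] < b)]
    total = int(sub["count_methylated"].sum() + sub["count_unmethylated"].sum())
    if total == 0:
        return None
    return float(sub["count_methylated"].sum() / total)


def calls_to_bed(calls: list[ChromatinRegionCall]) -> pd.DataFrame:
    """BED6+1 rows (p-value in the column after strand) for region calls."""
    return pd.DataFrame(
        [dict(chrom=c.chrom, start=c.start, end=c.end,
              name=f"{c.kind}_{i + 1}", score=0, strand=".",
              p_value=c.p_value) for i, c in enumerate(calls)]
    )
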