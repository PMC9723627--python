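"""Intron-retention quantification and retention calling.

For every intron and sample the module computes

    IRratio = intronic abundance / (intronic + exonic abundance)

where intronic abundance is the 30%-trimmed mean of per-base read depth over
the intron (bases covered by any annotated exon are masked out first) and
exonic abundance is the number of reads spanning the intron's own
exon-exon junction.  An intron is called *retained* in a sample when
IRratio >= 0.1, intron depth >= 10, >=90% of its unmasked bases are covered
and both flanking exons have PSI >= 0.9; *non-retained* when IRratio <= 0.01
and intron depth < 10; anything else (or an intron from a weakly expressed
host gene, FPKM < 1, or longer than 10 kb) is *ambiguous*.

Introns are additionally classified into Types A/B/C from the flanking-exon
context (constitutive vs alternative) and overlap with known exons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from . import io as iio
from .errors import DomainError, EmptyMeasurementError, InputIntegrityError

__all__ = [
    "IntronRecord",
    "IRMeasurement",
    "PsiValue",
    "extract_introns",
    "trimmed_intronic_abundance",
    "exonic_abundance",
    "compute_irratio",
    "coverage_fraction",
    "call_retention",
    "classify_intron_type",
    "compute_psi",
    "bin_introns",
    "quantify_sample",
    "quantify_cell_types",
    "RETAINED_IRRATIO_MIN",
    "RETAINED_DEPTH_MIN",
    "RETAINED_COVERAGE_MIN",
    "NON_RETAINED_IRRATIO_MAX",
    "PSI_INCLUDED_MIN",
    "HOST_FPKM_MIN",
    "MAX_INTRON_LENGTH",
    "TRIM_FRACTION",
]

RETAINED_IRRATIO_MIN = 0.1
RETAINED_DEPTH_MIN = 10.0
RETAINED_COVERAGE_MIN = 0.9
NON_RETAINED_IRRATIO_MAX = 0.01
PSI_INCLUDED_MIN = 0.9
HOST_FPKM_MIN = 1.0
MAX_INTRON_LENGTH = 10_000
TRIM_FRACTION = 0.3


@dataclass(frozen=True)
class IntronRecord:
    """An annotated intron with its flanking-exon context (0-based half-open)."""

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exon5_id: str
    exon3_id: str
    exon5_constitutive: bool
    exon3_constitutive: bool
    exon5_spliced_in: bool
    exon3_spliced_in: bool
    overlaps_known_exon: bool
    intron_type: str = "excluded"
    #: [start, end) of the flanking exons in genomic coordinates
    exon5_interval: tuple[int, int] = (0, 0)
    exon3_interval: tuple[int, int] = (0, 0)

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.intron_id}: end must exceed start")


@dataclass(frozen=True)
class IRMeasurement:
    intron_id: str
    sample: str
    intronic_abundance: float
    exonic_abundance: float
    irratio: float
    intron_depth: float
    coverage_fraction: float
    retention_call: Literal["retained", "non_retained", "ambiguous"] = "ambiguous"


@dataclass(frozen=True)
class PsiValue:
    exon_id: str
    sample: str
    psi: float | None  # None when no informative junctions exist

    @property
    def included(self) -> bool:
        return self.psi is not None and self.psi >= PSI_INCLUDED_MIN


# ---------------------------------------------------------------------------
# Annotation -> introns
# ---------------------------------------------------------------------------

def extract_introns(annotation: pd.DataFrame) -> list[IntronRecord]:
    """Introns = regions between consecutive exons of any transcript.

    Duplicate introns shared by several transcripts are merged.  A flanking
    exon is *constitutive* when an exon with identical coordinates appears in
    every transcript of the gene, *alternative* otherwise; it is *spliced-in*
    when it appears in at least one transcript (always true here by
    construction).  ``overlaps_known_exon`` flags any annotated exon of any
    transcript overlapping the intron interior.
    """
    exons = annotation[annotation["Feature"] == "exon"].copy()
    if not len(exons):
        return []
    exons = exons.sort_values(["gene_id", "transcript_id", "Start"])

    n_tx = exons.groupby("gene_id")["transcript_id"].nunique()
    exon_tx_count = (exons.drop_duplicates(["transcript_id", "Start", "End"])
                     .groupby(["gene_id", "Start", "End"])["transcript_id"].nunique())

    records: dict[str, dict] = {}
    for (gid, tid), tx in exons.groupby(["gene_id", "transcript_id"], sort=False):
        tx = tx.sort_values("Start")
        rows = list(tx.itertuples())
        for a, b in zip(rows[:-1], rows[1:]):
            start, end = int(a.End), int(b.Start)
            if end <= start:
                raise InputIntegrityError(
                    f"overlapping exons in transcript {tid} around {start}")
            strand = str(a.Strand)
            iid = f"{a.Chromosome}:{start}-{end}:{strand}"
            if strand == "+":
                up, down = a, b  # upstream exon donates the 5' splice site
            else:
                up, down = b, a
            const_up = exon_tx_count.loc[(gid, int(up.Start), int(up.End))] == n_tx.loc[gid]
            const_down = exon_tx_count.loc[(gid, int(down.Start), int(down.End))] == n_tx.loc[gid]
            rec = dict(
                intron_id=iid, chrom=str(a.Chromosome), start=start, end=end,
                strand=strand, gene_id=gid,
                exon5_id=f"{gid}:{int(up.Start)}-{int(up.End)}",
                exon3_id=f"{gid}:{int(down.Start)}-{int(down.End)}",
                exon5_constitutive=bool(const_up), exon3_constitutive=bool(const_down),
                exon5_spliced_in=True, exon3_spliced_in=True,
                exon5_interval=(int(up.Start), int(up.End)),
                exon3_interval=(int(down.Start), int(down.End)),
            )
            records.setdefault(iid, rec)

    ex_arr = exons.drop_duplicates(["Chromosome", "Start", "End"])
    result = []
    for rec in records.values():
        sub = ex_arr[(ex_arr["Chromosome"] == rec["chrom"])
                     & (ex_arr["Start"] < rec["end"])
                     & (ex_arr["End"] > rec["start"])]
        rec["overlaps_known_exon"] = bool(len(sub))
        result.append(classify_intron_type(IntronRecord(**rec)))
    return sorted(result, key=lambda r: (r.chrom, r.start, r.end))


def classify_intron_type(intron: IntronRecord) -> IntronRecord:
    """Assign Type A/B/C per the flanking-exon classification table.

    A: <10 kb, both flanks spliced-in and constitutive, no overlapping exon.
    B: as A but *with* a known overlapping exon.
    C: <10 kb, both flanks spliced-in, no overlapping exon, but a 5' or 3'
       flank of alternative type.  Everything else is excluded; the 10 kb
       length cap applies to all types.
    """
    t = "excluded"
    if intron.length < MAX_INTRON_LENGTH and intron.exon5_spliced_in and intron.exon3_spliced_in:
        both_const = intron.exon5_constitutive and intron.exon3_constitutive
        if both_const and not intron.overlaps_known_exon:
            t = "A"
        elif both_const and intron.overlaps_known_exon:
            t = "B"
        elif not intron.overlaps_known_exon:
            t = "C"
    import dataclasses

    return dataclasses.replace(intron, intron_type=t)


def exon_mask(intron: IntronRecord, annotation: pd.DataFrame) -> np.ndarray:
    """Boolean mask over the intron: True where an annotated exon overlaps."""
    mask = np.zeros(intron.length, dtype=bool)
    exons = annotation[(annotation["Feature"] == "exon")
                       & (annotation["Chromosome"] == intron.chrom)
                       & (annotation["Start"] < intron.end)
                       & (annotation["End"] > intron.start)]
    for ex in exons.itertuples():
        a = max(int(ex.Start), intron.start) - intron.start
        b = min(int(ex.End), intron.end) - intron.start
        mask[a:b] = True
    return mask


# ---------------------------------------------------------------------------
# Core per-intron arithmetic
# ---------------------------------------------------------------------------

def _apply_mask(depths, mask) -> np.ndarray:
    d = np.asarray(depths, dtype=float)
    if mask is None:
        return d
    if isinstance(mask, np.ndarray) and mask.dtype == bool:
        return d[~mask]
    keep = np.ones(len(d), dtype=bool)
    keep[list(mask)] = False
    return d[keep]


def trimmed_intronic_abundance(per_base_depths, mask=None,
                               trim: float = TRIM_FRACTION) -> float:
    """Mean depth after dropping the lowest and highest ``floor(trim*n)`` bases.

    ``mask`` marks positions to exclude beforehand (overlapping annotated
    features); it may be a set of indices or a boolean array.
    """
    d = _apply_mask(per_base_depths, mask)
    if d.size == 0:
        raise EmptyMeasurementError("no unmasked positions in intron")
    if np.any(d < 0):
        raise DomainError("negative depth")
    k = math.floor(trim * d.size)
    d = np.sort(d, kind="stable")
    if d.size - 2 * k <= 0:  # cannot happen for trim < 0.5, kept for safety
        return float(np.median(d))
    core = d[k : d.size - k]
    # fsum: correctly-rounded sum, independent of accumulation order
    return math.fsum(core) / core.size


def exonic_abundance(junctions: pd.DataFrame, intron: IntronRecord,
                     sample: str) -> int:
    """Reads across the intron's own junction (strand-aware exact match)."""
    sub = junctions[(junctions["chrom"] == intron.chrom)
                    & (junctions["donor"] == intron.start)
                    & (junctions["acceptor"] == intron.end)
                    & (junctions["strand"] == intron.strand)
                    & (junctions["sample"] == sample)]
    if len(sub) > 1:
        raise InputIntegrityError(
            f"duplicate junction records for {intron.intron_id} in {sample}")
    return int(sub["count"].iloc[0]) if len(sub) else 0


def compute_irratio(intronic: float, exonic: float) -> float:
    """intronic / (intronic + exonic); defined as 0 when both are 0."""
    if intronic < 0 or exonic < 0:
        raise DomainError("abundances must be non-negative")
    denom = intronic + exonic
    return 0.0 if denom == 0 else intronic / denom


def coverage_fraction(per_base_depths, mask=None) -> float:
    """Fraction of unmasked intronic bases with depth > 0."""
    d = _apply_mask(per_base_depths, mask)
    if d.size == 0:
        raise EmptyMeasurementError("no unmasked positions in intron")
    return float((d > 0).mean())


def call_retention(m: IRMeasurement, psi5: PsiValue | None, psi3: PsiValue | None,
                   host_fpkm: float, intron_length: int) -> str:
    """Three-way retention call under the study's filter cascade."""
    if host_fpkm < HOST_FPKM_MIN or intron_length >= MAX_INTRON_LENGTH:
        return "ambiguous"
    if (m.irratio >= RETAINED_IRRATIO_MIN
            and m.intron_depth >= RETAINED_DEPTH_MIN
            and m.coverage_fraction >= RETAINED_COVERAGE_MIN
            and psi5 is not None and psi5.psi is not None and psi5.psi >= PSI_INCLUDED_MIN
            and psi3 is not None and psi3.psi is not None and psi3.psi >= PSI_INCLUDED_MIN):
        return "retained"
    if m.irratio <= NON_RETAINED_IRRATIO_MAX and m.intron_depth < RETAINED_DEPTH_MIN:
        return "non_retained"
    return "ambiguous"


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(exon_interval: tuple[int, int], chrom: str, strand: str,
                junctions: pd.DataFrame, sample: str,
                form: str = "mean") -> float | None:
    """Percent-spliced-in of one exon from junction support.

    Inclusion evidence I: junctions ending at the exon's start (acceptor
    side) and junctions starting at its end (donor side), combined by mean
    (default) or min.  Exclusion evidence E: junctions that span the exon
    entirely.  Returns None when I + E carries no reads.
    """
    start, end = exon_interval
    sub = junctions[(junctions["chrom"] == chrom)
                    & (junctions["strand"] == strand)
                    & (junctions["sample"] == sample)]
    inc = []
    left = sub[sub["acceptor"] == start]["count"].sum()
    right = sub[sub["donor"] == end]["count"].sum()
    # only count the sides that have junction support structures at all
    if len(sub[sub["acceptor"] == start]) > 0:
        inc.append(left)
    if len(sub[sub["donor"] == end]) > 0:
        inc.append(right)
    if not inc:
        i_val = 0.0
    elif form == "min":
        i_val = float(min(inc))
    else:
        i_val = float(np.mean(inc))
    e_val = float(sub[(sub["donor"] <= start) & (sub["acceptor"] >= end)
                      & ~((sub["donor"] == start) | (sub["acceptor"] == end))
                      ]["count"].sum())
    if i_val + e_val == 0:
        return None
    return i_val / (i_val + e_val)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_introns(lengths: pd.Series | Iterable[int],
                fpkm: pd.Series | Iterable[float]) -> pd.DataFrame:
    """Length bins (<100 / 100-500 / >500 nt) and FPKM bins (1-25 / 25-75 / >=75).

    Hosts below FPKM 1 get the ``excluded`` expression label.  The printed
    length boundaries are taken edge-inclusive on the medium bin: 100 and 500
    are both *medium*.
    """
    lengths = pd.Series(list(lengths))
    fpkm = pd.Series(list(fpkm), dtype=float)
    length_bin = pd.Series(
        np.select([lengths < 100, lengths <= 500], ["short", "medium"], "long"),
        index=lengths.index,
    )
    expr_bin = pd.Series(
        np.select([fpkm < 1, fpkm < 25, fpkm < 75],
                  ["excluded", "low", "medium"], "high"),
        index=fpkm.index,
    )
    return pd.DataFrame({"length_bin": length_bin, "expression_bin": expr_bin})


# ---------------------------------------------------------------------------
# Per-sample / per-cell-type quantification drivers
# ---------------------------------------------------------------------------

def _mean_fpkm(expression: pd.DataFrame, gene: str, samples: list[str]) -> float:
    sub = expression[(expression["gene"] == gene)
                     & (expression["sample"].isin(samples))]
    return float(sub["fpkm"].mean()) if len(sub) else 0.0


def quantify_sample(introns: list[IntronRecord], annotation: pd.DataFrame,
                    coverage: pd.DataFrame, junctions: pd.DataFrame,
                    expression: pd.DataFrame, sample: str,
                    chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """IR table (one row per intron) for a single sample/pooled cell type.

    ``coverage`` may be the pooled (summed) bedGraph of several replicates,
    with ``junctions`` filtered/aggregated to a matching pseudo-sample.
    """
    depth_by_chrom = {
        c: iio.depth_array(coverage, c, chrom_lengths[c]) for c in chrom_lengths
    }
    rows = []
    for intr in introns:
        depths = depth_by_chrom[intr.chrom][intr.start:intr.end]
        mask = exon_mask(intr, annotation)
        if mask.all():
            continue  # nothing measurable under the intron
        intronic = trimmed_intronic_abundance(depths, mask)
        exonic = exonic_abundance(junctions, intr, sample)
        irr = compute_irratio(intronic, float(exonic))
        covf = coverage_fraction(depths, mask)
        m = IRMeasurement(intr.intron_id, sample, intronic, float(exonic),
                          irr, intronic, covf)
        psi5 = PsiValue(intr.exon5_id, sample,
                        compute_psi(intr.exon5_interval, intr.chrom, intr.strand,
                                    junctions, sample))
        psi3 = PsiValue(intr.exon3_id, sample,
                        compute_psi(intr.exon3_interval, intr.chrom, intr.strand,
                                    junctions, sample))
        fpkm = _mean_fpkm(expression, intr.gene_id, [sample])
        call = call_retention(m, psi5, psi3, fpkm, intr.length)
        rows.append(dict(intron_id=intr.intron_id, sample=sample,
                         gene_id=intr.gene_id, intron_type=intr.intron_type,
                         length=intr.length,
                         intronic_abundance=round(intronic, 4),
                         exonic_abundance=exonic, irratio=round(irr, 6),
                         intron_depth=round(intronic, 4),
                         coverage_fraction=round(covf, 6),
                         psi5=None if psi5.psi is None else round(psi5.psi, 6),
                         psi3=None if psi3.psi is None else round(psi3.psi, 6),
                         host_fpkm=round(fpkm, 3), retention_call=call))
    return pd.DataFrame(rows)


def pool_coverage(bedgraphs: list[pd.DataFrame],
                  chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Sum per-base coverage of replicate samples into one bedGraph."""
    frames = []
    for chrom, length in chrom_lengths.items():
        total = np.zeros(length)
        for bg in bedgraphs:
            total += iio.depth_array(bg, chrom, length)
        frames.append(iio.bedgraph_from_array(total, chrom))
    return pd.concat(frames, ignore_index=True)


def quantify_cell_types(introns: list[IntronRecord], annotation: pd.DataFrame,
                        coverage_by_sample: Mapping[str, pd.DataFrame],
                        junctions: pd.DataFrame, expression: pd.DataFrame,
                        sample_to_cell_type: Mapping[str, str],
                        chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Replicate-pooled IR tables, one row per intron x cell type.

    Replicates of one cell type are amalgamated by summing coverage and
    junction counts before quantification, so the macrophage-like
    single-replicate design and replicated designs flow through one code path.
    """
    tables = []
    by_ct: dict[str, list[str]] = {}
    for sample, ct in sample_to_cell_type.items():
        by_ct.setdefault(ct, []).append(sample)
    for ct, samples in by_ct.items():
        pooled_cov = pool_coverage([coverage_by_sample[s] for s in samples],
                                   chrom_lengths)
        jsub = junctions[junctions["sample"].isin(samples)]
        pooled_j = (jsub.groupby(["chrom", "donor", "acceptor", "strand"],
                                 as_index=False)["count"].sum())
        pooled_j["sample"] = ct
        expr = expression[expression["sample"].isin(samples)].copy()
        expr["sample"] = ct
        expr = expr.groupby(["gene", "sample"], as_index=False)["fpkm"].mean()
        tab = quantify_sample(introns, annotation, pooled_cov, pooled_j,
                              expr, ct, chrom_lengths)
        tab = tab.rename(columns={"sample": "cell_type"})
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
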