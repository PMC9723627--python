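"""Per-intron feature assembly over three 200-bp windows.

Each intron contributes three strand-oriented regions — ±100 bp around the 5'
splice site, ±100 bp around the 3' splice site, and ±100 bp around the intron
midpoint — from which sequence features (GC content, CpG density), epigenetic
features (mean CpG/GCH methylation, NFR and nucleosome presence, a 0/1/2
histone-mark code per mark) and intron-level intrinsic features (length,
splice-site strength from a log-odds position weight matrix, branch-point
strength and distance) are extracted, together with the flanking-exon PSI
values.  The ordered feature registry (43 features by default) is versioned
by a content hash recorded in the output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .irquant import IntronRecord
from .nome import region_methylation

__all__ = [
    "RegionTriplet",
    "define_regions",
    "gc_content",
    "cpg_density",
    "PwmScorer",
    "donor_window",
    "acceptor_window",
    "build_donor_pwm",
    "build_acceptor_pwm",
    "branch_point_features",
    "hm_overlap_code",
    "presence_flags",
    "feature_registry",
    "registry_hash",
    "assemble_features",
    "HISTONE_MARKS",
    "REGION_NAMES",
]

HISTONE_MARKS = ("H3K9me3", "H3K27me3", "H3K27ac", "H3K36me3", "H3K4me1", "H3K4me3")
REGION_NAMES = ("ss5", "ss3", "mid")
WINDOW_HALF = 100
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DONOR_EXONIC = 3    # MaxEnt-compatible window conventions
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3

BRANCH_WINDOW = (15, 100)  # scan range upstream of the 3' splice site
#: log-odds branch-point heptamer matrix (consensus TACTAAC, branch A at
#: position 6 of 7); rows A/C/G/T.  A compact default, replaceable by any
#: externally estimated matrix of the same shape.
_BP_CONSENSUS = "TACTAAC"
_BRANCH_A_POS = 5


@dataclass(frozen=True)
class RegionTriplet:
    """Three 200-bp windows, strand-oriented (5'/3' follow transcription)."""

    ss5: tuple[int, int]
    ss3: tuple[int, int]
    mid: tuple[int, int]
    clipped: bool = False

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"ss5": self.ss5, "ss3": self.ss3, "mid": self.mid}


def define_regions(intron: IntronRecord, contig_length: int | None = None) -> RegionTriplet:
    """Windows centred on the donor site, acceptor site and floor midpoint.

    For minus-strand introns the donor (5' splice site) is the genomic *end*
    of the intron, so the ss5/ss3 labels swap genomic sides.  Windows
    truncated by a contig edge are flagged ``clipped``.
    """
    if intron.strand == "+":
        donor, acceptor = intron.start, intron.end
    else:
        donor, acceptor = intron.end, intron.start
    mid = (intron.start + intron.end) // 2
    windows = {}
    clipped = False
    for name, centre in (("ss5", donor), ("ss3", acceptor), ("mid", mid)):
        a, b = centre - WINDOW_HALF, centre + WINDOW_HALF
        if a < 0 or (contig_length is not None and b > contig_length):
            clipped = True
            a = max(a, 0)
            if contig_length is not None:
                b = min(b, contig_length)
        windows[name] = (a, b)
    return RegionTriplet(windows["ss5"], windows["ss3"], windows["mid"], clipped)


# ---------------------------------------------------------------------------
# Sequence features
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float | None:
    """(G+C) / counted bases, case-insensitive; ambiguous bases excluded.

    Returns None for an all-ambiguous window.
    """
    s = seq.upper()
    counted = sum(s.count(b) for b in "ACGT")
    if counted == 0:
        return None
    return (s.count("G") + s.count("C")) / counted


def cpg_density(seq: str) -> float:
    """CG dinucleotides per 100 bp of window (overlap-free scan)."""
    s = seq.upper()
    if not s:
        return 0.0
    count = 0
    i = 0
    while i < len(s) - 1:
        if s[i] == "C" and s[i + 1] == "G":
            count += 1
            i += 2
        else:
            i += 1
    return 100.0 * count / len(s)


# ---------------------------------------------------------------------------
# Splice-site strength (pluggable PWM scorer)
# ---------------------------------------------------------------------------

class PwmScorer:
    """Log2-odds position weight matrix scorer.

    ``matrix`` has shape (positions, 4) of log2(p_pos(base)/q(base)) weights
    in A/C/G/T order.  External score tables (e.g. maximum-entropy model
    exports) plug in through the same shape.
    """

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must have shape (positions, 4)")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score(self, seq: str) -> float | None:
        """Sum of per-position log-odds; None if the window contains N."""
        s = seq.upper()
        if len(s) != self.width:
            raise ValueError(f"expected {self.width}-mer, got {len(s)}-mer")
        total = 0.0
        for k, b in enumerate(s):
            if b not in _BASE_INDEX:
                return None
            total += self.matrix[k, _BASE_INDEX[b]]
        return float(total)

    @classmethod
    def from_sites(cls, sites: list[str], background: np.ndarray | None = None,
                   pseudocount: float = 0.5) -> "PwmScorer":
        """Estimate log2-odds weights from aligned site sequences."""
        if not sites:
            raise ValueError("no sites to estimate the PWM from")
        width = len(sites[0])
        counts = np.full((width, 4), pseudocount)
        for s in sites:
            for k, b in enumerate(s.upper()):
                if b in _BASE_INDEX:
                    counts[k, _BASE_INDEX[b]] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(np.log2(probs / background))


def _fetch(sequences, chrom: str, a: int, b: int) -> str:
    seq = sequences[chrom]
    if a < 0 or b > len(seq):
        return ""
    return str(seq[a:b]).upper()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def donor_window(intron: IntronRecord, sequences) -> str:
    """9-mer: 3 exonic + 6 intronic bases at the 5' splice site."""
    if intron.strand == "+":
        s = _fetch(sequences, intron.chrom, intron.start - DONOR_EXONIC,
                   intron.start + DONOR_INTRONIC)
        return s
    s = _fetch(sequences, intron.chrom, intron.end - DONOR_INTRONIC,
               intron.end + DONOR_EXONIC)
    return _revcomp(s)


def acceptor_window(intron: IntronRecord, sequences) -> str:
    """23-mer: 20 intronic + 3 exonic bases at the 3' splice site."""
    if intron.strand == "+":
        s = _fetch(sequences, intron.chrom, intron.end - ACCEPTOR_INTRONIC,
                   intron.end + ACCEPTOR_EXONIC)
        return s
    s = _fetch(sequences, intron.chrom, intron.start - ACCEPTOR_EXONIC,
               intron.start + ACCEPTOR_INTRONIC)
    return _revcomp(s)


def build_donor_pwm(introns: list[IntronRecord], sequences) -> PwmScorer:
    """Donor PWM estimated from the annotation's constitutive splice sites."""
    sites = [donor_window(i, sequences) for i in introns
             if i.exon5_constitutive and i.exon3_constitutive]
    sites = [s for s in sites if len(s) == DONOR_EXONIC + DONOR_INTRONIC
             and "N" not in s]
    return PwmScorer.from_sites(sites, _background_composition(sequences))


def build_acceptor_pwm(introns: list[IntronRecord], sequences) -> PwmScorer:
    sites = [acceptor_window(i, sequences) for i in introns
             if i.exon5_constitutive and i.exon3_constitutive]
    sites = [s for s in sites if len(s) == ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC
             and "N" not in s]
    return PwmScorer.from_sites(sites, _background_composition(sequences))


def _background_composition(sequences) -> np.ndarray:
    counts = np.zeros(4)
    for chrom in list(sequences.keys() if hasattr(sequences, "keys") else sequences):
        s = str(sequences[chrom]).upper()
        for b, k in _BASE_INDEX.items():
            counts[k] += s.count(b)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


# ---------------------------------------------------------------------------
# Branch point
# ---------------------------------------------------------------------------

def default_branch_pwm() -> PwmScorer:
    """Heptamer log-odds matrix from the TACTAAC-like consensus (0.7/0.1 mix)."""
    probs = np.full((len(_BP_CONSENSUS), 4), 0.1)
    for k, b in enumerate(_BP_CONSENSUS):
        probs[k, _BASE_INDEX[b]] = 0.7
    return PwmScorer(np.log2(probs / 0.25))


def branch_point_features(intron: IntronRecord, sequences,
                          pwm: PwmScorer | None = None
                          ) -> tuple[float | None, int | None]:
    """Best branch-point score and its distance to the 3' splice site.

    Scans heptamer positions whose 3' end lies 15-100 bp upstream of the 3'
    splice site, requires an A at the branch position, and on ties reports
    the candidate closest to the 3' splice site.  Returns (None, None) when
    less than 100 bp of intron is available or no A-containing candidate
    exists.
    """
    pwm = pwm or default_branch_pwm()
    w = pwm.width
    lo, hi = BRANCH_WINDOW
    if intron.length < hi:
        return None, None
    if intron.strand == "+":
        intron_seq = _fetch(sequences, intron.chrom, intron.start, intron.end)
    else:
        intron_seq = _revcomp(_fetch(sequences, intron.chrom, intron.start,
                                     intron.end))
    L = len(intron_seq)
    best: tuple[float, int] | None = None
    # distance d = bases between the heptamer's 3' end and the 3' splice site
    for d in range(lo, hi + 1):
        end = L - d
        start = end - w
        if start < 0:
            break
        hept = intron_seq[start:end]
        if len(hept) < w or hept[_BRANCH_A_POS] != "A":
            continue
        score = pwm.score(hept)
        if score is None:
            continue
        if best is None or score > best[0]:  # strict >, so first (closest) wins ties
            best = (score, d)
    if best is None:
        return None, None
    return best


# ---------------------------------------------------------------------------
# Epigenetic overlap features
# ---------------------------------------------------------------------------

def peak_signal_stats(peaks: pd.DataFrame, pileup: pd.DataFrame,
                      chrom_lengths) -> tuple[float, float, np.ndarray]:
    """Mean and SD of summit pile-up over all peaks of one track.

    Returns (mean, sd, summit_values); peaks without pileup get NaN and are
    excluded from the statistics.
    """
    from . import io as iio

    values = np.full(len(peaks), np.nan)
    by_chrom = {}
    for i, pk in enumerate(peaks.itertuples()):
        if pk.chrom not in by_chrom:
            by_chrom[pk.chrom] = iio.depth_array(pileup, pk.chrom,
                                                 chrom_lengths[pk.chrom])
        summit = int(pk.start) + int(pk.summit)
        arr = by_chrom[pk.chrom]
        if 0 <= summit < len(arr):
            values[i] = arr[summit]
    ok = ~np.isnan(values)
    if not ok.any():
        return 0.0, 0.0, values
    return float(values[ok].mean()), float(values[ok].std()), values


def hm_overlap_code(window: tuple[int, int], chrom: str, peaks: pd.DataFrame,
                    summit_values: np.ndarray, strong_threshold: float) -> int:
    """0 = no peak overlap; 1 = peak below mean+SD; 2 = peak at/above mean+SD."""
    a, b = window
    sel = (peaks["chrom"] == chrom) & (peaks["start"] < b) & (peaks["end"] > a)
    idx = np.flatnonzero(sel.to_numpy())
    if len(idx) == 0:
        return 0
    vals = summit_values[idx]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return 1  # peak present but pile-up missing
    return 2 if float(vals.max()) >= strong_threshold else 1


def presence_flags(window: tuple[int, int], calls) -> tuple[int, int]:
    """(NFR, nucleosome) 0/1 flags for >=1 bp overlap (half-open intervals)."""
    a, b = window
    nfr = nuc = 0
    for c in calls:
        if c.start < b and c.end > a:
            if c.kind == "NFR":
                nfr = 1
            else:
                nuc = 1
    return nfr, nuc


# ---------------------------------------------------------------------------
# Registry and assembly
# ---------------------------------------------------------------------------

def feature_registry() -> list[str]:
    """Ordered feature names (43 by default).

    Intrinsic: intron length (log10), donor/acceptor splice-site strength,
    branch-point strength and distance, per-region GC and CpG density.
    Transcriptomic: PSI of the flanking exons.  Epigenetic, per region:
    mean CpG and GCH methylation, NFR and nucleosome presence, and one 0/1/2
    code per histone mark.
    """
    names = ["intron_length_log10", "ss5_strength", "ss3_strength",
             "branch_point_strength", "branch_point_distance"]
    names += [f"gc_{r}" for r in REGION_NAMES]
    names += [f"cpg_density_{r}" for r in REGION_NAMES]
    names += ["psi5", "psi3"]
    for r in REGION_NAMES:
        names += [f"cpg_meth_{r}", f"gch_meth_{r}", f"nfr_{r}", f"nucleosome_{r}"]
        names += [f"{mark}_{r}" for mark in HISTONE_MARKS]
    return names


def registry_hash(names: list[str] | None = None) -> str:
    names = names if names is not None else feature_registry()
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:12]


def feature_schema() -> dict:
    """JSON-serializable schema of the default registry: per-feature type
    and admissible range, plus the registry hash."""
    schema: dict = {"registry_hash": registry_hash(), "features": {}}
    for name in feature_registry():
        if name.startswith(("nfr_", "nucleosome_")):
            spec = {"type": "binary", "values": [0, 1]}
        elif any(name.startswith(m) for m in HISTONE_MARKS):
            spec = {"type": "ordinal", "values": [0, 1, 2]}
        elif name.startswith(("gc_", "cpg_meth_", "gch_meth_", "psi")):
            spec = {"type": "fraction", "range": [0, 1]}
        elif name == "branch_point_distance":
            spec = {"type": "integer", "range": [BRANCH_WINDOW[0],
                                                 BRANCH_WINDOW[1]]}
        elif name.startswith("cpg_density"):
            spec = {"type": "real", "range": [0, 100]}
        else:
            spec = {"type": "real"}
        schema["features"][name] = spec
    return schema


def assemble_features(intron: IntronRecord, label: str, sequences,
                      cpg_calls: pd.DataFrame, gch_calls: pd.DataFrame,
                      chromatin_calls, peaks_by_mark, stats_by_mark,
                      psi5: float | None, psi3: float | None,
                      donor_pwm: PwmScorer, acceptor_pwm: PwmScorer,
                      contig_length: int | None = None) -> dict | None:
    """One registry-ordered feature row for an intron in one cell type.

    Returns None (row dropped) when any intrinsic feature is missing —
    absence of sequence is not informative — while missing epigenetic
    features impute to 0/absent, which is.
    """
    regions = define_regions(intron, contig_length)
    row: dict = {"intron_id": intron.intron_id, "label": label}

    row["intron_length_log10"] = float(np.log10(intron.length))
    row["ss5_strength"] = donor_pwm.score(donor_window(intron, sequences)) \
        if len(donor_window(intron, sequences)) == donor_pwm.width else None
    row["ss3_strength"] = acceptor_pwm.score(acceptor_window(intron, sequences)) \
        if len(acceptor_window(intron, sequences)) == acceptor_pwm.width else None
    bp_score, bp_dist = branch_point_features(intron, sequences)
    row["branch_point_strength"] = bp_score
    row["branch_point_distance"] = bp_dist

    for name, (a, b) in regions.as_dict().items():
        seq = _fetch(sequences, intron.chrom, a, b)
        row[f"gc_{name}"] = gc_content(seq) if seq else None
        row[f"cpg_density_{name}"] = cpg_density(seq) if seq else None

    row["psi5"], row["psi3"] = psi5, psi3

    intrinsic = ["intron_length_log10", "ss5_strength", "ss3_strength",
                 "branch_point_strength", "branch_point_distance",
                 "gc_ss5", "gc_ss3", "gc_mid",
                 "cpg_density_ss5", "cpg_density_ss3", "cpg_density_mid",
                 "psi5", "psi3"]
    if any(row[k] is None for k in intrinsic):
        return None

    for name, window in regions.as_dict().items():
        cm = region_methylation(window, cpg_calls)
        gm = region_methylation(window, gch_calls)
        row[f"cpg_meth_{name}"] = 0.0 if cm is None else cm
        row[f"gch_meth_{name}"] = 0.0 if gm is None else gm
        nfr, nuc = presence_flags(window, chromatin_calls)
        row[f"nfr_{name}"] = nfr
        row[f"nucleosome_{name}"] = nuc
        for mark in HISTONE_MARKS:
            peaks = peaks_by_mark.get(mark)
            if peaks is None or not len(peaks):
                row[f"{mark}_{name}"] = 0
                continue
            summit_values, threshold = stats_by_mark[mark]
            row[f"{mark}_{name}"] = hm_overlap_code(window, intron.chrom,
                                                    peaks, summit_values,
                                                    threshold)
    return row


def validate_feature_table(table: pd.DataFrame) -> None:
    """Schema check: known columns, flags in {0,1}, codes in {0,1,2},
    fractions in [0,1].  Raises ValueError on the first violation."""
    for r in REGION_NAMES:
        for col, allowed in ((f"nfr_{r}", {0, 1}), (f"nucleosome_{r}", {0, 1})):
            bad = set(table[col].unique()) - allowed
            if bad:
                raise ValueError(f"{col} outside {allowed}: {bad}")
        for mark in HISTONE_MARKS:
            bad = set(table[f"{mark}_{r}"].unique()) - {0, 1, 2}
            if bad:
                raise ValueError(f"{mark}_{r} outside 0/1/2: {bad}")
        for col in (f"gc_{r}", f"cpg_meth_{r}", f"gch_meth_{r}"):
            v = table[col].to_numpy(float)
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError(f"{col} outside [0,1]")
    for col in ("psi5", "psi3"):
        v = table[col].to_numpy(float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError(f"{col} outside [0,1]")
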