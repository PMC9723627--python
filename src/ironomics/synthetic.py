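"""Synthetic multi-omics data with planted intron-retention structure.

The generator emulates the data layers of a NOMe-seq / WGBS / ChIP-seq /
mRNA-seq study of intron retention (IR) in a small panel of cell types:

* a genome (FASTA) and gene annotation (GTF) whose introns carry controlled
  intrinsic features (length, GC content, splice-site strength, branch point);
* per-sample read coverage (bedGraph), splice-junction counts and FPKM tables
  whose intronic/junction read depths encode a chosen true IRratio per intron
  and cell type;
* CpG and GCH cytosine reports in which accessible chromatin (planted
  nucleosome-free regions near the 5' splice sites of retained introns) shows
  elevated GCH methylation;
* histone-mark pileups and narrowPeak calls, with H3K36me3 depleted over
  retained introns that sit in dynamic chromatin.

Retention is *planted through a logistic score* over the intrinsic features
(`SimulationConfig.effect_weights`), so retained introns come out shorter,
GC-richer and with weaker splice sites — the couplings the downstream models
are expected to rediscover.  Ground truth (states, true IRratios, NFR
intervals, GCH profile archetypes) is returned alongside the files so every
pipeline stage can be scored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iio
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_transcriptome",
    "simulate_methylomes",
    "simulate_chip",
    "simulate_all",
    "archetype_level",
    "gch_site_positions",
    "cpg_site_positions",
    "sample_negative_binomial",
    "simulate_methylation_calls",
    "ARCHETYPE_NAMES",
]

BASES = np.array(list("ACGT"))
DONOR_EXON = "CAG"        # last 3 exonic bases at the 5' splice site
DONOR_INTRON = "GTAAGT"   # first 6 intronic bases (GT invariant)
ACCEPTOR_END = "AG"       # last 2 intronic bases (invariant)
BRANCH_CONSENSUS = "TACTAAC"  # heptamer planted upstream of the 3' splice site
HISTONE_MARKS = ("H3K9me3", "H3K27me3", "H3K27ac", "H3K36me3", "H3K4me1", "H3K4me3")

#: Five GCH-accessibility archetypes around the 5' splice site of
#: NFR-coupled retained introns (step functions over +/-200 bp, transcription
#: oriented; negative offsets are upstream of the donor).
ARCHETYPE_NAMES = {
    1: "nfr_upstream",
    2: "weak_accessibility",
    3: "nfr_downstream",
    4: "nfr_both_flanks",
    5: "strong_accessibility",
}


def _complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))


def revcomp(seq: str) -> str:
    return _complement(seq)[::-1]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic study.

    Defaults describe the study conditions exercised throughout the test
    suite: five immune-like cell types (two replicates each except the
    macrophage-like ``Ma`` with one), ~35% retained introns of which a
    quarter switch state between cell types, accessible chromatin at 35%
    GCH methylation against an 8% background, and mean exonic read depth 50.
    """

    n_genes: int = 150
    introns_per_gene: int = 4
    cell_types: Sequence[str] = ("Mo", "Ma", "TN", "CM", "EM")
    replicates: Mapping[str, int] | None = None  # default: 2 each, "Ma" -> 1
    fraction_retained: float = 0.35
    #: fraction of *retained* introns that are dynamic (state switches
    #: between cell types); the remainder are retained in every cell type.
    fraction_dynamic: float = 0.25
    effect_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "log_length": -1.2,
            "gc_content": 1.5,
            "ss5_strength": -0.9,
            "ss3_strength": -0.9,
        }
    )
    nfr_coupling_prob: float = 0.7
    gch_meth_nfr: float = 0.35
    gch_meth_background: float = 0.08
    cpg_bimodal_modes: tuple[float, float] = (0.05, 0.95)
    mean_coverage: float = 50.0
    nb_dispersion: float = 0.1
    gch_read_depth: float = 20.0
    cpg_read_depth: float = 20.0
    h3k36me3_depletion: float = 0.5
    #: fraction of fully non-retained genes given a second, alternatively
    #: spliced transcript (exercises Type B/C introns, masking and PSI<1).
    alt_transcript_fraction: float = 0.10
    exon_length_range: tuple[int, int] = (120, 200)
    intron_log_mean: float = 6.0
    intron_log_sd: float = 0.6
    intergenic_gap: int = 400
    retained_ir_range: tuple[float, float] = (0.30, 0.70)
    non_retained_ir_max: float = 0.003
    seed: int = 0

    def __post_init__(self):
        positive = ["n_genes", "introns_per_gene", "mean_coverage",
                    "gch_read_depth", "cpg_read_depth"]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        fractions = ["fraction_retained", "fraction_dynamic", "nfr_coupling_prob",
                     "gch_meth_nfr", "gch_meth_background",
                     "alt_transcript_fraction", "h3k36me3_depletion"]
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for v in self.cpg_bimodal_modes:
            if not (0.0 <= v <= 1.0):
                raise ConfigError("cpg_bimodal_modes must lie in [0, 1]")
        if len(self.cell_types) < 1:
            raise ConfigError("cell_types must be non-empty")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")

    def replicate_map(self) -> dict[str, int]:
        if self.replicates is not None:
            return dict(self.replicates)
        reps = {ct: 2 for ct in self.cell_types}
        if "Ma" in reps:
            reps["Ma"] = 1  # single-replicate design of the macrophage arm
        return reps

    def samples(self) -> list[tuple[str, str]]:
        """(cell_type, sample_name) pairs, e.g. ("Mo", "Mo_r1")."""
        out = []
        for ct in self.cell_types:
            for r in range(self.replicate_map().get(ct, 1)):
                out.append((ct, f"{ct}_r{r + 1}"))
        return out


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    config: SimulationConfig
    #: per gene: gene_id, chrom, start, end, strand, tss, expression_class
    genes: pd.DataFrame
    #: per intron: id, coords, intrinsic features, coupling flags, archetype
    introns: pd.DataFrame
    #: per intron x cell type: state ("retained"/"non_retained"), true_irratio
    states: pd.DataFrame
    #: planted NFR intervals (genomic) for NFR-coupled introns
    nfr_intervals: pd.DataFrame
    annotation: pd.DataFrame
    sequences: dict[str, str]

    def state_matrix(self) -> pd.DataFrame:
        return self.states.pivot(index="intron_id", columns="cell_type",
                                 values="state")

    def dynamic_introns(self) -> set[str]:
        m = self.state_matrix()
        ret = (m == "retained").any(axis=1)
        non = (m == "non_retained").any(axis=1)
        return set(m.index[ret & non])


def intron_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


# ---------------------------------------------------------------------------
# Low-level sampling helpers (reused by tests and benchmarks)
# ---------------------------------------------------------------------------

def sample_negative_binomial(rng: np.random.Generator, mean, dispersion: float,
                             size=None) -> np.ndarray:
    """NB draws parameterised by mean m and dispersion a (var = m + a m^2)."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean must be non-negative")
    n = 1.0 / dispersion
    out = np.zeros(np.broadcast_shapes(mean.shape if mean.shape else (1,),
                                       (size,) if np.isscalar(size) else (size or mean.shape)),
                   dtype=np.int64)
    m = np.broadcast_to(mean, out.shape)
    pos = m > 0
    p = n / (n + m[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def gch_site_positions(seq: np.ndarray) -> np.ndarray:
    """0-based cytosine positions in GCH context, both strands pooled.

    Plus strand: G C H with the methylated C at i (requires seq[i-1]=G,
    seq[i]=C, seq[i+1]!=G).  Minus strand: the mirrored pattern with the
    cytosine at plus-coordinate i (seq[i]=G, seq[i+1]=C, seq[i-1]!=C).
    """
    s = seq
    i = np.arange(1, len(s) - 1)
    plus = (s[i - 1] == "G") & (s[i] == "C") & (s[i + 1] != "G")
    minus = (s[i] == "G") & (s[i + 1] == "C") & (s[i - 1] != "C")
    return np.unique(i[plus | minus])


def cpg_site_positions(seq: np.ndarray) -> np.ndarray:
    """0-based cytosine positions in CpG context, both strands pooled."""
    s = seq
    i = np.arange(0, len(s) - 1)
    plus = (s[i] == "C") & (s[i + 1] == "G")
    j = np.arange(1, len(s))
    minus = (s[j] == "G") & (s[j - 1] == "C")
    return np.unique(np.concatenate([i[plus], j[minus]]))


def archetype_level(archetype: int, offsets: np.ndarray,
                    config: SimulationConfig) -> np.ndarray:
    """GCH methylation level at transcription-oriented offsets from the donor.

    The five archetypes are step functions over the +/-200 bp window; outside
    their accessible segments the level equals the genomic background.
    """
    bg = config.gch_meth_background
    nfr = config.gch_meth_nfr
    lvl = np.full(len(offsets), bg, dtype=float)
    o = offsets
    if archetype == 1:      # NFR upstream of the 5' splice site
        lvl[(o >= -150) & (o < -10)] = nfr
    elif archetype == 2:    # weakly accessible throughout
        lvl[(o >= -200) & (o < 200)] = min(1.0, 1.75 * bg)
    elif archetype == 3:    # NFR downstream, inside the intron
        lvl[(o >= 10) & (o < 150)] = nfr
    elif archetype == 4:    # NFRs on both flanks, protected splice site
        lvl[((o >= -150) & (o < -50)) | ((o >= 50) & (o < 150))] = nfr
    elif archetype == 5:    # strongly accessible across the whole window
        lvl[(o >= -200) & (o < 200)] = min(0.95, 1.8 * nfr)
    else:
        raise ValueError(f"unknown archetype {archetype}")
    return lvl


def archetype_intervals(archetype: int) -> list[tuple[int, int]]:
    """Accessible (NFR) segments of an archetype as donor-relative offsets."""
    return {
        1: [(-150, -10)],
        2: [],
        3: [(10, 150)],
        4: [(-150, -50), (50, 150)],
        5: [(-200, 200)],
    }[archetype]


def simulate_methylation_calls(positions: np.ndarray, levels: np.ndarray,
                               depth: float, rng: np.random.Generator,
                               context: str, chrom: str = "chr1") -> pd.DataFrame:
    """Binomial methylation calls at given sites; zero-coverage sites dropped."""
    cov = rng.poisson(depth, size=len(positions))
    keep = cov > 0
    positions, levels, cov = positions[keep], levels[keep], cov[keep]
    meth = rng.binomial(cov, levels)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions.astype(int),
            "strand": "+",
            "count_methylated": meth.astype(int),
            "count_unmethylated": (cov - meth).astype(int),
            "context": context,
            "tricontext": context,
        }
    )


# ---------------------------------------------------------------------------
# Focused benchmarks (single-layer generators reusing the same primitives)
# ---------------------------------------------------------------------------

def simulate_nfr_benchmark(n_regions: int = 200, region_len: int = 200,
                           level_nfr: float = 0.35, level_bg: float = 0.08,
                           depth: float = 20.0, gap: int = 2000,
                           seed: int = 0, chrom: str = "chr1"):
    """A single GCH track with regularly planted accessible regions.

    Returns (calls DataFrame, planted-interval DataFrame).  Site positions
    come from a random 50%-GC sequence, so GCH density matches the genome
    generator; planted regions sit ``gap`` bp apart so their 4 kb background
    flanks stay predominantly background.
    """
    rng = np.random.default_rng([seed, 71])
    length = n_regions * (region_len + gap) + gap
    seq = _random_seq(rng, length, 0.5)
    pos = gch_site_positions(seq)
    level = np.full(length, level_bg)
    planted = []
    for k in range(n_regions):
        a = gap + k * (region_len + gap)
        level[a : a + region_len] = level_nfr
        planted.append((f"nfr_{k}", chrom, a, a + region_len))
    calls = simulate_methylation_calls(pos, level[pos], depth, rng, "GCH", chrom)
    return calls, pd.DataFrame(planted, columns=["intron_id", "chrom",
                                                 "start", "end"])


def simulate_nucleosome_benchmark(n_regions: int = 30, region_len: int = 147,
                                  level_bg: float = 0.30, depth: float = 20.0,
                                  gap: int = 1200, seed: int = 0,
                                  chrom: str = "chr1"):
    """Fully protected (0% methylated) nucleosome footprints amid background.

    Sites are tiled densely (2-6 bp apart, GpC-island-like) so the 147 bp
    footprint is covered wall-to-wall; the >140 bp length rule leaves no
    margin otherwise.  Returns (calls, planted intervals).
    """
    rng = np.random.default_rng([seed, 83])
    length = n_regions * (region_len + gap) + gap
    pos = np.cumsum(rng.integers(2, 7, size=length // 3))
    pos = pos[pos < length]
    level = np.full(length, level_bg)
    planted = []
    for k in range(n_regions):
        a = gap + k * (region_len + gap)
        level[a : a + region_len] = 0.0
        planted.append((f"nuc_{k}", chrom, a, a + region_len))
    calls = simulate_methylation_calls(pos, level[pos], depth, rng, "GCH", chrom)
    return calls, pd.DataFrame(planted, columns=["intron_id", "chrom",
                                                 "start", "end"])


def simulate_null_methylome(n_sites: int = 5000, level: float = 0.3,
                            depth: float = 20.0, spacing: int = 10,
                            seed: int = 0, chrom: str = "chr1") -> pd.DataFrame:
    """Homogeneous GCH methylome (no structure) for false-positive checks."""
    rng = np.random.default_rng([seed, 73])
    pos = np.cumsum(rng.integers(2, 2 * spacing, size=n_sites))
    levels = np.full(len(pos), level)
    return simulate_methylation_calls(pos, levels, depth, rng, "GCH", chrom)


def simulate_archetype_profiles(n_per_archetype: int = 100, depth: float = 20.0,
                                mean_spacing: int = 5, seed: int = 0,
                                config: SimulationConfig | None = None):
    """Low-noise GCH call tracks for the five accessibility archetypes.

    Each synthetic intron gets its own ±200 bp window of GCH sites (mean
    spacing ~5 bp, i.e. GC-rich splice-site-proximal sequence) with binomial
    calls at the archetype's level.  Returns (anchors, calls, truth labels):
    ``anchors`` are light intron-like objects usable by
    :func:`ironomics.profiles.build_profile_matrix`.
    """
    from types import SimpleNamespace

    config = config or SimulationConfig()
    rng = np.random.default_rng([seed, 79])
    offs = np.arange(-200, 200)
    anchors, frames, labels = [], [], {}
    cursor = 500
    for arch in range(1, 6):
        lv = archetype_level(arch, offs, config)
        for i in range(n_per_archetype):
            centre = cursor
            cursor += 1500
            pos = np.cumsum(rng.integers(2, 2 * mean_spacing, size=400)) - 200
            pos = pos[(pos >= -200) & (pos < 200)]
            calls = simulate_methylation_calls(centre + pos, lv[pos + 200],
                                               depth, rng, "GCH")
            frames.append(calls)
            iid = f"arch{arch}_{i}"
            anchors.append(SimpleNamespace(intron_id=iid, start=centre,
                                           end=centre + 1000, strand="+"))
            labels[iid] = arch
    calls = pd.concat(frames, ignore_index=True).sort_values("pos")
    return anchors, calls.reset_index(drop=True), labels


# ---------------------------------------------------------------------------
# Annotation + genome
# ---------------------------------------------------------------------------

def _blend_motif(rng, consensus: str, strength: float, lock: int = 0) -> str:
    """Consensus bases kept with probability rising in `strength`; the first
    `lock` characters are invariant (canonical GT/AG dinucleotides)."""
    p = 0.40 + 0.55 * strength
    out = []
    for k, b in enumerate(consensus):
        if k < lock or rng.random() < p:
            out.append(b)
        else:
            out.append(str(rng.choice(BASES)))
    return "".join(out)


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def simulate_annotation(config: SimulationConfig):
    """Build genome + annotation and plant retention states.

    Returns a :class:`GroundTruth` holding the GTF rows (0-based internal),
    the chromosome sequences and all planted per-intron structure.
    """
    rng = np.random.default_rng([config.seed, 11])
    n_int = config.n_genes * config.introns_per_gene

    # --- intrinsic features, one row per intron ---------------------------
    lengths = np.maximum(
        80, rng.lognormal(config.intron_log_mean, config.intron_log_sd, n_int)
    ).astype(int)
    gc = rng.uniform(0.35, 0.65, n_int)
    ss5 = rng.uniform(0, 1, n_int)
    ss3 = rng.uniform(0, 1, n_int)
    bp_strength = rng.uniform(0, 1, n_int)
    bp_distance = rng.integers(20, 41, n_int)  # heptamer start .. 3'ss

    feats = {
        "log_length": np.log(lengths),
        "gc_content": gc,
        "ss5_strength": ss5,
        "ss3_strength": ss3,
        "bp_strength": bp_strength,
    }
    score = np.zeros(n_int)
    for name, w in config.effect_weights.items():
        x = feats[name]
        sd = x.std()
        score += w * (x - x.mean()) / (sd if sd > 0 else 1.0)
    score += rng.normal(0, 0.5, n_int)  # unexplained biological noise

    n_ret = int(round(config.fraction_retained * n_int))
    retained_any = np.zeros(n_int, dtype=bool)
    if n_ret > 0:
        retained_any[np.argsort(-score, kind="stable")[:n_ret]] = True
    ret_idx = np.flatnonzero(retained_any)
    n_dyn = int(round(config.fraction_dynamic * n_ret))
    dyn_idx = rng.choice(ret_idx, size=n_dyn, replace=False) if n_dyn else np.array([], int)
    dynamic = np.zeros(n_int, dtype=bool)
    dynamic[dyn_idx] = True

    # --- per-cell-type states and true IRratios ---------------------------
    cts = list(config.cell_types)
    lo, hi = config.retained_ir_range
    state_rows = []
    for i in range(n_int):
        if not retained_any[i]:
            ct_states = {ct: "non_retained" for ct in cts}
        elif dynamic[i] and len(cts) >= 2:
            k = rng.integers(1, len(cts))  # retained in 1..k-1 cell types
            ret_cts = set(rng.choice(cts, size=k, replace=False))
            ct_states = {ct: ("retained" if ct in ret_cts else "non_retained")
                         for ct in cts}
        else:
            ct_states = {ct: "retained" for ct in cts}
        for ct in cts:
            if ct_states[ct] == "retained":
                tir = rng.uniform(lo, hi)
            else:
                tir = rng.uniform(0, config.non_retained_ir_max)
            state_rows.append((i, ct, ct_states[ct], tir))

    # --- chromatin coupling ----------------------------------------------
    nfr_coupled = retained_any & (rng.random(n_int) < config.nfr_coupling_prob)
    archetype = np.where(nfr_coupled, rng.integers(1, 6, n_int), 0)

    # --- expression classes ----------------------------------------------
    expr_class = rng.choice(["low", "medium", "high"], size=config.n_genes,
                            p=[0.4, 0.4, 0.2])

    # --- lay out genes on one chromosome ---------------------------------
    exon_lo, exon_hi = config.exon_length_range
    strands = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    fully_non = np.array([
        not retained_any[g * config.introns_per_gene:(g + 1) * config.introns_per_gene].any()
        for g in range(config.n_genes)
    ])
    n_alt = int(round(config.alt_transcript_fraction * config.n_genes))
    alt_candidates = np.flatnonzero(fully_non & (strands == strands))  # all fully-non genes
    alt_genes = set(rng.choice(alt_candidates, size=min(n_alt, len(alt_candidates)),
                               replace=False).tolist())
    # half the alt genes get an exon-skipping isoform, half an extra exon
    alt_genes_sorted = sorted(alt_genes)
    skip_genes = set(alt_genes_sorted[::2])
    cryptic_genes = set(alt_genes_sorted[1::2])

    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    gene_rows, annot_rows, intron_rows, nfr_rows = [], [], [], []

    for g in range(config.n_genes):
        gid = f"G{g + 1:04d}"
        strand = strands[g]
        n_exons = config.introns_per_gene + 1
        exon_lengths = rng.integers(exon_lo, exon_hi + 1, n_exons)
        idx0 = g * config.introns_per_gene
        gene_introns = np.arange(idx0, idx0 + config.introns_per_gene)

        # transcription-oriented gene sequence, with recorded tx-coords
        parts: list[str] = []
        tx_pos = 0
        exon_tx: list[tuple[int, int]] = []
        intron_tx: list[tuple[int, int]] = []
        for e in range(n_exons):
            exon_seq = "".join(_random_seq(rng, int(exon_lengths[e]), 0.5))
            if e > 0:  # acceptor context at the exon start handled on intron
                pass
            parts.append(exon_seq)
            exon_tx.append((tx_pos, tx_pos + len(exon_seq)))
            tx_pos += len(exon_seq)
            if e < n_exons - 1:
                i = gene_introns[e]
                L = int(lengths[i])
                body = _random_seq(rng, L, gc[i])
                donor = _blend_motif(rng, DONOR_INTRON, ss5[i], lock=2)
                body[: len(donor)] = list(donor)
                # polypyrimidine tract + invariant AG
                ppt_len = 15
                ppt_p = 0.45 + 0.5 * ss3[i]
                ppt = np.where(rng.random(ppt_len) < ppt_p,
                               rng.choice(["C", "T"], ppt_len),
                               rng.choice(BASES, ppt_len))
                body[L - 2 - ppt_len : L - 2] = ppt
                body[L - 2 :] = list(ACCEPTOR_END)
                # branch-point heptamer ending bp_distance bp before the 3'ss
                bp = _blend_motif(rng, BRANCH_CONSENSUS, bp_strength[i])
                d = int(bp_distance[i])
                body[L - d - len(bp) : L - d] = list(bp)
                intron_seq = "".join(body)
                parts.append(intron_seq)
                intron_tx.append((tx_pos, tx_pos + L))
                tx_pos += L

        gene_seq_tx = "".join(parts)
        glen = len(gene_seq_tx)
        gene_start = cursor
        genome_parts.append(gene_seq_tx if strand == "+" else revcomp(gene_seq_tx))
        cursor += glen
        genome_parts.append("".join(_random_seq(rng, config.intergenic_gap, 0.5)))
        cursor += config.intergenic_gap

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return gene_start + a, gene_start + b
            return gene_start + glen - b, gene_start + glen - a

        gene_rows.append(
            dict(gene_id=gid, chrom=chrom, start=gene_start, end=gene_start + glen,
                 strand=strand, tss=(gene_start if strand == "+" else gene_start + glen - 1),
                 expression_class=expr_class[g])
        )
        annot_rows.append(dict(Chromosome=chrom, Feature="gene", Start=gene_start,
                               End=gene_start + glen, Strand=strand, gene_id=gid,
                               transcript_id="", exon_number=None))
        tid = f"{gid}.t1"
        annot_rows.append(dict(Chromosome=chrom, Feature="transcript", Start=gene_start,
                               End=gene_start + glen, Strand=strand, gene_id=gid,
                               transcript_id=tid, exon_number=None))
        for e, (a, b) in enumerate(exon_tx):
            s, t = to_genomic(a, b)
            annot_rows.append(dict(Chromosome=chrom, Feature="exon", Start=s, End=t,
                                   Strand=strand, gene_id=gid, transcript_id=tid,
                                   exon_number=e + 1))

        for e, (a, b) in enumerate(intron_tx):
            i = gene_introns[e]
            s, t = to_genomic(a, b)
            iid = intron_id(chrom, s, t, strand)
            donor_gpos = s if strand == "+" else t - 1  # genomic base of the 5'ss
            intron_rows.append(
                dict(intron_id=iid, gene_id=gid, chrom=chrom, start=s, end=t,
                     strand=strand, tx_position=e + 1, length=int(lengths[i]),
                     gc_content=float(gc[i]), ss5_strength=float(ss5[i]),
                     ss3_strength=float(ss3[i]), bp_strength=float(bp_strength[i]),
                     bp_distance=int(bp_distance[i]),
                     retained_any=bool(retained_any[i]), dynamic=bool(dynamic[i]),
                     nfr_coupled=bool(nfr_coupled[i]), archetype=int(archetype[i]),
                     expression_class=expr_class[g], row_index=int(i))
            )
            if nfr_coupled[i]:
                for off_a, off_b in archetype_intervals(int(archetype[i])):
                    if strand == "+":
                        ga, gb = donor_gpos + off_a, donor_gpos + off_b
                    else:
                        ga, gb = donor_gpos - off_b + 1, donor_gpos - off_a + 1
                    nfr_rows.append(dict(intron_id=iid, chrom=chrom,
                                         start=int(ga), end=int(gb)))

        # alternative isoforms for selected fully-non-retained genes
        if g in skip_genes and n_exons >= 3:
            skip_e = int(rng.integers(1, n_exons - 1))
            tid2 = f"{gid}.t2"
            annot_rows.append(dict(Chromosome=chrom, Feature="transcript",
                                   Start=gene_start, End=gene_start + glen,
                                   Strand=strand, gene_id=gid, transcript_id=tid2,
                                   exon_number=None))
            num = 0
            for e, (a, b) in enumerate(exon_tx):
                if e == skip_e:
                    continue
                num += 1
                s, t = to_genomic(a, b)
                annot_rows.append(dict(Chromosome=chrom, Feature="exon", Start=s,
                                       End=t, Strand=strand, gene_id=gid,
                                       transcript_id=tid2, exon_number=num))
        elif g in cryptic_genes:
            # extra exon in the middle of the longest intron -> Type B context
            e = int(np.argmax([b - a for a, b in intron_tx]))
            a, b = intron_tx[e]
            if b - a >= 240:
                mid = (a + b) // 2
                ca, cb = mid - 40, mid + 40
                tid2 = f"{gid}.t2"
                annot_rows.append(dict(Chromosome=chrom, Feature="transcript",
                                       Start=gene_start, End=gene_start + glen,
                                       Strand=strand, gene_id=gid,
                                       transcript_id=tid2, exon_number=None))
                num = 0
                for e2, (ea, eb) in enumerate(exon_tx):
                    num += 1
                    s, t = to_genomic(ea, eb)
                    annot_rows.append(dict(Chromosome=chrom, Feature="exon",
                                           Start=s, End=t, Strand=strand,
                                           gene_id=gid, transcript_id=tid2,
                                           exon_number=num))
                    if e2 == e:
                        num += 1
                        s, t = to_genomic(ca, cb)
                        annot_rows.append(dict(Chromosome=chrom, Feature="exon",
                                               Start=s, End=t, Strand=strand,
                                               gene_id=gid, transcript_id=tid2,
                                               exon_number=num))

    sequences = {chrom: "".join(genome_parts)}
    introns = pd.DataFrame(intron_rows)
    id_by_row = dict(zip(introns["row_index"], introns["intron_id"]))
    states = pd.DataFrame(state_rows, columns=["row_index", "cell_type",
                                               "state", "true_irratio"])
    states["intron_id"] = states["row_index"].map(id_by_row)
    states = states[["intron_id", "cell_type", "state", "true_irratio"]]

    return GroundTruth(
        config=config,
        genes=pd.DataFrame(gene_rows),
        introns=introns.drop(columns=["row_index"]),
        states=states,
        nfr_intervals=pd.DataFrame(nfr_rows, columns=["intron_id", "chrom",
                                                      "start", "end"]),
        annotation=pd.DataFrame(annot_rows),
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# Transcriptome: coverage, junctions, expression
# ---------------------------------------------------------------------------

_EXPR_MULT = {"low": 0.8, "medium": 1.0, "high": 1.5}
_FPKM_RANGE = {"low": (1.5, 25.0), "medium": (25.0, 75.0), "high": (75.0, 150.0)}


def simulate_transcriptome(truth: GroundTruth, config: SimulationConfig | None = None):
    """Per-sample coverage bedGraphs, junction counts and FPKM tables.

    Intronic per-base depth is negative binomial with mean
    ``true_irratio * gene_depth``; junction counts are Poisson with mean
    ``(1 - true_irratio) * gene_depth``, so the recomputed IRratio is an
    (asymptotically) unbiased readout of the planted one.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 23])
    chrom = truth.genes["chrom"].iloc[0]
    glen = len(truth.sequences[chrom])

    exon_df = truth.annotation[truth.annotation["Feature"] == "exon"]
    t1_exons = exon_df[exon_df["transcript_id"].str.endswith(".t1")]
    introns_by_gene = dict(tuple(truth.introns.groupby("gene_id", sort=False)))
    states_idx = truth.states.set_index(["intron_id", "cell_type"])

    coverage, junction_rows, expr_rows = {}, [], []
    fpkm_gene = {
        row.gene_id: rng.uniform(*_FPKM_RANGE[row.expression_class])
        for row in truth.genes.itertuples()
    }

    for ct, sample in config.samples():
        depth = np.zeros(glen)
        for gene in truth.genes.itertuples():
            gid = gene.gene_id
            mult = _EXPR_MULT[gene.expression_class]
            d = config.mean_coverage * mult * rng.uniform(0.9, 1.1)
            fpkm = fpkm_gene[gid] * rng.uniform(0.9, 1.1)
            expr_rows.append((gid, sample, round(float(fpkm), 3)))

            for ex in t1_exons[t1_exons["gene_id"] == gid].itertuples():
                n = int(ex.End - ex.Start)
                depth[int(ex.Start):int(ex.End)] += sample_negative_binomial(
                    rng, d, config.nb_dispersion, size=n)
            gi = introns_by_gene[gid]
            for intr in gi.itertuples():
                tir = states_idx.loc[(intr.intron_id, ct), "true_irratio"]
                n = int(intr.end - intr.start)
                if tir > 0:
                    depth[intr.start:intr.end] += sample_negative_binomial(
                        rng, tir * d, config.nb_dispersion, size=n)
                jc = rng.poisson((1.0 - tir) * d)
                junction_rows.append((chrom, intr.start, intr.end, intr.strand,
                                      int(jc), sample))
            # minor alternative isoform: cryptic exon coverage + skip junction
            t2 = exon_df[(exon_df["gene_id"] == gid)
                         & (exon_df["transcript_id"] == f"{gid}.t2")]
            if len(t2):
                q = 0.25  # minor isoform fraction
                t1g = t1_exons[t1_exons["gene_id"] == gid]
                t1_coords = set(zip(t1g["Start"], t1g["End"]))
                t2_coords = set(zip(t2["Start"], t2["End"]))
                extra = t2_coords - t1_coords
                for s, t in extra:  # cryptic exon expressed from isoform 2
                    depth[int(s):int(t)] += sample_negative_binomial(
                        rng, q * d, config.nb_dispersion, size=int(t - s))
                skipped = sorted(t1_coords - t2_coords)
                for s, t in skipped:  # junction skipping the missing exon
                    t1_sorted = t1g.sort_values("Start")
                    prev_end = t1_sorted[t1_sorted["End"] <= s]["End"].max()
                    next_start = t1_sorted[t1_sorted["Start"] >= t]["Start"].min()
                    if pd.notna(prev_end) and pd.notna(next_start):
                        jc = rng.poisson(q * d)
                        junction_rows.append((chrom, int(prev_end), int(next_start),
                                              gene.strand, int(jc), sample))
        coverage[sample] = iio.bedgraph_from_array(np.round(depth).astype(int), chrom)

    junctions = pd.DataFrame(junction_rows, columns=iio.JUNCTION_COLUMNS)
    junctions = (junctions.groupby(["chrom", "donor", "acceptor", "strand", "sample"],
                                   as_index=False, sort=True)["count"].sum())
    junctions = junctions[iio.JUNCTION_COLUMNS]
    expression = pd.DataFrame(expr_rows, columns=iio.EXPRESSION_COLUMNS)
    return coverage, junctions, expression


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def gch_level_track(truth: GroundTruth, cell_type: str,
                    config: SimulationConfig | None = None) -> np.ndarray:
    """Per-base true GCH methylation level for one cell type.

    Background everywhere except the +/-200 bp donor windows of NFR-coupled
    introns that are *retained in this cell type*, where the archetype step
    profile is painted (chromatin accessibility follows the IR state).
    """
    config = config or truth.config
    chrom = truth.genes["chrom"].iloc[0]
    level = np.full(len(truth.sequences[chrom]), config.gch_meth_background)
    st = truth.states[(truth.states["cell_type"] == cell_type)
                      & (truth.states["state"] == "retained")]
    retained_ids = set(st["intron_id"])
    coupled = truth.introns[truth.introns["nfr_coupled"]
                            & truth.introns["intron_id"].isin(retained_ids)]
    offs = np.arange(-200, 200)
    for intr in coupled.itertuples():
        lv = archetype_level(int(intr.archetype), offs, config)
        donor = intr.start if intr.strand == "+" else intr.end - 1
        if intr.strand == "+":
            pos = donor + offs
        else:
            pos = donor - offs
        ok = (pos >= 0) & (pos < len(level))
        level[pos[ok]] = np.maximum(level[pos[ok]], lv[ok])
    return level


def simulate_methylomes(truth: GroundTruth, config: SimulationConfig | None = None):
    """CpG and GCH cytosine-report tables per cell type."""
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 37])
    chrom = truth.genes["chrom"].iloc[0]
    seq = np.frombuffer(truth.sequences[chrom].encode(), dtype="S1").astype(str)
    gch_pos = gch_site_positions(seq)
    cpg_pos = cpg_site_positions(seq)

    gch, cpg = {}, {}
    for ct in config.cell_types:
        level = gch_level_track(truth, ct, config)
        gch[ct] = simulate_methylation_calls(gch_pos, level[gch_pos],
                                             config.gch_read_depth, rng,
                                             "GCH", chrom)
        lo, hi = config.cpg_bimodal_modes
        modes = np.where(rng.random(len(cpg_pos)) < 0.5, lo, hi)
        site_levels = np.clip(modes + rng.normal(0, 0.03, len(cpg_pos)), 0, 1)
        cpg[ct] = simulate_methylation_calls(cpg_pos, site_levels,
                                             config.cpg_read_depth, rng,
                                             "CpG", chrom)
    return cpg, gch


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------

_PROMOTER_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3")
_H3K36_BASE = 30.0


def simulate_chip(truth: GroundTruth, config: SimulationConfig | None = None):
    """Histone-mark pileup bedGraphs and narrowPeak calls per mark/cell type.

    H3K36me3 covers gene bodies (scaled by expression) and is multiplied by
    the depletion factor over retained introns sitting in dynamic chromatin
    (NFR-coupled, retained in the given cell type); the other five marks form
    promoter peaks whose heights are independent of IR.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 53])
    chrom = truth.genes["chrom"].iloc[0]
    glen = len(truth.sequences[chrom])

    pileups: dict[tuple[str, str], pd.DataFrame] = {}
    peaks: dict[tuple[str, str], pd.DataFrame] = {}
    states_idx = truth.states.set_index(["intron_id", "cell_type"])["state"]

    for ct in config.cell_types:
        # H3K36me3 -------------------------------------------------------
        track = np.zeros(glen)
        peak_rows = []
        for gene in truth.genes.itertuples():
            base = _H3K36_BASE * _EXPR_MULT[gene.expression_class] * rng.uniform(0.8, 1.2)
            track[gene.start:gene.end] = base
            gi = truth.introns[truth.introns["gene_id"] == gene.gene_id]
            for intr in gi.itertuples():
                if (intr.nfr_coupled
                        and states_idx.loc[(intr.intron_id, ct)] == "retained"):
                    track[intr.start:intr.end] *= config.h3k36me3_depletion
            summit = (gene.start + gene.end) // 2
            peak_rows.append((chrom, gene.start, gene.end,
                              f"{ct}_H3K36me3_{gene.gene_id}", 0, ".",
                              round(base, 3), -1, -1, summit - gene.start))
        track = np.round(track, 3)
        pileups[(ct, "H3K36me3")] = iio.bedgraph_from_array(track, chrom)
        peaks[(ct, "H3K36me3")] = pd.DataFrame(peak_rows,
                                               columns=iio.NARROWPEAK_COLUMNS)

        # promoter marks --------------------------------------------------
        for mark in _PROMOTER_MARKS:
            track = np.zeros(glen)
            peak_rows = []
            for gene in truth.genes.itertuples():
                if rng.random() < 0.6:  # not every promoter carries each mark
                    continue
                height = float(rng.lognormal(np.log(20.0), 0.6))
                a = max(0, gene.tss - 200)
                b = min(glen, gene.tss + 200)
                track[a:b] = np.maximum(track[a:b], round(height, 3))
                peak_rows.append((chrom, a, b, f"{ct}_{mark}_{gene.gene_id}",
                                  0, ".", round(height, 3), -1, -1, (b - a) // 2))
            pileups[(ct, mark)] = iio.bedgraph_from_array(np.round(track, 3), chrom)
            peaks[(ct, mark)] = pd.DataFrame(peak_rows,
                                             columns=iio.NARROWPEAK_COLUMNS)
    return pileups, peaks


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Paths of everything :func:`simulate_all` wrote, plus the ground truth."""

    outdir: str
    truth: GroundTruth
    gtf: str
    fasta: str
    coverage: dict[str, str]          # sample -> bedGraph
    junctions: str
    expression: str
    cpg_reports: dict[str, str]       # cell type -> cytosine report
    gch_reports: dict[str, str]
    chip_pileups: dict[tuple[str, str], str]
    chip_peaks: dict[tuple[str, str], str]


def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> SimulatedDataset:
    """Generate and write the complete linked dataset for one configuration."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    truth = simulate_annotation(config)

    gtf = os.path.join(outdir, "annotation.gtf")
    iio.write_gtf(truth.annotation, gtf)
    fasta = os.path.join(outdir, "genome.fa")
    iio.write_fasta(truth.sequences, fasta)

    coverage, junctions, expression = simulate_transcriptome(truth, config)
    cov_paths = {}
    for sample, bg in coverage.items():
        p = os.path.join(outdir, f"{sample}.coverage.bedgraph")
        iio.write_bedgraph(bg, p)
        cov_paths[sample] = p
    jpath = os.path.join(outdir, "junctions.tsv")
    iio.write_junctions(junctions, jpath)
    epath = os.path.join(outdir, "expression.tsv")
    iio.write_expression(expression, epath)

    cpg, gch = simulate_methylomes(truth, config)
    cpg_paths, gch_paths = {}, {}
    for ct in config.cell_types:
        cpg_paths[ct] = os.path.join(outdir, f"{ct}.cpg_report.txt")
        iio.write_cytosine_report(cpg[ct], cpg_paths[ct])
        gch_paths[ct] = os.path.join(outdir, f"{ct}.gch_report.txt")
        iio.write_cytosine_report(gch[ct], gch_paths[ct])

    pileups, peaks = simulate_chip(truth, config)
    pp, kp = {}, {}
    for key, bg in pileups.items():
        ct, mark = key
        pp[key] = os.path.join(outdir, f"{ct}.{mark}.pileup.bedgraph")
        iio.write_bedgraph(bg, pp[key])
    for key, pk in peaks.items():
        ct, mark = key
        kp[key] = os.path.join(outdir, f"{ct}.{mark}.narrowPeak")
        iio.write_narrowpeak(pk, kp[key])

    truth.states.to_csv(os.path.join(outdir, "truth_states.tsv"),
                        sep="\t", index=False)
    truth.introns.to_csv(os.path.join(outdir, "truth_introns.tsv"),
                         sep="\t", index=False)
    return SimulatedDataset(outdir=outdir, truth=truth, gtf=gtf, fasta=fasta,
                            coverage=cov_paths, junctions=jpath, expression=epath,
                            cpg_reports=cpg_paths, gch_reports=gch_paths,
                            chip_pileups=pp, chip_peaks=kp)
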