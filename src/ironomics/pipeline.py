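"""End-to-end driver: simulate -> quantify -> diffir -> nome -> features ->
classify -> cluster, with ground-truth scoring at every stage.

The pipeline is the integration surface used by the command-line interface
and the acceptance benchmarks; each stage delegates to the corresponding
module and the returned summary holds only quantities computed at run time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import differential, features, io as iio, irquant, models, nome, profiles, synthetic

__all__ = ["run_pipeline", "PipelineResult", "interval_recall"]


@dataclass
class PipelineResult:
    summary: dict = field(default_factory=dict)
    ir_table: pd.DataFrame | None = None
    feature_table: pd.DataFrame | None = None
    differential_tables: dict = field(default_factory=dict)
    dynamic_introns: set = field(default_factory=set)
    nfr_calls: dict = field(default_factory=dict)
    profile_matrix: "profiles.ProfileMatrix | None" = None
    en_ranking: "models.ImportanceRanking | None" = None
    crf_ranking: "models.ImportanceRanking | None" = None
    truth: "synthetic.GroundTruth | None" = None


def interval_recall(planted: pd.DataFrame, calls, min_overlap: float = 0.5) -> float:
    """Fraction of planted intervals recovered by calls at >= min_overlap
    reciprocal-to-planted positional overlap."""
    if not len(planted):
        return float("nan")
    hit = 0
    for row in planted.itertuples():
        plen = row.end - row.start
        for c in calls:
            ov = min(row.end, c.end) - max(row.start, c.start)
            if ov > 0 and ov / plen >= min_overlap:
                hit += 1
                break
    return hit / len(planted)


def _retention_concordance(ir_table: pd.DataFrame,
                           truth: synthetic.GroundTruth,
                           low: float = 0.005, high: float = 0.15) -> float:
    """Agreement of retention calls with truth on confidently-banded introns
    (true IRratio <= low or >= high)."""
    merged = ir_table.merge(truth.states, on=["intron_id", "cell_type"])
    banded = merged[(merged["true_irratio"] <= low)
                    | (merged["true_irratio"] >= high)]
    if not len(banded):
        return float("nan")
    return float((banded["retention_call"] == banded["state"]).mean())


def run_pipeline(config: synthetic.SimulationConfig, outdir: str,
                 n_trees: int = 100, run_models: bool = True) -> PipelineResult:
    """Run every stage on one simulated dataset and score it against truth."""
    res = PipelineResult()
    dataset = synthetic.simulate_all(config, outdir)
    truth = dataset.truth
    res.truth = truth
    summary = res.summary

    # ---- quantify -------------------------------------------------------
    annotation = iio.read_gtf(dataset.gtf)
    fasta = iio.read_fasta(dataset.fasta)
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}
    introns = irquant.extract_introns(annotation)
    coverage = {s: iio.read_bedgraph(p) for s, p in dataset.coverage.items()}
    junctions = iio.read_junctions(dataset.junctions)
    expression = iio.read_expression(dataset.expression)
    sample_to_ct = {s: ct for ct, s in config.samples()}
    ir_table = irquant.quantify_cell_types(introns, annotation, coverage,
                                           junctions, expression,
                                           sample_to_ct, chrom_lengths)
    res.ir_table = ir_table
    ir_table.to_csv(os.path.join(outdir, "ir_table.tsv"), sep="\t", index=False)
    summary["n_introns"] = len(introns)
    summary["n_retained_calls"] = int((ir_table["retention_call"] == "retained").sum())
    summary["n_retained_introns"] = int(
        ir_table[ir_table["retention_call"] == "retained"]["intron_id"].nunique())
    summary["retention_concordance"] = _retention_concordance(ir_table, truth)

    # ---- differential / dynamic ----------------------------------------
    cts = list(config.cell_types)
    for a, b in zip(cts[:-1], cts[1:]):
        tab = differential.differential_table(ir_table, a, b)
        res.differential_tables[(a, b)] = tab
    if len(cts) >= 2:
        dyn = differential.find_dynamic_introns(ir_table)
        res.dynamic_introns = dyn
        true_dyn = truth.dynamic_introns()
        summary["n_dynamic_called"] = len(dyn)
        summary["n_dynamic_true"] = len(true_dyn)
        summary["dynamic_sensitivity"] = (
            len(dyn & true_dyn) / len(true_dyn) if true_dyn else float("nan"))

    # ---- NOMe chromatin calls ------------------------------------------
    gch_by_ct = {ct: iio.read_cytosine_report(p)
                 for ct, p in dataset.gch_reports.items()}
    cpg_by_ct = {ct: nome.filter_cpg_coverage(iio.read_cytosine_report(p))
                 for ct, p in dataset.cpg_reports.items()}
    recalls = []
    for ct in cts:
        calls = nome.call_nfrs(gch_by_ct[ct])
        res.nfr_calls[ct] = calls
        retained_ids = set(truth.states[(truth.states["cell_type"] == ct)
                                        & (truth.states["state"] == "retained")
                                        ]["intron_id"])
        planted = truth.nfr_intervals[
            truth.nfr_intervals["intron_id"].isin(retained_ids)]
        if len(planted):
            recalls.append(interval_recall(planted, calls))
    summary["nfr_recovery_sensitivity"] = float(np.mean(recalls)) if recalls else float("nan")

    # ---- features -------------------------------------------------------
    intron_by_id = {i.intron_id: i for i in introns}
    donor_pwm = features.build_donor_pwm(introns, truth.sequences)
    acceptor_pwm = features.build_acceptor_pwm(introns, truth.sequences)
    pileups = {k: iio.read_bedgraph(p) for k, p in dataset.chip_pileups.items()}
    peaks = {k: iio.read_narrowpeak(p) for k, p in dataset.chip_peaks.items()}

    rows = []
    ir_idx = ir_table.set_index(["intron_id", "cell_type"])
    for ct in cts:
        stats_by_mark, peaks_by_mark = {}, {}
        for mark in features.HISTONE_MARKS:
            pk = peaks[(ct, mark)]
            peaks_by_mark[mark] = pk
            mean, sd, summits = features.peak_signal_stats(
                pk, pileups[(ct, mark)], chrom_lengths)
            stats_by_mark[mark] = (summits, mean + sd)
        chromatin_calls = list(res.nfr_calls[ct]) + list(
            nome.call_nucleosomes(gch_by_ct[ct]))
        sub = ir_table[(ir_table["cell_type"] == ct)
                       & (ir_table["retention_call"] != "ambiguous")]
        for r in sub.itertuples():
            intron = intron_by_id[r.intron_id]
            row = features.assemble_features(
                intron, r.retention_call, truth.sequences,
                cpg_by_ct[ct], gch_by_ct[ct], chromatin_calls,
                peaks_by_mark, stats_by_mark,
                ir_idx.loc[(r.intron_id, ct), "psi5"],
                ir_idx.loc[(r.intron_id, ct), "psi3"],
                donor_pwm, acceptor_pwm,
                chrom_lengths[intron.chrom])
            if row is not None:
                row["cell_type"] = ct
                rows.append(row)
    feature_table = pd.DataFrame(rows)
    res.feature_table = feature_table
    feature_table.to_csv(os.path.join(outdir, "features.tsv"), sep="\t",
                         index=False)
    import json

    with open(os.path.join(outdir, "features.schema.json"), "w") as fh:
        json.dump(features.feature_schema(), fh, indent=2)
    summary["n_feature_rows"] = len(feature_table)
    summary["feature_registry_hash"] = features.registry_hash()

    # ---- models ---------------------------------------------------------
    if run_models and len(feature_table) and feature_table["label"].nunique() == 2:
        fnames = features.feature_registry()
        balanced = models.downsample_balance(feature_table, config.seed)
        en = models.fit_elastic_net(balanced, fnames, seed=config.seed)
        crf = models.fit_conditional_forest(balanced, fnames, n_trees=n_trees,
                                            seed=config.seed)
        res.en_ranking = models.rank_features_en(en)
        res.crf_ranking = models.permutation_importance(crf, balanced)
        summary["en_cv_auc"] = en.cv_auc
        Xb, yb = models.prepare_xy(balanced, fnames)
        oob = crf.forest.oob_proba(Xb)
        ok = ~np.isnan(oob)
        from sklearn.metrics import roc_auc_score

        summary["crf_oob_auc"] = float(roc_auc_score(yb[ok], oob[ok]))
        summary["en_top5"] = res.en_ranking.top(5)
        summary["crf_top5"] = res.crf_ranking.top(5)

    # ---- GCH profile clustering ----------------------------------------
    coupled = truth.introns[truth.introns["nfr_coupled"]]
    parts, arch_truth = [], {}
    for ct in cts:
        retained_ids = set(truth.states[(truth.states["cell_type"] == ct)
                                        & (truth.states["state"] == "retained")
                                        ]["intron_id"])
        take = [intron_by_id[i] for i in coupled["intron_id"]
                if i in retained_ids and i not in arch_truth
                and i in intron_by_id]
        if take:
            # 20 bp bins: at genome-wide GCH density, 10 bp bins leave ~half
            # the bins empty and imputation swamps the archetype signal
            parts.append(profiles.build_profile_matrix(take, gch_by_ct[ct],
                                                       bin_size=20))
            for i in take:
                arch_truth[i.intron_id] = int(
                    coupled.set_index("intron_id").loc[i.intron_id, "archetype"])
    if parts:
        values = pd.concat([p.values for p in parts])
        pm = profiles.ProfileMatrix(values=values, bin_size=parts[0].bin_size,
                                    anchor="5ss")
        res.profile_matrix = pm
        pm.values.to_csv(os.path.join(outdir, "gch_profiles.tsv"), sep="\t")
        if len(values) >= 5:
            labels = profiles.cluster_profiles(pm, k=5)
            labels.to_csv(os.path.join(outdir, "gch_clusters.tsv"), sep="\t")
            from sklearn.metrics import adjusted_rand_score

            t = [arch_truth[i] for i in labels.index]
            summary["cluster_ari"] = float(adjusted_rand_score(t, labels.to_numpy()))
            summary["n_clustered"] = len(labels)

    # ---- H3K36me3 deconfounding ----------------------------------------
    rows36 = []
    ct0 = cts[0]
    track = iio.depth_array(pileups[(ct0, "H3K36me3")], truth.genes["chrom"].iloc[0],
                            chrom_lengths[truth.genes["chrom"].iloc[0]])
    gch0 = gch_by_ct[ct0]
    for r in ir_table[(ir_table["cell_type"] == ct0)
                      & (ir_table["retention_call"] != "ambiguous")].itertuples():
        intron = intron_by_id[r.intron_id]
        cnt = int(round(track[intron.start:intron.end].mean()))
        gm = nome.region_methylation((intron.start, intron.end), gch0)
        if gm is None:
            continue
        rows36.append((cnt, 100.0 * gm, r.retention_call))
    if len(rows36) > 20:
        arr = pd.DataFrame(rows36, columns=["count", "gch", "group"])
        glm = profiles.h3k36me3_glm_adjust(arr["count"].to_numpy(),
                                           arr["gch"].to_numpy(),
                                           arr["group"].to_numpy())
        summary["h3k36me3_glm_slope"] = glm["slope"]
        summary["h3k36me3_adjusted_p"] = glm["p_value"]

    return res
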