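"""Reference-oracle comparisons and property benchmarks.

Everything here recomputes a quantity with the package *and* with an
independent oracle (exact rational arithmetic, arbitrary precision, analytic
integration, or ground-truth simulation) and reports the agreement.  The test
suite asserts on these numbers; the acceptance script reports them.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from . import models, nome, profiles, synthetic
from .differential import audic_claverie_pvalue
from .irquant import trimmed_intronic_abundance
from .pipeline import interval_recall

__all__ = [
    "trimmed_mean_oracle_max_error",
    "ac_oracle_max_error",
    "ac_large_count_error",
    "fisher_oracle_max_error",
    "ac_null_fpr",
    "nfr_fisher_null_fpr",
    "nfr_recovery",
    "nucleosome_recovery",
    "bayes_auc",
    "model_parameter_recovery",
    "permuted_label_aucs",
    "xor_auc_gap",
    "archetype_clustering_ari",
    "glm_null_rate",
]


# ---------------------------------------------------------------------------
# Exact oracles
# ---------------------------------------------------------------------------

def trimmed_mean_oracle_max_error(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |implementation - sort/slice/mean oracle| over random vectors.

    The oracle sorts with plain Python, slices off floor(0.3 n) per side and
    takes the correctly-rounded mean, so agreement is exact (error 0.0).
    """
    import math

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 400))
        v = rng.gamma(1.0, 20.0, n).round(3)
        k = int(np.floor(0.3 * n))
        core = sorted(v.tolist())[k: n - k]
        oracle = math.fsum(core) / len(core)
        worst = max(worst, abs(trimmed_intronic_abundance(v) - oracle))
    return worst


def _ac_exact(x: int, y: int, n1, n2) -> Fraction:
    """Exact-rational doubled min enrichment tail of the AC distribution."""
    r = Fraction(n2) / Fraction(n1)

    def upper(x, y, r):
        if y == 0:
            return Fraction(1)
        return 1 - sum(r ** k * comb(x + k, k) / (1 + r) ** (x + k + 1)
                       for k in range(y))

    return min(Fraction(1), 2 * min(upper(x, y, r), upper(y, x, 1 / r)))


def ac_oracle_max_error(max_count: int = 50,
                        ratios=((1, 1), (2, 3))) -> float:
    """Max |log-space summation - exact rational oracle| over all x,y pairs."""
    worst = 0.0
    for n1, n2 in ratios:
        for x in range(max_count + 1):
            for y in range(max_count + 1):
                p = audic_claverie_pvalue(x, y, float(n1), float(n2))
                worst = max(worst, abs(p - float(_ac_exact(x, y, n1, n2))))
    return worst


def ac_large_count_error(x: int = 10_000, y: int = 10_000) -> float:
    """Overflow check at count 1e4 against an arbitrary-precision oracle."""
    import mpmath as mp

    mp.mp.dps = 40

    def upper(x, y):
        if y == 0:
            return mp.mpf(1)
        total = mp.mpf(0)
        lg = mp.log(mp.mpf(2))
        for k in range(y):
            total += mp.exp(mp.loggamma(x + k + 1) - mp.loggamma(x + 1)
                            - mp.loggamma(k + 1) - (x + k + 1) * lg)
        return 1 - total

    oracle = float(min(1, 2 * min(upper(x, y), upper(y, x))))
    return abs(audic_claverie_pvalue(x, y, 1, 1) - oracle)


def _hypergeom_tail_exact(a, b, c, d) -> Fraction:
    """One-sided (enrichment) Fisher p by exact enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    total = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if 0 <= col1 - k <= n - row1:
            total += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    return total


def fisher_oracle_max_error(seed: int = 0, n_random: int = 300,
                            max_margin: int = 200) -> float:
    """Fisher region test vs exact hypergeometric enumeration.

    Exhaustive over small tables (row sums <= 10) plus random tables with
    margins up to ``max_margin``.
    """
    from scipy.stats import fisher_exact

    tables = []
    for r1 in range(1, 11):
        for a in range(r1 + 1):
            for r2 in range(1, 11):
                for c in range(r2 + 1):
                    tables.append((a, r1 - a, c, r2 - c))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        r1, r2 = rng.integers(1, max_margin + 1, 2)
        a = int(rng.integers(0, r1 + 1))
        c = int(rng.integers(0, r2 + 1))
        tables.append((a, int(r1) - a, c, int(r2) - c))
    worst = 0.0
    for a, b, c, d in tables:
        p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        worst = max(worst, abs(p - float(_hypergeom_tail_exact(a, b, c, d))))
    return worst


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def ac_null_fpr(n_draws: int = 10_000, lam: float = 20.0,
                seed: int = 0) -> float:
    """Fraction of AC p-values <= 0.05 under paired Poisson null draws."""
    rng = np.random.default_rng(seed)
    x = rng.poisson(lam, n_draws)
    y = rng.poisson(lam, n_draws)
    hits = sum(audic_claverie_pvalue(int(a), int(b), 1.0, 1.0) <= 0.05
               for a, b in zip(x, y))
    return hits / n_draws


def nfr_fisher_null_fpr(n_windows: int = 200, seeds=(0, 1, 2)) -> float:
    """Fisher region tests of prespecified windows on homogeneous methylomes.

    Pools ``n_windows`` disjoint grid windows per seed across the given
    seeds (a single 200-window batch has binomial noise of ~1.5 points, so
    the calibration property is an ensemble statement).
    """
    hits = trials = 0
    for seed in seeds:
        calls = synthetic.simulate_null_methylome(n_sites=20_000, level=0.3,
                                                  depth=20, seed=seed)
        span = int(calls["pos"].max())
        step = max(1, (span - 8400) // n_windows)
        for a in range(4000, span - 4200, step):
            out = nome.fisher_region_test((a, a + 200), calls, 4000)
            if out is None:
                continue
            trials += 1
            hits += out.p_value <= 0.05
    return hits / max(trials, 1)


# ---------------------------------------------------------------------------
# Chromatin recovery
# ---------------------------------------------------------------------------

def nfr_recovery(n_regions: int = 200, seed: int = 0) -> float:
    calls, planted = synthetic.simulate_nfr_benchmark(n_regions=n_regions,
                                                      seed=seed)
    return interval_recall(planted, nome.call_nfrs(calls), min_overlap=0.5)


def nucleosome_recovery(n_regions: int = 30, seed: int = 0) -> float:
    calls, planted = synthetic.simulate_nucleosome_benchmark(
        n_regions=n_regions, seed=seed)
    return interval_recall(planted, nome.call_nucleosomes(calls),
                           min_overlap=0.5)


# ---------------------------------------------------------------------------
# Model parameter recovery
# ---------------------------------------------------------------------------

def bayes_auc(weights: np.ndarray) -> float:
    """Analytic AUC of the Bayes classifier for a logistic model with
    standard-normal features, by numerical integration over the score."""
    sigma = float(np.linalg.norm(weights))
    s = np.linspace(-10 * sigma, 10 * sigma, 20001)
    phi = np.exp(-0.5 * (s / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    p1 = 1.0 / (1.0 + np.exp(-s))
    f1 = phi * p1
    f0 = phi * (1 - p1)
    ds = s[1] - s[0]
    pi1, pi0 = f1.sum() * ds, f0.sum() * ds
    cum0 = np.cumsum(f0) * ds  # P(S0 < s)
    auc = float(np.sum(f1 * (cum0 - 0.5 * f0 * ds)) * ds / (pi1 * pi0))
    return auc


def _planted_tables(n, p, weights, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.zeros(p)
    for i, v in weights.items():
        w[i] = v
    y = rng.binomial(1, 1 / (1 + np.exp(-(X @ w))))
    tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    tab["label"] = np.where(y == 1, "retained", "non_retained")
    return tab, [f"f{i}" for i in range(p)], w


PLANTED_WEIGHTS = {3: 2.0, 17: -1.8, 31: 1.6}


def model_parameter_recovery(n_seeds: int = 10, n: int = 2000, p: int = 40,
                             n_trees: int = 200) -> dict:
    """Both models on planted logistic data: top-5 recovery and AUC vs Bayes.

    Returns per-seed top-5 hit flags and the mean held-out AUC per model next
    to the analytic Bayes AUC of the generating model.  The forest tunes
    mtry by out-of-bag pilot accuracy, as the caret-style workflow would.
    """
    planted = [f"f{i}" for i in PLANTED_WEIGHTS]
    en_hits, crf_hits, en_aucs, crf_aucs = [], [], [], []
    w = None
    for seed in range(n_seeds):
        tab, names, w = _planted_tables(n, p, PLANTED_WEIGHTS, seed)
        test, _, _ = _planted_tables(2 * n, p, PLANTED_WEIGHTS, 1000 + seed)
        balanced = models.downsample_balance(tab, seed)
        en = models.fit_elastic_net(balanced, names, seed=seed)
        crf = models.fit_conditional_forest(balanced, names, n_trees=n_trees,
                                            mtry="tune", seed=seed)
        en_rank = models.rank_features_en(en)
        crf_rank = models.permutation_importance(crf, balanced)
        en_hits.append(set(planted) <= set(en_rank.top(5)))
        crf_hits.append(set(planted) <= set(crf_rank.top(5)))
        en_aucs.append(models.evaluate(en, test).auc)
        crf_aucs.append(models.evaluate(crf, test).auc)
    return {
        "bayes_auc": bayes_auc(w[w != 0]),
        "en_top5_hits": int(np.sum(en_hits)),
        "crf_top5_hits": int(np.sum(crf_hits)),
        "n_seeds": n_seeds,
        "en_mean_auc": float(np.mean(en_aucs)),
        "crf_mean_auc": float(np.mean(crf_aucs)),
    }


def permuted_label_aucs(n: int = 2000, p: int = 40, n_seeds: int = 3,
                        n_trees: int = 200) -> dict:
    """Chance-level check: train on permuted labels, evaluate held out.

    Both models are scored on independent data whose labels are likewise
    independent of the features, so AUC must sit at 0.5.  (Out-of-bag AUC is
    deliberately not used here: under a null fit the per-row OOB tree subsets
    anti-correlate with the subsample class balance, biasing OOB AUC well
    below 0.5 — a known artifact, not model signal.)
    """
    en_aucs, crf_aucs = [], []
    for seed in range(n_seeds):
        tab, names, _ = _planted_tables(n, p, PLANTED_WEIGHTS, 100 + seed)
        rng = np.random.default_rng(seed)
        tab = tab.assign(label=rng.permutation(tab["label"].to_numpy()))
        test, _, _ = _planted_tables(2 * n, p, PLANTED_WEIGHTS, 300 + seed)
        test = test.assign(label=rng.permutation(test["label"].to_numpy()))
        en = models.fit_elastic_net(tab, names, seed=seed)
        en_aucs.append(models.evaluate(en, test).auc)
        crf = models.fit_conditional_forest(tab, names, n_trees=n_trees,
                                            seed=seed)
        crf_aucs.append(models.evaluate(crf, test).auc)
    return {"en_mean_auc": float(np.mean(en_aucs)),
            "crf_mean_auc": float(np.mean(crf_aucs))}


def xor_auc_gap(n_train: int = 1500, n_test: int = 2000, p_noise: int = 8,
                label_noise: float = 0.1, n_trees: int = 200,
                seed: int = 0) -> dict:
    """Forest-vs-EN AUC gap on a pure XOR interaction.

    Only works in the forest's always-split mode (the default): with a
    significance stopping rule a conditional-inference tree cannot enter a
    pure interaction at all, since every marginal association test is null
    at the root.
    """

    def make(n, s):
        rng = np.random.default_rng(s)
        X = rng.normal(size=(n, 2 + p_noise))
        y = (X[:, 0] * X[:, 1] > 0).astype(int)
        y = np.where(rng.random(n) < label_noise, 1 - y, y)
        tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(2 + p_noise)])
        tab["label"] = np.where(y == 1, "retained", "non_retained")
        return tab, [f"f{i}" for i in range(2 + p_noise)]

    train, names = make(n_train, seed)
    test, _ = make(n_test, seed + 1)
    en = models.fit_elastic_net(train, names, seed=seed)
    crf = models.fit_conditional_forest(train, names, n_trees=n_trees,
                                        seed=seed)
    en_auc = models.evaluate(en, test).auc
    crf_auc = models.evaluate(crf, test).auc
    return {"en_auc": en_auc, "crf_auc": crf_auc, "gap": crf_auc - en_auc}


# ---------------------------------------------------------------------------
# Clustering and GLM
# ---------------------------------------------------------------------------

def archetype_clustering_ari(n_per_archetype: int = 100, depth: float = 20.0,
                             seed: int = 0) -> float:
    from sklearn.metrics import adjusted_rand_score

    anchors, calls, labels = synthetic.simulate_archetype_profiles(
        n_per_archetype=n_per_archetype, depth=depth, seed=seed)
    matrix = profiles.build_profile_matrix(anchors, calls, bin_size=10)
    got = profiles.cluster_profiles(matrix, k=5)
    truth = [labels[i] for i in got.index]
    return float(adjusted_rand_score(truth, got.to_numpy()))


def glm_null_rate(n_seeds: int = 100, n_per_group: int = 200) -> float:
    """Fraction of seeds where the GCH-adjusted group contrast is null when
    H3K36me3 counts depend only on GCH methylation."""
    non_sig = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        groups = np.array(["retained"] * n_per_group
                          + ["non_retained"] * n_per_group)
        gch = np.where(groups == "retained",
                       rng.normal(40, 8, 2 * n_per_group),
                       rng.normal(15, 8, 2 * n_per_group)).clip(0, 100)
        counts = rng.poisson(np.exp(2.0 + 0.02 * gch))
        out = profiles.h3k36me3_glm_adjust(counts, gch, groups)
        non_sig += out["p_value"] > 0.05
    return non_sig / n_seeds
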