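"""Simulation studies characterizing the risk-score framework end to end.

Each study runs the full pipeline on synthetic cohorts with known truth and
summarizes an operating characteristic: how much of the planted signal the
P+T selection recovers, how well a discovery sub-community transports to an
independent cohort, how much additive multi-omics integration improves on
single layers, the empirical coverage of the DeLong interval, and the type-I
error of the built-in differential-abundance tests.  The same harnesses back
the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .da_tests import clr_ttest_da, wilcoxon_da
from .evaluation import auc_ci, roc_auc
from .feature_io import filter_features, to_relative_abundance
from .integration import (
    combined_cv_prediction,
    make_fixed_score_builder,
    make_mrs_builder,
    make_signed_logcount_builder,
)
from .mrs_core import SubCommunity, mrs_alpha
from .pt_selection import apply_subcommunity, pt_select
from .synthetic_data import default_spec, integration_spec, simulate_microbiome, simulate_multiomics


def signal_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """P+T recovery of planted signal taxa under the reference conditions.

    For each seed: simulate the default cohort (100+100 samples, 200 taxa,
    10 signal taxa at a 4-fold concentration effect), run LOO P+T selection
    with the Shannon sub-community score, and record (a) the fraction of
    truth taxa inside the chosen sub-community and (b) the margin of the
    cross-validated sub-community AUC over the whole-community Shannon AUC.
    """
    recoveries, cv_aucs, whole_aucs = [], [], []
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = simulate_microbiome(default_spec(seed))
        y = cohort.metadata.outcome
        pt = pt_select(cohort.microbiome, y, cv="loo", seed=seed)
        truth = set(cohort.truth["signal_taxa"])
        recoveries.append(len(truth & set(pt.chosen_taxa.taxa)) / len(truth))
        cv_aucs.append(float(pt.cv_auc.max()))
        whole = mrs_alpha(cohort.microbiome,
                          SubCommunity(cohort.microbiome.feature_ids), "shannon")
        whole_aucs.append(roc_auc(whole, y).auc)
    return {
        "mean_recovery": float(np.mean(recoveries)),
        "mean_cv_auc": float(np.mean(cv_aucs)),
        "mean_whole_community_auc": float(np.mean(whole_aucs)),
        "mean_auc_margin": float(np.mean(np.array(cv_aucs) - np.array(whole_aucs))),
        "n_seeds": n_seeds,
    }


def external_validation_study(n_reps: int = 50, base_seed: int = 0,
                              val_n_per_arm: int = 200) -> dict:
    """Transportability of a discovery sub-community to a fresh cohort.

    Discovery and validation cohorts are drawn from one generative model
    (shared population seed, independent sampling seeds); the validation
    cohort is twice the discovery size so that its AUC estimate contributes
    little noise to the comparison.  The discovery AUC is the final
    sub-community score evaluated on the discovery cohort with a DeLong 95%
    CI; the study reports how often the independent validation AUC falls
    inside that interval.
    """
    inside = 0
    disc_aucs, val_aucs = [], []
    for rep in range(n_reps):
        pop = base_seed * 1009 + 7919 + rep
        disc = simulate_microbiome(default_spec(seed=base_seed + 2 * rep,
                                                population_seed=pop))
        val = simulate_microbiome(default_spec(seed=base_seed + 2 * rep + 1,
                                               population_seed=pop,
                                               n_cases=val_n_per_arm,
                                               n_controls=val_n_per_arm))
        y = disc.metadata.outcome
        pt = pt_select(disc.microbiome, y, cv="loo", seed=base_seed + rep)
        disc_scores = apply_subcommunity(disc.microbiome, pt.chosen_taxa, "shannon")
        roc = auc_ci(disc_scores, y, method="delong")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_scores = apply_subcommunity(val.microbiome, pt.chosen_taxa, "shannon")
        val_auc = roc_auc(val_scores, val.metadata.outcome).auc
        inside += roc.ci_low <= val_auc <= roc.ci_high
        disc_aucs.append(roc.auc)
        val_aucs.append(val_auc)
    return {
        "coverage": inside / n_reps,
        "mean_discovery_auc": float(np.mean(disc_aucs)),
        "mean_validation_auc": float(np.mean(val_aucs)),
        "n_reps": n_reps,
    }


def integration_study(n_reps: int = 50, base_seed: int = 0,
                      with_noise_arm: bool = True) -> dict:
    """Additive logistic integration of microbiome and gene-expression scores.

    Under the two-layer preset (each layer's marginal CV-AUC near 0.7) the
    study measures how often the combined CV-AUC exceeds both marginals, and
    (optionally) how much a pure-noise third score perturbs the combination.
    """
    rows, noise_delta = [], []
    for rep in range(n_reps):
        seed = base_seed + rep
        cohort = simulate_multiomics(integration_spec(seed))
        y = cohort.metadata.outcome
        micro = make_mrs_builder(cohort.microbiome)
        genes = make_signed_logcount_builder(cohort.companion)
        _, r_micro = combined_cv_prediction([micro], y, cv="kfold", k=5, seed=seed)
        _, r_genes = combined_cv_prediction([genes], y, cv="kfold", k=5, seed=seed)
        _, r_comb = combined_cv_prediction([micro, genes], y, cv="kfold", k=5, seed=seed)
        rows.append((r_micro.auc, r_genes.auc, r_comb.auc))
        if with_noise_arm:
            rng = np.random.default_rng(10_000 + seed)
            noise = make_fixed_score_builder(rng.standard_normal(y.size))
            _, r_noise = combined_cv_prediction([micro, noise], y, cv="kfold",
                                                k=5, seed=seed)
            noise_delta.append(r_noise.auc - r_micro.auc)
    r = np.array(rows)
    out = {
        "mean_microbiome_auc": float(r[:, 0].mean()),
        "mean_gene_auc": float(r[:, 1].mean()),
        "mean_combined_auc": float(r[:, 2].mean()),
        "combined_beats_both_rate": float(np.mean(r[:, 2] > r[:, :2].max(axis=1))),
        "n_reps": n_reps,
    }
    if with_noise_arm:
        out["mean_noise_score_delta"] = float(np.mean(noise_delta))
    return out


def delong_coverage_study(n_sims: int = 500, n_per_class: int = 50,
                          true_auc: float = 0.75, seed: int = 7) -> dict:
    """Empirical coverage of the DeLong 95% CI under the binormal model."""
    rng = np.random.default_rng(seed)
    mu = np.sqrt(2) * stats.norm.ppf(true_auc)
    y = np.repeat([1, 0], n_per_class)
    covered = 0
    for _ in range(n_sims):
        x = np.concatenate([
            rng.normal(mu, 1, n_per_class), rng.normal(0, 1, n_per_class)
        ])
        r = auc_ci(x, y, method="delong")
        covered += r.ci_low <= true_auc <= r.ci_high
    return {"coverage": covered / n_sims, "n_sims": n_sims, "true_auc": true_auc}


def type1_error_study(n_reps: int = 500, n_per_class: int = 25,
                      n_taxa: int = 40, base_seed: int = 0) -> dict:
    """Rejection rate at nominal 5% of both built-in DA tests under the null."""
    p_w, p_t = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cohort = simulate_microbiome(default_spec(
                seed=base_seed + rep, n_cases=n_per_class, n_controls=n_per_class,
                n_taxa=n_taxa, log_fold_effect=0.0))
            table = filter_features(cohort.microbiome, min_prevalence=0.1)
            y = cohort.metadata.outcome
            p_w.append(wilcoxon_da(to_relative_abundance(table), y).p_value)
            p_t.append(clr_ttest_da(table, y).p_value)
    return {
        "wilcoxon_rate": float((np.concatenate(p_w) < 0.05).mean()),
        "clr_ttest_rate": float((np.concatenate(p_t) < 0.05).mean()),
        "n_reps": n_reps,
    }
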