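"""Reproduction studies: the package's headline computations, end to end.

Each function runs one self-contained study on synthetic data — design
arithmetic, density-table worked examples, the kinship contract, the
equivalence of the two marker-effect routes, REML parameter recovery, and
the qualitative accuracy phenomena (training-set size, cluster structure,
breeding cohorts, marker density) — and returns plain numbers.  They are
shared by the acceptance test suite and the reproduction script.

Scales are desk-sized: panels of 650-1,350 lines with 600-1,500 markers,
chosen so every study completes in minutes on one CPU while preserving the
structural regime of a large inbred wheat panel (five germplasm clusters in
two related pools, family structure within clusters, serial cohorts under
truncation selection, a gridded trial with repeated checks and AR1 x AR1
plot errors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .designs import cohort_designs, size_series_design
from .experiments import (ExperimentOptions, experiment_cluster_cv,
                          experiment_cohort_cv,
                          experiment_density_by_structure,
                          experiment_size_series, fit_full_model)
from .genotypes import GenotypeMatrix, build_kinship
from .markers import GeneticMap, summarize_subset
from .model import (VarianceComponents, backsolve_marker_effects,
                    fit_marker_model, fit_one_step, fit_training_model,
                    predict_lines)
from .simulate import (SimulationConfig, TrialConfig, grid_layout,
                       simulate_bundle, simulate_panel,
                       simulate_phenotypes_from_components, simulate_trial)

__all__ = [
    "design_arithmetic",
    "density_table_examples",
    "kinship_contract",
    "equivalence_study",
    "recovery_study",
    "reml_oracle_gap",
    "cluster_structure_study",
    "size_response_study",
    "density_interaction_study",
    "cohort_benefit_study",
]


# ---------------------------------------------------------------------------
# exact design arithmetic (panel-scale combinatorics, no model fits)


def design_arithmetic(seed: int = 0) -> dict:
    """Replicate counts and subset sizes of the cross-validation designs
    at the full panel scale (10,375 lines, five folds; four 996-line
    cohorts)."""
    ids = [f"l{i}" for i in range(10375)]
    sizes = [250, 500, 1000, 2000, 3000, 4000, 5000, 6000, 7000]
    design = size_series_design(ids, sizes, n_folds=5, seed=seed)
    meta = pd.DataFrame([s.meta for s in design])
    counts = (meta.groupby(["fold", "size"]).size()
                  .groupby("size").first())
    fold_size = len(design.splits[0].valid)

    years = np.repeat([2010, 2011, 2012, 2013], 996)
    labels = pd.Series(years,
                       index=pd.Index([f"c{i}" for i in range(len(years))]))
    cohorts = {d.label: d for d in cohort_designs(labels, seed=seed)}
    per_cohort = {
        d: len(cohorts[f"cohort_{d}prior"].splits[0].train) // d
        for d in (1, 2, 3)
    }
    return {
        "replicates": {int(s): int(counts[s]) for s in sizes},
        "fold_size": int(fold_size),
        "cohort_subset_sizes": per_cohort,
    }


def density_table_examples() -> dict:
    """Markers-per-position ratios for stacked consensus-map selections.

    Reconstructs the arithmetic of a dense selection summary: 10,000 markers
    on 4,590 unique positions and 13,639 on 4,593, on a 21-chromosome map.
    """
    out = {}
    for n_markers, n_positions in ((10000, 4590), (13639, 4593)):
        marker_ids = np.array([f"m{j}" for j in range(n_markers)])
        # distribute unique positions over 21 chromosomes, stack the rest
        pos_chrom = np.arange(n_positions) % 21
        pos_cm = (np.arange(n_positions) // 21).astype(float)
        take = np.arange(n_markers) % n_positions
        gmap = GeneticMap(marker_ids, pos_chrom[take].astype(str),
                          pos_cm[take])
        G = GenotypeMatrix(["a", "b"], marker_ids,
                           np.vstack([np.ones(n_markers),
                                      -np.ones(n_markers)]))
        s = summarize_subset(marker_ids, gmap, G)
        assert s["unique_positions"] == n_positions
        out[n_markers] = s["markers_per_position"]
    return out


def kinship_contract(seed: int = 0, n: int = 120, m: int = 300) -> dict:
    """Trace normalisation of the genomic relationship matrix."""
    rng = np.random.default_rng(seed)
    calls = rng.choice([-1.0, 1.0], size=(n, m))
    G = GenotypeMatrix([f"l{i}" for i in range(n)],
                       [f"mk{j}" for j in range(m)], calls)
    K = build_kinship(G)
    hand = build_kinship(GenotypeMatrix(
        ["a", "b"], ["m1", "m2"], np.array([[1.0, 1.0], [-1.0, -1.0]])))
    return {
        "trace_deviation": float(abs(np.trace(K.values) - n)),
        "hand_case_max_error": float(
            np.abs(hand.values - np.array([[1, -1], [-1, 1]])).max()),
    }


# ---------------------------------------------------------------------------
# model equivalence and parameter recovery


def equivalence_study(seed: int = 0) -> dict:
    """Back-solved vs directly estimated marker effects on one trial.

    300 lines, 1,000 markers: with more markers than training lines both
    routes are available; their validation predictions must agree up to the
    kinship scale constant.
    """
    cfg = SimulationConfig(n_pops=3, n_lines_per_pop=100, n_markers=1000,
                           n_chromosomes=7, n_cohorts=1, selected_trait=None,
                           seed=seed)
    b = simulate_bundle(cfg)
    full = fit_full_model(b, "trait_quant")
    frozen = full.vc.as_dict()
    checks = sorted(set(b.layout.check_line_ids()))
    ids = [i for i in b.G.line_ids if i not in set(checks)]
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(ids)
    train, valid = list(perm[:200]), list(perm[200:260])

    y = b.phenotypes["trait_quant"].to_numpy().copy()
    y[~np.isin(b.layout.line_ids, train + checks)] = np.nan
    M_t = b.G.subset_lines(train + checks)
    M_v = b.G.subset_lines(valid)

    K_t = build_kinship(M_t)
    fit = fit_training_model(y, b.layout, K_t, frozen, validation_ids=valid)
    q_back = backsolve_marker_effects(
        M_t, K_t, fit.gblup_additive.loc[M_t.line_ids].to_numpy(),
        ridge=True)
    pred_back = predict_lines(M_v, q_back)

    q_direct = fit_marker_model(y, b.layout, M_t, frozen,
                                validation_ids=valid)
    pred_direct = predict_lines(M_v, q_direct)
    r = stats.pearsonr(pred_back.to_numpy(), pred_direct.to_numpy())[0]
    return {"correlation": float(r), "n_lines": b.G.n_lines,
            "n_markers": b.G.n_markers}


RECOVERY_TRUTH = VarianceComponents(sigma2=0.5, sigma2_u=0.0, sigma2_a=1.0,
                                    sigma2_p=0.25, rho_r=0.5, rho_c=0.5)


def recovery_study(seed: int = 0, n_reps: int = 50) -> dict:
    """REML parameter recovery over replicated 400-line trials.

    Phenotypes are drawn from the one-step model at known components
    (sigma2_a = 1, sigma2_p = 0.25, sigma2 = 0.5, rho_r = rho_c = 0.5) on a
    checked grid layout; each replicate is refit from scratch and the mean
    estimates are reported.
    """
    cfg = SimulationConfig(n_pops=5, n_lines_per_pop=80, n_markers=800,
                           n_chromosomes=7, n_cohorts=1, selected_trait=None,
                           seed=seed)
    G, _, truth = simulate_panel(cfg)
    K = build_kinship(G)
    ests = []
    for r in range(n_reps):
        layout, _, _ = simulate_trial(G, truth, TrialConfig(n_cols=20),
                                      seed=seed + 1000 + r)
        y, _ = simulate_phenotypes_from_components(
            K, layout, RECOVERY_TRUTH, seed=seed + 5000 + r)
        fit = fit_one_step(y, layout, K)
        d = fit.vc.as_dict()
        ests.append([d["sigma2_a"], d["sigma2_p"], d["sigma2"],
                     d["rho_r"], d["rho_c"]])
    mean = np.mean(ests, axis=0)
    return {
        "mean_sigma2_a": float(mean[0]),
        "mean_sigma2_p": float(mean[1]),
        "mean_sigma2": float(mean[2]),
        "mean_rho_r": float(mean[3]),
        "mean_rho_c": float(mean[4]),
        "n_reps": n_reps,
        "n_lines": G.n_lines,
    }


def reml_oracle_gap(seed: int = 0) -> dict:
    """Solver optimum vs a dense grid search on a tiny instance.

    24 observations with independent residuals: the grid scans the variance
    ratio sigma2_a / sigma2 and the residual variance; the solver's
    log-likelihood must reach the grid's best value.
    """
    rng = np.random.default_rng(seed)
    n, m = 24, 40
    calls = rng.choice([-1.0, 1.0], size=(n, m))
    G = GenotypeMatrix([f"l{i}" for i in range(n)],
                       [f"mk{j}" for j in range(m)], calls)
    K = build_kinship(G)
    layout = grid_layout(G.line_ids, n_cols=6, seed=seed)
    vc = VarianceComponents(sigma2=1.0, sigma2_u=0.0, sigma2_a=2.0,
                            sigma2_p=0.0, rho_r=0.0, rho_c=0.0)
    y, _ = simulate_phenotypes_from_components(K, layout, vc, seed=seed + 1)
    fit = fit_one_step(y, layout, K, spatial=False, frozen={"sigma2_p": 0.0})

    order = {v: i for i, v in enumerate(K.line_ids)}
    Zg = np.zeros((n, n))
    for i, lid in enumerate(layout.line_ids):
        Zg[i, order[lid]] = 1.0
    ZKZ = Zg @ K.values @ Zg.T
    X = np.ones((n, 1))
    best = -np.inf
    for lam in np.geomspace(1e-3, 1e3, 200):
        for s2 in np.geomspace(0.05, 20.0, 120) * np.var(y):
            V = s2 * (lam * ZKZ + np.eye(n))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            ll = -0.5 * (np.linalg.slogdet(V)[1]
                         + np.linalg.slogdet(XtViX)[1]
                         + (y - X @ beta) @ Vi @ y)
            best = max(best, ll)
    return {"solver_loglik": float(fit.loglik), "grid_loglik": float(best),
            "gap": float(best - fit.loglik), "n_obs": n}


# ---------------------------------------------------------------------------
# qualitative accuracy phenomena


def _cluster_panel(seed: int, n_per_pop: int, n_markers: int,
                   divergence: float) -> SimulationConfig:
    return SimulationConfig(
        n_pops=5, n_lines_per_pop=n_per_pop, n_markers=n_markers,
        n_chromosomes=7, divergence=divergence, divergence_split=0.5,
        family_divergence=0.6, n_families_per_cohort=10, n_cohorts=1,
        selected_trait=None, seed=seed)


def cluster_structure_study(seed: int = 0, n_replicates: int = 3) -> dict:
    """Accuracy ordering of the four cluster designs, replicated panels.

    A moderately diverged five-cluster panel (650 lines, 600 markers);
    training 80, validation 30.  Mean accuracy per design over all splits
    and panel replicates.
    """
    frames = []
    for r in range(n_replicates):
        cfg = _cluster_panel(seed + 21 + r, n_per_pop=130, n_markers=600,
                             divergence=0.3)
        b = simulate_bundle(cfg)
        full = fit_full_model(b, "trait_quant")
        opts = ExperimentOptions(trait="trait_quant", per_cluster=120,
                                 train_size=80, valid_size=30, seed=3)
        frames.append(experiment_cluster_cv(b, opts, full_model=full))
    df = pd.concat(frames, ignore_index=True)
    means = df.groupby("design")["accuracy"].mean()
    return {k: float(v) for k, v in means.items()} | {
        "n_replicates": n_replicates, "n_splits": int(len(df))}


def size_response_study(seed: int = 0) -> dict:
    """Accuracy versus training-set size: monotone rise with a knee.

    One 650-line panel, sizes 30-240 plus the full pool under two-fold
    cross-validation; reports mean accuracy per size and the per-line slope
    of the first and last size increments.
    """
    cfg = _cluster_panel(seed + 21, n_per_pop=130, n_markers=600,
                         divergence=0.3)
    b = simulate_bundle(cfg)
    full = fit_full_model(b, "trait_quant")
    opts = ExperimentOptions(trait="trait_quant", sizes=[30, 60, 120, 240],
                             n_folds=2, seed=3)
    df = experiment_size_series(b, opts, full_model=full)
    # the two (slightly unequal) full pools collapse onto one size point
    df["size_group"] = np.where(df["size"] > 240, 999999, df["size"])
    acc = df.groupby("size_group")["accuracy"].mean()
    sizes = sorted(acc.index)
    pool = int(df.loc[df["size_group"] == 999999, "size"].mean())
    labelled = {(pool if s == 999999 else int(s)): float(acc[s])
                for s in sizes}
    xs = sorted(labelled)
    first_slope = (labelled[xs[1]] - labelled[xs[0]]) / (xs[1] - xs[0])
    last_slope = (labelled[xs[-1]] - labelled[xs[-2]]) / (xs[-1] - xs[-2])
    return {"accuracy_by_size": labelled,
            "first_per_line_slope": float(first_slope),
            "last_per_line_slope": float(last_slope)}


def density_interaction_study(seed: int = 0, n_replicates: int = 3) -> dict:
    """Response of each cluster design to marker density, replicated panels.

    Strongly structured panels (1,350 lines, 1,500 markers, two germplasm
    pools) with training sets of 160; accuracy at a 150-marker thinning and
    at the full panel.  The response is the full-density minus low-density
    mean accuracy per design, averaged over panel replicates.
    """
    responses = []
    for r in range(n_replicates):
        cfg = _cluster_panel(seed + 41 + r, n_per_pop=270, n_markers=1500,
                             divergence=0.5)
        b = simulate_bundle(cfg)
        full = fit_full_model(b, "trait_poly")
        opts = ExperimentOptions(trait="trait_poly", per_cluster=250,
                                 train_size=160, valid_size=50,
                                 density_targets=[150], seed=3)
        df = experiment_density_by_structure(b, opts, full_model=full)
        piv = df.groupby(["design", "n_markers"])["accuracy"].mean().unstack()
        responses.append(piv[1500] - piv[150])
    agg = pd.concat(responses, axis=1).mean(axis=1)
    return {f"response_{k}": float(v) for k, v in agg.items()} | {
        "n_replicates": n_replicates}


def cohort_benefit_study(seed: int = 0, n_replicates: int = 2) -> dict:
    """Gain from extra training cohorts: selected versus neutral trait.

    Panels with four serial cohorts under truncation selection (top 20%) on
    the polygenic trait; cohort designs with 180-line cohort samples.  The
    gain is mean accuracy with three prior cohorts minus one prior cohort.
    """
    frames = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_pops=5, n_lines_per_pop=160, n_markers=1500, n_chromosomes=7,
            divergence=0.5, divergence_split=0.5, family_divergence=0.6,
            n_families_per_cohort=10, n_cohorts=4, selection_intensity=0.2,
            selected_trait="trait_poly", seed=seed + 51 + r)
        b = simulate_bundle(cfg)
        opts = ExperimentOptions(seed=3, cohort_size=180)
        frames.append(experiment_cohort_cv(b, opts,
                                           traits=["trait_poly",
                                                   "trait_major"]))
    df = pd.concat(frames, ignore_index=True)
    piv = df.groupby(["trait", "design"])["accuracy"].mean().unstack()
    gains = piv["cohort_3prior"] - piv["cohort_1prior"]
    return {
        "gain_selected_trait": float(gains["trait_poly"]),
        "gain_neutral_trait": float(gains["trait_major"]),
        "n_replicates": n_replicates,
    }
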