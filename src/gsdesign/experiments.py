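"""End-to-end experiment orchestration.

Each experiment fits the full one-step model once, caches its additive
GBLUPs as the accuracy reference, builds the requested cross-validation
design suite and executes it.  These functions are the programmatic surface
behind the command-line interface and the reproduction scripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .designs import (cluster_designs, cohort_designs, records_frame, run_cv,
                      size_series_design)
from .genotypes import build_kinship
from .markers import density_series
from .model import FittedModel, fit_one_step
from .simulate import SyntheticBundle
from .structure import genetic_dissimilarity, kmeans_partition

__all__ = [
    "ExperimentOptions",
    "fit_full_model",
    "experiment_size_series",
    "experiment_cluster_cv",
    "experiment_cohort_cv",
    "experiment_density",
    "experiment_density_by_structure",
    "summarize_accuracy",
]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("size_series", "cluster_cv", "cohort_cv", "density",
               "density_by_structure")


@dataclass
class ExperimentOptions:
    """Design and model switches shared by the experiment drivers."""

    trait: str = "trait_poly"
    seed: int = 0
    sizes: Sequence[int] = (250, 500, 1000, 2000)
    n_folds: int = 5
    k_clusters: int = 5
    per_cluster: int = 1500
    train_size: int = 1000
    valid_size: int = 500
    density_targets: Sequence[int] = (100, 500, 1000, 3000, 5000, 10000, 13639)
    cohort_size: Optional[int] = None
    max_splits: Optional[int] = None
    marker_model_ratio: float = 0.9
    max_iter: int = 200
    fit_kwargs: dict = field(default_factory=dict)


def fit_full_model(bundle: SyntheticBundle, trait: str,
                   **fit_kwargs) -> FittedModel:
    """Fit the maximal one-step model on all lines for one trait."""
    K = build_kinship(bundle.G)
    y = bundle.phenotypes[trait].to_numpy()
    fit = fit_one_step(y, bundle.layout, K, **fit_kwargs)
    if not fit.converged:
        logger.warning("full model for %s did not converge", trait)
    return fit


def _test_line_ids(bundle: SyntheticBundle):
    """Panel lines eligible for designs: everything except the checks."""
    checks = set(bundle.layout.check_line_ids())
    return [i for i in bundle.G.line_ids if i not in checks]


def experiment_size_series(bundle: SyntheticBundle, opts: ExperimentOptions,
                           full_model: Optional[FittedModel] = None
                           ) -> pd.DataFrame:
    """Accuracy versus training-set size under n-fold cross-validation."""
    full = full_model or fit_full_model(bundle, opts.trait, **opts.fit_kwargs)
    design = size_series_design(_test_line_ids(bundle), opts.sizes,
                                n_folds=opts.n_folds, seed=opts.seed)
    if opts.max_splits is not None:
        design.splits = design.splits[: opts.max_splits]
    recs = run_cv(design, bundle.G, bundle.phenotypes[opts.trait],
                  bundle.layout, full, trait=opts.trait,
                  marker_model_ratio=opts.marker_model_ratio,
                  max_iter=opts.max_iter)
    return records_frame(recs)


def _partition(bundle: SyntheticBundle, opts: ExperimentOptions):
    test_ids = _test_line_ids(bundle)
    D = genetic_dissimilarity(bundle.G.subset_lines(test_ids))
    return kmeans_partition(D, k=opts.k_clusters, seed=opts.seed)


def experiment_cluster_cv(bundle: SyntheticBundle, opts: ExperimentOptions,
                          full_model: Optional[FittedModel] = None,
                          assignment=None,
                          G=None) -> pd.DataFrame:
    """The four cluster-structured designs on a K-means partition."""
    full = full_model or fit_full_model(bundle, opts.trait, **opts.fit_kwargs)
    assignment = assignment or _partition(bundle, opts)
    G = G or bundle.G
    frames = []
    for design in cluster_designs(assignment, per_cluster=opts.per_cluster,
                                  train_size=opts.train_size,
                                  valid_size=opts.valid_size, seed=opts.seed,
                                  max_splits=opts.max_splits):
        recs = run_cv(design, G, bundle.phenotypes[opts.trait],
                      bundle.layout, full, trait=opts.trait,
                      marker_model_ratio=opts.marker_model_ratio,
                      max_iter=opts.max_iter)
        frames.append(records_frame(recs))
    return pd.concat(frames, ignore_index=True)


def experiment_cohort_cv(bundle: SyntheticBundle, opts: ExperimentOptions,
                         traits: Optional[Sequence[str]] = None
                         ) -> pd.DataFrame:
    """Prior-cohort designs, optionally over several traits."""
    traits = list(traits or [opts.trait])
    cohorts = bundle.truth.cohort.loc[_test_line_ids(bundle)]
    designs = cohort_designs(cohorts, cohort_size=opts.cohort_size,
                             seed=opts.seed)
    frames = []
    for trait in traits:
        full = fit_full_model(bundle, trait, **opts.fit_kwargs)
        for design in designs:
            if opts.max_splits is not None:
                design = type(design)(design.label,
                                      design.splits[: opts.max_splits],
                                      design.seed)
            recs = run_cv(design, bundle.G, bundle.phenotypes[trait],
                          bundle.layout, full, trait=trait,
                          marker_model_ratio=opts.marker_model_ratio,
                          max_iter=opts.max_iter)
            frames.append(records_frame(recs))
    return pd.concat(frames, ignore_index=True)


def experiment_density(bundle: SyntheticBundle, opts: ExperimentOptions,
                       full_model: Optional[FittedModel] = None
                       ) -> pd.DataFrame:
    """Accuracy versus marker density under n-fold cross-validation.

    The full-model reference always uses the complete marker panel; only
    the training/prediction marker set is thinned.
    """
    full = full_model or fit_full_model(bundle, opts.trait, **opts.fit_kwargs)
    subsets = density_series(bundle.G, bundle.genetic_map,
                             opts.density_targets)
    frames = []
    for sub in subsets:
        G_sub = bundle.G.subset_markers(sub.marker_ids)
        design = size_series_design(_test_line_ids(bundle), [],
                                    n_folds=opts.n_folds, seed=opts.seed)
        if opts.max_splits is not None:
            design.splits = design.splits[: opts.max_splits]
        recs = run_cv(design, G_sub, bundle.phenotypes[opts.trait],
                      bundle.layout, full, trait=opts.trait,
                      marker_model_ratio=opts.marker_model_ratio,
                      max_iter=opts.max_iter)
        df = records_frame(recs)
        df["n_markers"] = sub.summary["n_markers"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def experiment_density_by_structure(bundle: SyntheticBundle,
                                    opts: ExperimentOptions,
                                    full_model: Optional[FittedModel] = None
                                    ) -> pd.DataFrame:
    """Cluster designs repeated at every marker density (the interaction)."""
    full = full_model or fit_full_model(bundle, opts.trait, **opts.fit_kwargs)
    assignment = _partition(bundle, opts)
    subsets = density_series(bundle.G, bundle.genetic_map,
                             opts.density_targets)
    frames = []
    for sub in subsets:
        G_sub = bundle.G.subset_markers(sub.marker_ids)
        df = experiment_cluster_cv(bundle, opts, full_model=full,
                                   assignment=assignment, G=G_sub)
        df["n_markers"] = sub.summary["n_markers"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_accuracy(df: pd.DataFrame, by=("design",)) -> pd.DataFrame:
    """Per-design accuracy quartiles, the boxplot statistics."""
    g = df.groupby(list(by))["accuracy"]
    out = g.agg(n="count", mean="mean", median="median",
                q1=lambda s: s.quantile(0.25),
                q3=lambda s: s.quantile(0.75))
    return out.reset_index()


def run_experiment(name: str, bundle: SyntheticBundle,
                   opts: ExperimentOptions, out_dir) -> dict:
    """Run one named experiment and write its accuracy table + manifest."""
    from . import io

    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from "
                         f"{EXPERIMENTS}")
    driver = {
        "size_series": experiment_size_series,
        "cluster_cv": experiment_cluster_cv,
        "cohort_cv": experiment_cohort_cv,
        "density": experiment_density,
        "density_by_structure": experiment_density_by_structure,
    }[name]
    df = driver(bundle, opts)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acc_path = out_dir / f"{name}_accuracy.csv"
    df.to_csv(acc_path, index=False)
    by = [c for c in ("design", "size", "n_markers", "trait")
          if c in df.columns]
    summ_path = out_dir / f"{name}_summary.csv"
    summarize_accuracy(df, by=by).to_csv(summ_path, index=False)
    io.write_manifest(out_dir / f"{name}_manifest.json", seed=opts.seed,
                      options={**opts.__dict__,
                               "experiment": name},
                      outputs={"accuracy": acc_path, "summary": summ_path},
                      diagnostics={"n_records": int(len(df)),
                                   "n_converged": int(df["converged"].sum())
                                   if "converged" in df else None})
    return {"accuracy": df, "paths": [acc_path, summ_path]}
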