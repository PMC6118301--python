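"""Structured cross-validation designs and the accuracy runner.

Three design families probe how training-set composition drives genomic
prediction accuracy:

* a training-set-size series inside a five-fold split, where each fold's
  training pool is carved into as many disjoint subsets of each target size
  as it can hold;
* four cluster-structured designs over a K-means partition of the panel
  ("all clusters", "within cluster", "between cluster - narrow training",
  "between cluster - broad training"), all with fixed training and
  validation sizes;
* breeding-cohort designs where one, two or three prior cohort years train a
  model to predict the following cohort year.

Accuracy is the Pearson correlation between validation-set genomic
predictions and the additive GBLUPs those lines receive in the full-data
model — a relative accuracy that is invariant to affine rescaling of the
predictions, so the kinship scaling constant carried by back-solved marker
effects cannot change any record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, build_kinship
from .model import (FittedModel, TrialLayout, backsolve_marker_effects,
                    fit_marker_model, fit_training_model, predict_lines)
from .structure import ClusterAssignment

__all__ = [
    "Split",
    "CVDesign",
    "AccuracyRecord",
    "size_series_design",
    "cluster_designs",
    "cohort_designs",
    "run_cv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Split:
    train: tuple
    valid: tuple
    replicate: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if set(self.train) & set(self.valid):
            raise ValueError("training and validation sets overlap")


@dataclass
class CVDesign:
    label: str
    splits: list
    seed: int

    def __iter__(self):
        return iter(self.splits)

    def __len__(self) -> int:
        return len(self.splits)


@dataclass
class AccuracyRecord:
    design: str
    trait: str
    replicate: int
    accuracy: float
    n_train: int
    n_valid: int
    converged: bool = True
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# designs


def size_series_design(line_ids, sizes: Sequence[int], *, n_folds: int = 5,
                       seed: int = 0) -> CVDesign:
    """Training-size series within an n-fold split.

    Lines are shuffled into ``n_folds`` folds.  For each fold, the remaining
    lines form the training pool; for each target size the pool is carved
    into ``floor(pool / size)`` disjoint subsets sampled without
    replacement, every subset predicting that fold.  The full pool is also
    emitted as the maximal training set.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(line_ids)
    perm = rng.permutation(len(ids))
    folds = np.array_split(ids[perm], n_folds)
    pool_min = len(ids) - max(len(f) for f in folds)
    for s in sizes:
        if s > pool_min:
            raise ValueError(f"training size {s} exceeds the pool ({pool_min})")

    splits = []
    for f, valid in enumerate(folds):
        pool = np.concatenate([folds[i] for i in range(n_folds) if i != f])
        for size in sizes:
            n_rep = len(pool) // size
            shuffled = rng.permutation(pool)
            for r in range(n_rep):
                train = shuffled[r * size:(r + 1) * size]
                splits.append(Split(tuple(train), tuple(valid), r,
                                    {"fold": f, "size": size}))
        splits.append(Split(tuple(pool), tuple(valid), 0,
                            {"fold": f, "size": len(pool)}))
    return CVDesign("size_series", splits, seed)


def cluster_designs(assignment: ClusterAssignment, *, per_cluster: int = 1500,
                    train_size: int = 1000, valid_size: int = 500,
                    seed: int = 0, max_splits: Optional[int] = None) -> list:
    """The four cluster-structured designs with fixed set sizes.

    ``per_cluster`` lines are sampled from each cluster, then partitioned
    and rotated to replicate each design:

    * ``all_clusters`` — every cluster contributes equally to training
      (train_size / k each) and validation (valid_size / k each);
    * ``within_cluster`` — training and validation drawn from one cluster;
    * ``between_narrow`` — training from one cluster, validation from a
      different one (all ordered cluster pairs);
    * ``between_broad`` — training split equally over the k - 1 clusters
      not being validated (all rotations).

    Replication uses aligned rotation of disjoint within-cluster partitions;
    ``max_splits`` optionally caps each design's split list.
    """
    rng = np.random.default_rng(seed)
    k = assignment.k
    if k < 2:
        raise ValueError("cluster designs need at least two clusters")
    if train_size % k or valid_size % k:
        raise ValueError("train_size and valid_size must be divisible by k")
    if train_size % (k - 1):
        raise ValueError("train_size must be divisible by k - 1 for the "
                         "broad design")

    pools = {}
    for c in range(1, k + 1):
        members = assignment.members(c)
        if len(members) < per_cluster:
            raise ValueError(
                f"cluster {c} has {len(members)} lines, fewer than the "
                f"{per_cluster} required"
            )
        pools[c] = rng.permutation(members)[:per_cluster]

    def chunk(c, start, size):
        return tuple(pools[c][start:start + size])

    designs = []

    # all clusters: per-cluster quotas, partitions rotated jointly
    tpc, vpc = train_size // k, valid_size // k
    n_rot = per_cluster // (tpc + vpc)
    splits = []
    for r in range(n_rot):
        train, valid = (), ()
        for c in pools:
            base = r * (tpc + vpc)
            train += chunk(c, base, tpc)
            valid += chunk(c, base + tpc, vpc)
        splits.append(Split(train, valid, r, {"design": "all_clusters"}))
    designs.append(CVDesign("all_clusters", splits, seed))

    # within cluster
    n_rot = per_cluster // (train_size + valid_size)
    splits = []
    for c in pools:
        for r in range(n_rot):
            base = r * (train_size + valid_size)
            splits.append(Split(chunk(c, base, train_size),
                                chunk(c, base + train_size, valid_size),
                                r, {"cluster": c}))
    designs.append(CVDesign("within_cluster", splits, seed))

    # between cluster, narrow training: ordered pairs, rotated validation
    n_rot = min(per_cluster // train_size, per_cluster // valid_size)
    splits = []
    for a in pools:
        for b in pools:
            if a == b:
                continue
            for r in range(n_rot):
                splits.append(Split(chunk(a, r * train_size, train_size),
                                    chunk(b, r * valid_size, valid_size),
                                    r, {"train_cluster": a,
                                        "valid_cluster": b}))
    designs.append(CVDesign("between_narrow", splits, seed))

    # between cluster, broad training: k rotations of the held-out cluster
    share = train_size // (k - 1)
    n_rot = min(per_cluster // share, per_cluster // valid_size)
    splits = []
    for v in pools:
        for r in range(n_rot):
            train = ()
            for c in pools:
                if c != v:
                    train += chunk(c, r * share, share)
            splits.append(Split(train, chunk(v, r * valid_size, valid_size),
                                r, {"valid_cluster": v}))
    designs.append(CVDesign("between_broad", splits, seed))

    if max_splits is not None:
        for d in designs:
            d.splits = d.splits[:max_splits]
    return designs


def cohort_designs(cohort_labels: pd.Series, *, cohort_size: Optional[int] = None,
                   seed: int = 0) -> list:
    """One-, two- and three-prior-cohort designs predicting the next cohort.

    ``cohort_labels`` maps line id to an orderable cohort year.  For the
    d-prior-cohort design the training set takes ``cohort_size // d`` lines
    from each of the d cohorts preceding the validation cohort, subsets
    rotated without replacement; validation is a full cohort-sized sample of
    the following year.  Designs lacking enough prior cohorts skip the
    infeasible target years with a log entry.
    """
    rng = np.random.default_rng(seed)
    years = sorted(cohort_labels.unique())
    by_year = {y: np.asarray(cohort_labels.index[cohort_labels == y])
               for y in years}
    size = cohort_size or min(len(v) for v in by_year.values())
    for y, members in by_year.items():
        if len(members) < size:
            raise ValueError(f"cohort {y} has {len(members)} lines, fewer "
                             f"than {size}")
    pools = {y: rng.permutation(m)[:size] for y, m in by_year.items()}

    designs = []
    for d in (1, 2, 3):
        per = size // d
        splits = []
        for ti, target in enumerate(years):
            if ti < d:
                logger.info("cohort design %d: target %s skipped "
                            "(needs %d prior cohorts)", d, target, d)
                continue
            prior = years[ti - d:ti]
            n_rot = size // per
            for r in range(n_rot):
                train = ()
                for y in prior:
                    train += tuple(pools[y][r * per:(r + 1) * per])
                splits.append(Split(train, tuple(pools[target]), r,
                                    {"target": target, "n_prior": d}))
        designs.append(CVDesign(f"cohort_{d}prior", splits, seed))
    return designs


# ---------------------------------------------------------------------------
# runner


def run_cv(design: CVDesign, G: GenotypeMatrix, y, layout: TrialLayout,
           full_model: FittedModel, *, trait: str = "trait",
           marker_model_ratio: float = 0.9, metric: str = "pearson",
           include_checks: bool = True, ridge: bool = True,
           max_iter: int = 200) -> list:
    """Execute a design: mask, refit, predict, correlate.

    Per split: validation (and unused-line) phenotype records are set to
    missing, a training model is fitted with the full model's non-genetic
    parameters frozen, marker effects come from the kinship back-solve — or
    directly from the reduced-rank marker model when the marker count falls
    below ``marker_model_ratio`` x training lines — and validation lines are
    predicted from their genotypes.  Accuracy correlates those predictions
    with the full model's additive GBLUPs of the validation lines.

    Check lines (repeated plots) stay in every training set so the spatial
    calibration they provide is retained.  Non-converged training fits are
    flagged and excluded from summaries by the caller.
    """
    y = np.asarray(y, dtype=float)
    frozen = full_model.vc.as_dict()
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[metric]
    check_ids = layout.check_line_ids() if include_checks else np.array([])

    records = []
    for split in design:
        train = list(dict.fromkeys(list(split.train) + list(check_ids)))
        valid = list(split.valid)
        train_set = set(train)

        y_masked = y.copy()
        drop = ~np.isin(layout.line_ids, list(train_set))
        y_masked[drop] = np.nan

        M_t = G.subset_lines(train)
        M_v = G.subset_lines(valid)
        use_marker_model = G.n_markers < marker_model_ratio * len(train)
        try:
            if use_marker_model:
                q = fit_marker_model(y_masked, layout, M_t, frozen,
                                     validation_ids=valid, max_iter=max_iter)
                fit = q.model
            else:
                K_t = build_kinship(M_t)
                fit = fit_training_model(y_masked, layout, K_t, frozen,
                                         validation_ids=valid,
                                         max_iter=max_iter)
                a_t = fit.gblup_additive.loc[M_t.line_ids].to_numpy()
                q = backsolve_marker_effects(M_t, K_t, a_t, ridge=ridge)
            preds = predict_lines(M_v, q)
        except Exception:
            logger.exception("split %s/%d failed", design.label,
                             split.replicate)
            records.append(AccuracyRecord(design.label, trait,
                                          split.replicate, np.nan,
                                          len(split.train), len(valid),
                                          converged=False, meta=split.meta))
            continue

        ref = full_model.gblup_additive.loc[preds.index].to_numpy()
        acc = float(corr(preds.to_numpy(), ref)[0])
        rec = AccuracyRecord(design.label, trait, split.replicate, acc,
                             len(split.train), len(valid),
                             converged=fit.converged, meta=dict(split.meta))
        if not fit.converged:
            logger.warning("training model for %s replicate %d did not "
                           "converge; record flagged", design.label,
                           split.replicate)
        records.append(rec)
    return records


def records_frame(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Tabulate accuracy records (converged splits only)."""
    rows = [{"design": r.design, "trait": r.trait, "replicate": r.replicate,
             "accuracy": r.accuracy, "n_train": r.n_train,
             "n_valid": r.n_valid, "converged": r.converged, **r.meta}
            for r in records]
    df = pd.DataFrame(rows)
    return df[df["converged"]] if len(df) else df
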