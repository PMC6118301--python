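"""One-step GBLUP mixed model with a separable spatial residual.

The phenotypic model for a gridded field trial is

    y = X tau + Z u + Zg (a + p) + e

with fixed effects ``tau`` (intercept and optional linear row/column trends),
optional extraneous design effects ``u ~ N(0, sigma2_u I)``, additive genetic
effects ``a ~ N(0, sigma2_a K)`` through the genomic kinship K, residual
(non-additive) genetic effects ``p ~ N(0, sigma2_p I)`` and plot errors
``e ~ N(0, sigma2 R)`` where ``R = AR1(rho_r) x AR1(rho_c)`` is a separable
first-order autoregressive correlation over the trial's row and column
dimensions.

Variance parameters are estimated by maximising the residual (REML)
log-likelihood

    l_R = -1/2 [ log|H| + log|X' H^-1 X| + y' P y ],

with H = var(y) and P the REML projection matrix, over a box-constrained
quasi-Newton search on log-variances and the autocorrelations.  GBLUPs of the
additive effects are recovered as ``a_hat = sigma2_a K Zg' P y``; marker
effects follow either by back-solving through the kinship matrix (when the
marker count supports a full-rank K) or directly from a reduced-rank
marker-effects formulation of the genetic term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genotypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "TrialLayout",
    "VarianceComponents",
    "FittedModel",
    "MarkerEffects",
    "fit_one_step",
    "fit_training_model",
    "backsolve_marker_effects",
    "predict_lines",
    "fit_marker_model",
]

logger = logging.getLogger(__name__)

#: relative lower bound for variance components (fraction of var(y))
VAR_FLOOR = 1e-8
#: bound keeping the AR1 parameters inside (-1, 1)
RHO_BOUND = 0.98

_VARIANCES = ("sigma2", "sigma2_u", "sigma2_a", "sigma2_p")
_RHOS = ("rho_r", "rho_c")


@dataclass
class TrialLayout:
    """Plot grid of a field trial: one entry per plot.

    ``rows``/``cols`` are zero-based grid indices, ``line_ids`` the line sown
    in each plot and ``is_check`` flags repeated check plots.  ``block_ids``
    optionally groups plots into extraneous design blocks.
    """

    rows: np.ndarray
    cols: np.ndarray
    line_ids: np.ndarray
    is_check: np.ndarray
    n_rows: int
    n_cols: int
    block_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.line_ids = np.asarray(self.line_ids)
        self.is_check = np.asarray(self.is_check, dtype=bool)
        n = len(self.rows)
        if not (len(self.cols) == len(self.line_ids) == len(self.is_check) == n):
            raise ValueError("layout arrays have inconsistent lengths")
        if self.rows.min(initial=0) < 0 or self.rows.max(initial=0) >= self.n_rows:
            raise ValueError("row index outside grid")
        if self.cols.min(initial=0) < 0 or self.cols.max(initial=0) >= self.n_cols:
            raise ValueError("column index outside grid")
        cells = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(cells) != n:
            raise ValueError("duplicate (row, column) plot positions")
        if self.block_ids is not None:
            self.block_ids = np.asarray(self.block_ids)
            if len(self.block_ids) != n:
                raise ValueError("block_ids length mismatch")

    @property
    def n_plots(self) -> int:
        return len(self.rows)

    def check_line_ids(self) -> np.ndarray:
        return np.unique(self.line_ids[self.is_check])


@dataclass
class VarianceComponents:
    sigma2: float          # residual (plot error) variance
    sigma2_u: float        # extraneous design-effect variance
    sigma2_a: float        # additive genetic variance
    sigma2_p: float        # residual genetic variance
    rho_r: float           # row-direction AR1 autocorrelation
    rho_c: float           # column-direction AR1 autocorrelation

    def __post_init__(self) -> None:
        for name in _VARIANCES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in _RHOS:
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie strictly inside (-1, 1)")

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in _VARIANCES + _RHOS}


@dataclass
class FittedModel:
    """REML fit of the one-step model: variance components, BLUEs and GBLUPs."""

    vc: VarianceComponents
    fixed_effects: np.ndarray
    fixed_names: Sequence[str]
    gblup_additive: pd.Series
    gblup_residual_genetic: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    pinned: Sequence[str] = field(default_factory=tuple)
    #: Zg' P y at the optimum, indexed by line — the sufficient statistic for
    #: both GBLUPs and marker-effect prediction
    zt_py: pd.Series = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class MarkerEffects:
    """Per-marker additive effects, back-solved or directly estimated."""

    marker_ids: np.ndarray
    effects: np.ndarray
    source: str  # "backsolved" or "direct"
    model: Optional[FittedModel] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.marker_ids):
            raise ValueError("effects length does not match marker_ids")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("non-finite marker effect")


# ---------------------------------------------------------------------------
# REML machinery


class _RemlProblem:
    """Precomputed pieces of the REML objective for one data configuration."""

    def __init__(self, y, layout: TrialLayout, K: KinshipMatrix, *,
                 fixed_trend: bool, spatial: bool):
        y = np.asarray(y, dtype=float)
        if len(y) != layout.n_plots:
            raise ValueError("phenotype vector length does not match layout")
        obs = np.isfinite(y)
        if obs.sum() < 3:
            raise ValueError("fewer than three observed plots")
        self.y = y[obs]
        self.n = int(obs.sum())
        rows = layout.rows[obs]
        cols = layout.cols[obs]

        kin_index = {v: i for i, v in enumerate(K.line_ids)}
        try:
            li = np.array([kin_index[v] for v in layout.line_ids[obs]])
        except KeyError as exc:
            raise KeyError(
                f"plot line {exc.args[0]!r} absent from the kinship matrix"
            ) from None
        self.line_pos = li
        self.K = K

        # fixed-effect design: intercept (+ centred linear trends)
        Xcols = [np.ones(self.n)]
        names = ["intercept"]
        if fixed_trend:
            Xcols.append(rows - rows.mean())
            Xcols.append(cols - cols.mean())
            names += ["row_lin", "col_lin"]
        self.X = np.column_stack(Xcols)
        self.fixed_names = names

        self.spatial = spatial
        if spatial:
            self.dr = np.abs(rows[:, None] - rows[None, :])
            self.dc = np.abs(cols[:, None] - cols[None, :])
        self.Gg = K.values[np.ix_(li, li)]
        self.Pp = (li[:, None] == li[None, :]).astype(float)
        if layout.block_ids is not None:
            b = layout.block_ids[obs]
            self.Zu = (b[:, None] == b[None, :]).astype(float)
        else:
            self.Zu = None
        self.vy = float(np.var(self.y))
        if self.vy <= 0:
            raise ValueError("phenotypes have zero variance")
        # mean genetic diagonal: ~1 for a trace-normalised kinship, ~marker
        # count for a raw Gram matrix; keeps sigma2_a search scale-free
        self.kdiag_mean = max(float(np.mean(np.diag(self.Gg))), 1e-12)

    def build_H(self, p: dict) -> np.ndarray:
        if self.spatial:
            R = (p["rho_r"] ** self.dr) * (p["rho_c"] ** self.dc)
        else:
            R = np.eye(self.n)
        H = p["sigma2"] * R
        H += p["sigma2_a"] * self.Gg
        H += p["sigma2_p"] * self.Pp
        if self.Zu is not None:
            H += p["sigma2_u"] * self.Zu
        return H

    def loglik(self, p: dict) -> float:
        """Residual log-likelihood (up to an additive constant)."""
        H = self.build_H(p)
        try:
            c, low = linalg.cho_factor(H, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_H = 2.0 * np.sum(np.log(np.diag(c)))
        Hi_y = linalg.cho_solve((c, low), self.y, check_finite=False)
        Hi_X = linalg.cho_solve((c, low), self.X, check_finite=False)
        XtHiX = self.X.T @ Hi_X
        sign, logdet_X = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtHiX, self.X.T @ Hi_y)
        yPy = float(self.y @ Hi_y - (self.X.T @ Hi_y) @ beta)
        return -0.5 * (logdet_H + logdet_X + yPy)

    def solution(self, p: dict):
        """BLUEs, P y and Zg' P y at the parameter values ``p``."""
        H = self.build_H(p)
        c, low = linalg.cho_factor(H, lower=True, check_finite=False)
        Hi_y = linalg.cho_solve((c, low), self.y, check_finite=False)
        Hi_X = linalg.cho_solve((c, low), self.X, check_finite=False)
        XtHiX = self.X.T @ Hi_X
        beta = np.linalg.solve(XtHiX, self.X.T @ Hi_y)
        Py = Hi_y - Hi_X @ beta
        zt_py = np.zeros(self.K.n_lines)
        np.add.at(zt_py, self.line_pos, Py)
        return beta, Py, zt_py


def _default_params(problem: _RemlProblem, has_blocks: bool) -> dict:
    vy = problem.vy
    ka = problem.kdiag_mean
    return {
        "sigma2": 0.4 * vy,
        "sigma2_u": 0.1 * vy if has_blocks else 0.0,
        "sigma2_a": 0.3 * vy / ka,
        "sigma2_p": 0.1 * vy,
        "rho_r": 0.2 if problem.spatial else 0.0,
        "rho_c": 0.2 if problem.spatial else 0.0,
    }


def fit_one_step(y, layout: TrialLayout, K: KinshipMatrix, *,
                 fixed_trend: bool = False, spatial: bool = True,
                 frozen: Optional[dict] = None,
                 max_iter: int = 500) -> FittedModel:
    """REML fit of the one-step genomic prediction model.

    Parameters
    ----------
    y
        Per-plot trait values aligned with ``layout``; NaN marks a missing
        (masked) record and drops the plot from the analysis.
    frozen
        Mapping of parameter names to fixed values; those parameters are not
        estimated.  Used by the training-set protocol to hold non-genetic
        parameters at their full-model estimates.
    spatial
        When False the plot errors are independent and both autocorrelations
        are held at zero.

    Returns a :class:`FittedModel` whose GBLUPs cover every line of ``K``
    (lines without observed plots are predicted through kinship alone).
    """
    frozen = dict(frozen or {})
    problem = _RemlProblem(y, layout, K, fixed_trend=fixed_trend,
                           spatial=spatial)
    has_blocks = problem.Zu is not None

    params = _default_params(problem, has_blocks)
    params.update(frozen)

    free = [n for n in _VARIANCES + _RHOS if n not in frozen]
    if not has_blocks:
        free = [n for n in free if n != "sigma2_u"]
        params["sigma2_u"] = frozen.get("sigma2_u", 0.0)
    if not problem.spatial:
        free = [n for n in free if n not in _RHOS]

    ref = {n: problem.vy for n in _VARIANCES}
    ref["sigma2_a"] = problem.vy / problem.kdiag_mean

    def pack(p):
        x = []
        for name in free:
            if name in _VARIANCES:
                x.append(np.log(max(p[name], VAR_FLOOR * ref[name])))
            else:
                x.append(p[name])
        return np.array(x)

    def unpack(x):
        p = dict(params)
        for name, v in zip(free, x):
            p[name] = float(np.exp(v)) if name in _VARIANCES else float(v)
        return p

    if free:
        bounds = [(np.log(VAR_FLOOR * ref[n]), np.log(1e3 * ref[n]))
                  if n in _VARIANCES else (-RHO_BOUND, RHO_BOUND)
                  for n in free]

        def nll(x):
            return -problem.loglik(unpack(x))

        res = optimize.minimize(nll, pack(params), method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": max_iter,
                                         "ftol": 1e-11, "gtol": 1e-7})
        n_iter = int(res.nit)
        if not res.success:
            # L-BFGS-B line searches can stall at the numeric-gradient noise
            # floor; a derivative-free polish from its iterate settles it
            polish = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8})
            if polish.fun <= res.fun + 1e-6:
                res = polish
                n_iter += int(polish.nit)
            res.x = np.clip(res.x, [b[0] for b in bounds],
                            [b[1] for b in bounds])
        params = unpack(res.x)
        converged = bool(res.success)
        loglik = -float(nll(res.x))
        if not converged:
            logger.warning("REML did not converge in %d iterations: %s",
                           n_iter, res.message)
    else:
        converged, n_iter = True, 0
        loglik = problem.loglik(params)

    pinned = tuple(n for n in free if n in _VARIANCES
                   and params[n] <= 2.0 * VAR_FLOOR * ref[n])
    if pinned:
        logger.info("variance components at the lower bound: %s", pinned)

    beta, _, zt_py = problem.solution(params)
    a_hat = params["sigma2_a"] * (K.values @ zt_py)
    p_hat = params["sigma2_p"] * zt_py
    idx = pd.Index(K.line_ids)
    return FittedModel(
        vc=VarianceComponents(**params),
        fixed_effects=beta,
        fixed_names=problem.fixed_names,
        gblup_additive=pd.Series(a_hat, index=idx),
        gblup_residual_genetic=pd.Series(p_hat, index=idx),
        loglik=float(loglik),
        converged=converged,
        n_iter=n_iter,
        pinned=pinned,
        zt_py=pd.Series(zt_py, index=idx),
    )


#: parameters held at their full-model estimates in training fits
NON_GENETIC = ("sigma2", "sigma2_u", "rho_r", "rho_c")


def fit_training_model(y_masked, layout: TrialLayout, K_t: KinshipMatrix,
                       frozen: dict, *, validation_ids=None,
                       **kwargs) -> FittedModel:
    """Training-set fit: non-genetic parameters frozen, genetic re-estimated.

    ``y_masked`` must have validation records set to NaN; every remaining
    observed plot must map to a line of ``K_t``.  ``frozen`` carries the
    full-model estimates of the non-genetic parameters (residual variance,
    block variance, both autocorrelations).  Only ``sigma2_a`` and
    ``sigma2_p`` are re-estimated.
    """
    missing = [k for k in ("sigma2", "rho_r", "rho_c") if k not in frozen]
    if missing:
        raise ValueError(f"frozen parameters missing: {missing}")
    if validation_ids is not None:
        overlap = set(np.asarray(validation_ids)) & set(K_t.line_ids)
        if overlap:
            raise ValueError(
                f"validation lines present in the training kinship matrix: "
                f"{sorted(overlap)[:5]}"
            )
    frozen = {k: frozen[k] for k in NON_GENETIC if k in frozen}
    return fit_one_step(y_masked, layout, K_t, frozen=frozen, **kwargs)


def backsolve_marker_effects(M_t: GenotypeMatrix, K_t: KinshipMatrix,
                             a_t, *, ridge: bool = False) -> MarkerEffects:
    """Back-solve marker effects from training GBLUPs: q = M' K^-1 a.

    Note the resulting effects carry the kinship scaling constant ``s``:
    ``M q = s a`` for full-rank K.  Downstream accuracies use correlations,
    which are invariant to this scale.

    Parameters
    ----------
    ridge
        When K is numerically singular, add ``1e-6 x mean(diag)`` to the
        diagonal before solving instead of raising.
    """
    order = list(M_t.line_ids)
    if list(K_t.line_ids) != order:
        K_t = K_t.subset(order)
    a = np.asarray(a_t, dtype=float)
    if len(a) != K_t.n_lines:
        raise ValueError("GBLUP vector length does not match kinship")
    V = K_t.values
    try:
        c = linalg.cho_factor(V, lower=True, check_finite=False)
        v = linalg.cho_solve(c, a, check_finite=False)
    except linalg.LinAlgError:
        if not ridge:
            raise linalg.LinAlgError(
                "training kinship matrix is singular; pass ridge=True to "
                "regularise"
            )
        eps = 1e-6 * float(np.mean(np.diag(V)))
        logger.info("singular training kinship: ridge %.3e added", eps)
        c = linalg.cho_factor(V + eps * np.eye(len(V)), lower=True)
        v = linalg.cho_solve(c, a)
    return MarkerEffects(M_t.marker_ids, M_t.calls.T @ v, source="backsolved")


def predict_lines(M_v: GenotypeMatrix, q: MarkerEffects) -> pd.Series:
    """Genomic predictions for validation lines: a_v = M_v q."""
    if len(M_v.marker_ids) != len(q.marker_ids) or \
            not np.array_equal(M_v.marker_ids, q.marker_ids):
        extra = set(M_v.marker_ids) ^ set(q.marker_ids)
        raise ValueError(
            "marker sets of genotypes and effects differ"
            + (f": {sorted(extra)[:5]}" if extra else " in order")
        )
    return pd.Series(M_v.calls @ q.effects, index=pd.Index(M_v.line_ids))


def fit_marker_model(y_masked, layout: TrialLayout, M_t_star: GenotypeMatrix,
                     frozen: dict, *, validation_ids=None,
                     **kwargs) -> MarkerEffects:
    """Reduced-rank marker-effects fit for low marker densities.

    When the marker count falls below the training-line count the kinship
    matrix is rank deficient, so the genetic term is reformulated as
    ``g = M* q + p`` with ``q ~ N(0, sigma2_a I)``.  The covariance
    contribution is then ``sigma2_a M* M*' + sigma2_p I``, which the standard
    solver handles with the raw (unscaled) marker cross-product in place of
    K.  Effects are recovered directly as ``q = sigma2_a M*' Zg' P y``.
    """
    if validation_ids is not None:
        overlap = set(np.asarray(validation_ids)) & set(M_t_star.line_ids)
        if overlap:
            raise ValueError(
                f"validation lines present in the training genotypes: "
                f"{sorted(overlap)[:5]}"
            )
    M = M_t_star.calls
    gram = KinshipMatrix(M_t_star.line_ids, M @ M.T, s=1.0)
    frozen = {k: frozen[k] for k in NON_GENETIC if k in frozen}
    fit = fit_one_step(y_masked, layout, gram, frozen=frozen, **kwargs)
    effects = fit.vc.sigma2_a * (M.T @ fit.zt_py.to_numpy())
    return MarkerEffects(M_t_star.marker_ids, effects, source="direct",
                         model=fit)
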