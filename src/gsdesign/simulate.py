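"""Synthetic breeding-program generator.

Emulates, at configurable (desk) scale, the statistical structure of a large
inbred wheat panel from a commercial breeding program:

* a multi-sub-population panel whose cluster structure is visible in PCA,
  generated by a hierarchical allele-frequency model (ancestral frequencies
  perturbed per population by a drift parameter, Balding-Nichols style);
* successive breeding cohorts within each sub-population, produced serially
  under truncation selection on one designated trait, so that cohort means of
  the selected trait rise and its QTL allele frequencies shift;
* traits of contrasting architecture, from one or two major loci to highly
  polygenic, each with its own heritability;
* a gridded, non-replicated field trial with repeated check plots at a fixed
  interval and plot errors drawn from a separable AR1 x AR1 spatial process.

All randomness flows from a single seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import GenotypeMatrix, KinshipMatrix
from .markers import GeneticMap
from .model import TrialLayout, VarianceComponents

__all__ = [
    "TraitSpec",
    "TrialConfig",
    "SimulationConfig",
    "TruthSet",
    "SyntheticBundle",
    "simulate_panel",
    "simulate_trial",
    "simulate_bundle",
    "simulate_phenotypes_from_components",
    "write_fixture",
]


@dataclass(frozen=True)
class TraitSpec:
    """Genetic architecture of one trait."""

    name: str
    n_qtl: int
    effect_scale: float = 1.0
    h2: float = 0.5  # narrow-sense heritability targeted on the trial

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be positive")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")


#: default architectures: a glaucousness-like major-gene trait, an
#: oligogenic maturity-like trait, a quantitative grain-size trait and a
#: highly polygenic, low-heritability yield-like trait.
DEFAULT_TRAITS = (
    TraitSpec("trait_major", n_qtl=2, h2=0.85),
    TraitSpec("trait_oligo", n_qtl=6, h2=0.70),
    TraitSpec("trait_quant", n_qtl=150, h2=0.60),
    TraitSpec("trait_poly", n_qtl=800, h2=0.35),
)


@dataclass(frozen=True)
class TrialConfig:
    """Field-trial layout and error-process parameters.

    The grid mirrors a long, narrow yield trial: ``n_cols`` ranges wide, as
    many rows as the panel needs.  One plot in every ``check_interval`` is a
    repeated check.  ``rho_r``/``rho_c`` parameterise the separable AR1
    spatial error; ``block_var_frac`` routes that fraction of the
    non-genetic variance into random block effects (contiguous row bands).
    """

    n_cols: int = 24
    n_rows: Optional[int] = None  # None: grown to fit the panel
    check_interval: int = 11
    n_check_lines: int = 3
    rho_r: float = 0.5
    rho_c: float = 0.5
    block_var_frac: float = 0.0
    n_blocks: int = 0

    def __post_init__(self) -> None:
        if self.check_interval < 2:
            raise ValueError("check_interval must be at least 2")
        if not (-1 < self.rho_r < 1 and -1 < self.rho_c < 1):
            raise ValueError("autocorrelations must lie inside (-1, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults give a desk-scale panel of 5 sub-populations x 400 lines
    (2,000 lines), 3,000 markers on 21 chromosomes of 150 cM, four breeding
    cohorts under truncation selection (top 20% retained) on the polygenic
    trait, and four traits of contrasting architecture.
    """

    n_pops: int = 5
    n_lines_per_pop: int = 400
    divergence: float = 0.15          # Wright's F_ST-like drift parameter
    n_cohorts: int = 4
    selection_intensity: float = 0.2  # fraction retained between cohorts
    selected_trait: Optional[str] = "trait_poly"
    n_markers: int = 3000
    n_chromosomes: int = 21
    map_length_cM: float = 150.0
    rare_fraction: float = 0.1        # ancestral-frequency mass near fixation
    divergence_split: float = 0.5     # share of drift at the super-group level
    n_families_per_cohort: int = 20   # crosses within a cohort
    family_divergence: float = 0.3    # within-population family-level drift
    trait_specs: Sequence[TraitSpec] = DEFAULT_TRAITS
    trial: TrialConfig = TrialConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence must lie in (0, 1)")
        if not 0.0 < self.selection_intensity <= 1.0:
            raise ValueError("selection_intensity must lie in (0, 1]")
        for f in ("n_pops", "n_lines_per_pop", "n_cohorts", "n_markers",
                  "n_chromosomes"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


@dataclass
class TruthSet:
    """Ground truth of a simulated panel, for recovery tests."""

    breeding_values: pd.DataFrame        # lines x traits
    qtl: dict                            # trait -> (marker ids, effects)
    population: pd.Series                # per-line population label
    cohort: pd.Series                    # per-line cohort year index
    h2: dict                             # trait -> target heritability


@dataclass
class SyntheticBundle:
    """A full simulated study: panel, map, trial and truth."""

    G: GenotypeMatrix
    genetic_map: GeneticMap
    truth: TruthSet
    layout: TrialLayout
    phenotypes: pd.DataFrame             # plots x traits
    trial_components: dict               # trait -> VarianceComponents used
    config: SimulationConfig


# ---------------------------------------------------------------------------
# panel


def _bn_drift(rng, q: np.ndarray, F: float, size=None) -> np.ndarray:
    """Balding-Nichols frequency perturbation at drift F."""
    if F <= 0:
        return q.copy() if size is None else np.broadcast_to(q, size).copy()
    a, b = q * (1 - F) / F, (1 - q) * (1 - F) / F
    return np.clip(rng.beta(a, b, size=size), 1e-4, 1 - 1e-4)


def _population_frequencies(rng, cfg: SimulationConfig) -> np.ndarray:
    """Per-population allele frequencies under the hierarchical drift model.

    Drift acts at two levels: ancestral frequencies diverge into two
    super-groups (germplasm pools), then into the populations within each
    pool.  ``divergence_split`` apportions the total drift between the
    levels, so clusters are related unevenly, as breeding programs are.
    """
    m = cfg.n_markers
    q0 = rng.uniform(0.05, 0.95, size=m)
    n_rare = int(round(cfg.rare_fraction * m))
    if n_rare:
        rare = rng.choice(m, size=n_rare, replace=False)
        q0[rare] = rng.uniform(0.01, 0.08, size=n_rare)
    F1 = cfg.divergence * cfg.divergence_split
    F2 = cfg.divergence * (1.0 - cfg.divergence_split)
    if cfg.n_pops < 4:
        F1, F2 = 0.0, cfg.divergence
    groups = (_bn_drift(rng, q0, F1), _bn_drift(rng, q0, F1))
    p = np.empty((cfg.n_pops, m))
    for k in range(cfg.n_pops):
        p[k] = _bn_drift(rng, groups[k % 2], F2)
    return p


def _draw_inbred(rng, freqs: np.ndarray, n: int) -> np.ndarray:
    """n fully inbred lines from allele frequencies: calls in {-1, +1}."""
    return np.where(rng.random((n, len(freqs))) < freqs, 1.0, -1.0)


def _selection_response(rng, freqs: np.ndarray, qtl, intensity: float,
                        n_virtual: int = 1000) -> np.ndarray:
    """Allele-frequency response of the parent pool to one selection cycle.

    Truncation selection (top ``intensity`` fraction on true breeding value)
    is evaluated on a large virtual sample of the pool, so successive
    cohorts are near-siblings of a slowly shifting parent population rather
    than a tight parent-child chain — wheat cohorts a year apart come from
    overlapping crossing pools, not from each other.
    """
    pos, eff = qtl
    virt = _draw_inbred(rng, freqs, n_virtual)
    tbv = virt[:, pos] @ eff
    n_keep = max(2, int(round(intensity * n_virtual)))
    if n_keep > n_virtual:
        raise ValueError("truncation selection removed every candidate")
    keep = np.argsort(tbv)[-n_keep:]
    return np.clip((virt[keep].mean(axis=0) + 1.0) / 2.0, 1e-4, 1 - 1e-4)


def _draw_cohort(rng, freqs: np.ndarray, n: int, n_families: int,
                 f_fam: float) -> np.ndarray:
    """One breeding cohort: families (crosses) drawn around cohort frequencies.

    Each family gets its own frequency vector, a Balding-Nichols perturbation
    of the cohort's at drift ``f_fam``; lines within a family share it.  This
    reproduces the strong within-cluster kinship blocks that crosses create
    in a real program.
    """
    if n_families <= 1 or f_fam <= 0:
        return _draw_inbred(rng, freqs, n)
    sizes = np.full(n_families, n // n_families)
    sizes[: n % n_families] += 1
    a = freqs * (1 - f_fam) / f_fam
    b = (1 - freqs) * (1 - f_fam) / f_fam
    parts = []
    for sz in sizes[sizes > 0]:
        fam = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        parts.append(_draw_inbred(rng, fam, int(sz)))
    return np.vstack(parts)


def simulate_panel(config: SimulationConfig):
    """Generate the panel: genotypes, map, labels and ground truth.

    Returns ``(G, genetic_map, truth)`` where ``truth`` carries population
    and cohort labels, per-trait true breeding values and QTL effects.

    Cohorts are produced serially within each sub-population: cohort 0 is
    drawn from the population's drifted allele frequencies; each later cohort
    is drawn from the allele frequencies of the previous cohort's selected
    fraction (truncation selection on the designated trait's true breeding
    values).  With ``selected_trait=None`` cohorts drift without selection.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers

    marker_ids = np.array([f"M{j:05d}" for j in range(m)])
    gmap = _uniform_map(rng, marker_ids, cfg)

    # QTL architecture: the selected trait's loci must exist before the
    # serial cohort generation; the remaining traits get theirs afterwards,
    # restricted to markers that actually segregate in the realised panel
    # (a major-gene trait must display variation, as field traits do)
    def _draw_qtl(spec, candidates):
        n_qtl = min(spec.n_qtl, len(candidates))
        pos = rng.choice(candidates, size=n_qtl, replace=False)
        eff = rng.normal(0.0, spec.effect_scale, size=n_qtl)
        return pos, eff

    names = [s.name for s in cfg.trait_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names")
    sel = cfg.selected_trait
    if sel is not None and sel not in names:
        raise ValueError(f"selected_trait {sel!r} not among trait specs")
    qtl: dict = {}
    for spec in cfg.trait_specs:
        if spec.name == sel:
            qtl[spec.name] = _draw_qtl(spec, np.arange(m))

    pop_freqs = _population_frequencies(rng, cfg)
    n_per_cohort = cfg.n_lines_per_pop // cfg.n_cohorts
    if n_per_cohort < 1:
        raise ValueError("n_lines_per_pop smaller than n_cohorts")

    calls_parts, pops, cohorts = [], [], []
    for k in range(cfg.n_pops):
        freqs = pop_freqs[k].copy()
        for c in range(cfg.n_cohorts):
            n_c = n_per_cohort + (cfg.n_lines_per_pop % cfg.n_cohorts
                                  if c == cfg.n_cohorts - 1 else 0)
            calls = _draw_cohort(rng, freqs, n_c, cfg.n_families_per_cohort,
                                 cfg.family_divergence)
            calls_parts.append(calls)
            pops += [f"P{k + 1}"] * n_c
            cohorts += [c] * n_c
            if sel is not None and c < cfg.n_cohorts - 1:
                freqs = _selection_response(rng, freqs, qtl[sel],
                                            cfg.selection_intensity)

    calls = np.vstack(calls_parts)
    n = len(calls)
    line_ids = np.array([f"L{i:05d}" for i in range(n)])
    G = GenotypeMatrix(line_ids, marker_ids, calls)

    segregating = np.flatnonzero(G.maf >= 0.05)
    if len(segregating) < 2:
        segregating = np.arange(m)
    for spec in cfg.trait_specs:
        if spec.name not in qtl:
            qtl[spec.name] = _draw_qtl(spec, segregating)

    idx = pd.Index(line_ids)
    bv = pd.DataFrame(
        {name: calls[:, pos] @ eff for name, (pos, eff) in qtl.items()},
        index=idx,
    )
    truth = TruthSet(
        breeding_values=bv,
        qtl={name: (marker_ids[pos], eff) for name, (pos, eff) in qtl.items()},
        population=pd.Series(pops, index=idx),
        cohort=pd.Series(cohorts, index=idx),
        h2={spec.name: spec.h2 for spec in cfg.trait_specs},
    )
    return G, gmap, truth


def _uniform_map(rng, marker_ids: np.ndarray, cfg: SimulationConfig) -> GeneticMap:
    m = len(marker_ids)
    base, extra = divmod(m, cfg.n_chromosomes)
    chrom, pos = [], []
    j = 0
    for c in range(cfg.n_chromosomes):
        n_c = base + (1 if c < extra else 0)
        p = np.sort(rng.uniform(0.0, cfg.map_length_cM, size=n_c))
        chrom += [f"C{c + 1:02d}"] * n_c
        pos.append(p)
        j += n_c
    return GeneticMap(marker_ids, np.array(chrom), np.concatenate(pos))


# ---------------------------------------------------------------------------
# trial


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.linalg.cholesky(rho ** d + 1e-10 * np.eye(n))


def _spatial_field(rng, n_rows: int, n_cols: int, rho_r: float,
                   rho_c: float) -> np.ndarray:
    """Unit-variance AR1 x AR1 Gaussian field on the grid."""
    Lr = _ar1_chol(n_rows, rho_r)
    Lc = _ar1_chol(n_cols, rho_c)
    return Lr @ rng.standard_normal((n_rows, n_cols)) @ Lc.T


def grid_layout(line_ids, n_cols: int = 20, *, seed: int = 0) -> TrialLayout:
    """One plot per line on a randomised row-major grid, no checks.

    The minimal layout for parameter-recovery studies where every line is
    phenotyped exactly once.  Plot order is randomised so genetic structure
    is not confounded with the spatial error field.
    """
    line_ids = np.random.default_rng(seed).permutation(np.asarray(line_ids))
    n = len(line_ids)
    idx = np.arange(n)
    return TrialLayout(idx // n_cols, idx % n_cols, line_ids,
                       np.zeros(n, dtype=bool),
                       n_rows=int(np.ceil(n / n_cols)), n_cols=n_cols)


def build_layout(n_test_lines: int, trial: TrialConfig) -> tuple:
    """Grid positions for test and check plots.

    Walks the grid in row-major order placing one check plot in every
    ``check_interval`` plots (checks cycle through the check entries) until
    every test line has a plot.  Returns ``(rows, cols, plot_kind)`` where
    ``plot_kind`` is -1 for a check plot, else the test-line serial number.
    """
    n_checks = math.ceil(n_test_lines / (trial.check_interval - 1))
    n_plots = n_test_lines + n_checks
    n_cols = trial.n_cols
    n_rows = trial.n_rows or math.ceil(n_plots / n_cols)
    if n_rows * n_cols < n_plots:
        raise ValueError(
            f"grid {n_rows}x{n_cols} cannot hold {n_plots} plots "
            f"({n_test_lines} test lines + {n_checks} checks); "
            f"need at least {math.ceil(n_plots / n_cols)} rows"
        )
    rows, cols, kind = [], [], []
    test_i = 0
    for p in range(n_plots):
        rows.append(p // n_cols)
        cols.append(p % n_cols)
        if p % trial.check_interval == 0:
            kind.append(-1)
        else:
            kind.append(test_i)
            test_i += 1
    return np.array(rows), np.array(cols), np.array(kind), n_rows, n_cols


def simulate_trial(G: GenotypeMatrix, truth: TruthSet,
                   trial: TrialConfig = TrialConfig(), *,
                   seed: int = 0):
    """Phenotype the panel in a gridded trial with spatial plot errors.

    The first ``n_check_lines`` panel lines serve as the repeated checks
    (they receive only check plots); every other line is sown once.  For
    each trait the residual and block variances are scaled so that the
    realised narrow-sense heritability among test plots matches the trait's
    target: ``sigma2_ng = var(tbv) (1 - h2) / h2``.

    Returns ``(layout, phenotypes, components)`` with per-plot phenotypes
    (plots x traits) and the per-trait variance components used.
    """
    rng = np.random.default_rng(seed)
    n_chk = trial.n_check_lines
    if G.n_lines <= n_chk:
        raise ValueError("panel smaller than the number of check lines")
    check_ids = G.line_ids[:n_chk]
    # randomised design: plot order must not mirror panel structure
    test_ids = rng.permutation(G.line_ids[n_chk:])

    rows, cols, kind, n_rows, n_cols = build_layout(len(test_ids), trial)
    is_check = kind < 0
    line_per_plot = np.empty(len(kind), dtype=object)
    check_slot = np.cumsum(is_check) - 1
    line_per_plot[is_check] = check_ids[check_slot[is_check] % n_chk]
    line_per_plot[~is_check] = test_ids[kind[~is_check]]
    line_per_plot = line_per_plot.astype(str)

    block_ids = None
    if trial.n_blocks > 0:
        band = math.ceil(n_rows / trial.n_blocks)
        block_ids = np.array([f"B{r // band + 1}" for r in rows])

    layout = TrialLayout(rows, cols, line_per_plot, is_check,
                         n_rows, n_cols, block_ids=block_ids)

    bv = truth.breeding_values
    phen = {}
    components = {}
    for name in bv.columns:
        tbv_plot = bv.loc[line_per_plot, name].to_numpy()
        h2 = truth.h2[name]
        var_g = float(bv.loc[test_ids, name].var())
        sigma_ng = var_g * (1.0 - h2) / h2
        sigma2_u = trial.block_var_frac * sigma_ng if block_ids is not None else 0.0
        sigma2 = max(sigma_ng - sigma2_u, 0.0)
        y = tbv_plot.copy()
        if sigma2 > 0:
            fld = _spatial_field(rng, n_rows, n_cols, trial.rho_r, trial.rho_c)
            y = y + math.sqrt(sigma2) * fld[rows, cols]
        if sigma2_u > 0:
            blocks = np.unique(block_ids)
            be = rng.normal(0.0, math.sqrt(sigma2_u), size=len(blocks))
            lut = dict(zip(blocks, be))
            y = y + np.array([lut[b] for b in block_ids])
        phen[name] = y
        components[name] = VarianceComponents(
            sigma2=sigma2, sigma2_u=sigma2_u, sigma2_a=var_g, sigma2_p=0.0,
            rho_r=trial.rho_r if sigma2 > 0 else 0.0,
            rho_c=trial.rho_c if sigma2 > 0 else 0.0,
        )
    return layout, pd.DataFrame(phen), components


def simulate_phenotypes_from_components(
        K: KinshipMatrix, layout: TrialLayout, vc: VarianceComponents, *,
        seed: int = 0, mu: float = 0.0):
    """Draw one trial phenotype vector from stated variance components.

    Used by parameter-recovery studies: ``a ~ N(0, sigma2_a K)``,
    ``p ~ N(0, sigma2_p I)`` per line, spatial plot error at
    ``(sigma2, rho_r, rho_c)`` and optional block effects.  Returns
    ``(y, a)`` with the simulated additive effects for reference.
    """
    rng = np.random.default_rng(seed)
    n = K.n_lines
    w, V = linalg.eigh(K.values)
    w = np.clip(w, 0.0, None)
    a = V @ (np.sqrt(w * vc.sigma2_a) * rng.standard_normal(n))
    p = rng.normal(0.0, math.sqrt(vc.sigma2_p), size=n) if vc.sigma2_p > 0 \
        else np.zeros(n)
    g = pd.Series(a + p, index=pd.Index(K.line_ids))

    y = mu + g.loc[layout.line_ids].to_numpy()
    if vc.sigma2 > 0:
        fld = _spatial_field(rng, layout.n_rows, layout.n_cols,
                             vc.rho_r, vc.rho_c)
        y = y + math.sqrt(vc.sigma2) * fld[layout.rows, layout.cols]
    if vc.sigma2_u > 0 and layout.block_ids is not None:
        blocks = np.unique(layout.block_ids)
        be = rng.normal(0.0, math.sqrt(vc.sigma2_u), size=len(blocks))
        lut = dict(zip(blocks, be))
        y = y + np.array([lut[b] for b in layout.block_ids])
    return y, pd.Series(a, index=pd.Index(K.line_ids))


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Panel plus trial in one call; the single entry point for experiments."""
    G, gmap, truth = simulate_panel(config)
    layout, phen, comps = simulate_trial(G, truth, config.trial,
                                         seed=config.seed + 1)
    return SyntheticBundle(G, gmap, truth, layout, phen, comps, config)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(bundle: SyntheticBundle, directory, *,
                  overwrite: bool = False) -> dict:
    """Write a bundle to delimited text files that round-trip bit-identically.

    Emits ``genotypes.csv``, ``map.csv``, ``phenotypes.csv`` (layout plus
    trait columns), ``labels.csv`` and ``truth.csv``; returns the path map.
    """
    from . import io  # local import: io depends on the model types

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True"
        )
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.csv",
        "map": directory / "map.csv",
        "phenotypes": directory / "phenotypes.csv",
        "labels": directory / "labels.csv",
        "truth": directory / "truth.csv",
    }
    io.write_genotypes(bundle.G, paths["genotypes"])
    io.write_map(bundle.genetic_map, paths["map"])
    io.write_phenotypes(bundle.layout, bundle.phenotypes, paths["phenotypes"])
    labels = pd.DataFrame({
        "line_id": bundle.truth.population.index,
        "population": bundle.truth.population.to_numpy(),
        "cohort": bundle.truth.cohort.to_numpy(),
    })
    labels.to_csv(paths["labels"], index=False)
    truth_long = bundle.truth.breeding_values.stack().rename("true_value")
    truth_long.index.names = ["line_id", "trait"]
    truth_long.reset_index().to_csv(paths["truth"], index=False)
    return paths
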