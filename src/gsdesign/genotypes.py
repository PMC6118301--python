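"""Genotype containers, allele-frequency filtering and the genomic kinship matrix.

Lines are assumed to come from an inbred (line-breeding) program, so calls are
coded on the homozygote axis: -1 and +1 for the two homozygote classes, 0 for
the rare heterozygote.  The kinship matrix is the raw cross-product
``K = M M' / s`` with the scaling constant ``s = trace(M M') / n`` chosen so
that ``trace(K)`` equals the number of lines, which puts the additive and
residual genetic variance components on comparable scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "encode_genotypes",
    "filter_maf",
    "build_kinship",
]

#: recognised raw coding schemes -> mapping onto the {-1, 0, +1} scale
_CODINGS = {
    "signed": {-1.0: -1.0, 0.0: 0.0, 1.0: 1.0},
    "dosage": {0.0: -1.0, 1.0: 0.0, 2.0: 1.0},
    "ab": {"A": -1.0, "H": 0.0, "B": 1.0},
}


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of biallelic calls on the {-1, 0, +1} scale.

    ``calls`` may contain fractional values for markers where missing calls
    were mean-imputed.  ``maf`` holds the per-marker minor allele frequency
    computed from the pre-imputation calls.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    calls: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        for name, ids in (("line", self.line_ids), ("marker", self.marker_ids)):
            if len(np.unique(ids)) != len(ids):
                dup = _first_duplicate(ids)
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.maf is None:
            self.maf = compute_maf(self.calls)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def line_index(self, ids) -> np.ndarray:
        """Positions of ``ids`` in ``line_ids`` (error on unknown id)."""
        return _index_of(self.line_ids, ids, "line")

    def subset_lines(self, ids) -> "GenotypeMatrix":
        idx = self.line_index(ids)
        return GenotypeMatrix(self.line_ids[idx], self.marker_ids,
                              self.calls[idx], self.maf)

    def subset_markers(self, ids) -> "GenotypeMatrix":
        idx = _index_of(self.marker_ids, ids, "marker")
        return GenotypeMatrix(self.line_ids, self.marker_ids[idx],
                              self.calls[:, idx], self.maf[idx])


@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix with its trace-normalising constant."""

    line_ids: np.ndarray
    values: np.ndarray
    s: float

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match line count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, ids) -> "KinshipMatrix":
        """Restrict to ``ids``; the scaling constant is kept as built."""
        idx = _index_of(self.line_ids, ids, "line")
        return KinshipMatrix(self.line_ids[idx],
                             self.values[np.ix_(idx, idx)], self.s)


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _index_of(universe: np.ndarray, ids, what: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(universe)}
    try:
        return np.array([lookup[i] for i in np.asarray(ids)], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown {what} id: {exc.args[0]!r}") from None


def compute_maf(calls: np.ndarray) -> np.ndarray:
    """Minor allele frequency per marker from {-1, 0, +1} calls.

    Heterozygotes (0) contribute half an allele count to each class; NaNs
    (missing) are ignored.
    """
    calls = np.asarray(calls, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean((calls + 1.0) / 2.0, axis=0)
    return np.minimum(p, 1.0 - p)


def encode_genotypes(raw_calls, line_ids, marker_ids, coding: str = "auto",
                     max_missing: float = 0.2) -> GenotypeMatrix:
    """Map a raw allele table onto the {-1, 0, +1} scale and impute missing calls.

    Parameters
    ----------
    raw_calls
        Lines x markers array.  Accepted codings: ``signed`` (-1/0/+1),
        ``dosage`` (0/1/2) or ``ab`` (A/H/B strings); ``auto`` detects which.
    max_missing
        Markers whose missing-call fraction exceeds this cap are rejected.

    Missing calls (NaN, empty or ``NA``) are imputed to the marker mean after
    coding; the stored MAF is computed before imputation.
    """
    raw = np.asarray(raw_calls)
    if raw.dtype.kind in "UOS":
        coded = _encode_strings(raw, marker_ids)
    else:
        raw = raw.astype(float)
        if coding == "auto":
            vals = raw[np.isfinite(raw)]
            coding = "dosage" if vals.size and vals.max() > 1.0 else "signed"
        mapping = _CODINGS[coding]
        coded = np.full(raw.shape, np.nan)
        for k, v in mapping.items():
            coded[raw == k] = v
        bad = np.isfinite(raw) & np.isnan(coded)
        if bad.any():
            j = int(np.argwhere(bad)[0, 1])
            raise ValueError(
                f"marker {marker_ids[j]!r} has calls outside the "
                f"{coding} coding"
            )

    missing = np.isnan(coded)
    frac = missing.mean(axis=0)
    if (frac >= 1.0).any():
        j = int(np.argmax(frac >= 1.0))
        raise ValueError(f"marker {marker_ids[j]!r} has no observed calls")
    if (frac > max_missing).any():
        j = int(np.argmax(frac > max_missing))
        raise ValueError(
            f"marker {marker_ids[j]!r} exceeds the missing-call cap "
            f"({frac[j]:.2f} > {max_missing})"
        )

    maf = compute_maf(coded)
    if missing.any():
        col_mean = np.nanmean(coded, axis=0)
        coded = np.where(missing, col_mean[None, :], coded)
    return GenotypeMatrix(line_ids, marker_ids, coded, maf)


def _encode_strings(raw: np.ndarray, marker_ids) -> np.ndarray:
    """A/H/B string coding; per-marker check for biallelism."""
    coded = np.full(raw.shape, np.nan)
    alph = {"A": -1.0, "H": 0.0, "B": 1.0, "": np.nan, "NA": np.nan}
    for j in range(raw.shape[1]):
        col = raw[:, j]
        seen = {str(v).strip().upper() for v in col}
        unknown = seen - set(alph)
        if unknown:
            raise ValueError(
                f"marker {marker_ids[j]!r} has more than two alleles or "
                f"unrecognised calls: {sorted(unknown)}"
            )
        coded[:, j] = [alph[str(v).strip().upper()] for v in col]
    return coded


def filter_maf(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Remove markers with MAF strictly below ``threshold``.

    A marker at exactly the threshold is retained.  Marker order is preserved
    and the line set is unchanged.
    """
    keep = G.maf >= threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at {threshold} removed every marker"
        )
    if keep.all():
        return G
    return GenotypeMatrix(G.line_ids, G.marker_ids[keep],
                          G.calls[:, keep], G.maf[keep])


def build_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix K = MM'/s with s = trace(MM')/n.

    The scaling forces ``trace(K) = n_lines``.  Calls must be complete
    (imputation happens in :func:`encode_genotypes`).
    """
    M = G.calls
    if np.isnan(M).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    MMt = M @ M.T
    tr = float(np.trace(MMt))
    n = G.n_lines
    if tr <= 0.0:
        raise ValueError("all-zero marker matrix: kinship undefined")
    if np.allclose(M, M.flat[0]):
        warnings.warn("all genotype calls identical: kinship is degenerate "
                      "(rank one)", stacklevel=2)
    s = tr / n
    return KinshipMatrix(G.line_ids, MMt / s, s)
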