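"""Map-guided marker-density subsetting.

Reduced marker panels are selected to be evenly spread over the genetic map
while carrying high minor allele frequency: the genome is divided into
contiguous centimorgan bins (one per target marker, allocated to chromosomes
in proportion to their map length) and the highest-MAF marker in each bin is
kept.  Summaries follow the conventional density-table layout: marker count,
unique map positions, markers per position, mean interval between unique
positions and mean MAF across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "GeneticMap",
    "MarkerSubset",
    "select_subset",
    "summarize_subset",
    "density_series",
]


@dataclass
class GeneticMap:
    """Marker positions in centimorgans, sorted within chromosome on load."""

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position, dtype=float)
        if not (len(self.chromosome) == len(self.position)
                == len(self.marker_ids)):
            raise ValueError("map columns have inconsistent lengths")
        if len(np.unique(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker id in map")
        if (self.position < 0).any():
            raise ValueError("negative map position")
        order = np.lexsort((self.position, self.chromosome))
        self.marker_ids = self.marker_ids[order]
        self.chromosome = self.chromosome[order]
        self.position = self.position[order]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chromosome": self.chromosome,
            "position_cM": self.position,
        })

    def chromosome_lengths(self) -> pd.Series:
        df = self.frame()
        g = df.groupby("chromosome")["position_cM"]
        return g.max() - g.min()

    def total_length(self) -> float:
        return float(self.chromosome_lengths().sum())


@dataclass
class MarkerSubset:
    """A density-targeted marker selection with its summary row."""

    target_n: int
    marker_ids: np.ndarray
    summary: dict

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids)


def _allocate_bins(lengths: pd.Series, total: int) -> pd.Series:
    """Largest-remainder apportionment of ``total`` bins by map length."""
    if lengths.sum() <= 0:
        # degenerate map: spread evenly
        base = total // len(lengths)
        alloc = pd.Series(base, index=lengths.index)
        for c in lengths.index[: total - base * len(lengths)]:
            alloc[c] += 1
        return alloc
    quota = lengths / lengths.sum() * total
    alloc = np.floor(quota).astype(int)
    short = total - int(alloc.sum())
    remainders = (quota - alloc).sort_values(ascending=False)
    for c in remainders.index[:short]:
        alloc[c] += 1
    return alloc


def select_subset(G: GenotypeMatrix, gmap: GeneticMap,
                  target_n: int) -> MarkerSubset:
    """Pick ``target_n`` markers: per-bin MAF maxima over equal-cM bins.

    Bins are allocated to chromosomes proportionally to map length
    (largest-remainder rounding); within a bin the highest-MAF marker wins,
    ties broken by marker id.  Bins holding no marker are backfilled from
    the globally highest-MAF unselected mapped markers so the subset size
    is exactly ``target_n``.
    """
    panel = set(G.marker_ids)
    mapped = np.array([m in panel for m in gmap.marker_ids])
    map_ids = gmap.marker_ids[mapped]
    map_chrom = gmap.chromosome[mapped]
    map_pos = gmap.position[mapped]
    n_mapped = len(map_ids)
    if target_n > n_mapped:
        raise ValueError(
            f"target {target_n} exceeds the {n_mapped} mapped markers"
        )

    maf_lut = dict(zip(G.marker_ids, G.maf))
    maf = np.array([maf_lut[m] for m in map_ids])

    df = pd.DataFrame({"marker_id": map_ids, "chromosome": map_chrom,
                       "position_cM": map_pos, "maf": maf})
    lengths = (df.groupby("chromosome")["position_cM"]
                 .agg(lambda p: p.max() - p.min()))
    alloc = _allocate_bins(lengths, target_n)

    selected: list = []
    for chrom, sub in df.groupby("chromosome"):
        n_bins = int(alloc.get(chrom, 0))
        if n_bins <= 0:
            continue
        lo, hi = sub["position_cM"].min(), sub["position_cM"].max()
        if hi > lo:
            edges = np.linspace(lo, hi, n_bins + 1)
            which = np.clip(np.searchsorted(edges, sub["position_cM"],
                                            side="right") - 1, 0, n_bins - 1)
        else:
            which = np.zeros(len(sub), dtype=int)
        sub = sub.assign(_bin=which)
        # per bin: highest MAF, ties by marker id (ascending)
        best = (sub.sort_values(["_bin", "maf", "marker_id"],
                                ascending=[True, False, True])
                   .groupby("_bin", sort=True).head(1))
        selected.append(best["marker_id"].to_numpy())
    chosen = np.concatenate(selected) if selected else np.array([], dtype=object)

    deficit = target_n - len(chosen)
    if deficit > 0:
        pool = df[~df["marker_id"].isin(chosen)]
        extra = (pool.sort_values(["maf", "marker_id"],
                                  ascending=[False, True])
                     .head(deficit)["marker_id"].to_numpy())
        chosen = np.concatenate([chosen, extra])

    # preserve panel order for downstream genotype subsetting
    order = {m: i for i, m in enumerate(G.marker_ids)}
    chosen = np.array(sorted(chosen, key=order.__getitem__))
    summary = summarize_subset(chosen, gmap, G)
    return MarkerSubset(target_n, chosen, summary)


def summarize_subset(member_ids, gmap: Optional[GeneticMap],
                     G: GenotypeMatrix) -> dict:
    """Density-table summary of a marker subset.

    ``unique_positions`` counts distinct (chromosome, position) pairs;
    ``markers_per_position`` is their ratio to 2 decimals; ``mean_interval``
    divides the full map length by the unique-position count; ``mean_maf``
    averages MAF across the whole panel.  A map-free subset (the full
    post-filter panel) reports only size and mean MAF.
    """
    member_ids = np.asarray(member_ids)
    maf_lut = dict(zip(G.marker_ids, G.maf))
    mean_maf = float(np.mean([maf_lut[m] for m in member_ids]))
    out = {"n_markers": int(len(member_ids)), "mean_maf": mean_maf}
    if gmap is None:
        out.update(unique_positions=None, markers_per_position=None,
                   mean_interval_cM=None)
        return out
    frame = gmap.frame().set_index("marker_id")
    present = frame.loc[frame.index.intersection(member_ids)]
    uniq = len(present.groupby(["chromosome", "position_cM"]))
    out["unique_positions"] = int(uniq)
    out["markers_per_position"] = round(len(member_ids) / uniq, 2) if uniq else None
    out["mean_interval_cM"] = (gmap.total_length() / uniq) if uniq else None
    return out


def density_series(G: GenotypeMatrix, gmap: GeneticMap,
                   targets: Sequence[int]) -> list:
    """One subset per ascending target plus the full (map-free) panel.

    The final entry is the complete post-MAF-filter marker panel, summarised
    without map statistics, mirroring how a full array panel exceeds its
    consensus map.
    """
    targets = list(targets)
    if sorted(targets) != targets:
        raise ValueError("targets must be ascending")
    subsets = [select_subset(G, gmap, t) for t in targets]
    full = MarkerSubset(G.n_markers, G.marker_ids.copy(),
                        summarize_subset(G.marker_ids, None, G))
    subsets.append(full)
    return subsets
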