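"""Delimited-text readers and writers for the package's data types.

Dialect: comma-separated, UTF-8, "." decimal.  Genotype tables have lines as
rows with a leading ``line_id`` column and marker ids as the header; maps are
three columns (marker, chromosome, cM position); phenotype/layout tables
carry the grid coordinates, line id, check flag, optional block and one
column per trait.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, encode_genotypes
from .markers import GeneticMap
from .model import TrialLayout

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_map", "write_map",
    "read_phenotypes", "write_phenotypes",
    "read_labels", "write_manifest",
]

_LAYOUT_COLS = ["row", "col", "line_id", "is_check"]


def read_genotypes(path, coding: str = "auto",
                   markers=None) -> GenotypeMatrix:
    """Read a genotype table; codings -1/0/+1, 0/1/2 or A/H/B auto-detected.

    ``markers`` optionally restricts the columns to a subset-membership list
    (one marker id per line, or an iterable of ids).
    """
    with open(path) as fh:  # pandas silently renames duplicate columns
        header = fh.readline().rstrip("\n").split(",")[1:]
    seen: set = set()
    for m in header:
        if m in seen:
            raise ValueError(f"duplicate marker id: {m!r}")
        seen.add(m)
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate line id: {dup!r}")
    if markers is not None:
        if isinstance(markers, (str, Path)):
            markers = [ln.strip() for ln in Path(markers).read_text().split()
                       if ln.strip()]
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise KeyError(f"markers absent from genotype file: "
                           f"{missing[:5]}")
        df = df[list(markers)]
    return encode_genotypes(df.to_numpy(), df.index.to_numpy(),
                            df.columns.to_numpy(), coding=coding)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.calls, index=pd.Index(G.line_ids, name="line_id"),
                      columns=G.marker_ids)
    df.to_csv(path)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    need = {"marker_id", "chromosome", "position_cM"}
    if not need <= set(df.columns):
        raise ValueError(f"map file must have columns {sorted(need)}")
    return GeneticMap(df["marker_id"].to_numpy(),
                      df["chromosome"].astype(str).to_numpy(),
                      df["position_cM"].to_numpy())


def write_map(gmap: GeneticMap, path) -> None:
    gmap.frame().to_csv(path, index=False)


def read_phenotypes(path):
    """Read a layout+phenotype table -> (TrialLayout, traits DataFrame)."""
    df = pd.read_csv(path)
    missing = [c for c in _LAYOUT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks layout columns {missing}")
    block = df["block"].to_numpy() if "block" in df.columns else None
    layout = TrialLayout(
        df["row"].to_numpy(), df["col"].to_numpy(),
        df["line_id"].to_numpy(), df["is_check"].to_numpy(dtype=bool),
        n_rows=int(df["row"].max()) + 1, n_cols=int(df["col"].max()) + 1,
        block_ids=block,
    )
    traits = df.drop(columns=_LAYOUT_COLS + (["block"] if block is not None
                                             else []))
    return layout, traits


def write_phenotypes(layout: TrialLayout, traits: pd.DataFrame, path) -> None:
    df = pd.DataFrame({
        "row": layout.rows, "col": layout.cols,
        "line_id": layout.line_ids, "is_check": layout.is_check,
    })
    if layout.block_ids is not None:
        df["block"] = layout.block_ids
    for c in traits.columns:
        df[c] = np.asarray(traits[c])
    df.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Cluster / cohort membership table indexed by line id."""
    return pd.read_csv(path).set_index("line_id")


def write_manifest(path, *, seed, options: dict, outputs: dict,
                   diagnostics: dict | None = None) -> dict:
    """JSON run manifest: seed, options and a hash of every output file."""
    hashes = {}
    for name, p in outputs.items():
        p = Path(p)
        hashes[name] = {
            "path": p.name,
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
        }
    manifest = {"seed": seed, "options": options, "outputs": hashes,
                "diagnostics": diagnostics or {}}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
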