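"""Readers and writers for the pipeline's on-disk formats.

* image stacks — multi-page TIFF, plane-major with interleaved channels
  (shape planes x height x width x channels), plus a JSON sidecar naming
  the channels;
* plate layout — CSV with columns well_id, drug, dose, role, replicate;
* per-organoid measurements — CSV, one row per organoid;
* count matrices — MatrixMarket (genes x cells) with genes/cells text
  files, or a delimited genes x cells table;
* signatures — GMT or two-column (signature, gene) text;
* per-cell truth / condition labels — CSV indexed by cell id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from scipy import io as sio
from scipy import sparse

from .types import ImageStack, OrganoidMeasurement

LAYOUT_COLUMNS = ["well_id", "drug", "dose", "role", "replicate"]


# --------------------------------------------------------------------- TIFF

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF plus a JSON channel sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, metadata={"axes": "ZYXS"})
    sidecar = {
        "channel_names": list(stack.channel_names),
        "layout": "plane-major, channel-interleaved",
        "voxel_size": stack.voxel_size,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path, channel_names: Iterable[str] | None = None) -> ImageStack:
    """Read a stack written by :func:`write_stack` (sidecar optional)."""
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 3:  # single channel
        voxels = voxels[..., None]
    sidecar = path.with_suffix(path.suffix + ".json")
    voxel_size = None
    if channel_names is None:
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            channel_names = meta["channel_names"]
            vs = meta.get("voxel_size")
            voxel_size = tuple(vs) if vs else None
        else:
            channel_names = [f"ch{i}" for i in range(voxels.shape[-1])]
    return ImageStack(voxels=voxels, channel_names=list(channel_names), voxel_size=voxel_size)


# ---------------------------------------------------------------- CSV tables

def write_layout(path: str | Path, layout: pd.DataFrame) -> None:
    layout.loc[:, LAYOUT_COLUMNS].to_csv(path, index=False)


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    missing = set(LAYOUT_COLUMNS) - set(layout.columns)
    if missing:
        raise ValueError(f"layout {path} is missing columns {sorted(missing)}")
    return layout


def write_measurements(
    path: str | Path,
    measurements: Iterable[OrganoidMeasurement],
    per_plane_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write one row per organoid; optionally a long per-plane CSV too."""
    ms = list(measurements)
    table = pd.DataFrame([m.as_row() for m in ms])
    table.to_csv(path, index=False)
    if per_plane_path is not None:
        rows = []
        for m in ms:
            for key, values in m.per_plane.items():
                for plane, value in enumerate(values):
                    rows.append(
                        {"well_id": m.well_id, "plane": plane, "field": key, "value": value}
                    )
        pd.DataFrame(rows).to_csv(per_plane_path, index=False)
    return table


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------- matrices

def write_counts_mtx(dirpath: str | Path, counts: pd.DataFrame) -> None:
    """Write a genes x cells matrix as matrix.mtx + genes.txt + cells.txt."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(dirpath / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    (dirpath / "genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    (dirpath / "cells.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(dirpath: str | Path) -> pd.DataFrame:
    dirpath = Path(dirpath)
    matrix = sio.mmread(dirpath / "matrix.mtx").toarray()
    genes = (dirpath / "genes.txt").read_text().splitlines()
    cells = (dirpath / "cells.txt").read_text().splitlines()
    return pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=cells)


def read_counts_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited genes x cells table (gene names in the first column)."""
    return pd.read_csv(path, sep=sep, engine="python", index_col=0)


# ---------------------------------------------------------------- signatures

def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Read signatures from GMT or two-column (signature<TAB/,>gene) text."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    sig: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            parts = ln.split("\t")
            sig[parts[0]] = [g for g in parts[2:] if g]
        return sig
    for ln in lines:
        parts = [p for p in ln.replace(",", "\t").split("\t") if p.strip()]
        if len(parts) < 2:
            raise ValueError(f"cannot parse signature line: {ln!r}")
        sig.setdefault(parts[0].strip(), []).append(parts[1].strip())
    return sig


def write_signatures(path: str | Path, signatures: dict[str, list[str]]) -> None:
    """Write signatures as GMT."""
    lines = ["\t".join([name, name, *genes]) for name, genes in signatures.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cell_labels(path: str | Path) -> pd.DataFrame:
    """Read a per-cell label CSV indexed by cell id."""
    return pd.read_csv(path, index_col=0)
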