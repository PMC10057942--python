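"""Readers and writers: parameter sets, CSV dialect, legacy VTK, manifests.

CSV dialect: comma-separated, '.' decimal, '#'-prefixed header comment block
echoing the parameters needed to reproduce the run.  3-D label and
concentration fields are written as legacy ASCII VTK STRUCTURED_POINTS files
(one per output time) with CELL_DATA; a matching minimal reader covers the
files this package writes.  Run manifests are JSON with a config echo,
package version and sha256 checksums of every output.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .calibration import DegradationDataset
from .geometry import VoxelGrid
from .kinetics import KineticParameters
from .observables import ReleaseRecord

__all__ = [
    "load_parameter_set",
    "list_parameter_sets",
    "load_activation_energies",
    "params_to_dict",
    "params_from_dict",
    "write_release_csv",
    "read_release_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_vtk_structured_points",
    "read_vtk_structured_points",
    "write_manifest",
]

_PARAM_KEYS = {
    "k1": "k1_per_day",
    "k2": "k2_m3_per_mol_day",
    "d0": "d0_m2_per_day",
    "ce0": "ce0_mol_per_m3",
    "beta": "beta",
    "alpha": "alpha",
    "temperature": "temperature_K",
}


def _packaged_yaml() -> dict:
    text = resources.files("polyerode.data").joinpath("parameter_sets.yaml").read_text()
    return yaml.safe_load(text)


def list_parameter_sets() -> list[str]:
    return sorted(_packaged_yaml()["parameter_sets"])


def load_parameter_set(name: str = "plla_50c") -> KineticParameters:
    """Load a packaged parameter set by name ('plla_50c', 'plga_literature')."""
    sets = _packaged_yaml()["parameter_sets"]
    if name not in sets:
        raise KeyError(f"unknown parameter set {name!r}; have {sorted(sets)}")
    return params_from_dict(sets[name])


def load_activation_energies() -> dict[str, float]:
    """Placeholder activation energies (J/mol) for Arrhenius transfer."""
    return {k: float(v) for k, v in _packaged_yaml()["activation_energies_J_per_mol"].items()}


def params_to_dict(params: KineticParameters) -> dict:
    return {key: float(getattr(params, field)) for field, key in _PARAM_KEYS.items()}


def params_from_dict(d: Mapping) -> KineticParameters:
    kwargs = {field: float(d[key]) for field, key in _PARAM_KEYS.items() if key in d}
    return KineticParameters(**kwargs)


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def _header_block(metadata: Mapping | None) -> str:
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_release_csv(
    path: str | Path,
    records: Iterable[ReleaseRecord],
    metadata: Mapping | None = None,
) -> Path:
    """Release time series as CSV (time_days, group, flux, cumulative)."""
    path = Path(path)
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "time_days": rec.times,
                    "group": rec.group,
                    "flux_mol_per_day": rec.flux,
                    "cumulative_mol": rec.cumulative,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_header_block(metadata))
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_release_csv(path: str | Path) -> list[ReleaseRecord]:
    df = pd.read_csv(path, comment="#")
    out = []
    for group, sub in df.groupby("group", sort=True):
        out.append(
            ReleaseRecord(
                group=str(group),
                times=sub["time_days"].to_numpy(),
                flux=sub["flux_mol_per_day"].to_numpy(),
                cumulative=sub["cumulative_mol"].to_numpy(),
            )
        )
    return out


def write_dataset_csv(
    path: str | Path, dataset: DegradationDataset, metadata: Mapping | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        meta = dict(metadata or {})
        meta.setdefault("temperature_K", dataset.temperature)
        meta.setdefault("rod_radius_m", dataset.radius)
        meta.setdefault("rod_height_m", dataset.height)
        meta.setdefault("mn0_g_per_mol", dataset.mn0)
        fh.write(_header_block(meta))
        dataset.to_dataframe().to_csv(fh, index=False, float_format="%.12g")
    return path


def read_dataset_csv(
    path: str | Path,
    temperature: float | None = None,
    radius: float | None = None,
    height: float | None = None,
) -> DegradationDataset:
    """Read a replicate Mn dataset; header comments supply geometry defaults."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            try:
                meta[key.strip()] = float(val)
            except ValueError:
                pass
    df = pd.read_csv(path, comment="#")
    return DegradationDataset.from_dataframe(
        df,
        temperature=temperature if temperature is not None else meta["temperature_K"],
        radius=radius if radius is not None else meta.get("rod_radius_m", 0.8e-3),
        height=height if height is not None else meta.get("rod_height_m", 6e-3),
        mn0=meta.get("mn0_g_per_mol"),
    )


# --------------------------------------------------------------------------
# legacy VTK structured points
# --------------------------------------------------------------------------

def write_vtk_structured_points(
    path: str | Path,
    grid: VoxelGrid,
    cell_fields: Mapping[str, np.ndarray] | None = None,
    title: str = "polyerode fields",
) -> Path:
    """Legacy ASCII VTK STRUCTURED_POINTS file with CELL_DATA fields.

    The labels are always written; additional per-cell scalar fields (same
    shape as the grid) follow.  Cell data means POINT dimensions are
    ``dims + 1``.
    """
    path = Path(path)
    nx, ny, nz = grid.dims
    h = grid.spacing
    fields = {"labels": grid.labels.astype(float)}
    for name, arr in (cell_fields or {}).items():
        if arr.shape != grid.labels.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid {grid.dims}")
        fields[name] = np.asarray(arr, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}\n")
        fh.write(f"SPACING {h:.9g} {h:.9g} {h:.9g}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\n")
            fh.write("LOOKUP_TABLE default\n")
            flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
            for i in range(0, flat.size, 6):
                fh.write(" ".join(f"{v:.9g}" for v in flat[i : i + 6]) + "\n")
    return path


def read_vtk_structured_points(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    """Minimal reader for the files written by this package.

    Returns (header, fields) where header has dims/origin/spacing and fields
    maps scalar names to (nx, ny, nz) arrays.
    """
    header: dict = {}
    fields: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    dims = None
    current = None
    values: list[float] = []
    n_cells = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("DIMENSIONS"):
            pts = [int(v) for v in line.split()[1:]]
            dims = (pts[0] - 1, pts[1] - 1, pts[2] - 1)
            header["dims"] = dims
        elif line.startswith("ORIGIN"):
            header["origin"] = tuple(float(v) for v in line.split()[1:])
        elif line.startswith("SPACING"):
            header["spacing"] = float(line.split()[1])
        elif line.startswith("CELL_DATA"):
            n_cells = int(line.split()[1])
        elif line.startswith("SCALARS"):
            if current is not None:
                fields[current] = _vtk_reshape(values, dims)
            current = line.split()[1]
            values = []
            i += 1  # skip LOOKUP_TABLE
        elif current is not None and line:
            values.extend(float(v) for v in line.split())
        i += 1
    if current is not None:
        fields[current] = _vtk_reshape(values, dims)
    for name, arr in fields.items():
        if arr.size != n_cells:
            raise ValueError(f"field {name!r} has {arr.size} values, expected {n_cells}")
    return header, fields


def _vtk_reshape(values: list[float], dims) -> np.ndarray:
    nx, ny, nz = dims
    return np.asarray(values).reshape(nz, ny, nx).transpose(2, 1, 0)


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    outputs: Iterable[str | Path],
    extra: Mapping | None = None,
) -> Path:
    from . import __version__

    path = Path(path)
    manifest = {
        "package": "polyerode",
        "version": __version__,
        "config": dict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {str(Path(p).name): sha256_of(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
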