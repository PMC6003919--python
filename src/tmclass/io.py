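"""Bit-stable serialization for every artifact the pipeline produces.

One HDF5 container per run keeps provenance atomic:

* ``/dataset`` — spectra (paired float64 real/imag arrays, index-aligned
  with ``illuminations``), illumination lattice vectors, grid attributes,
  configuration tag;
* ``/truth`` — optional ground-truth ``phi_i``, ``phi_o``, ``g`` from the
  simulator;
* ``/state`` — ``theta_i``, ``theta_o``, ``intensity_trace`` and solver
  metadata;
* ``/config`` — the YAML configuration echoed verbatim.

Complex arrays are stored as paired real/imag float64 datasets for
portability across HDF5 readers; datasets are written without timestamp
tracking so identical payloads produce identical bytes.  Interferogram
stacks export as multi-page 16-bit TIFF with a JSON sidecar carrying the
quantization scale, carrier and grid metadata; phase maps and PSFs export
as float32 TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from numpy.typing import NDArray

from .core import (
    Grid,
    IlluminationSet,
    TransmissionDataset,
    make_grid,
)
from .solver import CorrectionState
from .synth import Interferogram

__all__ = [
    "save_dataset",
    "load_dataset",
    "load_truth",
    "save_state",
    "load_state",
    "save_interferograms",
    "load_interferograms",
    "save_phase_tiff",
    "write_report",
    "load_config",
]

_DS_OPTS = dict(track_times=False)


def _write_complex(group: h5py.Group, name: str, arr: NDArray) -> None:
    arr = np.asarray(arr, dtype=np.complex128)
    group.create_dataset(f"{name}_real", data=arr.real, **_DS_OPTS)
    group.create_dataset(f"{name}_imag", data=arr.imag, **_DS_OPTS)


def _read_complex(group: h5py.Group, name: str) -> NDArray:
    return group[f"{name}_real"][()] + 1j * group[f"{name}_imag"][()]


def _write_grid_attrs(group: h5py.Group, grid: Grid) -> None:
    group.attrs["fov"] = grid.fov
    group.attrs["n"] = grid.n
    group.attrs["wavelength"] = grid.wavelength


def _read_grid_attrs(group: h5py.Group) -> Grid:
    return make_grid(float(group.attrs["fov"]), int(group.attrs["n"]),
                     float(group.attrs["wavelength"]))


def save_dataset(
    path: str | Path,
    dataset: TransmissionDataset,
    truth: dict | None = None,
    config_text: str | None = None,
) -> None:
    """Write a dataset (and optional simulator ground truth / config echo)
    to one HDF5 container."""
    with h5py.File(path, "w") as f:
        g = f.create_group("dataset")
        _write_grid_attrs(g, dataset.grid)
        g.attrs["configuration"] = dataset.configuration
        g.attrs["na_ill"] = dataset.na_ill
        g.attrs["na_col"] = dataset.na_col
        g.attrs["provenance"] = dataset.provenance
        g.create_dataset("illuminations", data=dataset.illuminations.kvecs, **_DS_OPTS)
        _write_complex(g, "spectra", dataset.spectra)
        if truth:
            t = f.create_group("truth")
            for key, arr in truth.items():
                t.create_dataset(key, data=np.asarray(arr), **_DS_OPTS)
        if config_text is not None:
            f.create_dataset("config", data=config_text)


def load_dataset(path: str | Path) -> TransmissionDataset:
    with h5py.File(path, "r") as f:
        if "dataset" not in f:
            raise ValueError(f"{path}: not a tmclass dataset container")
        g = f["dataset"]
        grid = _read_grid_attrs(g)
        na_ill = float(g.attrs["na_ill"])
        illums = IlluminationSet(grid=grid, na_ill=na_ill, kvecs=g["illuminations"][()])
        return TransmissionDataset(
            grid=grid,
            illuminations=illums,
            spectra=_read_complex(g, "spectra"),
            configuration=str(g.attrs["configuration"]),
            na_ill=na_ill,
            na_col=float(g.attrs["na_col"]),
            provenance=str(g.attrs["provenance"]),
        )


def load_truth(path: str | Path) -> dict | None:
    """Ground-truth arrays stored alongside a dataset or state, if any."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            return None
        return {k: f["truth"][k][()] for k in f["truth"]}


def save_state(
    path: str | Path,
    state: CorrectionState,
    configuration: str,
    truth: dict | None = None,
    config_text: str | None = None,
) -> None:
    """Write a correction state (plus the configuration tag of the dataset
    it was computed from, so downstream separation can check pairing)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("state")
        _write_grid_attrs(g, state.grid)
        g.attrs["configuration"] = configuration
        g.attrs["na_ill"] = state.illuminations.na_ill
        g.attrs["na_col"] = state.na_col
        g.attrs["n_iter"] = state.n_iter
        g.attrs["converged"] = state.converged
        g.create_dataset("illuminations", data=state.illuminations.kvecs, **_DS_OPTS)
        g.create_dataset("theta_i", data=state.theta_i, **_DS_OPTS)
        g.create_dataset("theta_o", data=state.theta_o, **_DS_OPTS)
        g.create_dataset("intensity_trace", data=np.asarray(state.intensity_trace), **_DS_OPTS)
        if state.gauge is not None:
            gg = g.create_group("gauge")
            gg.attrs["piston_i"] = state.gauge["piston_i"]
            gg.attrs["piston_o"] = state.gauge["piston_o"]
            gg.create_dataset("tilt", data=state.gauge["tilt"], **_DS_OPTS)
        if truth:
            t = f.create_group("truth")
            for key, arr in truth.items():
                t.create_dataset(key, data=np.asarray(arr), **_DS_OPTS)
        if config_text is not None:
            f.create_dataset("config", data=config_text)


def load_state(path: str | Path) -> tuple[CorrectionState, str]:
    """Read back a correction state; returns (state, configuration tag)."""
    with h5py.File(path, "r") as f:
        if "state" not in f:
            raise ValueError(f"{path}: not a tmclass state container")
        g = f["state"]
        grid = _read_grid_attrs(g)
        illums = IlluminationSet(
            grid=grid, na_ill=float(g.attrs["na_ill"]), kvecs=g["illuminations"][()]
        )
        gauge = None
        if "gauge" in g:
            gauge = {
                "piston_i": float(g["gauge"].attrs["piston_i"]),
                "piston_o": float(g["gauge"].attrs["piston_o"]),
                "tilt": g["gauge"]["tilt"][()],
            }
        state = CorrectionState(
            grid=grid,
            illuminations=illums,
            na_col=float(g.attrs["na_col"]),
            theta_i=g["theta_i"][()],
            theta_o=g["theta_o"][()],
            intensity_trace=list(g["intensity_trace"][()]),
            n_iter=int(g.attrs["n_iter"]),
            converged=bool(g.attrs["converged"]),
            gauge=gauge,
        )
        return state, str(g.attrs["configuration"])


# --------------------------------------------------------------------------
# TIFF
# --------------------------------------------------------------------------

def save_interferograms(
    path: str | Path, holos: list[Interferogram], sidecar_path: str | Path
) -> None:
    """Multi-page 16-bit TIFF (one page per illumination) plus a JSON
    sidecar with the quantization scale, carrier, reference amplitude and
    grid metadata."""
    if not holos:
        raise ValueError("no interferograms to write")
    stack = np.stack([h.intensity for h in holos])
    peak = float(stack.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    pages = np.clip(np.rint(stack / scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    grid = holos[0].grid
    sidecar = {
        "scale": scale,
        "carrier": list(holos[0].carrier),
        "ref_amplitude": holos[0].ref_amplitude,
        "grid": {"fov": grid.fov, "n": grid.n, "wavelength": grid.wavelength},
        "n_pages": len(holos),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def load_interferograms(path: str | Path, sidecar_path: str | Path) -> list[Interferogram]:
    meta = json.loads(Path(sidecar_path).read_text())
    grid = make_grid(**meta["grid"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return [
        Interferogram(
            grid=grid,
            intensity=page.astype(float) * meta["scale"],
            carrier=tuple(meta["carrier"]),
            ref_amplitude=meta["ref_amplitude"],
        )
        for page in pages
    ]


def save_phase_tiff(path: str | Path, phase_map: NDArray) -> None:
    """Float32 TIFF export of a phase map or PSF for visual inspection."""
    tifffile.imwrite(path, np.asarray(phase_map, dtype=np.float32))


# --------------------------------------------------------------------------
# reports and configs
# --------------------------------------------------------------------------

def write_report(path: str | Path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
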