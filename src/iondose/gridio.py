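"""File formats: raw+JSON grids, CSV curves with metadata headers, and
optional DICOM CT import.

Grids (phantoms, dose) are stored as a flat little-endian binary array
next to a JSON sidecar carrying shape, spacing, dtype and run metadata.
Every artifact header records the package version, seed, physics toggles,
mean excitation energies and the calibration checksum, so a result can be
traced to its exact configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .materials import (HUCalibration, VoxelPhantom, build_default_calibration,
                        phantom_from_hu)


def run_metadata(seed: int | None = None, config=None,
                 phantom: VoxelPhantom | None = None,
                 calibration: HUCalibration | None = None) -> dict:
    """Standard metadata block embedded in every output artifact."""
    meta: dict = {"generator": "iondose", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["physics"] = {
            "straggling_model": config.straggling_model,
            "mcs_model": config.mcs_model,
            "nuclear_model": config.nuclear_model,
            "tail_params": list(config.tail_params),
            "delta_threshold_MeV": config.delta_threshold,
            "max_fractional_energy_loss": (
                config.max_fractional_energy_loss_per_step),
        }
        meta["surrogates"] = ["straggling:gaussian-bohr", "mcs:highland",
                              "nuclear:attenuation+tail"]
    if phantom is not None:
        meta["mean_excitation_energies_eV"] = {
            m.name: m.mean_excitation_energy for m in phantom.materials
        }
    if calibration is not None:
        h = hashlib.sha256()
        for s in calibration.segments:
            h.update(f"{s.hu_low},{s.hu_high},{s.material_id},"
                     f"{s.nominal_density},{s.density_slope};".encode())
        meta["calibration_sha256"] = h.hexdigest()[:16]
    return meta


def save_grid(prefix: str | Path, array: np.ndarray,
              spacing_mm: tuple[float, float, float],
              meta: dict | None = None, encoding: str = "value") -> None:
    """Write ``<prefix>.raw`` (little-endian, C order) and
    ``<prefix>.json``."""
    prefix = Path(prefix)
    arr = np.ascontiguousarray(array)
    dtype = "<f8" if arr.dtype.kind == "f" else "<i4"
    arr.astype(dtype).tofile(prefix.with_suffix(".raw"))
    sidecar = {
        "shape": list(arr.shape),
        "spacing_mm": list(spacing_mm),
        "dtype": dtype,
        "encoding": encoding,
        "metadata": meta or {},
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_grid(prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    arr = np.fromfile(prefix.with_suffix(".raw"),
                      dtype=np.dtype(sidecar["dtype"]))
    return arr.reshape(sidecar["shape"]), sidecar


def save_hu_phantom(prefix: str | Path, hu_grid: np.ndarray,
                    spacing_mm: tuple[float, float, float],
                    meta: dict | None = None) -> None:
    save_grid(prefix, np.asarray(hu_grid, dtype=float), spacing_mm, meta,
              encoding="HU")


def load_hu_phantom(prefix: str | Path,
                    calibration: HUCalibration | None = None
                    ) -> VoxelPhantom:
    arr, sidecar = load_grid(prefix)
    if sidecar.get("encoding") != "HU":
        raise ValueError(f"{prefix}: sidecar encoding is not 'HU'")
    return phantom_from_hu(arr, tuple(sidecar["spacing_mm"]), calibration)


def write_curve_csv(path: str | Path, curve, meta: dict | None = None
                    ) -> None:
    """DepthDoseCurve -> CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    lines = [f"# {k}: {json.dumps(v)}" for k, v in (meta or {}).items()]
    import pandas as pd
    df = pd.DataFrame({"depth_mm": curve.depth_centers,
                       "dose": curve.dose,
                       "sigma": curve.statistical_sigma})
    path.write_text("\n".join(lines) + ("\n" if lines else "")
                    + df.to_csv(index=False))


def import_dicom_ct(directory: str | Path) -> tuple[np.ndarray, tuple]:
    """Read a DICOM CT series into a HU grid (x, y, z) plus spacing (mm),
    applying RescaleSlope/RescaleIntercept."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(getattr(s, "SliceLocation",
                                            s.InstanceNumber)))
    hu = np.stack([
        s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
        + float(getattr(s, "RescaleIntercept", 0.0))
        for s in slices
    ], axis=-1).transpose(1, 0, 2)  # (rows, cols, z) -> (x, y, z)
    first = slices[0]
    px = [float(v) for v in first.PixelSpacing]
    dz = float(getattr(first, "SliceThickness", 1.0))
    return hu.astype(float), (px[1], px[0], dz)
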