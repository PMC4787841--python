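"""Reading and writing slices, sinograms, geometry and diagnostics.

Rasters travel as 32-bit float TIFF (tifffile) or as .npy arrays;
geometry as a small YAML document (angle count or explicit list plus
rotation center); ring vectors as one value per line; energy traces as
CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import Image2D, ProjectionGeometry, Sinogram

__all__ = [
    "read_raster",
    "write_raster",
    "read_geometry",
    "write_geometry",
    "write_ring_vector",
    "read_ring_vector",
    "write_energy_trace",
]


def read_raster(path: str | Path) -> np.ndarray:
    """Load a 2-D array from TIFF or .npy, by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    return np.asarray(arr, dtype=np.float64)


def write_raster(path: str | Path, arr: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, np.asarray(arr, dtype=np.float64))
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")


def write_geometry(path: str | Path, geom: ProjectionGeometry) -> None:
    doc = {
        "n_bins": int(geom.n_bins),
        "rotation_center": float(geom.rotation_center),
        "angles_rad": [float(a) for a in geom.angles_rad],
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_geometry(path: str | Path) -> ProjectionGeometry:
    """YAML geometry: either an explicit ``angles_rad`` list or ``n_angles``
    (evenly spaced over [0, π))."""
    doc = yaml.safe_load(Path(path).read_text())
    n_bins = int(doc["n_bins"])
    center = doc.get("rotation_center")
    if "angles_rad" in doc:
        return ProjectionGeometry(tuple(doc["angles_rad"]), n_bins, center)
    return ProjectionGeometry.uniform(int(doc["n_angles"]), n_bins, center)


def sinogram_from_files(raster: str | Path, geometry: str | Path) -> Sinogram:
    return Sinogram(read_raster(raster), read_geometry(geometry))


def write_ring_vector(path: str | Path, u: np.ndarray) -> None:
    """One value per line, detector-bin order."""
    Path(path).write_text("".join(f"{v:.10g}\n" for v in np.asarray(u)))


def read_ring_vector(path: str | Path) -> np.ndarray:
    return np.array([float(x) for x in Path(path).read_text().split()])


def write_energy_trace(path: str | Path, trace: np.ndarray,
                       terms: np.ndarray | None = None) -> None:
    """CSV columns: iteration, fidelity, regularization, ring_l1, total."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "fidelity", "regularization", "ring_l1", "total"])
        for k, total in enumerate(trace):
            if terms is not None:
                fid, reg, ring = terms[k]
            else:
                fid = reg = ring = float("nan")
            w.writerow([k, f"{fid:.10g}", f"{reg:.10g}", f"{ring:.10g}",
                        f"{total:.10g}"])
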