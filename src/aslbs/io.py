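"""NIfTI and configuration I/O.

Complex volumes are stored as paired real/imaginary NIfTI-1 files with
``_real``/``_imag`` suffixes, since complex NIfTI dtypes are not handled
consistently across neuroimaging tools.  Configuration files are YAML or
JSON with unit suffixes spelled out in the key names (``pld_ms``,
``fwhm_mm``) — every time in this package is milliseconds and every
length millimetres, and the keys say so.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import yaml

from .recon import ComplexVolumeSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_complex_series",
    "load_complex_series",
    "load_config",
    "validate_matched_shapes",
]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (3.4, 3.4, 4.0),
) -> Path:
    """Write a real-valued array (3D, or 4D with trailing repetition axis)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), zooms


def _companion_paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    name = base.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            stem = name[: -len(ext)]
            return base.with_name(f"{stem}_real{ext}"), base.with_name(
                f"{stem}_imag{ext}"
            )
    raise ValueError(f"{base} does not look like a NIfTI path (.nii / .nii.gz)")


def save_complex_series(
    series: ComplexVolumeSeries, base_path: str | Path
) -> tuple[Path, Path]:
    """Write a complex series as ``<base>_real`` / ``<base>_imag`` NIfTIs.

    Repetitions go to the 4th NIfTI dimension (x, y, z, rep); a
    single-repetition series is written as a plain 3D volume.
    """
    real_p, imag_p = _companion_paths(base_path)
    data = np.moveaxis(series.data, 0, -1)  # (x, y, z, rep)
    if data.shape[-1] == 1:
        data = data[..., 0]
    save_volume(np.real(data), real_p, series.voxel_size)
    save_volume(np.imag(data), imag_p, series.voxel_size)
    return real_p, imag_p


def load_complex_series(
    base_path: str | Path, role: str = "control"
) -> ComplexVolumeSeries:
    """Read a ``_real``/``_imag`` NIfTI pair back into a complex series."""
    real_p, imag_p = _companion_paths(base_path)
    if not real_p.exists():
        raise FileNotFoundError(f"missing real-part file {real_p}")
    if not imag_p.exists():
        raise FileNotFoundError(
            f"missing imaginary companion {imag_p}; if the data are "
            "magnitude-only, load with load_volume and use the magnitude "
            "reconstruction pathway instead"
        )
    real, vs = load_volume(real_p)
    imag, vs_i = load_volume(imag_p)
    if real.shape != imag.shape:
        raise ValueError(
            f"real part {real.shape} ({real_p.name}) does not match "
            f"imaginary part {imag.shape} ({imag_p.name})"
        )
    data = real + 1j * imag
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return ComplexVolumeSeries(data=data, voxel_size=vs, role=role)


def validate_matched_shapes(**named_series: ComplexVolumeSeries) -> None:
    """Raise naming the offending input if spatial shapes disagree."""
    items = list(named_series.items())
    ref_name, ref = items[0]
    for name, series in items[1:]:
        if series.spatial_shape != ref.spatial_shape:
            raise ValueError(
                f"{name} spatial shape {series.spatial_shape} does not match "
                f"{ref_name} {ref.spatial_shape}"
            )
    ctrl = named_series.get("control")
    lab = named_series.get("label")
    if ctrl is not None and lab is not None and ctrl.n_rep != lab.n_rep:
        raise ValueError(
            f"control has {ctrl.n_rep} repetitions but label has {lab.n_rep}"
        )


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
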