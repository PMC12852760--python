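"""File formats: RF shape text files, NIfTI / TIFF image stacks, configs.

Shape files are plain two-column text (one sample per line) with a ``#``
comment header carrying duration, peak amplitude and labelling metadata.
Two dialects are written:

* ``two-column``: amplitude in rad/s, unwrapped phase in rad;
* ``normalized``: amplitude as a fraction of peak in [0, 1], phase in
  degrees wrapped to [0, 360) -- the vendor-style form, with the wrap
  count recoverable from the stated convention only for slowly varying
  phase, so the reader of this dialect returns the wrapped track.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .waveforms import RFShape

SHAPE_DIALECTS = ("two-column", "normalized")


def export_shape(shape: RFShape, path, dialect: str = "two-column") -> Path:
    """Write a shape file; returns the path written."""
    if dialect not in SHAPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SHAPE_DIALECTS}")
    if shape.n_samples == 0:
        raise ValueError("cannot export an empty shape")
    path = Path(path)
    phase = shape.phase
    if dialect == "two-column":
        amp_col, ph_col = shape.amplitude, phase
    else:
        peak = shape.peak_amplitude or 1.0
        amp_col = shape.amplitude / peak
        ph_col = np.degrees(phase) % 360.0
    header = [
        "# raffsim shape file",
        f"# dialect={dialect}",
        f"# label={shape.label}",
        f"# n_samples={shape.n_samples}",
        f"# dt_s={float(shape.dt)!r}",
        f"# duration_s={float(shape.duration)!r}",
        f"# peak_rad_s={float(shape.peak_amplitude)!r}",
        "# columns: amplitude phase"
        + (" (rad/s, rad)" if dialect == "two-column" else " (fraction, deg)"),
    ]
    body = "\n".join(f"{a:.12e} {p:.12e}" for a, p in zip(amp_col, ph_col))
    path.write_text("\n".join(header) + "\n" + body + "\n")
    return path


def read_shape(path) -> RFShape:
    """Read a shape file written by :func:`export_shape`.

    Blank lines and ``#`` comments are tolerated anywhere.  Malformed
    content raises ValueError naming the offending line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    amps: list[float] = []
    phases: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            amps.append(float(parts[0]))
            phases.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not amps:
        raise ValueError(f"{path}: no samples found")
    dialect = meta.get("dialect", "two-column")
    try:
        dt = float(meta["dt_s"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing dt_s header") from exc
    n_expect = meta.get("n_samples")
    if n_expect is not None and int(n_expect) != len(amps):
        raise ValueError(
            f"{path}: truncated file: header says {n_expect} samples, found {len(amps)}"
        )
    amp = np.asarray(amps)
    ph = np.asarray(phases)
    if dialect == "normalized":
        peak = float(meta.get("peak_rad_s", 1.0))
        amp = amp * peak
        ph = np.radians(ph)
    return RFShape.from_amp_phase(amp, ph, dt, label=meta.get("label", ""))


def write_stack_nifti(stack: np.ndarray, path, voxel_mm: float = 1.0) -> Path:
    """Write a (time, rows, cols) stack as NIfTI (stored rows x cols x time)."""
    path = Path(path)
    stack = np.asarray(stack)
    data = np.moveaxis(stack, 0, -1) if stack.ndim == 3 else stack
    img = nib.Nifti1Image(data.astype(np.float64), affine=np.diag([voxel_mm] * 3 + [1.0]))
    nib.save(img, str(path))
    return path


def read_stack_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return np.moveaxis(data, -1, 0) if data.ndim == 3 else data


def write_stack_tiff(stack: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32), photometric='minisblack')
    return path


def read_stack_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_provenance(path, config: dict, seed: int | None, extras: dict | None = None) -> Path:
    """JSON sidecar sufficient to re-run the artifact next to it."""
    import numpy
    import scipy

    from . import __version__

    path = Path(path)
    payload = {
        "raffsim_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "seed": seed,
        "config": config,
    }
    if extras:
        payload.update(extras)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
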