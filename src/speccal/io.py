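"""File readers/writers and configuration handling.

Formats are deliberately plain text:

* spectrum files -- 1 or 2 delimited columns (intensity, or
  pixel,intensity with contiguous 1..n indices); an optional header row is
  auto-skipped; comma/tab/whitespace delimiters are auto-detected.
* line-list files -- delimited text with a header naming at least a
  ``wavelength_nm`` column; ``uncertainty_nm`` and ``label`` are optional.
* spectrometer configuration -- flat ``key = value`` text with instrument
  units (mm, um, degrees, lines/mm) converted here to the model's
  canonical nm/radians.  Unknown keys are rejected with their location.

Calibration tables are written at full double precision so a re-read is
bit-exact.  Four packaged instrument
configurations and two lamp line lists ship under ``speccal/data``.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult
from .errors import ConfigError, ValidationError
from .optics_model import SpectrometerParams
from .peaks import LampLineList, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_lines",
    "read_config",
    "params_from_config",
    "write_calibration",
    "read_calibration_table",
    "packaged_config",
    "packaged_lines",
    "PACKAGED_CONFIGS",
    "PACKAGED_LINE_LISTS",
]

PACKAGED_CONFIGS = (
    "czerny_turner_300",
    "czerny_turner_600",
    "czerny_turner_1000",
    "transmission_2455",
)
PACKAGED_LINE_LISTS = ("neon_nist_air", "krypton_synthetic")

_CONFIG_KEYS = {
    "focal_length_mm": float,
    "pixel_pitch_um": float,
    "grating_lines_per_mm": float,
    "half_deviation_deg": float,
    "grating_angle_deg": float,
    "grating_type": str,
    "diffraction_order": int,
    "n_pixels": int,
    "center_offset_um": float,
    # optional: overrides the grating_type -> sign mapping for fixed
    # transmission instruments whose detector sits on the diffracted arm
    "model_sign": int,
}
_REQUIRED_KEYS = set(_CONFIG_KEYS) - {"model_sign"}


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [c.strip() for c in line.split(",")]
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    return line.split()


def read_spectrum(path) -> Spectrum:
    """Read a 1- or 2-column delimited spectrum file."""
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = _split_row(line)
            try:
                values = [float(c) for c in cells]
            except ValueError:
                if not rows:  # header row
                    continue
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            if width is None:
                width = len(values)
                if width not in (1, 2):
                    raise ValidationError(
                        f"{path}:{lineno}: expected 1 or 2 columns, got {width}"
                    )
            elif len(values) != width:
                raise ValidationError(
                    f"{path}:{lineno}: inconsistent column count"
                )
            rows.append(values)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if width == 2:
        pix = arr[:, 0]
        if not np.array_equal(pix, np.arange(1, len(pix) + 1)):
            raise ValidationError(
                f"{path}: pixel column must be contiguous 1..{len(pix)}"
            )
        intens = arr[:, 1]
    else:
        intens = arr[:, 0]
    if np.any(intens < 0):
        bad = int(np.flatnonzero(intens < 0)[0])
        raise ValidationError(f"{path}: negative intensity at pixel {bad + 1}")
    return Spectrum(intens, meta={"source": str(path)})


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as comma-delimited (pixel, intensity) text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pixel,intensity\n")
        for p, v in zip(spectrum.pixels, spectrum.intensities):
            fh.write(f"{p},{v:.12g}\n")


def read_lines(path) -> LampLineList:
    """Read a lamp line list; sorts (with a warning) if needed."""
    path = Path(path)
    df = None
    for sep in (",", "\t", r"\s+"):
        try:
            candidate = pd.read_csv(path, sep=sep, engine="python", comment="#")
        except Exception:
            continue
        df = candidate
        if "wavelength_nm" in candidate.columns:
            break
    if df is None:
        raise ValidationError(f"{path}: cannot parse line list")
    if "wavelength_nm" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'wavelength_nm'")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    unc = (
        df["uncertainty_nm"].to_numpy(dtype=float)
        if "uncertainty_nm" in df.columns
        else None
    )
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    order = np.argsort(lam)
    if not np.array_equal(order, np.arange(lam.size)):
        import warnings

        warnings.warn(f"{path}: line list was not sorted; sorting", UserWarning)
        lam = lam[order]
        unc = unc[order] if unc is not None else None
        labels = [labels[i] for i in order] if labels is not None else None
    return LampLineList(lam, unc, labels, name=path.stem)


def read_config(path) -> dict:
    """Parse a flat key-value spectrometer configuration file."""
    path = Path(path)
    raw: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, value = line.partition(sep)
                    break
            else:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = key.strip(), value.strip()
            if key not in _CONFIG_KEYS:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            if key in raw:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            raw[key] = value
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing keys {sorted(missing)}")
    out: dict = {}
    for key, value in raw.items():
        typ = _CONFIG_KEYS[key]
        try:
            out[key] = typ(value)
        except ValueError:
            raise ConfigError(f"{path}: key {key!r} has invalid value {value!r}") from None
    if out["grating_type"] not in ("reflection", "transmission"):
        raise ConfigError(
            f"{path}: grating_type must be 'reflection' or 'transmission'"
        )
    return out


def params_from_config(config: dict) -> SpectrometerParams:
    """Build canonical-unit model parameters from a parsed configuration.

    ``grating_type`` maps to the grating-equation sign (+1 transmission on
    the straight-through axis, -1 reflection); an explicit ``model_sign``
    overrides it (needed for fixed transmission gratings whose detector
    sits on the first-order arm; see the optics-model docs).
    """
    k = +1 if config["grating_type"] == "transmission" else -1
    k = config.get("model_sign", k)
    return SpectrometerParams(
        f=config["focal_length_mm"] * 1e6,
        T=config["pixel_pitch_um"] * 1e3,
        C=config["center_offset_um"] * 1e3,
        d_eff=1e6 / config["grating_lines_per_mm"],
        alpha=math.radians(config["half_deviation_deg"]),
        theta_d=math.radians(config["grating_angle_deg"]),
        k=k,
        n_order=config["diffraction_order"],
        n_pixels=config["n_pixels"],
    )


def write_calibration(
    result: CalibrationResult, prefix, *, seed: int | None = None, extra: dict | None = None
) -> tuple[Path, Path]:
    """Write the per-pixel table and a key-value report; returns both paths.

    The table is ``{prefix}_calibration.csv`` with exact integer pixels
    1..n and full-precision (round-trippable) wavelengths; the report
    ``{prefix}_report.txt`` records method, grid cell, residual error,
    peak count, per-peak residuals and the seed, so a run is re-readable
    and bit-stable for fixed inputs.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table_path = prefix.with_name(prefix.name + "_calibration.csv")
    report_path = prefix.with_name(prefix.name + "_report.txt")
    with table_path.open("w") as fh:
        fh.write("pixel,wavelength_nm\n")
        for p, lam in enumerate(result.lambda_cal, start=1):
            fh.write(f"{p},{lam:.17g}\n")
    lines = [
        f"method = {result.method}",
        f"err = {result.err:.12g}",
        f"n_peaks = {result.peak_residuals_nm.size}",
        f"monotone = {result.monotone}",
        f"seed = {seed if seed is not None else 'none'}",
    ]
    if result.grid_cell:
        for name, value in result.grid_cell.items():
            lines.append(f"grid_cell.{name} = {value:.12g}")
    if result.params is not None:
        p = result.params
        for name in ("f", "T", "C", "d_eff", "alpha", "theta_d"):
            lines.append(f"params.{name} = {getattr(p, name):.12g}")
        lines.append(f"params.k = {p.k}")
        lines.append(f"params.n_order = {p.n_order}")
        lines.append(f"params.n_pixels = {p.n_pixels}")
    if result.pixel_map is not None:
        lines.append(f"pixel_map.slope = {result.pixel_map.slope:.12g}")
        lines.append(f"pixel_map.intercept = {result.pixel_map.intercept:.12g}")
    lines.append(
        "peak_residuals_nm = "
        + ",".join(f"{r:.6g}" for r in result.peak_residuals_nm)
    )
    for key, value in (extra or {}).items():
        lines.append(f"{key} = {value}")
    report_path.write_text("\n".join(lines) + "\n")
    return table_path, report_path


def read_calibration_table(path) -> np.ndarray:
    """Read back a per-pixel calibration table; returns the wavelength column."""
    df = pd.read_csv(path)
    if list(df.columns) != ["pixel", "wavelength_nm"]:
        raise ValidationError(f"{path}: unexpected calibration table schema")
    if not np.array_equal(df["pixel"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValidationError(f"{path}: pixel column must be 1..n")
    return df["wavelength_nm"].to_numpy(dtype=float)


def _data_path(name: str, suffix: str) -> Path:
    ref = resources.files("speccal.data").joinpath(name + suffix)
    with resources.as_file(ref) as p:
        return Path(p)


def packaged_config(name: str) -> SpectrometerParams:
    """Load one of the packaged instrument configurations by short name."""
    if name not in PACKAGED_CONFIGS:
        raise ValidationError(f"unknown packaged config {name!r}; {PACKAGED_CONFIGS}")
    return params_from_config(read_config(_data_path(name, ".cfg")))


def packaged_lines(name: str) -> LampLineList:
    """Load one of the packaged lamp line lists by short name."""
    if name not in PACKAGED_LINE_LISTS:
        raise ValidationError(f"unknown line list {name!r}; {PACKAGED_LINE_LISTS}")
    return read_lines(_data_path(name, ".csv"))
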