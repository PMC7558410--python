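"""Plain-text readers and writers for correlograms, spectra, Stewart
standards and extrusion experiment descriptors, plus the run configuration.

All tabular dialects are whitespace- or comma-delimited text with
'#'-comment lines and an optional header row; writers emit the same
dialect the readers accept.  Experiment descriptors and configuration use
YAML key-value files.  Malformed rows are reported with their line
numbers.
"""

from __future__ import annotations

import os

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .concentration import ExtrusionPair
from .dls import Correlogram
from .spectra import EmissionSpectrum

__all__ = [
    "ParseError",
    "RunConfig",
    "read_table",
    "read_correlogram",
    "write_correlogram",
    "read_spectrum",
    "write_spectrum",
    "read_standards",
    "write_standards",
    "read_experiment",
    "write_experiment",
]


class ParseError(ValueError):
    """A text input could not be parsed; the message names file and line."""


class RunConfig(BaseModel):
    """Validated analysis configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    wavelength_nm: float = Field(532.0, gt=0)
    angle_deg: float = Field(90.0, gt=0, lt=180)
    refractive_index: float = Field(1.333, ge=1)
    temperature_K: float = Field(293.15, gt=0)
    viscosity_mPas: float = Field(1.002, gt=0)
    cumulants_order: int = Field(2, ge=1, le=2)
    contin_grid_size: int = Field(80, ge=4)
    contin_reg_lambda: float | str = "auto"
    peak_window_nm: float = Field(5.0, gt=0)
    seed: int = 0

    def optical(self):
        from .core import OpticalConfig

        return OpticalConfig(
            wavelength_nm=self.wavelength_nm,
            angle_deg=self.angle_deg,
            refractive_index=self.refractive_index,
            temperature_K=self.temperature_K,
            viscosity_mPas=self.viscosity_mPas,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a key-value mapping")
        return cls(**data)


def _split_row(line: str) -> list[str]:
    line = line.split("#", 1)[0].strip()
    if not line:
        return []
    return line.replace(",", " ").split()


def read_table(
    path: str | os.PathLike, n_columns_min: int, n_columns_max: int | None = None
) -> tuple[np.ndarray, dict[str, str]]:
    """Read a delimited numeric table with '#' comments and optional header.

    Returns the data as a 2-D array plus any ``# key = value`` metadata
    found in the comments.  Rows with the wrong column count or
    non-numeric cells raise :class:`ParseError` naming the line.
    """
    n_columns_max = n_columns_max if n_columns_max is not None else n_columns_min
    rows: list[list[float]] = []
    meta: dict[str, str] = {}
    header_allowed = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = _split_row(raw)
            if not fields:
                continue
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if header_allowed:  # one non-numeric row is taken as the header
                    header_allowed = False
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell in row {fields!r}"
                ) from None
            header_allowed = False
            if not n_columns_min <= len(values) <= n_columns_max:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_columns_min}"
                    + (f"-{n_columns_max}" if n_columns_max != n_columns_min else "")
                    + f" columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows found")
    width = max(len(r) for r in rows)
    if any(len(r) != width for r in rows):
        raise ParseError(f"{path}: inconsistent column counts across rows")
    return np.array(rows, dtype=float), meta


def read_correlogram(path: str | os.PathLike) -> Correlogram:
    """Read a two-column (lag_us, g2) correlogram file."""
    data, _ = read_table(path, 2)
    try:
        return Correlogram(data[:, 0], data[:, 1])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_correlogram(path: str | os.PathLike, c: Correlogram) -> None:
    with open(path, "w") as fh:
        fh.write("# correlogram\nlag_us\tg2\n")
        for t, g in zip(c.lags_us, c.g2):
            fh.write(f"{t:.9g}\t{g:.9g}\n")


def read_spectrum(
    path: str | os.PathLike, excitation_nm: float | None = None
) -> EmissionSpectrum:
    """Read a (wavelength_nm, intensity) spectrum file.

    The excitation wavelength is taken from a ``# excitation_nm = ...``
    comment unless overridden by the ``excitation_nm`` argument.
    """
    data, meta = read_table(path, 2)
    if excitation_nm is None:
        if "excitation_nm" not in meta:
            raise ParseError(
                f"{path}: no excitation wavelength ('# excitation_nm = ...' comment missing)"
            )
        excitation_nm = float(meta["excitation_nm"])
    try:
        return EmissionSpectrum(data[:, 0], data[:, 1], excitation_nm)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectrum(path: str | os.PathLike, spec: EmissionSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# emission spectrum\n# excitation_nm = {spec.excitation_nm:.6g}\n")
        fh.write("wavelength_nm\tintensity\n")
        for w, i in zip(spec.wavelengths_nm, spec.intensities):
            fh.write(f"{w:.9g}\t{i:.9g}\n")


def read_standards(path: str | os.PathLike):
    """Read Stewart standards: (conc_mg_ml, absorbance[, se]) columns.

    Returns (concentrations, absorbances, se) with se = None when absent.
    """
    data, _ = read_table(path, 2, 3)
    se = data[:, 2] if data.shape[1] == 3 else None
    return data[:, 0], data[:, 1], se


def write_standards(path: str | os.PathLike, conc, absorbance, se=None) -> None:
    with open(path, "w") as fh:
        fh.write("# Stewart calibration standards\nconc_mg_ml\tabsorbance")
        fh.write("\tse\n" if se is not None else "\n")
        for i in range(len(conc)):
            row = f"{conc[i]:.9g}\t{absorbance[i]:.9g}"
            if se is not None:
                row += f"\t{se[i]:.9g}"
            fh.write(row + "\n")


_EXPERIMENT_KEYS = {"m0_mg", "v1_ml", "v2_ml", "vt_ml", "d1", "d2"}
_EXPERIMENT_LISTS = {"intensity_extrusion1", "intensity_extrusion2", "buffer_intensity"}


def read_experiment(path: str | os.PathLike) -> ExtrusionPair:
    """Read a YAML extrusion-experiment descriptor into an ExtrusionPair.

    Required scalar keys: m0_mg, v1_ml, v2_ml, vt_ml, d1, d2; required
    lists: intensity_extrusion1 and intensity_extrusion2 (replicate
    readings); optional: buffer_intensity (raw-reading mode with buffer
    subtraction).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: experiment descriptor must be a key-value mapping")
    unknown = set(data) - _EXPERIMENT_KEYS - _EXPERIMENT_LISTS
    if unknown:
        raise ParseError(f"{path}: unknown keys {sorted(unknown)}")
    missing = (_EXPERIMENT_KEYS | {"intensity_extrusion1", "intensity_extrusion2"}) - set(data)
    if missing:
        raise ParseError(f"{path}: missing keys {sorted(missing)}")
    try:
        return ExtrusionPair.from_replicates(
            m0_mg=float(data["m0_mg"]),
            v1_ml=float(data["v1_ml"]),
            v2_ml=float(data["v2_ml"]),
            vt_ml=float(data["vt_ml"]),
            d1=float(data["d1"]),
            d2=float(data["d2"]),
            i1_replicates=data["intensity_extrusion1"],
            i2_replicates=data["intensity_extrusion2"],
            buffer_replicates=data.get("buffer_intensity"),
        )
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_experiment(
    path: str | os.PathLike,
    m0_mg: float,
    v1_ml: float,
    v2_ml: float,
    vt_ml: float,
    d1: float,
    d2: float,
    i1_replicates,
    i2_replicates,
    buffer_replicates=None,
) -> None:
    data = {
        "m0_mg": float(m0_mg),
        "v1_ml": float(v1_ml),
        "v2_ml": float(v2_ml),
        "vt_ml": float(vt_ml),
        "d1": float(d1),
        "d2": float(d2),
        "intensity_extrusion1": [float(x) for x in i1_replicates],
        "intensity_extrusion2": [float(x) for x in i2_replicates],
    }
    if buffer_replicates is not None:
        data["buffer_intensity"] = [float(x) for x in buffer_replicates]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
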