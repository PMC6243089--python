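"""File formats and configuration.

Linear spectra travel as two-column delimited text (wavenumber cm⁻¹,
absorbance) with ``#`` comment lines.  A waiting-time series is a
directory of per-frame delimited matrices plus a ``meta.json`` document
holding the axes, the Tw list, units and provenance — diff-able and
language-neutral.  ``AnalysisConfig`` validates run settings before any
stage executes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .kubo import LinearSpectrum
from .simulate import Spectrum2D, TwSeries2D

__all__ = [
    "read_spectrum_1d",
    "write_spectrum_1d",
    "read_series_2d",
    "write_series_2d",
    "AnalysisConfig",
]


def read_spectrum_1d(path: str | Path) -> LinearSpectrum:
    """Read a two-column text spectrum; either axis order; '#' comments.

    Raises with the offending line number on non-numeric rows or duplicate
    frequencies.
    """
    path = Path(path)
    freqs, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {raw!r}")
            try:
                freqs.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
    freqs = np.array(freqs)
    values = np.array(values)
    order = np.argsort(freqs)
    freqs, values = freqs[order], values[order]
    dup = np.nonzero(np.diff(freqs) == 0)[0]
    if dup.size:
        # report the first duplicate's position in the sorted file order
        bad = freqs[dup[0]]
        raise ValueError(f"{path}: duplicate frequency {bad} cm⁻¹")
    return LinearSpectrum(freqs, values)


def write_spectrum_1d(path: str | Path, spectrum: LinearSpectrum, header: str = "") -> None:
    """Write a spectrum as two-column text (full double precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1  absorbance\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for f, a in zip(spectrum.frequency, spectrum.absorbance):
            fh.write(f"{float(f)!r} {float(a)!r}\n")


def write_series_2d(
    directory: str | Path,
    series: TwSeries2D,
    seed: int | None = None,
    model: dict | None = None,
) -> None:
    """Write a Tw series as ``frame_###.txt`` matrices plus ``meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "omega1_cm1": series.omega1.tolist(),
        "omega3_cm1": series.omega3.tolist(),
        "t_w_ps": series.t_w.tolist(),
        "units": {"axes": "cm^-1", "t_w": "ps", "amplitude": "arbitrary"},
        "frames": [f"frame_{k:03d}.txt" for k in range(len(series))],
        "seed": seed,
        "model": model,
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for k, frame in enumerate(series):
        np.savetxt(
            directory / f"frame_{k:03d}.txt",
            frame.amplitude,
            header=f"t_w = {frame.t_w} ps; rows = omega3, cols = omega1",
        )


def read_series_2d(directory: str | Path) -> TwSeries2D:
    """Read a series directory; validates shapes, frame count and Tw order."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in {directory}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    omega1 = np.asarray(meta["omega1_cm1"], dtype=float)
    omega3 = np.asarray(meta["omega3_cm1"], dtype=float)
    tws = meta["t_w_ps"]
    names = meta["frames"]
    if len(tws) != len(names):
        raise ValueError("t_w list and frame list differ in length")
    if np.any(np.diff(tws) <= 0):
        raise ValueError("waiting times in meta.json are not strictly increasing")
    frames = []
    for tw, name in zip(tws, names):
        fpath = directory / name
        if not fpath.exists():
            raise FileNotFoundError(f"missing frame for t_w = {tw} ps: {name}")
        amp = np.loadtxt(fpath)
        if amp.shape != (omega3.size, omega1.size):
            raise ValueError(
                f"{name}: shape {amp.shape} does not match axes "
                f"({omega3.size}, {omega1.size})"
            )
        frames.append(Spectrum2D(omega1, omega3, float(tw), amp))
    return TwSeries2D(tuple(frames))


class AnalysisConfig(BaseModel):
    """Validated settings for an end-to-end analysis run."""

    series_dir: str | None = None
    linear_path: str | None = None
    fixture: str | None = Field(default=None, pattern="^(wt|l358p|pdx)$")
    noise_sd: float = Field(default=0.0, ge=0.0, le=0.5)
    seed: int = Field(default=0, ge=0, lt=2**31)
    model_selection_alpha: float = Field(default=0.01, gt=0.0, lt=0.5)
    window_factor: float = Field(default=0.6, gt=0.1, le=2.0)
    out_dir: str = "."

    @field_validator("fixture")
    @classmethod
    def _known_fixture(cls, v):
        return v

    def model_post_init(self, __context) -> None:
        if self.fixture is None and self.series_dir is None:
            raise ValueError("either a fixture name or a series directory is required")

    def provenance(self) -> dict:
        payload = self.model_dump()
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        from importlib.metadata import PackageNotFoundError, version

        try:
            pkg_version = version("ir2d")
        except PackageNotFoundError:
            pkg_version = "unknown"
        return {"config": payload, "config_hash": digest, "package_version": pkg_version}
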