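"""Saturation transfer difference (STD) NMR binder calling.

A ligand bound by the RNA receives saturation transferred from the
on-resonance irradiation, so its proton signals are attenuated in the
on-resonance spectrum and survive in the (off − on) difference spectrum.
The calls here are binary: a compound whose 1D spectrum shows usable
proton signals is *testable*; a testable compound is a *binder* when at
least one peak clears the signal-to-noise threshold in its difference
spectrum, outside the solvent windows.

Noise σ is estimated from the raw trace in a signal-free region (default
10–12 ppm); peak detection runs on a 3-point-smoothed trace against the
raw-σ threshold, which suppresses single-point noise spikes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum1D",
    "STDConfig",
    "STDCall",
    "check_testable",
    "difference_spectrum",
    "call_std",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class Spectrum1D:
    """A 1D NMR trace on a uniform, strictly decreasing ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size == 0:
            raise ValueError("empty spectrum")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity arrays must have equal length")
        d = np.diff(self.ppm)
        if not np.all(d < 0):
            raise ValueError("ppm axis must be strictly decreasing")
        if self.ppm.size > 2:
            step = d.mean()
            if np.max(np.abs(d - step)) > 1e-9 * abs(step):
                raise ValueError("ppm axis must be uniformly spaced")

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass(frozen=True)
class STDConfig:
    """Detection settings for testability and binder calls."""

    snr_min: float = 3.0
    noise_region: tuple[float, float] = (10.0, 12.0)  # ppm, signal-free
    excluded_windows: tuple[tuple[float, float], ...] = (
        (4.6, 5.0),  # residual water
        (2.45, 2.55),  # DMSO
    )
    smooth: bool = True
    axis_tol: float = 1e-6  # ppm per point, for difference compatibility


@dataclass
class STDCall:
    compound_id: str
    difference: Spectrum1D | None
    detected_peaks: list[tuple[float, float]]  # (ppm, snr)
    call: str  # binder | non_binder | untestable
    noise_sigma: float


def estimate_noise(spec: Spectrum1D, region: tuple[float, float]) -> float:
    lo, hi = sorted(region)
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not mask.any():
        raise ValueError(f"noise region {region} outside the spectrum axis")
    sigma = float(np.std(spec.intensity[mask]))
    if sigma <= 0:
        # Degenerate (e.g. synthetic noiseless) traces: fall back to a tiny
        # positive sigma so SNRs stay finite.
        sigma = max(float(np.max(np.abs(spec.intensity))) * 1e-12, 1e-300)
    return sigma


def _smooth3(y: np.ndarray) -> np.ndarray:
    kernel = np.ones(3) / 3.0
    out = np.convolve(y, kernel, mode="same")
    # edges see only 2 points; copy raw values to avoid edge artefacts
    out[0], out[-1] = y[0], y[-1]
    return out


def _excluded(ppm: float, windows) -> bool:
    return any(lo <= ppm <= hi for lo, hi in (sorted(w) for w in windows))


def find_signal_peaks(
    spec: Spectrum1D, cfg: STDConfig = STDConfig()
) -> tuple[list[tuple[float, float]], float]:
    """Local maxima above snr_min·σ outside the excluded windows.

    Returns (peaks, sigma) with peaks as (ppm, SNR) pairs; σ comes from
    the raw trace in the configured noise region.
    """
    sigma = estimate_noise(spec, cfg.noise_region)
    trace = _smooth3(spec.intensity) if cfg.smooth else spec.intensity
    idx, props = find_peaks(trace, height=cfg.snr_min * sigma)
    peaks = [
        (float(spec.ppm[i]), float(props["peak_heights"][j] / sigma))
        for j, i in enumerate(idx)
        if not _excluded(float(spec.ppm[i]), cfg.excluded_windows)
    ]
    peaks.sort(key=lambda t: -t[1])
    return peaks, sigma


def check_testable(spectrum: Spectrum1D, cfg: STDConfig = STDConfig()) -> bool:
    """A compound is STD-testable iff its plain 1D spectrum has at least one
    detectable proton peak outside the solvent windows."""
    peaks, _ = find_signal_peaks(spectrum, cfg)
    return bool(peaks)


def difference_spectrum(off: Spectrum1D, on: Spectrum1D) -> Spectrum1D:
    """Pointwise off − on difference; requires matching ppm axes."""
    if len(off) != len(on) or np.max(np.abs(off.ppm - on.ppm)) > STDConfig.axis_tol:
        raise ValueError("incompatible axes between off- and on-resonance spectra")
    meta = {
        "resonance_role": "difference",
        "off_irradiation_ppm": off.meta.get("irradiation_ppm"),
        "on_irradiation_ppm": on.meta.get("irradiation_ppm"),
    }
    return Spectrum1D(ppm=off.ppm.copy(), intensity=off.intensity - on.intensity, meta=meta)


def _noise_region_usable(cfg: STDConfig) -> bool:
    lo, hi = sorted(cfg.noise_region)
    covered = 0.0
    for wlo, whi in (sorted(w) for w in cfg.excluded_windows):
        covered += max(0.0, min(hi, whi) - max(lo, wlo))
    return covered < (hi - lo) - 1e-12


def call_std(
    diff: Spectrum1D, cfg: STDConfig = STDConfig(), compound_id: str = ""
) -> STDCall:
    """Call binder/non_binder from a difference spectrum.

    Binder iff at least one peak reaches SNR ≥ snr_min outside the
    excluded windows; detected peaks are reported with their ppm and SNR.
    """
    if not _noise_region_usable(cfg):
        raise ValueError("noise region lies entirely within the excluded windows")
    peaks, sigma = find_signal_peaks(diff, cfg)
    return STDCall(
        compound_id=compound_id,
        difference=diff,
        detected_peaks=peaks,
        call="binder" if peaks else "non_binder",
        noise_sigma=sigma,
    )


def run_std(
    compound_id: str,
    plain: Spectrum1D,
    off: Spectrum1D | None,
    on: Spectrum1D | None,
    cfg: STDConfig = STDConfig(),
) -> STDCall:
    """Testability gate plus binder call for one compound."""
    if not check_testable(plain, cfg):
        return STDCall(
            compound_id=compound_id,
            difference=None,
            detected_peaks=[],
            call="untestable",
            noise_sigma=estimate_noise(plain, cfg.noise_region),
        )
    if off is None or on is None:
        raise ValueError(f"testable compound {compound_id!r} lacks an STD pair")
    return call_std(difference_spectrum(off, on), cfg, compound_id=compound_id)


def read_spectrum(path, meta: dict | None = None) -> Spectrum1D:
    """Read a two-column (ppm, intensity) text spectrum; comma or whitespace separated."""
    with open(path) as fh:
        text = fh.read()
    delim = "," if "," in text.splitlines()[0] else None
    arr = np.loadtxt(io.StringIO(text), delimiter=delim)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("spectrum file must have exactly two columns (ppm, intensity)")
    return Spectrum1D(ppm=arr[:, 0], intensity=arr[:, 1], meta=meta or {})


def write_spectrum(path, spec: Spectrum1D) -> None:
    np.savetxt(path, np.column_stack([spec.ppm, spec.intensity]), fmt="%.6f,%.8g")
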