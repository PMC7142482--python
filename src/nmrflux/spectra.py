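"""Spectrum data model, preprocessing and alignment for 1D proton NMR.

A :class:`Spectrum` is a strictly monotonic chemical-shift axis (ppm) with
matched real intensities plus sample metadata.  Every transforming operation
appends an entry to ``history`` so the full parameter chain of a processed
spectrum can be audited and replayed.

Preprocessing mirrors standard metabolomics practice: exponential
apodization of the time-domain signal, Fourier transformation, reference-peak
or total-area normalization over the analysis window, removal of unwanted
regions (e.g. the residual water band), and chemical-shift alignment either
globally (FFT cross-correlation against a reference spectrum) or per interval
(icoshift-style co-shifting of each spectrum toward a target).

Shifts are integer grid bins only; vacated edge points repeat the boundary
value so normalized spectra never acquire spurious zeros.  Ties in the
correlation score resolve to the smallest \\|lag\\|, then the negative lag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_REGION = (-0.5, 10.0)
WATER_REGION = (4.5, 5.0)
DEFAULT_MAX_SHIFT = 50


class SpectrumError(ValueError):
    """Invalid spectrum, parameter, or preprocessing request."""


@dataclass
class Fid:
    """Complex time-domain NMR signal with its sampling interval.

    Parameters
    ----------
    signal : complex array
    dwell : seconds per point (> 0)
    """

    signal: np.ndarray
    dwell: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        if self.signal.ndim != 1 or self.signal.size < 2:
            raise SpectrumError("FID must be a 1-D signal with at least 2 points")
        if not self.dwell > 0:
            raise SpectrumError(f"dwell must be positive, got {self.dwell}")


@dataclass
class Spectrum:
    """A 1D spectrum: ppm axis, intensities, metadata and processing history."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise SpectrumError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        if self.ppm.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectrumError("ppm axis must be strictly monotonic")

    # -- helpers ---------------------------------------------------------
    def copy(self) -> "Spectrum":
        return Spectrum(
            self.ppm.copy(), self.intensity.copy(), dict(self.meta), list(self.history)
        )

    def with_history(self, op: str, **params) -> "Spectrum":
        s = self.copy()
        s.history.append({"op": op, **params})
        return s

    def same_grid(self, other: "Spectrum", tol: float = 1e-12) -> bool:
        return self.ppm.size == other.ppm.size and np.allclose(
            self.ppm, other.ppm, atol=tol, rtol=0
        )

    def __len__(self) -> int:
        return self.ppm.size


# ---------------------------------------------------------------------------
# time-domain processing
# ---------------------------------------------------------------------------

def apodize_exponential(fid: Fid, lb: float = 1.0) -> Fid:
    """Exponential line-broadening: point k is weighted by exp(-pi*lb*k*dwell).

    ``lb`` is the line broadening in Hz; 0 leaves the FID unchanged.
    """
    if lb < 0:
        raise SpectrumError(f"line broadening must be >= 0, got {lb}")
    k = np.arange(fid.signal.size)
    weights = np.exp(-np.pi * lb * k * fid.dwell)
    return Fid(fid.signal * weights, fid.dwell)


def fourier_transform(fid: Fid) -> tuple[np.ndarray, np.ndarray]:
    """Frequency axis (Hz) and complex DFT of the FID, zero frequency centered."""
    f = np.fft.fftshift(np.fft.fft(fid.signal))
    freqs = np.fft.fftshift(np.fft.fftfreq(fid.signal.size, d=fid.dwell))
    return freqs, f


def fourier_spectrum(
    fid: Fid, spectrometer_mhz: float = 600.0, center_ppm: float = 4.7, meta: dict | None = None
) -> Spectrum:
    """Real part of the DFT mapped onto a ppm axis.

    The frequency axis is converted to chemical shift via the spectrometer
    frequency (Hz per ppm = MHz) around ``center_ppm`` (carrier position).
    """
    freqs, f = fourier_transform(fid)
    ppm = center_ppm + freqs / spectrometer_mhz
    return Spectrum(
        ppm,
        f.real,
        dict(meta or {}),
        [{"op": "fourier_spectrum", "spectrometer_mhz": spectrometer_mhz, "center_ppm": center_ppm}],
    )


def phase_correct(s: Spectrum) -> Spectrum:
    """Global phase correction hook.

    Synthetic spectra are generated phased, so this is a recorded no-op kept
    for real-data extension.
    """
    return s.with_history("phase_correct", mode="noop")


# ---------------------------------------------------------------------------
# normalization and region handling
# ---------------------------------------------------------------------------

def _window_integral(s: Spectrum, window: Sequence[float]) -> float:
    lo, hi = sorted(window)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise SpectrumError(f"window {window} covers fewer than 2 grid points")
    return float(np.trapezoid(s.intensity[mask], s.ppm[mask]))


def normalize_reference_peak(
    s: Spectrum, ref_window: Sequence[float] = (-0.05, 0.05)
) -> Spectrum:
    """Divide by the integrated intensity over the reference (DSS) window."""
    area = _window_integral(s, ref_window)
    if area <= 0:
        raise SpectrumError(f"reference integral over {ref_window} is {area:g}, must be > 0")
    out = s.with_history("normalize_reference_peak", ref_window=tuple(ref_window))
    out.intensity = out.intensity / area
    return out


def normalize_total_area(s: Spectrum, region: Sequence[float] = DEFAULT_REGION) -> Spectrum:
    """Scale so the integral over the analysis region equals 1."""
    area = _window_integral(s, region)
    if area <= 0:
        raise SpectrumError(f"total area over {region} is {area:g}, must be > 0")
    out = s.with_history("normalize_total_area", region=tuple(region))
    out.intensity = out.intensity / area
    return out


def trim_region(s: Spectrum, keep: Sequence[float]) -> Spectrum:
    """Keep only grid points with ppm inside ``keep`` (inclusive)."""
    lo, hi = sorted(keep)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise SpectrumError(f"trim to {keep} leaves fewer than 2 points")
    out = s.with_history("trim_region", keep=(lo, hi))
    out.ppm = out.ppm[mask]
    out.intensity = out.intensity[mask]
    return out


def exclude_region(s: Spectrum, window: Sequence[float] = WATER_REGION) -> Spectrum:
    """Remove grid points strictly inside ``window`` (water exclusion)."""
    lo, hi = sorted(window)
    mask = ~((s.ppm > lo) & (s.ppm < hi))
    if mask.sum() < 2:
        raise SpectrumError(f"excluding {window} leaves fewer than 2 points")
    out = s.with_history("exclude_region", window=(lo, hi))
    out.ppm = out.ppm[mask]
    out.intensity = out.intensity[mask]
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def shift_intensity(y: np.ndarray, lag: int) -> np.ndarray:
    """Shift by ``lag`` bins toward higher index, repeating the boundary value."""
    n = y.size
    if lag == 0:
        return y.copy()
    out = np.empty_like(y)
    if lag > 0:
        lag = min(lag, n)
        out[lag:] = y[: n - lag]
        out[:lag] = y[0]
    else:
        k = min(-lag, n)
        out[: n - k] = y[k:]
        out[n - k:] = y[-1]
    return out


def _lag_candidates(max_shift: int) -> list[int]:
    # ordered for the tie-break: smallest |lag| first, negative before positive
    return sorted(range(-max_shift, max_shift + 1), key=lambda l: (abs(l), l))


def _best_circular_lag(y: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Lag maximizing the circular cross-correlation, computed by FFT."""
    corr = np.fft.ifft(np.fft.fft(ref) * np.conj(np.fft.fft(y))).real
    best_lag, best_score = 0, None
    for lag in _lag_candidates(min(max_shift, y.size - 1)):
        score = corr[lag % y.size]
        if best_score is None or score > best_score + 1e-12 * max(1.0, abs(best_score)):
            best_lag, best_score = lag, score
    return best_lag


def align_fft(
    s: Spectrum, reference: Spectrum, max_shift: int = DEFAULT_MAX_SHIFT
) -> tuple[Spectrum, int]:
    """Globally align ``s`` to ``reference`` by FFT cross-correlation.

    Returns the shifted spectrum and the integer lag applied (grid bins).
    """
    if not s.same_grid(reference):
        raise SpectrumError("spectra must share the same ppm grid for alignment")
    lag = _best_circular_lag(s.intensity, reference.intensity, max_shift)
    out = s.with_history("align_fft", lag=lag, max_shift=max_shift)
    out.intensity = shift_intensity(out.intensity, lag)
    return out, lag


def _best_segment_lag(seg: np.ndarray, target: np.ndarray, max_shift: int) -> int:
    """Lag maximizing the dot product of the edge-filled shifted segment with target."""
    best_lag, best_score = 0, None
    for lag in _lag_candidates(min(max_shift, seg.size - 1)):
        score = float(np.dot(target, shift_intensity(seg, lag)))
        if best_score is None or score > best_score + 1e-12 * max(1.0, abs(best_score)):
            best_lag, best_score = lag, score
    return best_lag


def align_icoshift(
    spectra: Sequence[Spectrum],
    intervals: Sequence[Sequence[float]],
    target: str | int = "median",
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> tuple[list[Spectrum], np.ndarray]:
    """Interval-wise co-shifting of a spectrum set toward a common target.

    Within each ppm interval every spectrum is independently shifted by the
    integer number of bins (bounded by ``max_shift``) that maximizes its
    cross-correlation with the target restricted to that interval; points
    outside the intervals are untouched.  ``target`` is the pointwise
    ``"median"`` or ``"mean"`` across spectra, or an integer index.

    Returns the aligned spectra and a (n_spectra, n_intervals) lag matrix.
    """
    spectra = list(spectra)
    if not spectra:
        return [], np.zeros((0, len(intervals)), dtype=int)
    grid = spectra[0]
    for s in spectra[1:]:
        if not s.same_grid(grid):
            raise SpectrumError("all spectra must share the same ppm grid")
    ivals = [tuple(sorted(iv)) for iv in intervals]
    for i, a in enumerate(ivals):
        for b in ivals[i + 1:]:
            if a[0] < b[1] and b[0] < a[1]:
                raise SpectrumError(f"intervals {a} and {b} overlap")

    stack = np.vstack([s.intensity for s in spectra])
    if target == "median":
        tgt = np.median(stack, axis=0)
    elif target == "mean":
        tgt = stack.mean(axis=0)
    elif isinstance(target, int):
        tgt = stack[target]
    else:
        raise SpectrumError(f"unknown target {target!r}")

    lags = np.zeros((len(spectra), len(ivals)), dtype=int)
    out = [
        s.with_history("align_icoshift", intervals=ivals, target=target, max_shift=max_shift)
        for s in spectra
    ]
    for j, (lo, hi) in enumerate(ivals):
        mask = (grid.ppm >= lo) & (grid.ppm <= hi)
        if mask.sum() < 2:
            continue
        tseg = tgt[mask]
        for i, s in enumerate(out):
            lag = _best_segment_lag(s.intensity[mask], tseg, max_shift)
            lags[i, j] = lag
            if lag:
                s.intensity[mask] = shift_intensity(s.intensity[mask], lag)
    return out, lags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum_tsv(s: Spectrum, path: str | Path) -> None:
    """Two-column TSV (ppm, intensity)."""
    df = pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_spectrum_tsv(path: str | Path, meta: dict | None = None) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (ppm, intensity)")
    cols = list(df.columns[:2])
    return Spectrum(
        df[cols[0]].to_numpy(float),
        df[cols[1]].to_numpy(float),
        dict(meta or {}),
        [{"op": "read_tsv", "path": str(path)}],
    )


def read_jcamp(path: str | Path, meta: dict | None = None) -> Spectrum:
    """Minimal JCAMP-DX reader for the fixed-point ``(X++(Y..Y))`` XYDATA dialect.

    Supports AFFN (space/comma separated) ordinates with FIRSTX/LASTX/NPOINTS
    and X/YFACTOR scaling.  XUNITS of HZ are converted to ppm when
    ``.OBSERVE FREQUENCY`` (MHz) is present.
    """
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^##([^=]+)=\s*(.*)$", text, flags=re.M):
        fields[m.group(1).strip().upper()] = m.group(2).strip()

    m = re.search(r"^##XYDATA=.*$", text, flags=re.M)
    if m is None:
        raise SpectrumError(f"{path}: no XYDATA block")
    block = text[m.end():]
    end = re.search(r"^##", block, flags=re.M)
    if end:
        block = block[: end.start()]

    ys: list[float] = []
    for line in block.strip().splitlines():
        vals = re.split(r"[,\s]+", line.strip())
        if not vals:
            continue
        # first value on each line is the abscissa; the rest are ordinates
        ys.extend(float(v) for v in vals[1:])
    if not ys:
        raise SpectrumError(f"{path}: empty XYDATA block")

    npoints = int(float(fields.get("NPOINTS", len(ys))))
    firstx = float(fields.get("FIRSTX", 0.0))
    lastx = float(fields.get("LASTX", npoints - 1))
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    if len(ys) != npoints:
        raise SpectrumError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read")
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys) * yfactor
    if fields.get("XUNITS", "").upper() == "HZ":
        freq = fields.get(".OBSERVE FREQUENCY")
        if freq is None:
            raise SpectrumError(f"{path}: XUNITS=HZ but no .OBSERVE FREQUENCY to convert to ppm")
        x = x / float(freq)
    order = np.argsort(x)
    return Spectrum(x[order], y[order], dict(meta or {}), [{"op": "read_jcamp", "path": str(path)}])
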