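"""Summary statistics and pattern diagnostics shared by all models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import fft as sfft
from scipy import signal

from .game import PayoffMatrix, payoffs

__all__ = ["SummaryRecord", "spatial_averages", "PatternDiagnostics", "dominant_mode"]


@dataclass(frozen=True)
class SummaryRecord:
    """Spatial means of densities and density-weighted mean payoffs.

    Payoff averages weight each location by that strategy's density there,
    <p_H> = integral(p_H u) / integral(u); a strategy absent everywhere has
    no payoff average and is reported as NaN.
    """

    mean_u: float
    mean_v: float
    mean_pH: float
    mean_pD: float
    window: Optional[Tuple[float, float]] = None


def spatial_averages(
    u: np.ndarray,
    v: np.ndarray,
    matrix: PayoffMatrix,
    window: Optional[Tuple[float, float]] = None,
) -> SummaryRecord:
    """Summarize a density profile (PDE cells or lattice patch means).

    On a uniform grid the length-normalized integrals reduce to plain means,
    so the same formula serves fields and lattices.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0:
        raise ValueError("empty domain")
    p_h, p_d = payoffs(u, v, matrix)
    tot_u, tot_v = u.sum(), v.sum()
    mean_ph = float(np.sum(p_h * u) / tot_u) if tot_u > 0 else float("nan")
    mean_pd = float(np.sum(p_d * v) / tot_v) if tot_v > 0 else float("nan")
    return SummaryRecord(
        mean_u=float(u.mean()), mean_v=float(v.mean()),
        mean_pH=mean_ph, mean_pD=mean_pd, window=window,
    )


@dataclass(frozen=True)
class PatternDiagnostics:
    mode: int
    peaks: int
    amplitude: float


def _count_peaks(field: np.ndarray) -> float:
    """Full peaks of a zero-flux profile: interior maxima above the spatial
    mean of the 3-point-smoothed field (plateaus of equal samples count
    once), plus one half per boundary maximum above the mean.  A pure
    cos(m pi x/l) profile with even m then counts m/2 full peaks regardless
    of its sign."""
    if field.size < 3:
        return 0.0
    kernel = np.ones(3) / 3.0
    padded = np.concatenate([field[:1], field, field[-1:]])
    smooth = np.convolve(padded, kernel, mode="valid")
    mean = smooth.mean()
    peaks, _ = signal.find_peaks(smooth, height=mean)
    count = float(peaks.size)
    if smooth[0] > smooth[1] and smooth[0] > mean:
        count += 0.5
    if smooth[-1] > smooth[-2] and smooth[-1] > mean:
        count += 0.5
    return count


def dominant_mode(
    field: np.ndarray, boundary: str = "zero-flux", rel_tol: float = 1e-10
) -> PatternDiagnostics:
    """Dominant spatial mode index, peak count, and half-range amplitude.

    Zero-flux profiles are projected on the cos(m pi x/l) basis (DCT-II at
    cell centers is exactly that basis); periodic profiles on the
    cos/sin(2 m pi x/l) basis, reporting the index m of the 2m-convention.
    A flat field reports mode 0 with zero peaks.  Invariant under adding a
    constant and under amplitude scaling.
    """
    field = np.asarray(field, dtype=float)
    if field.size < 8:
        raise ValueError("need at least 8 samples for mode detection")
    centered = field - field.mean()
    scale = np.max(np.abs(centered))
    amplitude = 0.5 * float(field.max() - field.min())
    if scale <= rel_tol * max(1.0, abs(float(field.mean()))):
        return PatternDiagnostics(mode=0, peaks=0, amplitude=amplitude)
    if boundary == "zero-flux":
        coeffs = np.abs(sfft.dct(centered, type=2, norm="ortho"))
    elif boundary == "periodic":
        coeffs = np.abs(sfft.rfft(centered))
    else:
        raise ValueError("boundary must be 'zero-flux' or 'periodic'")
    coeffs[0] = 0.0
    mode = int(np.argmax(coeffs))
    peaks = int(round(_count_peaks(field)))
    return PatternDiagnostics(mode=mode, peaks=peaks, amplitude=amplitude)
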