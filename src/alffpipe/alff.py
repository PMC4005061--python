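"""Amplitude of low-frequency fluctuations (ALFF) and its standardization.

Per voxel, the (detrended) BOLD series is taken to the frequency domain with
a plain DFT — no taper, no zero-padding, transform length equal to the number
of volumes — and the single-sided amplitude spectrum

    a_k = (2 / nt) * |X_k|,   k = 1 .. floor(nt/2)

is averaged over the DFT bins whose frequency k/(nt*TR) falls inside the
low-frequency band (default 0.01-0.08 Hz, both edges inclusive). With this
convention a unit-amplitude sinusoid sitting exactly on an in-band bin
contributes a_k = 1 at that bin. The absolute scale is immaterial for group
analysis: dividing each voxel by the global mean ALFF over the brain mask
(the mALFF map) cancels any fixed positive scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .image_io import BrainMask, ScalarMap, TimeSeriesImage, _require_same_grid

__all__ = ["BandSpec", "AlffResult", "detrend_linear", "band_bins", "compute_alff",
           "standardize_alff", "alff_maps"]

log = logging.getLogger(__name__)

_EDGE_EPS = 1e-12  # absolute slack when a band edge lands exactly on a bin


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz; must sit strictly inside (0, Nyquist)."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")

    def validate_for(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.high_hz >= nyquist:
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz exceeds the Nyquist "
                f"frequency {nyquist:.4g} Hz at TR = {tr} s"
            )


@dataclass
class AlffResult:
    alff: ScalarMap
    malff: ScalarMap
    band: BandSpec
    n_bins: int
    global_mean: float


def detrend_linear(ts: TimeSeriesImage) -> TimeSeriesImage:
    """Remove the per-voxel least-squares line (intercept + slope * t)."""
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to fit a line")
    data = scipy.signal.detrend(ts.data, axis=-1, type="linear")
    return TimeSeriesImage(ts.grid, data, ts.tr)


def band_bins(nt: int, tr: float, band: BandSpec) -> np.ndarray:
    """DFT bin indices k with low <= k/(nt*tr) <= high, both edges inclusive.

    Bin 0 (DC) is never included; candidates run to floor(nt/2).
    """
    band.validate_for(tr)
    k = np.arange(1, nt // 2 + 1)
    freqs = k / (nt * tr)
    sel = k[(freqs >= band.low_hz - _EDGE_EPS) & (freqs <= band.high_hz + _EDGE_EPS)]
    if sel.size == 0:
        raise ValueError(
            f"band ({band.low_hz}, {band.high_hz}) Hz contains no DFT bins "
            f"for nt={nt}, TR={tr} s (bin spacing {1.0 / (nt * tr):.4g} Hz)"
        )
    return sel


def compute_alff(ts: TimeSeriesImage, band: BandSpec, mask: BrainMask) -> ScalarMap:
    """Mean single-sided DFT amplitude over the in-band bins, per masked voxel.

    Voxels outside the mask are set to 0. Constant (zero-variance) series
    inside the mask get ALFF 0 and are counted in the log, not dropped.
    """
    _require_same_grid(ts.grid, mask.grid, "compute_alff")
    bins = band_bins(ts.n_volumes, ts.tr, band)
    nt = ts.n_volumes
    y = ts.data[mask.data]                       # (V, nt)
    n_const = int(np.sum(np.ptp(y, axis=1) == 0))
    if n_const:
        log.info("compute_alff: %d masked voxels have a constant series (ALFF=0)", n_const)
    spec = np.fft.rfft(y, axis=1)
    amp = (2.0 / nt) * np.abs(spec[:, bins])
    out = np.zeros(ts.grid.shape, dtype=np.float64)
    out[mask.data] = amp.mean(axis=1)
    return ScalarMap(ts.grid, out, kind="alff")


def standardize_alff(alff: ScalarMap, mask: BrainMask) -> tuple[ScalarMap, float]:
    """Divide by the global mean ALFF within the brain mask (mALFF).

    Returns the standardized map (mean exactly 1 over the mask, 0 outside)
    together with the divisor that was used.
    """
    _require_same_grid(alff.grid, mask.grid, "standardize_alff")
    vals = alff.data[mask.data]
    if np.any(vals < 0):
        raise ValueError("ALFF map has negative values inside the mask")
    gmean = float(vals.mean())
    if gmean <= 0.0:
        raise ValueError("global mean ALFF within the mask is zero; cannot standardize")
    out = np.zeros_like(alff.data)
    out[mask.data] = vals / gmean
    return ScalarMap(alff.grid, out, kind="malff"), gmean


def alff_maps(
    ts: TimeSeriesImage,
    mask: BrainMask,
    band: BandSpec | None = None,
    detrend: bool = True,
) -> AlffResult:
    """Convenience wrapper: (detrend) -> ALFF -> global-mean standardization."""
    band = band or BandSpec()
    if detrend:
        ts = detrend_linear(ts)
    alff = compute_alff(ts, band, mask)
    malff, gmean = standardize_alff(alff, mask)
    n_bins = band_bins(ts.n_volumes, ts.tr, band).size
    return AlffResult(alff=alff, malff=malff, band=band, n_bins=n_bins, global_mean=gmean)
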