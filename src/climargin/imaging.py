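"""Deterministic image-processing chain for specimen CLI frames.

Stages mirror the intraoperative workflow: pixel binning, gamma-strike
suppression (median then Gaussian), empty-tray background subtraction,
and conversion of photon counts to calibrated radiance maps.

Raster convention: row-major, origin top-left, 0-based (row, col)
indexing, pixel centres at half-integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy import ndimage

from .errors import ContractError, DomainError

FILTER_NONE = "none"
FILTER_SHORTPASS_550 = "shortpass_550"
VALID_FILTERS = (FILTER_NONE, FILTER_SHORTPASS_550)

#: Unbinned pixel pitch [um] chosen so that 2x2 binning gives 234 um pixels.
DEFAULT_UNBINNED_PITCH_UM = 117.0


@dataclass(frozen=True)
class AcquisitionSettings:
    """Exposure, binning and optical-filter state of one acquisition.

    The clinical protocol space is exposures {30, 60, 150, 300} s,
    binning {2, 4, 8} and filter in {none, shortpass_550}; any positive
    exposure and binning >= 1 are accepted.
    """

    exposure_s: float
    binning: int = 2
    optical_filter: str = FILTER_NONE
    unbinned_pitch_um: float = DEFAULT_UNBINNED_PITCH_UM

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise DomainError("exposure_s must be positive")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise DomainError("binning must be a positive integer")
        if self.optical_filter not in VALID_FILTERS:
            raise DomainError(f"optical_filter must be one of {VALID_FILTERS}")
        if self.unbinned_pitch_um <= 0:
            raise DomainError("unbinned_pitch_um must be positive")

    @property
    def binned_pitch_um(self) -> float:
        return self.unbinned_pitch_um * self.binning

    def matches(self, other: "AcquisitionSettings") -> bool:
        """Same exposure, binning and filter (the background-pairing contract)."""
        return (self.exposure_s == other.exposure_s
                and self.binning == other.binning
                and self.optical_filter == other.optical_filter)


@dataclass
class CLIFrame:
    """A photon-count raster with its acquisition metadata.

    Raw frames carry integer-valued counts within the camera bit depth;
    processed frames (filtered/subtracted) carry non-negative floats.
    ``processing_history`` is append-only.
    """

    counts: np.ndarray
    settings: AcquisitionSettings
    acquisition_time: datetime
    kind: str = "specimen"  # or "background"
    view: str | None = None
    processing_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DomainError("counts must be a 2-D raster")
        signed = any(step.endswith(":signed") for step in self.processing_history)
        if not signed and np.any(self.counts < 0):
            raise DomainError("counts must be non-negative")
        if self.kind not in ("specimen", "background"):
            raise DomainError("kind must be 'specimen' or 'background'")

    def evolve(self, counts: np.ndarray, step: str,
               settings: AcquisitionSettings | None = None) -> "CLIFrame":
        return CLIFrame(
            counts=counts,
            settings=settings or self.settings,
            acquisition_time=self.acquisition_time,
            kind=self.kind,
            view=self.view,
            processing_history=[*self.processing_history, step],
        )


@dataclass
class RadianceMap:
    """Calibrated radiance raster in p/s/cm^2/sr."""

    values: np.ndarray
    settings: AcquisitionSettings
    acquisition_time: datetime
    view: str | None = None
    calibration_id: str = "uncalibrated-1.0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise DomainError("radiance values must be non-negative")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bin_pixels(frame: CLIFrame, factor: int) -> CLIFrame:
    """Sum ``factor`` x ``factor`` blocks of pixels (software binning).

    Trailing rows/columns that do not fill a block are cropped; total
    counts over the retained area are conserved exactly. The binned pixel
    pitch scales by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise DomainError("binning factor must be a positive integer")
    if factor == 1:
        return frame.evolve(frame.counts.copy(), "bin:1")
    binned = bin_raster(frame.counts, factor)
    new_settings = replace(frame.settings,
                           binning=frame.settings.binning * factor)
    return frame.evolve(binned, f"bin:{factor}", settings=new_settings)


def bin_raster(raster: np.ndarray, factor: int) -> np.ndarray:
    """Block-sum a raster by ``factor``, cropping non-divisible trailing edges."""
    r, c = raster.shape
    r2, c2 = (r // factor) * factor, (c // factor) * factor
    trimmed = raster[:r2, :c2]
    return trimmed.reshape(r2 // factor, factor, c2 // factor, factor).sum(axis=(1, 3))


def suppress_gamma_strikes(frame: CLIFrame, median_window: int = 3,
                           gaussian_sigma: float = 3.0,
                           order: str = "median_first") -> CLIFrame:
    """Remove sparse high-amplitude gamma strikes and smooth residual noise.

    Default is a 3x3 median followed by a sigma = 3 px Gaussian, both with
    reflecting boundaries. The median is applied first so that impulses
    are deleted before linear smoothing can spread them; ``order`` can be
    set to "gaussian_first" to match the alternative listing order.
    """
    if median_window < 1 or median_window % 2 == 0:
        raise DomainError("median_window must be odd and >= 1")
    if gaussian_sigma < 0:
        raise DomainError("gaussian_sigma must be non-negative")
    if order not in ("median_first", "gaussian_first"):
        raise DomainError("order must be 'median_first' or 'gaussian_first'")
    data = frame.counts.astype(float)
    if order == "median_first":
        if median_window > 1:
            data = ndimage.median_filter(data, size=median_window, mode="reflect")
        if gaussian_sigma > 0:
            data = ndimage.gaussian_filter(data, sigma=gaussian_sigma, mode="reflect")
    else:
        if gaussian_sigma > 0:
            data = ndimage.gaussian_filter(data, sigma=gaussian_sigma, mode="reflect")
        if median_window > 1:
            data = ndimage.median_filter(data, size=median_window, mode="reflect")
    step = f"suppress_strikes:median{median_window},gauss{gaussian_sigma:g},{order}"
    return frame.evolve(data, step)


def subtract_background(frame: CLIFrame, background: CLIFrame,
                        clip_negative: bool = True) -> CLIFrame:
    """Subtract a settings-matched empty-tray background frame.

    The background must share exposure, binning and filter with the
    specimen frame (re-using a background acquired under different
    settings is a contract violation). Negative differences are clamped
    to zero by default since radiance is physical; pass
    ``clip_negative=False`` for signed diagnostic output.
    """
    if background.kind != "background":
        raise ContractError("second argument must be a background frame")
    if not frame.settings.matches(background.settings):
        raise ContractError(
            "background settings (exposure/binning/filter) must match the frame; "
            f"got {frame.settings} vs {background.settings}")
    if frame.counts.shape != background.counts.shape:
        raise ContractError("frame and background shapes differ")
    diff = frame.counts.astype(float) - background.counts.astype(float)
    step = "subtract_background"
    if clip_negative:
        diff = np.maximum(diff, 0.0)
    else:
        step += ":signed"  # diagnostic mode: negatives allowed downstream
    return frame.evolve(diff, step)


def counts_to_radiance(frame: CLIFrame, calibration: float = 1.0,
                       calibration_id: str | None = None) -> RadianceMap:
    """Convert counts to mean radiance: counts / (calibration x exposure).

    ``calibration`` is the device constant in counts per (p/s/cm^2/sr)
    per second for the frame's binned pixel; the default 1.0 yields
    arbitrary-unit radiance (TBRs are invariant to it).
    """
    if calibration <= 0:
        raise DomainError("calibration must be positive")
    values = np.maximum(frame.counts.astype(float), 0.0) / (
        calibration * frame.settings.exposure_s)
    return RadianceMap(
        values=values,
        settings=frame.settings,
        acquisition_time=frame.acquisition_time,
        view=frame.view,
        calibration_id=calibration_id or f"scalar-{calibration:g}",
    )


def process_frame(frame: CLIFrame, background: CLIFrame,
                  calibration: float = 1.0, median_window: int = 3,
                  gaussian_sigma: float = 3.0) -> RadianceMap:
    """Full chain: strike suppression on both frames, subtraction, calibration."""
    f = suppress_gamma_strikes(frame, median_window, gaussian_sigma)
    b = suppress_gamma_strikes(background, median_window, gaussian_sigma)
    return counts_to_radiance(subtract_background(f, b), calibration)
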