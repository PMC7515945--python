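"""Hotspot detection and the filtered/unfiltered persistence margin rule.

A hotspot is a connected region of elevated radiance on an intact-specimen
view. Because short-wavelength Cerenkov light is attenuated much faster
with depth, a hotspot that persists through a 550 nm shortpass filter must
originate close to the excised surface: the view is then called a
suspected positive surgical margin (PSM). A hotspot visible only without
the filter indicates activity further from the margin and the view stays
a negative surgical margin (NSM).

The detector here (mean + k*sd threshold, connected components) is an
algorithmic surrogate for the visual hotspot marking done clinically; it
is fully parameterised so the threshold question can be explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError, DomainError
from .imaging import RadianceMap
from .phantom import GroundTruth

#: 4-connectivity structuring element for hotspot components.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class MarginParams:
    """Tunable knobs of the margin classifier.

    ``tau_persist`` is the filtered-TBR level above which a hotspot
    counts as persistent; 2.0 sits below every histopathology-positive
    filtered TBR observed clinically (>= 2.5) while well above the
    filtered TBR a deep lesion can produce.
    """

    k_sigma: float = 3.0
    min_area_px: int = 4
    tau_persist: float = 2.0


@dataclass
class Hotspot:
    view: str | None
    mask: np.ndarray  # boolean connected component on the binned grid
    core_mask: np.ndarray  # pixels above half the peak excess: the ROI analogue
    peak_radiance: float
    tbr_unfiltered: float
    tbr_filtered: float | None = None
    persistent: bool | None = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class MarginCall:
    view: str | None
    verdict: str  # "PSM_suspected" | "NSM"
    hotspots: list[Hotspot] = field(default_factory=list)
    rationale: str = ""


def estimate_background_stats(radiance_map: RadianceMap, clip_sigma: float = 3.0,
                              n_iter: int = 5) -> tuple[float, float]:
    """Sigma-clipped mean and sd of a map: a robust benign-level estimate."""
    values = radiance_map.values.ravel().astype(float)
    for _ in range(n_iter):
        m, s = values.mean(), values.std()
        if s == 0:
            break
        kept = values[np.abs(values - m) <= clip_sigma * s]
        if kept.size == values.size or kept.size == 0:
            break
        values = kept
    return float(values.mean()), float(values.std())


def detect_hotspots(radiance_map: RadianceMap,
                    background_stats: tuple[float, float],
                    k_sigma: float = 3.0, min_area_px: int = 4) -> list[Hotspot]:
    """Connected components above mean + k*sd with at least ``min_area_px`` pixels.

    Each hotspot is annotated with its peak radiance and its TBR against
    the supplied background mean. TBRs are measured over the hotspot
    *core* — component pixels at or above half the peak excess over the
    background mean — emulating the compact ROI a clinician draws around
    a hotspot rather than the full faint skirt of the detection mask.
    A degenerate background (sd = 0 on a constant map) yields no hotspots.
    """
    mean, sd = background_stats
    if sd < 0:
        raise DomainError("background sd must be non-negative")
    if min_area_px < 1:
        raise DomainError("min_area_px must be >= 1")
    values = radiance_map.values
    if sd == 0 and np.all(values == values.flat[0]):
        return []
    above = values > mean + k_sigma * sd
    labels, n = ndimage.label(above, structure=_FOUR_CONN)
    hotspots = []
    for idx in range(1, n + 1):
        mask = labels == idx
        if mask.sum() < min_area_px:
            continue
        peak = float(values[mask].max())
        core = mask & (values >= mean + 0.5 * (peak - mean))
        tbr_u = float(values[core].mean() / mean) if mean > 0 else np.inf
        hotspots.append(Hotspot(view=radiance_map.view, mask=mask,
                                core_mask=core, peak_radiance=peak,
                                tbr_unfiltered=tbr_u))
    return hotspots


def match_filtered(hotspot: Hotspot, filtered_map: RadianceMap,
                   background_stats_filtered: tuple[float, float],
                   tau_persist: float = 2.0) -> Hotspot:
    """Annotate a hotspot with its TBR on the shortpass-filtered map.

    The same core pixel mask is evaluated on the filtered map; the
    hotspot is persistent when the filtered TBR reaches ``tau_persist``.
    """
    if filtered_map.values.shape != hotspot.mask.shape:
        raise ContractError("filtered map geometry does not match the hotspot")
    mean_f, _ = background_stats_filtered
    if mean_f <= 0:
        raise DomainError("filtered background mean must be positive")
    tbr_f = float(filtered_map.values[hotspot.core_mask].mean() / mean_f)
    hotspot.tbr_filtered = tbr_f
    hotspot.persistent = tbr_f >= tau_persist
    return hotspot


def classify_view(unfiltered_map: RadianceMap,
                  filtered_map: RadianceMap | None,
                  params: MarginParams | None = None) -> MarginCall:
    """Persistence rule for one view: PSM_suspected iff a hotspot persists.

    Without a filtered map the verdict falls back to the unfiltered TBR
    alone and is flagged low-confidence in the rationale.
    """
    params = params or MarginParams()
    stats_u = estimate_background_stats(unfiltered_map)
    hotspots = detect_hotspots(unfiltered_map, stats_u,
                               params.k_sigma, params.min_area_px)
    view = unfiltered_map.view
    if not hotspots:
        return MarginCall(view=view, verdict="NSM", hotspots=[],
                          rationale="no hotspot on unfiltered image")
    if filtered_map is None:
        persistent = [h for h in hotspots if h.tbr_unfiltered >= params.tau_persist]
        verdict = "PSM_suspected" if persistent else "NSM"
        return MarginCall(view=view, verdict=verdict, hotspots=hotspots,
                          rationale="LOW CONFIDENCE: no filtered image; verdict "
                                    "from unfiltered TBR only")
    if filtered_map.values.shape != unfiltered_map.values.shape:
        raise ContractError("filtered and unfiltered maps are not co-registered")
    stats_f = estimate_background_stats(filtered_map)
    for h in hotspots:
        match_filtered(h, filtered_map, stats_f, params.tau_persist)
    persistent = [h for h in hotspots if h.persistent]
    if persistent:
        return MarginCall(view=view, verdict="PSM_suspected", hotspots=hotspots,
                          rationale=f"{len(persistent)} persistent hotspot(s) on "
                                    "shortpass-filtered image")
    return MarginCall(view=view, verdict="NSM", hotspots=hotspots,
                      rationale="non-persistent hotspot (unfiltered only)")


def classify_specimen(calls: list[MarginCall]) -> str:
    """Specimen-level verdict: PSM_suspected if any view is suspected."""
    return ("PSM_suspected"
            if any(c.verdict == "PSM_suspected" for c in calls) else "NSM")


@dataclass
class ConfusionTable:
    """Exact-agreement counts, with near-margin (CLOSE) views kept apart.

    CLOSE views (tumour within 0.1 mm of the surface) are the clinically
    ambiguous cases: a suspected PSM there is not counted as a plain
    false positive.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    close_called_psm: int = 0
    close_called_nsm: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def evaluate_against_truth(calls: list[MarginCall],
                           truth: GroundTruth) -> ConfusionTable:
    """Tally margin calls against ground-truth view labels."""
    table = ConfusionTable()
    labels = truth.labels
    for call in calls:
        if call.view not in labels:
            raise ContractError(f"call for unknown view {call.view!r}")
        true_label = labels[call.view]
        suspected = call.verdict == "PSM_suspected"
        if true_label == "PSM":
            table.tp += suspected
            table.fn += not suspected
        elif true_label == "CLOSE":
            table.close_called_psm += suspected
            table.close_called_nsm += not suspected
        else:
            table.fp += suspected
            table.tn += not suspected
    return table
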