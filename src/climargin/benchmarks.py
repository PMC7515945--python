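"""Reproducible synthetic benchmarks of the full pipeline.

Two study designs drive the validation of the margin-assessment method:

* :func:`protocol_tbr_benchmark` — a read-noise-dominated phantom imaged
  across the clinical protocol grid (exposures 30/60/150/300 s at 8x8
  binning; binnings 2/4/8 at 150 s), measuring how the apparent TBR
  improves with collected signal. This reproduces, as a property, the
  protocol-optimisation behaviour observed clinically (higher binning
  and longer exposure raise the TBR).
* :func:`persistence_benchmark` — a cohort of specimen studies with
  lesions at depths {0, 0.05, 3, 6} mm, classified by the persistence
  rule, measuring surface-lesion sensitivity, deep-lesion specificity
  and the depth dependence of the filtered/unfiltered contrast ratio.

Both run the same rendering, processing and classification code paths
as the command-line workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import FILTER_NONE, FILTER_SHORTPASS_550, AcquisitionSettings, process_frame
from .margin import MarginParams, classify_view
from .phantom import (VIEWS, GroundTruth, SpecimenStudy, noise_dominated_phantom,
                      render_study, synthetic_cohort)
from .quantify import ROI, tbr_from_map

PROTOCOL_EXPOSURES_S = (30.0, 60.0, 150.0, 300.0)
PROTOCOL_BINNINGS = (2, 4, 8)


def _processed_map(study: SpecimenStudy, frame):
    return process_frame(frame, study.background_for(frame))


def _mean_view_tbr(study: SpecimenStudy, truth: GroundTruth,
                   settings: AcquisitionSettings) -> float:
    """TBR averaged over the six views for one acquisition setting."""
    tbrs = []
    for view in VIEWS:
        frame = study.frame(view, settings.optical_filter, settings.exposure_s,
                            settings.binning)
        rmap = _processed_map(study, frame)
        t_roi = ROI(truth.tumour_mask(view, settings.binning), "tumour", view)
        b_roi = ROI(truth.background_mask(view, settings.binning), "background", view)
        tbrs.append(tbr_from_map(rmap, t_roi, b_roi))
    return float(np.mean(tbrs))


def protocol_tbr_replicate(seed: int | np.random.SeedSequence) -> dict:
    """One seeded replicate of the protocol-optimisation experiment.

    Returns ``{"exposure": {t: TBR}, "binning": {b: TBR}}`` with TBRs
    measured on ground-truth ROIs of the noise-dominated phantom,
    averaged over the six views. Each setting is imaged as its own
    session starting at the same post-injection time, so the settings
    are compared at matched activity; backgrounds are rendered per view
    so the view TBRs are independent.
    """
    phantom, start = noise_dominated_phantom()
    settings_grid = [AcquisitionSettings(t, 8, FILTER_NONE)
                     for t in PROTOCOL_EXPOSURES_S]
    settings_grid += [AcquisitionSettings(150.0, b, FILTER_NONE)
                      for b in PROTOCOL_BINNINGS if b != 8]
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    measured: dict[tuple[float, int], float] = {}
    for k, settings in enumerate(settings_grid):
        child = np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=ss.spawn_key + (k,))
        study, truth = render_study(phantom, [settings], start, seed=child,
                                    backgrounds="per_view")
        measured[(settings.exposure_s, settings.binning)] = \
            _mean_view_tbr(study, truth, settings)
    exposure = {t: measured[(t, 8)] for t in PROTOCOL_EXPOSURES_S}
    binning = {b: measured[(150.0, b)] for b in PROTOCOL_BINNINGS}
    return {"exposure": exposure, "binning": binning}


@dataclass
class ProtocolBenchmarkResult:
    exposure_tbr: np.ndarray  # (n_replicates, len(PROTOCOL_EXPOSURES_S))
    binning_tbr: np.ndarray   # (n_replicates, len(PROTOCOL_BINNINGS))

    @property
    def exposure_endpoint_fraction(self) -> float:
        """Fraction of replicates with TBR(300 s) >= TBR(30 s)."""
        return float(np.mean(self.exposure_tbr[:, -1] >= self.exposure_tbr[:, 0]))

    @property
    def binning_endpoint_fraction(self) -> float:
        """Fraction of replicates with TBR(8x8) >= TBR(2x2)."""
        return float(np.mean(self.binning_tbr[:, -1] >= self.binning_tbr[:, 0]))

    @property
    def exposure_chain_fraction(self) -> float:
        """Fraction of replicates with the whole exposure series non-decreasing."""
        return float(np.mean(np.all(np.diff(self.exposure_tbr, axis=1) >= 0, axis=1)))

    @property
    def binning_chain_fraction(self) -> float:
        return float(np.mean(np.all(np.diff(self.binning_tbr, axis=1) >= 0, axis=1)))


def protocol_tbr_benchmark(n_replicates: int = 50,
                           seed: int = 0) -> ProtocolBenchmarkResult:
    """Run ``n_replicates`` seeded protocol replicates."""
    ss = np.random.SeedSequence(seed)
    exp_rows, bin_rows = [], []
    for i in range(n_replicates):
        rep = protocol_tbr_replicate(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(i,)))
        exp_rows.append([rep["exposure"][t] for t in PROTOCOL_EXPOSURES_S])
        bin_rows.append([rep["binning"][b] for b in PROTOCOL_BINNINGS])
    return ProtocolBenchmarkResult(exposure_tbr=np.array(exp_rows),
                                   binning_tbr=np.array(bin_rows))


@dataclass
class PersistenceBenchmarkResult:
    sensitivity_depth0: float
    specificity_deep: float        # lesions at >= 3 mm called NSM
    close_called_psm: int
    close_total: int
    contrast_ratio_by_depth: dict  # depth_mm -> mean filtered/unfiltered contrast


def persistence_benchmark(n_studies: int = 20,
                          depths: tuple[float, ...] = (0.0, 0.05, 3.0, 6.0),
                          seed: int = 0,
                          params: MarginParams | None = None
                          ) -> PersistenceBenchmarkResult:
    """Classify a synthetic cohort and score it against ground truth.

    Each study carries one lesion per depth on a distinct view (views
    beyond the depth list stay lesion-free) and is imaged at the
    clinically selected protocol: 150 s, 8x8 binning, with and without
    the 550 nm shortpass filter.
    """
    params = params or MarginParams()
    protocol = [AcquisitionSettings(150.0, 8, FILTER_NONE),
                AcquisitionSettings(150.0, 8, FILTER_SHORTPASS_550)]
    cohort = synthetic_cohort(n_studies, depths=depths, seed=seed)
    depth_views = dict(zip(VIEWS, depths))
    tp = fn = 0
    deep_tn = deep_fp = 0
    close_psm = close_total = 0
    contrast_f: dict[float, list[float]] = {d: [] for d in depths}
    contrast_u: dict[float, list[float]] = {d: [] for d in depths}
    ss = np.random.SeedSequence(seed)
    for i, (phantom, start) in enumerate(cohort):
        study, truth = render_study(
            phantom, protocol, start,
            seed=np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1000 + i,)),
            backgrounds="per_view")
        for view, depth in depth_views.items():
            unf = _processed_map(study, study.frame(view, FILTER_NONE))
            fil = _processed_map(study, study.frame(view, FILTER_SHORTPASS_550))
            call = classify_view(unf, fil, params)
            suspected = call.verdict == "PSM_suspected"
            label = truth.labels[view]
            if label == "PSM":
                tp += suspected
                fn += not suspected
            elif label == "CLOSE":
                close_psm += suspected
                close_total += 1
            elif depth >= 3.0:
                deep_fp += suspected
                deep_tn += not suspected
            t_roi = ROI(truth.tumour_mask(view, 8), "tumour", view)
            b_roi = ROI(truth.background_mask(view, 8), "background", view)
            contrast_u[depth].append(tbr_from_map(unf, t_roi, b_roi) - 1.0)
            contrast_f[depth].append(tbr_from_map(fil, t_roi, b_roi) - 1.0)
    # pooled ratio of cohort-mean contrasts: robust to per-study noise
    ratio = {d: float(np.mean(contrast_f[d]) / np.mean(contrast_u[d]))
             for d in depths}
    return PersistenceBenchmarkResult(
        sensitivity_depth0=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity_deep=deep_tn / (deep_tn + deep_fp) if (deep_tn + deep_fp)
        else float("nan"),
        close_called_psm=close_psm,
        close_total=close_total,
        contrast_ratio_by_depth=ratio,
    )
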