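"""Study manifests and on-disk formats.

Frames are written as TIFF (16-bit counts for raw frames, 32-bit float
for radiance maps) with a JSON sidecar per frame carrying acquisition
settings, timestamp and processing history. A YAML manifest ties a
study together; ground truth from the simulator goes to JSON.
Timestamps are ISO-8601 with explicit offsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .errors import ConfigurationError, ContractError
from .imaging import AcquisitionSettings, CLIFrame, RadianceMap
from .phantom import GroundTruth, SpecimenStudy

MANIFEST_SCHEMA = "climargin-study-1"


@dataclass
class FrameEntry:
    path: str
    view: str | None
    kind: str  # specimen | background | radiance
    exposure_s: float
    binning: int
    optical_filter: str
    acquisition_time: str  # ISO-8601

    def settings(self, unbinned_pitch_um: float = 117.0) -> AcquisitionSettings:
        return AcquisitionSettings(exposure_s=self.exposure_s, binning=self.binning,
                                   optical_filter=self.optical_filter,
                                   unbinned_pitch_um=unbinned_pitch_um)


@dataclass
class StudyManifest:
    patient_id: str
    isotope: str
    injected_activity_mbq: float
    injection_time: str  # ISO-8601
    frames: list[FrameEntry] = field(default_factory=list)
    ground_truth_path: str | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def injection_datetime(self) -> datetime:
        return datetime.fromisoformat(self.injection_time)

    def save(self, path: str | Path) -> None:
        doc = {"schema": MANIFEST_SCHEMA, **asdict(self)}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @staticmethod
    def load(path: str | Path) -> "StudyManifest":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or doc.get("schema") != MANIFEST_SCHEMA:
            raise ConfigurationError(f"not a {MANIFEST_SCHEMA} manifest: {path}")
        doc = dict(doc)
        doc.pop("schema")
        frames = [FrameEntry(**f) for f in doc.pop("frames", [])]
        manifest = StudyManifest(frames=frames, **doc)
        base = Path(path).parent
        for entry in manifest.frames:
            if not (base / entry.path).exists():
                raise ConfigurationError(f"frame file missing: {entry.path}")
        return manifest


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_block(config=None) -> dict:
    return {"tool": f"climargin {__version__}",
            "config_hash": config_hash(config) if config is not None else None}


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def write_frame(frame: CLIFrame, path: str | Path) -> None:
    """Write counts as 16-bit TIFF plus a JSON sidecar (bit-exact round trip)."""
    path = Path(path)
    data = np.asarray(frame.counts)
    if not np.issubdtype(data.dtype, np.integer):
        raise ContractError("write_frame expects an integer-valued raw frame; "
                            "use write_radiance_map for processed output")
    tifffile.imwrite(path, data.astype(np.uint16))
    sidecar = {
        "kind": frame.kind,
        "view": frame.view,
        "exposure_s": frame.settings.exposure_s,
        "binning": frame.settings.binning,
        "optical_filter": frame.settings.optical_filter,
        "unbinned_pitch_um": frame.settings.unbinned_pitch_um,
        "acquisition_time": frame.acquisition_time.isoformat(),
        "processing_history": frame.processing_history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame(path: str | Path) -> CLIFrame:
    path = Path(path)
    counts = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    settings = AcquisitionSettings(exposure_s=meta["exposure_s"],
                                   binning=meta["binning"],
                                   optical_filter=meta["optical_filter"],
                                   unbinned_pitch_um=meta.get("unbinned_pitch_um", 117.0))
    return CLIFrame(counts=counts, settings=settings,
                    acquisition_time=datetime.fromisoformat(meta["acquisition_time"]),
                    kind=meta["kind"], view=meta["view"],
                    processing_history=list(meta.get("processing_history", [])))


def write_radiance_map(rmap: RadianceMap, path: str | Path,
                       history: list[str] | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, rmap.values.astype(np.float32))
    sidecar = {
        "kind": "radiance",
        "view": rmap.view,
        "exposure_s": rmap.settings.exposure_s,
        "binning": rmap.settings.binning,
        "optical_filter": rmap.settings.optical_filter,
        "acquisition_time": rmap.acquisition_time.isoformat(),
        "calibration_id": rmap.calibration_id,
        "processing_history": history or [],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_radiance_map(path: str | Path) -> RadianceMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    settings = AcquisitionSettings(exposure_s=meta["exposure_s"],
                                   binning=meta["binning"],
                                   optical_filter=meta["optical_filter"])
    return RadianceMap(values=values, settings=settings,
                       acquisition_time=datetime.fromisoformat(meta["acquisition_time"]),
                       view=meta["view"], calibration_id=meta.get("calibration_id", ""))


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------

def write_study(study: SpecimenStudy, truth: GroundTruth, out_dir: str | Path,
                patient_id: str = "synthetic", config=None) -> Path:
    """Write all frames, the ground truth and a YAML manifest; returns manifest path."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    entries: list[FrameEntry] = []
    for i, frame in enumerate(study.background_frames + study.specimen_frames):
        name = (f"frames/{frame.kind}_{i:03d}_{frame.view or 'tray'}_"
                f"{frame.settings.optical_filter}_{frame.settings.exposure_s:g}s_"
                f"b{frame.settings.binning}.tif")
        write_frame(frame, out / name)
        entries.append(FrameEntry(
            path=name, view=frame.view, kind=frame.kind,
            exposure_s=frame.settings.exposure_s, binning=frame.settings.binning,
            optical_filter=frame.settings.optical_filter,
            acquisition_time=frame.acquisition_time.isoformat()))
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1))
    manifest = StudyManifest(
        patient_id=patient_id,
        isotope=study.phantom.isotope.name,
        injected_activity_mbq=study.phantom.injected_activity_mbq,
        injection_time=study.phantom.injection_time.isoformat(),
        frames=entries,
        ground_truth_path="ground_truth.json",
        provenance=provenance_block(config),
    )
    manifest_path = out / "manifest.yaml"
    manifest.save(manifest_path)
    return manifest_path
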