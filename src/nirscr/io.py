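"""Data model and on-disk containers for multi-wavelength fNIRS recordings.

The in-memory model mirrors what a wearable continuous-wave fNIRS device
produces: raw optical intensities per channel and wavelength, a montage
describing source-detector geometry (short ~7.5 mm scalp-sensitive channels
vs. long ~30 mm channels that see scalp + cortex), and a block-design event
list.  Two on-disk dialects are supported:

* ``snirf`` — the community-standard SNIRF (HDF5) layout, written with h5py;
* ``csv_bundle`` — one intensity CSV per wavelength plus a JSON sidecar for
  montage/events/meta, convenient for eyeballing.

Times are seconds from recording start; sample 0 is t = 0 and windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Channel",
    "Montage",
    "EventBlock",
    "RawRecording",
    "HemoSeries",
    "channel_role",
    "build_default_montage",
    "read_recording",
    "write_recording",
]

#: separation (mm) at or below which a channel counts as short-separation
SHORT_SEPARATION_MM = 10.0

CONDITIONS = ("left", "right")


class FormatError(ValueError):
    """A container file is missing required structure."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


def channel_role(separation_mm: float) -> str:
    """Channel role as a pure function of source-detector separation."""
    return "short" if separation_mm <= SHORT_SEPARATION_MM else "long"


@dataclass(frozen=True)
class Channel:
    source_id: int
    detector_id: int
    separation_mm: float
    roi_id: int | None = None

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValidationError(f"separation must be > 0, got {self.separation_mm}")
        if self.role == "long" and self.roi_id is None:
            raise ValidationError("long channels must map to a ROI")

    @property
    def role(self) -> str:
        return channel_role(self.separation_mm)


@dataclass(frozen=True)
class Montage:
    channels: tuple[Channel, ...]
    wavelengths: tuple[float, ...]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, float)
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def long_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.role == "long"])

    @property
    def short_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.role == "short"])

    @property
    def roi_map(self) -> dict[int, tuple[int, ...]]:
        """roi_id -> indices of the long channels probing that region."""
        rois: dict[int, list[int]] = {}
        for i, c in enumerate(self.channels):
            if c.role == "long":
                rois.setdefault(c.roi_id, []).append(i)
        return {k: tuple(v) for k, v in sorted(rois.items())}

    @property
    def separations_mm(self) -> np.ndarray:
        return np.array([c.separation_mm for c in self.channels])


@dataclass(frozen=True)
class EventBlock:
    condition: str
    onset: float
    duration: float

    def __post_init__(self):
        if self.onset < 0:
            raise ValidationError("onset must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def _check_events(events) -> None:
    evs = sorted(events, key=lambda e: e.onset)
    for a, b in zip(evs, evs[1:]):
        if a.offset > b.onset + 1e-9:
            raise ValidationError(f"events overlap: {a} / {b}")


@dataclass
class RawRecording:
    """Raw optical intensities, ``[n_samples, n_channels, n_wavelengths]`` volts."""

    intensities: np.ndarray
    fs: float
    montage: Montage
    events: tuple[EventBlock, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, float)
        self.events = tuple(self.events)
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be [samples, channels, wavelengths]")
        n, c, w = self.intensities.shape
        if c != self.montage.n_channels:
            raise ValidationError(
                f"{c} channels in data vs {self.montage.n_channels} in montage"
            )
        if w != len(self.montage.wavelengths):
            raise ValidationError("wavelength count mismatch with montage")
        bad = ~np.isfinite(self.intensities)
        if bad.any():
            s, ch, wl = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-finite intensity at sample {s}, channel {ch}, wavelength {wl}"
            )
        _check_events(self.events)
        if self.events:
            end = max(e.offset for e in self.events)
            if end > self.duration + 1e-9:
                raise ValidationError("last event ends after recording end")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class HemoSeries:
    """Hemoglobin concentration changes (uM), ``[n_samples, n_channels]``."""

    o2hb: np.ndarray
    hhb: np.ndarray
    fs: float
    montage: Montage
    events: tuple[EventBlock, ...] = ()
    tag: str = "NR"  # NR (no regression) or SCR (short-channel regressed)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.o2hb = np.asarray(self.o2hb, float)
        self.hhb = np.asarray(self.hhb, float)
        self.events = tuple(self.events)
        if self.o2hb.shape != self.hhb.shape:
            raise ValidationError("o2hb and hhb must have identical shape")
        if not (np.isfinite(self.o2hb).all() and np.isfinite(self.hhb).all()):
            raise ValidationError("hemoglobin series must be finite")
        if self.o2hb.shape[1] != self.montage.n_channels:
            raise ValidationError("channel count mismatch with montage")

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def chromophore(self, name: str) -> np.ndarray:
        if name not in ("o2hb", "hhb"):
            raise ValueError(f"unknown chromophore {name!r}")
        return getattr(self, name)

    def copy_with(self, **kw) -> "HemoSeries":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# default study montage


def build_default_montage() -> Montage:
    """Montage of the 8-optode motor-cortex layout used throughout.

    Eight optode modules sit symmetrically over the two hemispheres (four per
    side, covering M1 and premotor areas).  Each module contributes one short
    7.5 mm channel (source i -> detector i) and pairs with its ring neighbours
    to form 16 long 30 mm channels.  The two long channels of each adjacent
    optode pair probe the same patch of cortex and define one of 8 ROIs:
    ROI 1 is left M1, ROI 5 right M1 (the contralateral targets of right- and
    left-hand grasping).  Channel order: 16 long channels (ROI 1..8, two
    each), then 8 short channels (optode 0..7).
    """
    channels: list[Channel] = []
    # ring adjacency within each hemisphere: optodes (0,1,2,3) and (4,5,6,7)
    for hemi in (0, 1):
        base = 4 * hemi
        pairs = [(base, base + 1), (base + 1, base + 2),
                 (base + 2, base + 3), (base + 3, base)]
        for k, (a, b) in enumerate(pairs):
            roi = 4 * hemi + k + 1
            channels.append(Channel(a, b, 30.0, roi))
            channels.append(Channel(b, a, 30.0, roi))
    for opt in range(8):
        channels.append(Channel(opt, opt, 7.5, None))
    return Montage(tuple(channels), (774.0, 817.0, 865.0, 892.0))


def optode_hemisphere(optode_id: int) -> int:
    """0 for left-hemisphere optodes (0-3), 1 for right (4-7)."""
    return 0 if optode_id < 4 else 1


def channel_hemisphere(ch: Channel) -> int:
    return optode_hemisphere(ch.source_id)


# ---------------------------------------------------------------------------
# serialization helpers


def _montage_to_dict(m: Montage) -> dict:
    return {
        "wavelengths": list(m.wavelengths),
        "channels": [
            {
                "source_id": c.source_id,
                "detector_id": c.detector_id,
                "separation_mm": c.separation_mm,
                "roi_id": c.roi_id,
            }
            for c in m.channels
        ],
    }


def _montage_from_dict(d: dict) -> Montage:
    chans = tuple(
        Channel(c["source_id"], c["detector_id"], c["separation_mm"], c.get("roi_id"))
        for c in d["channels"]
    )
    return Montage(chans, tuple(d["wavelengths"]))


def _events_to_rows(events) -> list[dict]:
    return [{"condition": e.condition, "onset": e.onset, "duration": e.duration}
            for e in events]


def _events_from_rows(rows) -> tuple[EventBlock, ...]:
    return tuple(EventBlock(r["condition"], r["onset"], r["duration"]) for r in rows)


def _optode_positions(montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Nominal 3D source/detector positions (mm) for the SNIRF probe block.

    Optodes are laid out on two 30 mm squares, one per hemisphere; the
    detector sits at the optode anchor and the source 7.5 mm anterior.  The
    layout is schematic: authoritative separations live in the montage and
    are also serialized verbatim.
    """
    n_src = max(c.source_id for c in montage.channels) + 1
    n_det = max(c.detector_id for c in montage.channels) + 1
    anchors = {}
    square = [(0.0, 0.0), (30.0, 0.0), (30.0, 30.0), (0.0, 30.0)]
    for opt in range(max(n_src, n_det)):
        hemi = optode_hemisphere(opt)
        x0 = -65.0 if hemi == 0 else 35.0
        sx, sy = square[opt % 4]
        anchors[opt] = np.array([x0 + sx, sy, 0.0])
    det = np.stack([anchors[i] for i in range(n_det)])
    src = det[:n_src] + np.array([0.0, 7.5, 0.0])
    return src, det


# ---------------------------------------------------------------------------
# SNIRF dialect


def _write_snirf(rec: RawRecording, path: Path) -> None:
    n, c, w = rec.intensities.shape
    flat = rec.intensities.reshape(n, c * w)  # measurement = (channel, wavelength)
    src, det = _optode_positions(rec.montage)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.time)
        for m in range(c * w):
            ch, wl = divmod(m, w)
            chan = rec.montage.channels[ch]
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=chan.source_id + 1)
            ml.create_dataset("detectorIndex", data=chan.detector_id + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.montage.wavelengths))
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        for i, e in enumerate(rec.events):
            stim = nirs.create_group(f"stim{i + 1}")
            stim.create_dataset("name", data=e.condition)
            stim.create_dataset("data", data=np.array([[e.onset, e.duration, 1.0]]))
        tags = nirs.create_group("metaDataTags")
        tags.create_dataset("SubjectID", data=str(rec.meta.get("subject", "")))
        tags.create_dataset("MeasurementDate", data="unknown")
        tags.create_dataset("MeasurementTime", data="unknown")
        tags.create_dataset("LengthUnit", data="mm")
        tags.create_dataset("TimeUnit", data="s")
        tags.create_dataset("FrequencyUnit", data="Hz")
        tags.create_dataset(
            "nirscrSidecar",
            data=json.dumps(
                {"montage": _montage_to_dict(rec.montage), "meta": rec.meta, "fs": rec.fs}
            ),
        )


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "nirs1" not in f:
            raise FormatError(f"{path}: missing /nirs1 group")
        nirs = f["nirs1"]
        if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
            raise FormatError(f"{path}: missing wavelength table in probe block")
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())
        tags = nirs.get("metaDataTags", {})
        meta: dict = {}
        montage = None
        fs = None
        if "nirscrSidecar" in tags:
            side = json.loads(_read_str(tags["nirscrSidecar"]))
            montage = _montage_from_dict(side["montage"])
            meta = side.get("meta", {})
            fs = side.get("fs")
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(time)))
        if montage is None:
            montage = _montage_from_positions(nirs, flat.shape[1], wavelengths)
        n_w = len(wavelengths)
        intensities = flat.reshape(flat.shape[0], flat.shape[1] // n_w, n_w)
        events = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            name = _read_str(stim["name"])
            for onset, dur, _amp in np.atleast_2d(np.asarray(stim["data"])):
                events.append(EventBlock(name, float(onset), float(dur)))
        events.sort(key=lambda e: e.onset)
        return RawRecording(intensities, float(fs), montage, tuple(events), meta)


def _montage_from_positions(nirs, n_meas, wavelengths) -> Montage:
    probe = nirs["probe"]
    src = np.asarray(probe["sourcePos3D"])
    det = np.asarray(probe["detectorPos3D"])
    n_w = len(wavelengths)
    chans = []
    for m in range(0, n_meas, n_w):
        ml = nirs["data1"][f"measurementList{m + 1}"]
        si = int(np.asarray(ml["sourceIndex"])) - 1
        di = int(np.asarray(ml["detectorIndex"])) - 1
        sep = float(np.linalg.norm(src[si] - det[di]))
        roi = None if channel_role(sep) == "short" else -1
        chans.append(Channel(si, di, sep, roi))
    return Montage(tuple(chans), tuple(wavelengths))


# ---------------------------------------------------------------------------
# csv_bundle dialect


def _write_csv_bundle(rec: RawRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for wi, wl in enumerate(rec.montage.wavelengths):
        np.savetxt(
            path / f"intensity_{wl:g}nm.csv",
            rec.intensities[:, :, wi],
            delimiter=",",
            fmt="%.17g",
        )
    sidecar = {
        "fs": rec.fs,
        "montage": _montage_to_dict(rec.montage),
        "events": _events_to_rows(rec.events),
        "meta": rec.meta,
    }
    (path / "recording.json").write_text(json.dumps(sidecar, indent=1))


def _read_csv_bundle(path: Path) -> RawRecording:
    side_path = path / "recording.json"
    if not side_path.exists():
        raise FormatError(f"{path}: missing recording.json sidecar")
    side = json.loads(side_path.read_text())
    if "montage" not in side or "wavelengths" not in side["montage"]:
        raise FormatError(f"{path}: sidecar missing montage/wavelength table")
    montage = _montage_from_dict(side["montage"])
    planes = []
    for wl in montage.wavelengths:
        f = path / f"intensity_{wl:g}nm.csv"
        if not f.exists():
            raise FormatError(f"{path}: missing intensity file for {wl:g} nm")
        planes.append(np.atleast_2d(np.loadtxt(f, delimiter=",")))
    intensities = np.stack(planes, axis=-1)
    return RawRecording(
        intensities,
        float(side["fs"]),
        montage,
        _events_from_rows(side.get("events", [])),
        side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# public entry points


def _infer_dialect(path: Path) -> str:
    return "csv_bundle" if path.is_dir() or path.suffix == "" else "snirf"


def write_recording(rec: RawRecording, path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "snirf":
        _write_snirf(rec, path)
    elif dialect == "csv_bundle":
        _write_csv_bundle(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str | None = None) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "snirf":
        return _read_snirf(path)
    if dialect == "csv_bundle":
        return _read_csv_bundle(path)
    raise ValueError(f"unknown dialect {dialect!r}")
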