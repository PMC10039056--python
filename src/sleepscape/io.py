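"""Typed containers and readers/writers for every format the pipeline touches.

Time convention: seconds from the first fMRI volume; intervals are half-open
``[start, end)``; volume indices are 0-based, so frame ``k`` covers
``[k*TR, (k+1)*TR)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("sleepscape")

STATES = ("AW", "NREM", "REM")
EVENT_TYPES = ("spindle", "SWR", "slow_wave")
CHANNEL_KINDS = ("ECoG", "iEEG", "LFP", "EMG", "REF")

EVENT_COLUMNS = [
    "type", "channel", "center_s", "start_s", "end_s",
    "peak_amp", "coupled", "state",
]

#: duration limits (s) enforced per event type; None = unconstrained
EVENT_DURATION_LIMITS = {
    "spindle": (0.4, 3.0),
    "slow_wave": (0.4, 2.0),
    "SWR": None,
}


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


@dataclass
class Channel:
    """One recorded electrode: name, modality and (for surface grids) position."""

    name: str
    kind: str = "ECoG"
    layout_xy: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValidationError(f"unknown channel kind {self.kind!r}")
        if self.layout_xy is not None:
            self.layout_xy = (float(self.layout_xy[0]), float(self.layout_xy[1]))


@dataclass
class EphysRecording:
    """Multichannel electrophysiology with MRI slice-trigger timestamps.

    ``data`` is channels x samples in microvolts; ``triggers`` are slice
    trigger times in seconds on the scan clock.
    """

    data: np.ndarray
    fs: float
    channels: list[Channel]
    triggers: np.ndarray = field(default_factory=lambda: np.empty(0))
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.triggers = np.asarray(self.triggers, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.channels)} channels are declared")
        if self.triggers.size and np.any(np.diff(self.triggers) <= 0):
            raise ValidationError("slice triggers must be strictly increasing")
        for ch in self.channels:
            if ch.kind == "ECoG" and ch.layout_xy is None:
                raise ValidationError(f"ECoG channel {ch.name!r} lacks layout_xy")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy(self) -> "EphysRecording":
        return EphysRecording(self.data.copy(), self.fs, list(self.channels),
                              self.triggers.copy(), self.session_id)


@dataclass
class Hypnogram:
    """Scored sleep states as a tiling of ``[0, duration)`` by epochs.

    ``epochs`` is a list of ``(state, start_s, end_s)`` with half-open
    intervals; per-second labels are materialised on demand.
    """

    epochs: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        eps = [(str(s), float(a), float(b)) for s, a, b in self.epochs]
        if not eps:
            raise ValidationError("hypnogram needs at least one epoch")
        for s, a, b in eps:
            if s not in STATES:
                raise ValidationError(f"unknown state {s!r}")
            if b <= a:
                raise ValidationError(f"epoch [{a}, {b}) has non-positive length")
        for (s0, a0, b0), (s1, a1, b1) in zip(eps, eps[1:]):
            if not np.isclose(b0, a1):
                kind = "gap" if a1 > b0 else "overlap"
                raise ValidationError(f"{kind} between epochs at {b0} / {a1} s")
        self.epochs = eps

    @classmethod
    def from_labels(cls, labels: Sequence[str], t0: float = 0.0) -> "Hypnogram":
        """Build from a per-second label sequence (each label covers 1 s)."""
        labels = list(labels)
        if not labels:
            raise ValidationError("empty label sequence")
        epochs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                epochs.append((labels[start], t0 + start, t0 + i))
                start = i
        return cls(epochs)

    @property
    def start(self) -> float:
        return self.epochs[0][1]

    @property
    def end(self) -> float:
        return self.epochs[-1][2]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def labels(self) -> list[str]:
        """Per-second labels; second ``i`` is sampled at its midpoint."""
        n = int(round(self.duration))
        mids = self.start + np.arange(n) + 0.5
        return [self.state_at(t) for t in mids]

    def state_at(self, t: float) -> str:
        for s, a, b in self.epochs:
            if a <= t < b:
                return s
        if np.isclose(t, self.end):
            return self.epochs[-1][0]
        raise ValidationError(f"time {t} outside hypnogram [{self.start}, {self.end})")

    def state_mask(self, state: str, n_seconds: Optional[int] = None) -> np.ndarray:
        lab = self.labels
        if n_seconds is not None:
            lab = (lab + [lab[-1]] * n_seconds)[:n_seconds]
        return np.array([l == state for l in lab])

    def epochs_of(self, state: str) -> list[tuple[float, float]]:
        return [(a, b) for s, a, b in self.epochs if s == state]

    def min_epoch_duration(self) -> float:
        return min(b - a for _, a, b in self.epochs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return len(self.epochs) == len(other.epochs) and all(
            s0 == s1 and np.isclose(a0, a1) and np.isclose(b0, b1)
            for (s0, a0, b0), (s1, a1, b1) in zip(self.epochs, other.epochs))


class EventTable:
    """Detected spindles / SWRs / slow waves as a validated DataFrame."""

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        df = df.reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        self.df = df[EVENT_COLUMNS].copy()
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        bad_rows = []
        for i, row in df.iterrows():
            if row["type"] not in EVENT_TYPES:
                bad_rows.append((i, f"unknown type {row['type']!r}"))
                continue
            if not (row["start_s"] <= row["center_s"] <= row["end_s"]):
                bad_rows.append((i, "center outside [start, end]"))
            lim = EVENT_DURATION_LIMITS[row["type"]]
            if lim is not None:
                dur = row["end_s"] - row["start_s"]
                if not (lim[0] - 1e-9 <= dur <= lim[1] + 1e-9):
                    bad_rows.append((i, f"duration {dur:.3f} s outside {lim}"))
            if row["coupled"] not in ("coupled", "uncoupled", "NA"):
                bad_rows.append((i, f"bad coupled flag {row['coupled']!r}"))
            if row["state"] not in STATES + ("NA",):
                bad_rows.append((i, f"bad state {row['state']!r}"))
        if bad_rows:
            msg = "; ".join(f"row {i}: {m}" for i, m in bad_rows[:10])
            raise ValidationError(f"{len(bad_rows)} invalid event rows: {msg}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        a, b = self.df, other.df
        num = ["center_s", "start_s", "end_s", "peak_amp"]
        cat = ["type", "channel", "coupled", "state"]
        return (np.allclose(a[num].to_numpy(float), b[num].to_numpy(float))
                and all((a[c].astype(str) == b[c].astype(str)).all() for c in cat))

    def select(self, type: Optional[str] = None, state: Optional[str] = None,
               coupled: Optional[str] = None) -> "EventTable":
        df = self.df
        if type is not None:
            df = df[df["type"] == type]
        if state is not None:
            df = df[df["state"] == state]
        if coupled is not None:
            df = df[df["coupled"] == coupled]
        return EventTable(df)

    @staticmethod
    def concat(tables: Sequence["EventTable"]) -> "EventTable":
        frames = [t.df for t in tables if len(t)]
        if not frames:
            return EventTable()
        df = pd.concat(frames, ignore_index=True)
        return EventTable(df.sort_values("center_s").reset_index(drop=True))


@dataclass
class BoldSeries:
    """4D BOLD volume with masks and motion parameters.

    ``rp`` columns are 3 translations (mm) then 3 rotations (rad).
    """

    volume: np.ndarray
    TR: float
    brain_mask: np.ndarray
    nonbrain_mask: np.ndarray
    rp: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.2, 0.2, 0.5)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.nonbrain_mask = np.asarray(self.nonbrain_mask, dtype=bool)
        self.rp = np.asarray(self.rp, dtype=np.float64)
        if self.volume.ndim != 4:
            raise ValidationError("volume must be 4D (x, y, z, t)")
        if self.TR <= 0:
            raise ValidationError("TR must be positive")
        grid = self.volume.shape[:3]
        if self.brain_mask.shape != grid or self.nonbrain_mask.shape != grid:
            raise ValidationError("mask grid does not match volume grid")
        if np.any(self.brain_mask & self.nonbrain_mask):
            raise ValidationError("brain and non-brain masks overlap")
        if self.rp.shape != (self.volume.shape[3], 6):
            raise ValidationError(
                f"rp must be {self.volume.shape[3]} x 6, got {self.rp.shape}")

    @property
    def n_frames(self) -> int:
        return self.volume.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.TR

    def masked(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Return a frames x voxels matrix of the masked series."""
        if mask is None:
            mask = self.brain_mask
        return self.volume[mask].T.copy()

    def with_volume(self, volume: np.ndarray) -> "BoldSeries":
        return BoldSeries(volume, self.TR, self.brain_mask, self.nonbrain_mask,
                          self.rp, self.voxel_size_mm)


@dataclass
class SessionBundle:
    """One simultaneous ephys + fMRI session on a shared scan clock."""

    ephys: EphysRecording
    bold: BoldSeries
    hypnogram: Optional[Hypnogram] = None
    events: Optional[EventTable] = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_ephys(rec: EphysRecording, path) -> None:
    """Write raw little-endian float32 channel-major binary + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.data.astype("<f4").tofile(path)
    sidecar = {
        "session_id": rec.session_id,
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "channels": [
            {"name": ch.name, "kind": ch.kind,
             "layout_xy": list(ch.layout_xy) if ch.layout_xy else None}
            for ch in rec.channels
        ],
        "triggers": rec.triggers.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_ephys(path) -> EphysRecording:
    """Read raw binary + JSON sidecar, or an EDF file (extension .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"unparseable sidecar: {e}") from e
    channels = [Channel(c["name"], c["kind"],
                        tuple(c["layout_xy"]) if c.get("layout_xy") else None)
                for c in meta["channels"]]
    raw = np.fromfile(path, dtype="<f4")
    n_ch = len(channels)
    if n_ch == 0 or raw.size % n_ch != 0:
        raise FormatError(
            f"binary has {raw.size} samples, not divisible by {n_ch} channels")
    data = raw.reshape(n_ch, -1).astype(np.float64)
    if "n_samples" in meta and data.shape[1] != meta["n_samples"]:
        raise FormatError(
            f"sidecar claims {meta['n_samples']} samples/channel, "
            f"binary holds {data.shape[1]}")
    return EphysRecording(data, float(meta["fs"]), channels,
                          np.asarray(meta.get("triggers", []), float),
                          meta.get("session_id", ""))


def _read_edf(path: Path) -> EphysRecording:
    """Minimal EDF reader (continuous records, identical per-channel rates)."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise FormatError("truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii").strip())
        record_dur = float(hdr[244:252].decode("ascii").strip())
        n_sig = int(hdr[252:256].decode("ascii").strip())
        sig_hdr = f.read(256 * n_sig)

        def fields(offset, width):
            base = offset * n_sig
            return [sig_hdr[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_sig)]

        labels = fields(0, 16)
        phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dig_min = [float(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dig_max = [float(v) for v in fields(16 + 80 + 8 + 24, 8)]
        n_samp = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(n_samp)) != 1:
            raise FormatError("EDF with per-channel sampling rates not supported")
        fs = n_samp[0] / record_dur
        data = [[] for _ in range(n_sig)]
        for _ in range(n_records):
            for i in range(n_sig):
                raw = np.frombuffer(f.read(2 * n_samp[i]), dtype="<i2")
                gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
                data[i].append(raw * gain + (phys_min[i] - dig_min[i] * gain))
    matrix = np.stack([np.concatenate(ch) for ch in data])
    kinds = {"EMG": "EMG", "LFP": "LFP", "IEEG": "iEEG"}
    channels = []
    for lab in labels:
        kind = next((v for k, v in kinds.items() if k in lab.upper()), "LFP")
        channels.append(Channel(lab, kind))
    return EphysRecording(matrix, fs, channels, session_id=path.stem)


def write_events(table: EventTable, path) -> None:
    table.validate()
    df = table.df.rename(columns={})
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    if len(df) == 0 and list(df.columns) != EVENT_COLUMNS:
        # header-only file written by an empty table
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    return EventTable(df)


def write_hypnogram(h: Hypnogram, path) -> None:
    df = pd.DataFrame(h.epochs, columns=["state", "start_s", "end_s"])
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    return Hypnogram(list(df.itertuples(index=False, name=None)))


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_bold(series: BoldSeries, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.voxel_size_mm)
    paths = {
        "bold": out / "bold.nii.gz",
        "brain_mask": out / "brain_mask.nii.gz",
        "nonbrain_mask": out / "nonbrain_mask.nii.gz",
        "rp": out / "rp.txt",
    }
    img = nib.Nifti1Image(series.volume.astype(np.float32), aff)
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.TR,))
    nib.save(img, paths["bold"])
    nib.save(nib.Nifti1Image(series.brain_mask.astype(np.uint8), aff),
             paths["brain_mask"])
    nib.save(nib.Nifti1Image(series.nonbrain_mask.astype(np.uint8), aff),
             paths["nonbrain_mask"])
    np.savetxt(paths["rp"], series.rp, fmt="%.8f")
    return paths


def read_bold(path_4d, path_brainmask, path_nonbrainmask, path_rp,
              TR: Optional[float] = None) -> BoldSeries:
    """Load a 4D NIfTI + masks + motion parameters.

    TR is taken from the NIfTI header unless overridden.
    """
    img = nib.load(str(path_4d))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValidationError("expected a 4D NIfTI")
    zooms = img.header.get_zooms()
    if TR is None:
        TR = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    brain = np.asarray(nib.load(str(path_brainmask)).dataobj) > 0
    nonbrain = np.asarray(nib.load(str(path_nonbrainmask)).dataobj) > 0
    rp = np.loadtxt(path_rp)
    if rp.ndim == 1:
        rp = rp.reshape(1, -1)
    if rp.shape[0] != vol.shape[3]:
        raise ValidationError(
            f"rp has {rp.shape[0]} rows for {vol.shape[3]} volumes")
    return BoldSeries(vol, TR, brain, nonbrain, rp,
                      tuple(float(z) for z in zooms[:3]))
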