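"""Readers and writers for FLIM acquisitions, phasor bundles and object tables.

On-disk dialects
----------------
``TCSPCStack`` can live either in a multipage TIFF (the ``F`` per-frame
intensity images followed by ``T`` decay planes, 16-bit unsigned) with a JSON
sidecar carrying acquisition metadata, or in a single HDF5 container with
datasets ``/frames`` and ``/decay`` and metadata as root attributes.
``PhasorBundle`` uses the HDF5 container only (``/g``, ``/s``, ``/intensity``
plus attributes); it is an open stand-in for the proprietary SimFCS R64
format, holding the referenced (g, s) arrays that format carries.

Pixel convention: 0-based, row-major, origin top-left, y increases downward.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: fixed column order of the object-table CSV contract
OBJECT_TABLE_COLUMNS = [
    "id",
    "group",
    "area_px",
    "size_um",
    "centroid_y",
    "centroid_x",
    "g_mean",
    "s_mean",
    "fb_fraction",
    "outlier_flag",
    "free_fraction",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ShapeError(ValueError):
    """Array dimensions disagree with declared metadata."""


class DataError(ValueError):
    """Array contents violate an invariant (e.g. negative photon counts)."""


@dataclasses.dataclass
class TCSPCStack:
    """One time-correlated single-photon-counting acquisition.

    Parameters
    ----------
    frames : ndarray, shape (F, H, W)
        Per-frame photon-count intensity images.
    decay : ndarray, shape (H, W, T) or None
        Per-pixel photon arrival-time histogram accumulated over all frames.
    rep_rate_hz : float
        Laser pulse repetition rate in Hz (80 MHz in two-photon NADH work).
    pixel_size_um : float
        Physical pixel size in micrometres per pixel.
    decay_subsampled : bool
        If True the decay was stored subsampled and photon conservation
        against ``frames`` is only checked with a warning.
    """

    frames: np.ndarray
    decay: np.ndarray | None
    rep_rate_hz: float
    pixel_size_um: float
    decay_subsampled: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeError(f"frames must be (F, H, W); got {self.frames.shape}")
        if self.decay is not None:
            self.decay = np.asarray(self.decay)
            if self.decay.ndim != 3:
                raise ShapeError(f"decay must be (H, W, T); got {self.decay.shape}")
            if self.decay.shape[:2] != self.frames.shape[1:]:
                raise ShapeError(
                    f"decay spatial dims {self.decay.shape[:2]} != frame dims "
                    f"{self.frames.shape[1:]}"
                )
        self.validate()

    # -- derived geometry ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def t_bins(self) -> int:
        return 0 if self.decay is None else self.decay.shape[2]

    @property
    def period_ns(self) -> float:
        """Laser period in ns; period_ns * rep_rate_hz == 1e9 by construction."""
        return 1e9 / self.rep_rate_hz

    @property
    def accumulated(self) -> np.ndarray:
        """Total photons per pixel summed over frames."""
        return self.frames.sum(axis=0)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for name, arr in (("frames", self.frames), ("decay", self.decay)):
            if arr is None:
                continue
            if np.any(arr < 0):
                raise DataError(f"{name} holds negative photon counts")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise DataError(f"{name} holds non-integral photon counts")
        if self.rep_rate_hz <= 0:
            raise DataError("rep_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise DataError("pixel_size_um must be positive")
        if self.decay is not None:
            conserved = np.array_equal(
                self.decay.sum(axis=2), self.frames.sum(axis=0)
            )
            if not conserved:
                msg = (
                    "photon conservation violated: per-pixel decay totals "
                    "differ from per-pixel frame totals"
                )
                if self.decay_subsampled:
                    warnings.warn(msg + " (decay flagged as subsampled)")
                else:
                    raise DataError(msg)


@dataclasses.dataclass
class PhasorBundle:
    """Per-pixel first-harmonic phasor field with photon totals.

    ``g``/``s`` are NaN wherever ``intensity`` is zero (undefined phasor).
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    rep_rate_hz: float
    harmonic: int = 1
    calibrated: bool = False
    reference_lifetime_ns: float | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if not (self.g.shape == self.s.shape == self.intensity.shape):
            raise ShapeError("g, s and intensity must share one shape")

    @property
    def valid(self) -> np.ndarray:
        return (self.intensity > 0) & np.isfinite(self.g) & np.isfinite(self.s)

    @property
    def meta(self) -> dict:
        return {
            "rep_rate_hz": self.rep_rate_hz,
            "harmonic": self.harmonic,
            "calibrated": self.calibrated,
            "reference_lifetime_ns": self.reference_lifetime_ns,
        }


# ---------------------------------------------------------------------------
# TCSPC stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_tcspc_stack(stack: TCSPCStack, path: str | Path) -> Path:
    """Write a stack as multipage TIFF + JSON sidecar, or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=stack.frames)
            if stack.decay is not None:
                f.create_dataset("decay", data=stack.decay)
            f.attrs["rep_rate_hz"] = stack.rep_rate_hz
            f.attrs["pixel_size_um"] = stack.pixel_size_um
            f.attrs["decay_subsampled"] = stack.decay_subsampled
        return path

    frames = stack.frames
    decay = stack.decay if stack.decay is not None else np.zeros(
        stack.shape + (0,), dtype=frames.dtype
    )
    pages = [np.asarray(fr) for fr in frames] + [
        decay[:, :, t] for t in range(decay.shape[2])
    ]
    peak = max(int(p.max(initial=0)) for p in pages)
    if peak > np.iinfo(np.uint16).max:
        raise DataError("photon counts exceed 16-bit TIFF range")
    tifffile.imwrite(path, np.stack([p.astype(np.uint16) for p in pages]))
    meta = {
        "rep_rate_hz": stack.rep_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
        "F": int(stack.n_frames),
        "T": int(stack.t_bins),
        "decay_subsampled": stack.decay_subsampled,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_tcspc_stack(path: str | Path) -> TCSPCStack:
    """Read a stack written by :func:`write_tcspc_stack`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise FormatError(f"{path}: missing dataset 'frames'")
            frames = f["frames"][()]
            decay = f["decay"][()] if "decay" in f else None
            return TCSPCStack(
                frames=frames,
                decay=decay,
                rep_rate_hz=float(f.attrs["rep_rate_hz"]),
                pixel_size_um=float(f.attrs["pixel_size_um"]),
                decay_subsampled=bool(f.attrs.get("decay_subsampled", False)),
            )

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    F, T = int(meta["F"]), int(meta["T"])
    if pages.shape[0] != F + T:
        raise ShapeError(
            f"{path}: {pages.shape[0]} pages but sidecar declares F+T={F + T}"
        )
    frames = pages[:F]
    decay = np.moveaxis(pages[F:], 0, 2) if T else None
    return TCSPCStack(
        frames=frames,
        decay=decay,
        rep_rate_hz=float(meta["rep_rate_hz"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        decay_subsampled=bool(meta.get("decay_subsampled", False)),
    )


# ---------------------------------------------------------------------------
# Phasor bundles
# ---------------------------------------------------------------------------

def write_phasor_bundle(bundle: PhasorBundle, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("g", data=bundle.g.astype(np.float64))
        f.create_dataset("s", data=bundle.s.astype(np.float64))
        f.create_dataset("intensity", data=bundle.intensity)
        f.attrs["rep_rate_hz"] = bundle.rep_rate_hz
        f.attrs["harmonic"] = bundle.harmonic
        f.attrs["calibrated"] = bundle.calibrated
        if bundle.reference_lifetime_ns is not None:
            f.attrs["reference_lifetime_ns"] = bundle.reference_lifetime_ns
    return path


def read_phasor_bundle(path: str | Path) -> PhasorBundle:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("g", "s", "intensity"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '{name}'")
        ref = f.attrs.get("reference_lifetime_ns")
        return PhasorBundle(
            g=f["g"][()],
            s=f["s"][()],
            intensity=f["intensity"][()],
            rep_rate_hz=float(f.attrs["rep_rate_hz"]),
            harmonic=int(f.attrs["harmonic"]),
            calibrated=bool(f.attrs["calibrated"]),
            reference_lifetime_ns=None if ref is None else float(ref),
        )


# ---------------------------------------------------------------------------
# Object tables
# ---------------------------------------------------------------------------

def write_object_table(records: Sequence, path: str | Path) -> Path:
    """Write per-mitochondrion records as CSV with the fixed column contract.

    An empty record list writes a header-only file.
    """
    path = Path(path)
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        d.setdefault("free_fraction", 1.0 - d["fb_fraction"])
        rows.append({c: d[c] for c in OBJECT_TABLE_COLUMNS})
    df = pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_object_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBJECT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df
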