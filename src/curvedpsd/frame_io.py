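"""Frame-stack files and the text tables linking pipeline stages.

A frame stack on disk is a directory holding one raw binary file per frame
plus a human-readable YAML sidecar (``stack.yaml``) describing geometry,
scan and storage mode.  Two dialects exist:

* ``full``  - little-endian 4-byte unsigned pixels over the full
  ``n_x x n_y`` face (a 512 x 512 frame is exactly 1 MiB);
* ``reduced`` - little-endian 2-byte unsigned pixels cropped to the active
  detector window; values above 65535 saturate (with a warning).  Reading a
  reduced stack re-embeds the crop into full-face coordinates with zeros
  outside.

The intermediate text tables (``peaks``, ``qlist``, ``ub``, ``hkl``) are
whitespace-delimited with a single ``#``-prefixed header line; all writers
and readers are exact inverses on valid data.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Cell, DetectorGeometry, ScanConfig
from .profiles import geometry_from_dict, profile_to_dict, scan_from_dict

__all__ = [
    "ImageFrame", "FrameStack", "PeakListRecord", "CorruptStackError",
    "write_stack", "read_stack", "stack_nominal_size",
    "write_table", "read_table", "TABLE_SCHEMAS",
]


class CorruptStackError(IOError):
    """Sidecar and binary payload disagree."""


@dataclass
class ImageFrame:
    """One detector image at a single rotation increment."""

    counts: np.ndarray          # (n_x, n_y) non-negative ints, axis 0 = X
    frame_index: int
    phi_mid: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


@dataclass
class FrameStack:
    """Ordered image frames of one continuous rotation scan."""

    frames: list
    scan: ScanConfig
    geom: DetectorGeometry

    def __post_init__(self):
        if len(self.frames) != self.scan.n_frames:
            raise ValueError(
                f"{len(self.frames)} frames but scan declares "
                f"{self.scan.n_frames}")
        for i, fr in enumerate(self.frames):
            if fr.frame_index != i:
                raise ValueError("frame indices must be 0..n-1 in order")
            expected = self.scan.phi_mid(i)
            if abs(fr.phi_mid - expected) > 1e-9:
                raise ValueError(f"frame {i}: phi_mid {fr.phi_mid} != "
                                 f"scan midpoint {expected}")
            if fr.counts.shape != (self.geom.n_x, self.geom.n_y):
                raise ValueError(f"frame {i}: shape {fr.counts.shape} does "
                                 f"not match geometry")

    def __len__(self):
        return len(self.frames)

    def counts_array(self):
        """All counts as one (n_frames, n_x, n_y) array."""
        if not self.frames:
            return np.zeros((0, self.geom.n_x, self.geom.n_y), dtype=np.uint32)
        return np.stack([f.counts for f in self.frames])


@dataclass(frozen=True)
class PeakListRecord:
    """One found 2D peak as stored in the peaks table."""

    peak_number: int
    file_number: int            # frame index
    x: float
    y: float
    intensity: float

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


def stack_nominal_size(n_frames: int, n_x: int = 512, n_y: int = 512,
                       bytes_per_pixel: int = 4):
    """(exact bytes, nominal MB per frame, nominal GB per set).

    The nominal figures follow the instrument bookkeeping convention:
    one 512 x 512 x 4-byte frame is counted as 1 MB (2**20 bytes) and
    1000 MB as 1 GB, so an 1800-frame scan is "1.8 GB".
    """
    exact = n_frames * n_x * n_y * bytes_per_pixel
    mb_per_frame = n_x * n_y * bytes_per_pixel / 2**20
    return exact, mb_per_frame, n_frames * mb_per_frame / 1000.0


# ---------------------------------------------------------------------------
# binary stacks
# ---------------------------------------------------------------------------

_DTYPES = {"full": np.dtype("<u4"), "reduced": np.dtype("<u2")}


def _crop_slices(geom: DetectorGeometry):
    (xmin, ymin), (xmax, ymax) = geom.active_window
    return (slice(int(math.floor(xmin)), int(math.ceil(xmax)) + 1),
            slice(int(math.floor(ymin)), int(math.ceil(ymax)) + 1))


def write_stack(stack: FrameStack, mode: str, path):
    """Write a stack directory; returns the list of files written."""
    if mode not in _DTYPES:
        raise ValueError(f"mode must be 'full' or 'reduced', got {mode!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dtype = _DTYPES[mode]
    sx, sy = _crop_slices(stack.geom)
    written = []
    for fr in stack.frames:
        data = fr.counts
        if mode == "reduced":
            data = data[sx, sy]
            if np.any(data > 65535):
                warnings.warn(
                    f"frame {fr.frame_index}: pixel values above 65535 "
                    "saturated in reduced mode", stacklevel=2)
                data = np.minimum(data, 65535)
        else:
            if np.any(np.asarray(data, dtype=np.uint64) > 2**32 - 1):
                raise ValueError(f"frame {fr.frame_index}: counts exceed "
                                 "32-bit range")
        fname = path / f"frame_{fr.frame_index:05d}.raw"
        np.ascontiguousarray(data, dtype=dtype).tofile(fname)
        written.append(fname)
    sidecar = profile_to_dict(stack.geom, stack.scan)
    sidecar["stack"] = {
        "mode": mode,
        "n_frames": len(stack.frames),
        "frame_shape": ([stack.geom.n_x, stack.geom.n_y] if mode == "full"
                        else [sx.stop - sx.start, sy.stop - sy.start]),
        "crop_origin": None if mode == "full" else [sx.start, sy.start],
        "dtype": dtype.str,
        "frame_files": [f.name for f in written],
    }
    side = path / "stack.yaml"
    with open(side, "w") as fh:
        yaml.safe_dump(sidecar, fh, default_flow_style=None, sort_keys=False)
    written.append(side)
    return written


def read_stack(path) -> FrameStack:
    """Lossless inverse of :func:`write_stack`.

    Reduced-mode frames are re-embedded into full-face coordinates with
    zeros outside the crop.
    """
    path = Path(path)
    side = path / "stack.yaml"
    if not side.exists():
        raise CorruptStackError(f"{path}: missing sidecar stack.yaml")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    geom = geometry_from_dict(meta["geometry"])
    scan = scan_from_dict(meta["scan"])
    info = meta["stack"]
    shape = tuple(info["frame_shape"])
    dtype = np.dtype(info["dtype"])
    nbytes = shape[0] * shape[1] * dtype.itemsize
    frames = []
    for i, name in enumerate(info["frame_files"]):
        fname = path / name
        if not fname.exists():
            raise CorruptStackError(f"frame file missing: {fname}")
        raw = np.fromfile(fname, dtype=dtype)
        if raw.size * dtype.itemsize != nbytes:
            raise CorruptStackError(
                f"frame {i} ({name}): expected {nbytes} bytes, found "
                f"{raw.size * dtype.itemsize}")
        data = raw.reshape(shape)
        if info["mode"] == "reduced":
            full = np.zeros((geom.n_x, geom.n_y), dtype=np.uint32)
            ox, oy = info["crop_origin"]
            full[ox:ox + shape[0], oy:oy + shape[1]] = data
            data = full
        else:
            data = data.astype(np.uint32)
        frames.append(ImageFrame(data, i, float(scan.phi_mid(i))))
    if len(frames) != info["n_frames"]:
        raise CorruptStackError("frame count mismatch against sidecar")
    return FrameStack(frames, scan, geom)


# ---------------------------------------------------------------------------
# text tables
# ---------------------------------------------------------------------------

#: column schemas of the inter-stage tables
TABLE_SCHEMAS = {
    "peaks": ["peak_number", "file_number", "x", "y", "intensity"],
    "qlist": ["peak_number", "qx", "qy", "qz", "intensity"],
    "ub": None,   # 3x3 matrix + cell, special-cased
    "hkl": ["h", "k", "l", "f2", "sigma_f2", "flag"],
}

_INT_COLS = {"peak_number", "file_number", "h", "k", "l"}
_STR_COLS = {"flag"}


def _records_to_frame(kind, records):
    cols = TABLE_SCHEMAS[kind]
    if isinstance(records, pd.DataFrame):
        missing = set(cols) - set(records.columns)
        if missing:
            raise ValueError(f"{kind} table missing columns {sorted(missing)}")
        return records[cols].copy()
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        if isinstance(rec, dict):
            rows.append([rec[c] for c in cols])
        else:
            rows.append(list(rec))
    df = pd.DataFrame(rows, columns=cols)
    return df


def write_table(kind: str, records, path):
    """Write an inter-stage text table (kind: peaks|qlist|ub|hkl)."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if kind == "ub":
        ub, cell = records
        ub = np.asarray(ub, dtype=float)
        if ub.shape != (3, 3):
            raise ValueError("ub table needs a 3x3 matrix")
        with open(path, "w") as fh:
            fh.write("# ub row-major (1/A), then cell a b c alpha beta gamma\n")
            for row in ub:
                fh.write(" ".join(f"{v: .12e}" for v in row) + "\n")
            if cell is not None:
                fh.write(" ".join(f"{v:.6f}" for v in cell.parameters) + "\n")
        return path
    df = _records_to_frame(kind, records)
    for i, (col, val) in enumerate(df.items()):
        if col in _INT_COLS:
            if not np.allclose(val, np.round(val)):
                bad = int(np.argmax(~np.isclose(val, np.round(val))))
                raise ValueError(f"{kind} table row {bad}, column {col!r}: "
                                 f"non-integer value {val.iloc[bad]}")
            df[col] = val.astype(int)
    if kind in ("peaks", "qlist") and np.any(df["intensity"] < 0):
        bad = int(np.argmax(df["intensity"].to_numpy() < 0))
        raise ValueError(f"{kind} table row {bad}, column 'intensity': "
                         "negative value")
    with open(path, "w") as fh:
        fh.write("# " + " ".join(df.columns) + "\n")
        for _, row in df.iterrows():
            parts = []
            for col in df.columns:
                v = row[col]
                if col in _INT_COLS:
                    parts.append(f"{int(v)}")
                elif col in _STR_COLS:
                    parts.append(str(v))
                else:
                    parts.append(f"{float(v):.10g}")
            fh.write(" ".join(parts) + "\n")
    return path


def read_table(kind: str, path):
    """Read a table written by :func:`write_table`.

    peaks/qlist/hkl return a DataFrame; ub returns (matrix, Cell or None).
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if kind == "ub":
        lines = [ln for ln in path.read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        if len(lines) < 3:
            raise ValueError(f"{path}: truncated ub table")
        ub = np.array([[float(v) for v in lines[i].split()] for i in range(3)])
        cell = None
        if len(lines) > 3:
            cell = Cell(*[float(v) for v in lines[3].split()])
        return ub, cell
    cols = TABLE_SCHEMAS[kind]
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=cols,
                     header=None)
    if df.empty:
        return pd.DataFrame(columns=cols)
    for col in cols:
        if col in _INT_COLS:
            df[col] = df[col].astype(int)
        elif col not in _STR_COLS:
            df[col] = df[col].astype(float)
    return df
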