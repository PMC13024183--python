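"""Sequence and table readers/writers.

Frames are exchanged as 0-255 grayscale float grids. Image directories are
read in lexicographic name order; color inputs are collapsed with the
standard luma transform (0.299 R + 0.587 G + 0.114 B). Detections and
ground-truth tracks round-trip through CSV with 0-based (row, col)
coordinates, row increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .feedback import Detection
from .synthetic import GroundTruth

__all__ = [
    "read_sequence",
    "write_sequence",
    "to_grayscale",
    "write_detections_csv",
    "read_detections_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "RunManifest",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an (h, w[, 3|4]) image to a 2-D luma grid (alpha ignored)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[:, :, :3] @ _LUMA
    raise ValueError(f"unsupported image shape {img.shape}")


def read_sequence(path: str | Path) -> np.ndarray:
    """Load an ordered grayscale frame stack from an image directory or a
    video file; enforces a constant frame shape."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        frames = [to_grayscale(iio.imread(p)) for p in files]
    elif path.is_file():
        frames = [to_grayscale(f) for f in iio.imiter(path)]
        if not frames:
            raise ValueError(f"no frames decodable from {path}")
    else:
        raise FileNotFoundError(str(path))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def write_sequence(frames: np.ndarray, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as 8-bit PNGs named ``<prefix>_000042.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{t:06d}.png"
        iio.imwrite(p, np.clip(np.round(frame), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_detections_csv(
    detections_by_frame: dict[int, list[Detection]], path: str | Path
) -> None:
    """Columns frame,row,col,response (0-based row/col, row downward)."""
    rows = [
        {"frame": t, "row": d.position[0], "col": d.position[1], "response": d.response}
        for t in sorted(detections_by_frame)
        for d in detections_by_frame[t]
    ]
    pd.DataFrame(rows, columns=["frame", "row", "col", "response"]).to_csv(
        path, index=False
    )


def read_detections_csv(path: str | Path) -> dict[int, list[Detection]]:
    df = pd.read_csv(path)
    out: dict[int, list[Detection]] = {}
    for rec in df.itertuples(index=False):
        t = int(rec.frame)
        out.setdefault(t, []).append(
            Detection((int(rec.row), int(rec.col)), float(rec.response), t)
        )
    return out


def write_ground_truth_csv(gt: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(gt.entries, columns=["frame", "row", "col"]).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    """Ground-truth tracks as {frame: [(row, col), ...]}."""
    df = pd.read_csv(path)
    out: dict[int, list[tuple[float, float]]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(int(rec.frame), []).append((float(rec.row), float(rec.col)))
    return out


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-identically."""

    config: dict
    input: str | dict
    seed: int
    version: str
    mode: str
    outputs: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
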