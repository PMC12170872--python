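"""Shared containers and deterministic RNG plumbing.

The pipeline passes voxel geometry alongside every image so that all
downstream measurements (volumes, surfaces, perimeters, distances) come out
in physical units rather than pixels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

__all__ = [
    "SynthConfig",
    "ImageStack3D",
    "GroundTruth",
    "rng_for",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition geometry and noise settings for all synthetic data.

    Defaults mirror the imaging setups the pipeline targets: confocal
    z-stacks at 0.2 um z-steps, TEM at 2.94 nm/px (so a 2-pixel erosion
    step corresponds to 5.88 nm), and a 3 s frame interval for ratiometric
    time-lapse recordings.
    """

    seed: int = 0
    voxel_xy_nm: float = 65.0
    voxel_z_nm: float = 200.0
    tem_px_nm: float = 2.94
    frame_interval_s: float = 3.0
    gaussian_sd: float = 0.05
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        for name in ("voxel_xy_nm", "voxel_z_nm", "tem_px_nm", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def rng_for(config: SynthConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by name.

    Each generator draws from its own child of the master seed, so adding a
    new generator never perturbs the randomness of existing ones.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(config.seed) % (2**31), spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass
class ImageStack3D:
    """Voxel grid with physical calibration.

    data is indexed (z, y, x) for a single channel, (c, z, y, x) for
    multi-channel stacks, or (t, z, y, x) for time series; the axes string
    records the order.
    """

    data: np.ndarray
    voxel_xy_nm: float
    voxel_z_nm: float
    axes: str = "ZYX"
    frame_interval_s: float | None = None

    @property
    def voxel_volume_um3(self) -> float:
        return (self.voxel_xy_nm * 1e-3) ** 2 * (self.voxel_z_nm * 1e-3)

    def channel(self, i: int) -> "ImageStack3D":
        if "C" not in self.axes:
            raise ValueError("stack has no channel axis")
        ax = self.axes.index("C")
        return ImageStack3D(
            data=np.take(self.data, i, axis=ax),
            voxel_xy_nm=self.voxel_xy_nm,
            voxel_z_nm=self.voxel_z_nm,
            axes=self.axes.replace("C", ""),
            frame_interval_s=self.frame_interval_s,
        )


class GroundTruth(dict):
    """Record of the parameters that generated a synthetic dataset.

    A plain mapping (serialisable to YAML) so recovery tests can compare
    pipeline output against the generating truth without touching the
    generator internals again.
    """

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(dict(self)), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a YAML sidecar with geometry."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    sidecar = {
        "axes": stack.axes,
        "voxel_xy_nm": float(stack.voxel_xy_nm),
        "voxel_z_nm": float(stack.voxel_z_nm),
        "frame_interval_s": (
            None if stack.frame_interval_s is None else float(stack.frame_interval_s)
        ),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_stack(path: str | Path) -> ImageStack3D:
    path = Path(path)
    data = tifffile.imread(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ImageStack3D(
        data=data,
        voxel_xy_nm=meta["voxel_xy_nm"],
        voxel_z_nm=meta["voxel_z_nm"],
        axes=meta["axes"],
        frame_interval_s=meta.get("frame_interval_s"),
    )
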