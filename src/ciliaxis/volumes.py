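"""Volume data model and channel arithmetic.

All volumes are 3D scalar fields in (z, y, x) axis order with a physical
voxel spacing in micrometers per axis. Physical coordinates refer to voxel
centers; indices are 0-based. Photon-count volumes are integer valued.

The module provides the primitives every downstream stage consumes:
isotropic resampling (confocal stacks are typically anisotropic, e.g.
41 x 41 x 189 nm or 0.053 x 0.053 x 0.311 um), spectral linear unmixing,
and lifetime-gated separation of a photon-counting channel into signal and
autofluorescence background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "MultiChannelVolume",
    "FlimVolume",
    "MixingMatrix",
    "resample_isotropic",
    "linear_unmix",
    "flim_split",
    "read_volume",
    "write_volume",
    "read_multichannel",
    "write_multichannel",
]


@dataclass
class VoxelVolume:
    """A 3D scalar field with per-axis physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensities (arbitrary units) or photon counts.
    spacing : tuple of float
        Voxel size in um, (z, y, x) order. All components > 0.
    channel : str
        Free-text channel label (e.g. "ADCY3", "Hoechst").
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) values, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive um values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-3))


@dataclass
class MultiChannelVolume:
    """Named collection of :class:`VoxelVolume` sharing one grid."""

    channels: dict[str, VoxelVolume]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        vols = list(self.channels.values())
        ref = vols[0]
        for v in vols[1:]:
            if v.shape != ref.shape:
                raise ValueError("all channels must share dimensions")
            if not np.allclose(v.spacing, ref.spacing):
                raise ValueError("all channels must share spacing")

    def __getitem__(self, name: str) -> VoxelVolume:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class FlimVolume:
    """Paired photon-count and lifetime fields from a FLIM acquisition.

    ``counts`` holds per-voxel photon counts; ``arrival`` holds the mean
    photon arrival time or fitted lifetime in ns. ``arrival`` must be finite
    wherever ``counts > 0``.
    """

    counts: np.ndarray
    arrival: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.arrival = np.asarray(self.arrival, dtype=float)
        if self.counts.shape != self.arrival.shape:
            raise ValueError("counts and arrival must share shape")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be >= 0")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("photon counts must be integer valued")
            self.counts = np.round(self.counts).astype(np.int64)
        occupied = self.counts > 0
        if not np.all(np.isfinite(self.arrival[occupied])):
            raise ValueError("arrival must be finite wherever counts > 0")
        if np.any(self.arrival[occupied] < 0):
            raise ValueError("arrival times must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class MixingMatrix:
    """Detection-channels x fluorophores spectral mixing coefficients."""

    matrix: np.ndarray
    max_condition: float = field(default=1e8, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("mixing matrix must be 2D")
        d, f = self.matrix.shape
        if d < f:
            raise ValueError(f"underdetermined mixing: {d} detection channels for {f} fluorophores")
        if np.any(self.matrix < 0):
            raise ValueError("mixing coefficients must be >= 0")
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ValueError(f"mixing matrix is singular or ill-conditioned (cond={cond:.3g})")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def resample_isotropic(
    vol: VoxelVolume,
    target: float,
    order: int = 1,
    downsample_only: bool = False,
) -> VoxelVolume:
    """Resample a volume onto an isotropic grid of ``target`` um voxels.

    The physical extent (shape x spacing) is preserved within one voxel per
    axis. ``order`` selects the interpolation spline: 1 (linear) for
    intensities, 0 (nearest-neighbor) for masks and labels.
    """
    if not np.isfinite(target) or target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if vol.values.size == 0:
        raise ValueError("cannot resample an empty volume")
    if downsample_only and target < max(vol.spacing) - 1e-9:
        raise ValueError(
            f"target {target} um is finer than coarsest axis {max(vol.spacing)} um "
            "(downsample-only mode)"
        )
    factors = tuple(s / target for s in vol.spacing)
    if np.allclose(factors, 1.0, atol=1e-9):
        return replace(vol, values=vol.values.copy(), spacing=(target,) * 3)
    out = ndimage.zoom(
        np.asarray(vol.values, dtype=float),
        factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    return VoxelVolume(out, (target,) * 3, vol.channel)


def linear_unmix(mc: MultiChannelVolume, mix: MixingMatrix,
                 fluorophores: Sequence[str] | None = None) -> MultiChannelVolume:
    """Solve per-voxel fluorophore abundances from mixed detection channels.

    The detection channels (rows of ``mix``) are taken in ``mc.names`` order.
    Abundances solve the linear model in the least-squares sense; voxels with
    negative components are refined with non-negative least squares so that
    output abundances are physical (>= 0). The number of refined voxels is
    logged.
    """
    names = mc.names
    d, f = mix.matrix.shape
    if len(names) != d:
        raise ValueError(f"{len(names)} detection channels but mixing matrix has {d} rows")
    if fluorophores is None:
        fluorophores = [f"fluor{i}" for i in range(f)] if f != d else names
    if len(fluorophores) != f:
        raise ValueError("one name per fluorophore required")

    shape = mc.shape
    y = np.stack([np.asarray(mc[n].values, dtype=float).ravel() for n in names])  # (d, N)
    x, *_ = np.linalg.lstsq(mix.matrix, y, rcond=None)  # (f, N)

    neg = np.any(x < -1e-12, axis=0)
    n_neg = int(neg.sum())
    if n_neg:
        logger.info("linear_unmix: refining %d voxels with negative components via NNLS", n_neg)
        idx = np.flatnonzero(neg)
        for j in idx:
            x[:, j], _ = optimize.nnls(mix.matrix, y[:, j])
    np.clip(x, 0.0, None, out=x)

    spacing = mc.spacing
    channels = {
        name: VoxelVolume(x[i].reshape(shape), spacing, channel=name)
        for i, name in enumerate(fluorophores)
    }
    return MultiChannelVolume(channels)


def flim_split(fv: FlimVolume, gate: float = 1.0) -> tuple[VoxelVolume, VoxelVolume]:
    """Separate a photon-counting channel by mean arrival time.

    Voxels whose mean photon arrival time is >= ``gate`` (ns) contribute their
    counts to the signal volume, the rest to the background volume. The two
    output volumes sum to ``fv.counts`` exactly. The default 1.0 ns gate sits
    between the autofluorescence population (peak 0.3 ns) and dye-conjugate
    signal (peak 2.3 ns).
    """
    if not np.isfinite(gate) or gate <= 0:
        raise ValueError(f"gate must be a positive finite time in ns, got {gate}")
    hot = (fv.arrival >= gate) & (fv.counts > 0)
    signal = np.where(hot, fv.counts, 0)
    background = fv.counts - signal
    return (
        VoxelVolume(signal, fv.spacing, channel="signal"),
        VoxelVolume(background, fv.spacing, channel="background"),
    )


# ---------------------------------------------------------------------------
# OME-TIFF I/O with spacing metadata (JSON sidecar fallback)

def _ome_safe(arr: np.ndarray) -> np.ndarray:
    """Coerce to a dtype the OME-TIFF writer supports."""
    if arr.dtype == np.float64:
        return arr.astype(np.float32)
    if arr.dtype in (np.int64, np.uint64):
        return arr.astype(np.int32)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    return arr


def _spacing_metadata(spacing: Sequence[float]) -> dict:
    z, y, x = spacing
    return {
        "PhysicalSizeZ": z, "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": y, "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": x, "PhysicalSizeXUnit": "µm",
    }


def write_volume(path: str | Path, vol: VoxelVolume) -> None:
    """Write a single-channel volume as OME-TIFF with spacing metadata."""
    path = Path(path)
    meta = {"axes": "ZYX", **_spacing_metadata(vol.spacing)}
    if vol.channel:
        meta["Channel"] = {"Name": [vol.channel]}
    tifffile.imwrite(path, _ome_safe(np.asarray(vol.values)), ome=True,
                     photometric="minisblack", metadata=meta)


def write_multichannel(path: str | Path, mc: MultiChannelVolume) -> None:
    """Write a multichannel volume as OME-TIFF (CZYX)."""
    path = Path(path)
    stack = _ome_safe(np.stack([np.asarray(mc[n].values) for n in mc.names]))
    meta = {
        "axes": "CZYX",
        **_spacing_metadata(mc.spacing),
        "Channel": {"Name": mc.names},
    }
    tifffile.imwrite(path, stack, ome=True, photometric="minisblack", metadata=meta)


def _read_ome(path: Path) -> tuple[np.ndarray, tuple | None, list[str]]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = None
        names: list[str] = []
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                sz = px.get("PhysicalSizeZ")
                sy = px.get("PhysicalSizeY")
                sx = px.get("PhysicalSizeX")
                if sz and sy and sx:
                    spacing = (float(sz), float(sy), float(sx))
                names = [
                    c.get("Name") or f"ch{i}"
                    for i, c in enumerate(px.findall("ome:Channel", ns))
                ]
    return data, spacing, names


def _sidecar_spacing(path: Path) -> tuple | None:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sp = meta.get("spacing_um") or meta.get("spacing")
        if sp is not None:
            return tuple(float(v) for v in sp)
    return None


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a single-channel OME-TIFF/TIFF volume.

    Spacing comes from OME metadata or a ``<name>.tif.json`` sidecar with a
    ``spacing_um`` entry; a volume without spacing is a hard error.
    """
    path = Path(path)
    data, spacing, names = _read_ome(path)
    if spacing is None:
        spacing = _sidecar_spacing(path)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in OME metadata and no JSON sidecar; "
            "refusing to guess physical units"
        )
    if data.ndim == 4 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VoxelVolume(data, spacing, channel=names[0] if names else "")


def read_multichannel(path: str | Path) -> MultiChannelVolume:
    """Read a CZYX OME-TIFF as a :class:`MultiChannelVolume`."""
    path = Path(path)
    data, spacing, names = _read_ome(path)
    if spacing is None:
        spacing = _sidecar_spacing(path)
    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing metadata (OME or sidecar)")
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected CZYX data, got shape {data.shape}")
    if len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return MultiChannelVolume(
        {n: VoxelVolume(data[i], spacing, channel=n) for i, n in enumerate(names)}
    )
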