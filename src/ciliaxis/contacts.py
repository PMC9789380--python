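"""Skeleton-based cilium-axon contact mapping.

Segmented cilia and axon masks are reduced to one-voxel central axes
(3D topological thinning); connected skeleton components define instances.
Distances from every cilium skeleton voxel to the nearest target voxel
(axon skeleton, synaptophysin mask, nuclei) come from the Euclidean
distance transform of the target, sampled along the cilium axis. A cilium
is axon-contacting when its minimum axis-to-axis distance is within the
contact cutoff (2 um by default, the upper end of the 1-3 um varicosity
scale); puncta within 1 um of an axon axis are axon-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .puncta import PunctaSet
from .segmentation import BinaryMask
from .volumes import VoxelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonSet",
    "ContactParams",
    "skeletonize_instances",
    "cilium_length",
    "distance_on_skeleton",
    "filter_cilia",
    "classify_contacts",
    "associate_puncta",
    "percent_of",
    "ciliary_fraction",
    "build_cilium_table",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ContactParams:
    """Cutoffs for contact classification (um) and boundary exclusion (voxels)."""

    contact_cutoff: float = 2.0
    puncta_axon_cutoff: float = 1.0
    boundary_margin: int = 1

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.puncta_axon_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")


@dataclass
class SkeletonSet:
    """Per-instance skeleton voxel chains on an isotropic grid.

    ``instances`` holds one (n_i, 3) integer voxel-index array per connected
    skeleton component; ``spacing`` and ``shape`` describe the source grid.
    """

    instances: list[np.ndarray]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for inst in self.instances:
            if len(inst) < 1:
                raise ValueError("skeleton instances must have >= 1 voxel")

    def __len__(self) -> int:
        return len(self.instances)

    def to_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for inst in self.instances:
            out[tuple(inst.T)] = True
        return out


def _require_isotropic(spacing) -> float:
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        raise ValueError(
            f"anisotropic spacing {tuple(spacing)}: resample to an isotropic grid "
            "first (resample_isotropic)"
        )
    return float(spacing[0])


def _penalized_centerline(comp: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Centerline of one mask component as an EDT-penalized geodesic.

    Steps through high-distance (central) voxels are cheap, so the shortest
    path between the farthest voxel pair hugs the medial axis. Used where
    parity-sensitive topological thinning collapses.
    """
    edt = ndimage.distance_transform_edt(comp)
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(np.sqrt(3) + 1e-6):
        step = float(np.linalg.norm(coords[i] - coords[j]))
        penalty = (1.0 + 0.5 * (edt[tuple(coords[i])] + edt[tuple(coords[j])])) ** 2
        g.add_edge(i, j, weight=step / penalty)
    start = next(iter(max(nx.connected_components(g), key=len)))
    d0 = nx.single_source_dijkstra_path_length(g, start)
    a = max(d0, key=d0.get)
    da = nx.single_source_dijkstra_path_length(g, a)
    b = max(da, key=da.get)
    return coords[nx.dijkstra_path(g, a, b)]


def skeletonize_instances(mask: BinaryMask) -> SkeletonSet:
    """Central axes of a binary mask; connected components become instances.

    3D topological thinning is the primary skeletonizer. Thinning of
    even-thickness symmetric tubes can collapse (partially or entirely), so
    each mask component whose thinned skeleton is missing, fragmented, or
    covers less than half the component's spatial extent falls back to an
    EDT-penalized geodesic centerline.
    """
    _require_isotropic(mask.spacing)
    sk = skeletonize(mask.values)
    comp_labels, n = ndimage.label(mask.values, structure=_CONN26)
    objects = ndimage.find_objects(comp_labels)
    instances = []
    for i in range(1, n + 1):
        sl = objects[i - 1]
        comp = comp_labels[sl] == i
        sk_comp = sk[sl] & comp
        offset = np.array([s.start for s in sl])
        coords_sk = np.argwhere(sk_comp)
        ok = len(coords_sk) > 0
        if ok:
            _, n_sk = ndimage.label(sk_comp, structure=_CONN26)
            extent_sk = np.linalg.norm(np.ptp(coords_sk, axis=0))
            extent_comp = np.linalg.norm(np.ptp(np.argwhere(comp), axis=0))
            ok = n_sk == 1 and extent_sk >= 0.5 * extent_comp
        if ok:
            instances.append(coords_sk + offset)
        else:
            logger.info("skeletonize_instances: thinning collapsed component %d; "
                        "using penalized-geodesic centerline", i)
            coords = np.argwhere(comp)
            instances.append(_penalized_centerline(comp, coords) + offset)
    return SkeletonSet(instances, mask.spacing, mask.shape)


def _skeleton_graph(coords: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    if len(coords) > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(np.sqrt(3) + 1e-6):
            g.add_edge(i, j, weight=float(np.linalg.norm(coords[i] - coords[j])))
    return g


def _longest_geodesic(coords: np.ndarray) -> np.ndarray:
    """Ordered voxel path of the longest geodesic through a skeleton instance.

    Two sweeps of Dijkstra from an arbitrary node find the graph diameter;
    short side branches are bypassed by construction.
    """
    if len(coords) <= 2:
        return coords.astype(float)
    g = _skeleton_graph(coords)
    comp = max(nx.connected_components(g), key=len)
    start = next(iter(comp))
    d0 = nx.single_source_dijkstra_path_length(g, start)
    a = max(d0, key=d0.get)
    da = nx.single_source_dijkstra_path_length(g, a)
    b = max(da, key=da.get)
    path = nx.dijkstra_path(g, a, b)
    return coords[path].astype(float)


def _smooth_path(path: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(path) <= 2:
        return path.astype(float)
    k = np.ones(window) / window
    pad = window // 2
    out = np.empty_like(path, dtype=float)
    for ax in range(path.shape[1]):
        out[:, ax] = np.convolve(np.pad(path[:, ax], pad, mode="edge"), k, mode="valid")
    out[0], out[-1] = path[0], path[-1]
    return out


def cilium_length(
    instance: np.ndarray,
    spacing,
    mask: np.ndarray | None = None,
    smooth_window: int = 5,
) -> float:
    """Physical length (um) of one skeleton instance.

    The longest geodesic path through the instance is smoothed with a short
    moving average (raw 26-connectivity step sums inflate oblique straight
    runs by the lattice effect) and its segment lengths summed. When the
    source ``mask`` is given, each end of the path is extended along its
    local tangent to the mask boundary minus the local tube radius (distance
    transform at the endpoint), compensating the end retraction of
    topological thinning. ``smooth_window=1`` with ``mask=None`` gives the
    raw step-length sum.
    """
    instance = np.asarray(instance)
    if len(instance) == 0:
        raise ValueError("empty skeleton instance")
    iso = _require_isotropic(spacing)
    if len(instance) == 1:
        return 0.0
    path = _longest_geodesic(instance)
    smoothed = _smooth_path(path, smooth_window)
    length = float(np.sum(np.linalg.norm(np.diff(smoothed, axis=0), axis=1))) * iso
    if mask is None:
        return length
    # crop to the path neighborhood: the EDT is only read at the path ends
    # and the tangent march never leaves the pad
    pad = 20
    lo = np.maximum(path.min(axis=0).astype(int) - pad, 0)
    hi = np.minimum(path.max(axis=0).astype(int) + pad + 1, np.asarray(mask.shape))
    mask = np.asarray(mask)[tuple(slice(l, h) for l, h in zip(lo, hi))]
    smoothed = smoothed - lo
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    shape = np.asarray(mask.shape)
    interior = smoothed[2:-2] if len(smoothed) > 6 else smoothed
    idx_int = np.clip(np.round(interior).astype(int), 0, shape - 1)
    r_tube = float(np.median(edt[tuple(idx_int.T)]))
    k = min(5, len(smoothed) - 1)
    for end, inner in ((0, k), (-1, -1 - k)):
        tangent = smoothed[end] - smoothed[inner]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        p = smoothed[end]
        step, traveled = 0.25, 0.0
        while traveled < 60.0:
            q = p + tangent * (traveled + step)
            idx = np.round(q).astype(int)
            if np.any(idx < 0) or np.any(idx >= shape) or not mask[tuple(idx)]:
                break
            traveled += step
        # extend to the mask boundary, minus the tube radius: corrects both
        # thinning end-retraction (positive) and tip-to-tip centerline
        # overshoot (negative)
        length += traveled * iso - r_tube
    return max(length, 0.0)


def distance_on_skeleton(
    cilia: SkeletonSet,
    target: BinaryMask | SkeletonSet,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Distance (um) from every cilium axis voxel to the nearest target voxel.

    The Euclidean distance transform of the target mask is sampled at the
    cilium skeleton voxels ("multiplying" the distance field by the skeleton
    mask). Returns the per-voxel distance arrays and the per-cilium minima;
    an empty target yields +inf distances (flagged with a warning).
    """
    if isinstance(target, SkeletonSet):
        if target.shape != cilia.shape:
            raise ValueError("cilia and target skeletons must share the grid")
        target_mask = target.to_mask()
        spacing = target.spacing
    else:
        if target.shape != cilia.shape:
            raise ValueError("cilia skeleton and target mask must share the grid")
        target_mask = target.values
        spacing = target.spacing
    if not np.allclose(spacing, cilia.spacing):
        raise ValueError("cilia and target must share voxel spacing")
    _require_isotropic(spacing)

    if not target_mask.any():
        logger.warning("distance_on_skeleton: empty target, distances are +inf")
        per_voxel = [np.full(len(inst), np.inf) for inst in cilia.instances]
        return per_voxel, np.full(len(cilia), np.inf)

    edt = ndimage.distance_transform_edt(~target_mask, sampling=spacing)
    per_voxel = [edt[tuple(inst.T)] for inst in cilia.instances]
    minima = np.array([d.min() if len(d) else np.inf for d in per_voxel])
    return per_voxel, minima


def filter_cilia(
    skels: SkeletonSet,
    layer: BinaryMask,
    nuclei_centers: np.ndarray,
    params: ContactParams | None = None,
) -> pd.DataFrame:
    """Flag cilia to exclude: near the volume boundary or owned by an
    out-of-layer nucleus.

    Each cilium is assigned to the nucleus centroid nearest to its base (the
    geodesic endpoint closest to any nucleus); the cilium is excluded when
    that centroid falls outside the layer mask. Returns a cilium table with
    ``excluded`` / ``exclusion_reason`` / ``nucleus_id`` /
    ``min_nucleus_distance`` columns.
    """
    params = params or ContactParams()
    if layer.shape != skels.shape:
        raise ValueError("layer mask and skeletons must share the grid")
    spacing = np.asarray(skels.spacing)
    shape = np.asarray(skels.shape)
    centers = np.asarray(nuclei_centers, dtype=float).reshape(-1, 3)
    tree = cKDTree(centers) if len(centers) else None

    rows = []
    for i, inst in enumerate(skels.instances):
        reason = "none"
        near_edge = bool(
            np.any(inst < params.boundary_margin)
            or np.any(inst >= shape - params.boundary_margin)
        )
        nucleus_id, nucleus_dist = -1, np.inf
        if tree is not None:
            path = _longest_geodesic(inst)
            ends_um = path[[0, -1]] * spacing
            d, idx = tree.query(ends_um)
            base = int(np.argmin(d))
            nucleus_dist = float(np.min(d))
            nucleus_id = int(np.atleast_1d(idx)[base])
        if near_edge:
            reason = "boundary"
        elif nucleus_id >= 0:
            c_vox = np.round(centers[nucleus_id] / spacing).astype(int)
            c_vox = np.clip(c_vox, 0, shape - 1)
            if not layer.values[tuple(c_vox)]:
                reason = "non_layer_nucleus"
        rows.append(
            {
                "id": i,
                "excluded": reason != "none",
                "exclusion_reason": reason,
                "nucleus_id": nucleus_id,
                "min_nucleus_distance": nucleus_dist,
            }
        )
    return pd.DataFrame(rows)


def classify_contacts(table: pd.DataFrame, params: ContactParams | None = None) -> pd.DataFrame:
    """Set the ``contacting`` flag from ``min_axon_distance``.

    Inclusive comparison: a cilium at exactly the cutoff counts as
    contacting. Excluded cilia keep ``contacting`` as missing.
    """
    params = params or ContactParams()
    if "min_axon_distance" not in table:
        raise ValueError("min_axon_distance not populated")
    if table["min_axon_distance"].isna().any():
        raise ValueError("min_axon_distance contains missing values")
    out = table.copy()
    active = ~out["excluded"] if "excluded" in out else np.ones(len(out), dtype=bool)
    out["contacting"] = pd.array([pd.NA] * len(out), dtype="boolean")
    out.loc[active, "contacting"] = (
        out.loc[active, "min_axon_distance"] <= params.contact_cutoff
    )
    return out


def associate_puncta(
    puncta: PunctaSet,
    axon_skel: SkeletonSet,
    params: ContactParams | None = None,
) -> PunctaSet:
    """Label puncta within the axon cutoff of any axon central-axis voxel."""
    params = params or ContactParams()
    if len(puncta.coords) == 0:
        return PunctaSet(puncta.coords, puncta.responses, puncta.channel,
                         association=np.zeros(0, dtype=bool))
    all_vox = [inst for inst in axon_skel.instances if len(inst)]
    if not all_vox:
        assoc = np.zeros(len(puncta.coords), dtype=bool)
    else:
        skel_um = np.vstack(all_vox) * np.asarray(axon_skel.spacing)
        d, _ = cKDTree(skel_um).query(puncta.coords)
        assoc = d <= params.puncta_axon_cutoff
    return PunctaSet(puncta.coords, puncta.responses, puncta.channel, association=assoc)


def percent_of(count: int, total: int) -> int:
    """Percentage rounded to the nearest integer, e.g. 426/1209 -> 35."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(np.rint(100.0 * count / total))


def ciliary_fraction(
    receptor: VoxelVolume,
    cilia_mask: BinaryMask,
    dilate_px: int = 1,
    total_threshold: float = 20.0,
) -> float:
    """Fraction of total receptor signal that is ciliary.

    Integrated receptor intensity inside the ``dilate_px``-dilated cilia mask
    divided by the integrated intensity over all voxels at or above
    ``total_threshold`` (photon counts; 20 by default).
    """
    if receptor.shape != cilia_mask.shape:
        raise ValueError("receptor volume and cilia mask must share the grid")
    vals = np.asarray(receptor.values, dtype=float)
    supra = vals * (vals >= total_threshold)
    total = supra.sum()
    if total <= 0:
        raise ValueError("no receptor signal at or above the total threshold")
    mask = cilia_mask.values
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, structure=_CONN26, iterations=dilate_px)
    inside = supra[mask].sum()
    return float(inside / total)


def build_cilium_table(
    cilia_skels: SkeletonSet,
    axon_skels: SkeletonSet,
    layer: BinaryMask,
    nuclei_centers: np.ndarray,
    cilia_mask: BinaryMask | None = None,
    sert_synaptophysin: BinaryMask | None = None,
    params: ContactParams | None = None,
) -> pd.DataFrame:
    """One row per cilium: length, minimum distances, exclusion, contact flag.

    Convenience pipeline tying together exclusion filtering, axis-to-axis
    distance encoding, length measurement and contact classification.
    """
    params = params or ContactParams()
    table = filter_cilia(cilia_skels, layer, nuclei_centers, params)
    _, min_axon = distance_on_skeleton(cilia_skels, axon_skels)
    table["min_axon_distance"] = min_axon
    if sert_synaptophysin is not None:
        _, min_syp = distance_on_skeleton(cilia_skels, sert_synaptophysin)
        table["min_sert_synaptophysin_distance"] = min_syp
    mask_arr = cilia_mask.values if cilia_mask is not None else None
    table["length"] = [
        cilium_length(inst, cilia_skels.spacing, mask=mask_arr)
        for inst in cilia_skels.instances
    ]
    return classify_contacts(table, params)
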