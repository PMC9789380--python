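"""Synthetic microscopy scenes with known ground truth.

The package's only data source: multichannel volumes emulating stained
hippocampal tissue (a band of nuclei, tubular cilia emanating from them,
axons with 1-3 um varicosities, diffraction-limited puncta, receptor signal
enriched on ciliary subsegments), ratiometric nuclear stainings with
planted per-nucleus marker/DNA ratios and depth attenuation, FLIM volumes
with parametric lifetime fields, and stimulus-locked biosensor traces.

Every planted quantity is recorded in a truth object so each pipeline stage
can be scored against ground truth. Identical parameters and seed give
bit-identical scenes; independent random substreams per structure keep
added structures from perturbing existing ones.

Scene geometry places each cilium-axon pair in its own grid cell with
alternating z levels, so a pair's planted minimum axis-to-axis distance is
also the global minimum over all axons (cross-cell distances exceed the
largest planted distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .photophysics import DoseResponse, Trace
from .volumes import FlimVolume, MultiChannelVolume, VoxelVolume

__all__ = [
    "ContactSceneParams",
    "ContactTruth",
    "make_contact_scene",
    "RatioSceneParams",
    "RatioTruth",
    "make_ratiometric_scene",
    "FlimSceneParams",
    "FlimTruth",
    "make_flim_scene",
    "TraceParams",
    "TraceTruth",
    "make_traces",
]


# ---------------------------------------------------------------------------
# rasterization helpers

def _curve_mask(shape, spacing, pts, radii) -> np.ndarray:
    """Voxels within ``radii`` (um) of a polyline given by dense ``pts`` (um)."""
    from scipy.spatial import cKDTree

    pts = np.asarray(pts, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(pts),))
    sp = np.asarray(spacing)
    rmax = radii.max()
    lo = np.maximum(np.floor((pts.min(axis=0) - rmax) / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((pts.max(axis=0) + rmax) / sp).astype(int) + 2,
                    np.asarray(shape))
    if np.any(hi <= lo):
        return np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1) * sp
    dist, idx = cKDTree(pts).query(vox)
    inside = dist <= radii[idx]
    out = np.zeros(shape, dtype=bool)
    box = tuple(g.ravel()[inside] for g in grids)
    out[box] = True
    return out


def _sphere_mask(shape, spacing, center, radius) -> np.ndarray:
    sp = np.asarray(spacing)
    center = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor((center - radius) / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + radius) / sp).astype(int) + 2, np.asarray(shape))
    out = np.zeros(shape, dtype=bool)
    if np.any(hi <= lo):
        return out
    grids = np.ogrid[tuple(slice(l, h) for l, h in zip(lo, hi))]
    d2 = sum(((g * s - c) ** 2) for g, s, c in zip(grids, sp, center))
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] = d2 <= radius**2
    return out


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _finish_channel(raster, amplitude, background, psf_sigma_vox, attenuation,
                    poisson, read_noise, rng):
    """Blur, attenuate, add background and noise to a float intensity field."""
    img = np.asarray(raster, dtype=float) * amplitude
    if psf_sigma_vox is not None and np.any(np.asarray(psf_sigma_vox) > 0):
        img = ndimage.gaussian_filter(img, psf_sigma_vox)
    img += background
    if attenuation is not None:
        img *= attenuation[:, None, None]
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if read_noise > 0:
        img = img + rng.normal(0.0, read_noise, size=img.shape)
    return np.clip(img, 0, None)


# ---------------------------------------------------------------------------
# contact scene

@dataclass
class ContactSceneParams:
    """Study-scale geometry of the stained-volume scene.

    Sizes follow the imaging conditions the pipeline targets: 0.189 um
    isotropic grid, cilium lengths around a 7 um median, tube radii of a few
    hundred nm, varicosities on the 1-3 um scale, and planted cilium-axon
    distances split across the 2 um contact cutoff. The default receptor
    enrichment places 94% of supra-threshold receptor signal on cilia.
    """

    shape: tuple[int, int, int] = (64, 256, 256)
    spacing: float = 0.189
    grid: tuple[int, int] = (4, 5)
    n_pairs: int = 20
    cilium_length_range: tuple[float, float] = (5.0, 8.5)
    cilium_radius: float = 0.25
    axon_radius: float = 0.25
    varicosity_radius: float = 0.45
    varicosity_spacing: float = 2.0
    contact_distances: tuple[float, ...] | None = None
    contact_fraction: float = 0.35  # the fraction of cilia in axon contact
    contact_cutoff: float = 2.0
    nucleus_radius: float = 1.5
    n_stray_nuclei: int = 0
    puncta_per_cell: tuple[int, int] = (2, 1)  # (associated, unassociated)
    puncta_offsets: tuple[float, float] = (0.4, 1.6)
    puncta_sigma: float = 0.15
    receptor_ciliary_fraction: float = 0.94
    amplitude: float = 500.0
    background: float = 2.0
    psf_sigma: tuple[float, float, float] | None = (0.3, 0.1, 0.1)
    poisson_noise: bool = True
    read_noise: float = 1.5
    z_levels: tuple[float, float] = (3.5, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if self.n_pairs > rows * cols:
            raise ValueError(f"{self.n_pairs} pairs do not fit a {rows}x{cols} cell grid")
        if self.cilium_radius <= 0 or self.axon_radius <= 0 or self.nucleus_radius <= 0:
            raise ValueError("radii must be > 0")
        extent_y = self.shape[1] * self.spacing / rows
        if self.cilium_length_range[1] > extent_y - 3.4:
            raise ValueError(
                f"cilium length {self.cilium_length_range[1]} um does not fit a "
                f"{extent_y:.1f} um grid cell"
            )


@dataclass
class ContactTruth:
    """Ground truth for a contact scene."""

    cilia: pd.DataFrame           # id, length, axon_distance, contact, nucleus_id, in_layer
    curves: list[np.ndarray]      # dense cilium centerlines (um)
    axon_curves: list[np.ndarray]
    nuclei_centers: np.ndarray    # (n, 3) um
    nuclei_in_layer: np.ndarray   # bool per nucleus
    puncta: pd.DataFrame          # z_um, y_um, x_um, associated
    receptor_ciliary_fraction: float
    masks: dict[str, np.ndarray]  # noise-free boolean rasters per channel


def _cilium_curve(base, direction_y, length, rng, n=300):
    """Gently curved centerline from ``base`` along +/-y with a distal bend.

    The bend is confined to the distal 30% and points in -x / +z, i.e. away
    from the paired axon, so the planted minimum distance is attained on the
    straight proximal segment.
    """
    t = np.linspace(0.0, 1.0, n)
    bend = np.clip(t - 0.7, 0.0, None) ** 2 / 0.09  # 0 -> 1 over distal 30%
    ax = 0.5 + 0.3 * rng.random()
    az = 0.4 + 0.3 * rng.random()
    pts = np.empty((n, 3))
    pts[:, 0] = base[0] + az * bend
    pts[:, 1] = base[1] + direction_y * length * t
    pts[:, 2] = base[2] - ax * bend
    # rescale y extent so the arc length matches the requested length
    arc = _polyline_length(pts)
    pts[:, 1] = base[1] + direction_y * length * t * (length / arc)
    return pts


def _axon_curve(x_contact, y_mid, y_half, z_level, rng, n=400):
    """Axon centerline along y, at x_contact in the central window, bending
    away (+x) toward the ends so the closest approach is in the window."""
    y = np.linspace(y_mid - y_half, y_mid + y_half, n)
    away = np.clip(np.abs(y - y_mid) - 1.2, 0.0, None) ** 2 * 0.25
    away = np.minimum(away, 1.0)
    z_wiggle = 0.3 * np.sin((y - y_mid) / y_half * np.pi) * np.clip(
        np.abs(y - y_mid) - 1.2, 0, None
    ) / y_half
    pts = np.empty((n, 3))
    pts[:, 0] = z_level + z_wiggle
    pts[:, 1] = y
    pts[:, 2] = x_contact + away
    return pts


def make_contact_scene(params: ContactSceneParams | None = None,
                       seed: int | None = None) -> tuple[MultiChannelVolume, ContactTruth]:
    """Generate a five-channel stained-volume scene with planted geometry.

    Channels: ``nuclei`` (DNA stain), ``cilia`` (ciliary marker), ``axon``
    (serotonergic-axon marker), ``puncta`` (presynaptic vesicle marker),
    ``receptor`` (ciliary receptor). Returns the volume and a
    :class:`ContactTruth` with per-cilium planted lengths, minimum
    cilium-axon axis distances, contact labels, puncta coordinates and
    association labels, and the noise-free channel rasters.
    """
    params = params or ContactSceneParams()
    if seed is not None:
        params = ContactSceneParams(**{**params.__dict__, "seed": seed})
    sp = (params.spacing,) * 3
    shape = params.shape
    rows, cols = params.grid
    extent = np.asarray(shape) * params.spacing
    cell_y, cell_x = extent[1] / rows, extent[2] / cols

    ss = np.random.SeedSequence(params.seed)
    geom_ss, punc_ss, noise_ss = ss.spawn(3)
    cell_rngs = [np.random.default_rng(s) for s in geom_ss.spawn(rows * cols)]
    punc_rng = np.random.default_rng(punc_ss)
    noise_rng = np.random.default_rng(noise_ss)

    # planted distances: a contacting and a non-contacting population, each
    # at least 0.5 um clear of the cutoff
    if params.contact_distances is not None:
        dists = np.asarray(params.contact_distances, dtype=float)
        if len(dists) != params.n_pairs:
            raise ValueError("one planted distance per pair required")
    else:
        n_contact = int(round(params.contact_fraction * params.n_pairs))
        master = np.random.default_rng(geom_ss)
        near = master.uniform(0.5, params.contact_cutoff - 0.5, size=n_contact)
        far = master.uniform(params.contact_cutoff + 0.5, 3.0,
                             size=params.n_pairs - n_contact)
        dists = np.concatenate([near, far])
        master.shuffle(dists)

    masks = {name: np.zeros(shape, dtype=bool)
             for name in ("nuclei", "cilia", "axon", "puncta_sites", "receptor")}
    puncta_field = np.zeros(shape, dtype=float)

    curves, axon_curves = [], []
    nuc_centers, nuc_in_layer = [], []
    cil_rows, punc_rows = [], []
    receptor_in = np.zeros(shape, dtype=bool)

    for k in range(params.n_pairs):
        r, c = divmod(k, cols)
        rng = cell_rngs[k]
        y0c, x0c = r * cell_y, c * cell_x
        zc = params.z_levels[r % 2]
        length = rng.uniform(*params.cilium_length_range)
        d = float(dists[k])
        x_cil = x0c + 2.5
        flip = r % 2 == 1  # bidirectional launch: alternate rows point -y
        if not flip:
            nuc_y = y0c + 1.7
            base = np.array([zc, y0c + 3.0, x_cil])
            direction = 1.0
        else:
            nuc_y = y0c + cell_y - 1.7
            base = np.array([zc, y0c + cell_y - 3.0, x_cil])
            direction = -1.0
        nuc_center = np.array([zc, nuc_y, x_cil])
        curve = _cilium_curve(base, direction, length, rng)
        true_len = _polyline_length(curve)
        y_mid = float(curve[len(curve) // 2, 1])
        axon = _axon_curve(x_cil + d, y_mid, min(5.0, cell_y / 2 - 0.4), zc, rng)

        masks["nuclei"] |= _sphere_mask(shape, sp, nuc_center, params.nucleus_radius)
        cil_mask = _curve_mask(shape, sp, curve, params.cilium_radius)
        masks["cilia"] |= cil_mask
        # varicosities: radius bumps at the stated spacing along the axon
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(axon, axis=0), axis=1))])
        phase = rng.uniform(0, params.varicosity_spacing)
        bump = np.exp(-0.5 * ((np.mod(s - phase, params.varicosity_spacing)
                               - params.varicosity_spacing / 2) / 0.3) ** 2)
        radii = params.axon_radius + (params.varicosity_radius - params.axon_radius) * bump
        masks["axon"] |= _curve_mask(shape, sp, axon, radii)

        # receptor enrichment on the distal half of the cilium
        distal = _curve_mask(shape, sp, curve[len(curve) // 2:], params.cilium_radius)
        receptor_in |= distal

        curves.append(curve)
        axon_curves.append(axon)
        nuc_centers.append(nuc_center)
        nuc_in_layer.append(True)
        cil_rows.append({
            "id": k, "length": true_len, "axon_distance": d,
            "contact": d <= params.contact_cutoff, "nucleus_id": k, "in_layer": True,
        })

        # puncta: associated within the axon cutoff, unassociated beyond it
        n_assoc, n_far = params.puncta_per_cell
        off_near, off_far = params.puncta_offsets
        for n_p, off, assoc in ((n_assoc, off_near, True), (n_far, off_far, False)):
            for _ in range(n_p):
                j = punc_rng.integers(40, len(axon) - 40)
                phi = punc_rng.uniform(0, 2 * np.pi)
                offset = np.array([np.sin(phi) * off, 0.0, np.abs(np.cos(phi)) * off])
                if offset[2] == 0:
                    offset[2] = off * 0.2
                pos = axon[j] + offset
                punc_rows.append({"z_um": pos[0], "y_um": pos[1], "x_um": pos[2],
                                  "associated": assoc})

    # densify the nucleus band so it reads as one cell layer: filler nuclei
    # along each row's nucleus line plus bridge chains between rows, all
    # connected under a ~1.5 um layer dilation
    pair_x = {round(c * cell_x + 2.5, 3) for c in range(cols)}
    row_lines = []
    for r in range(rows):
        zc = params.z_levels[r % 2]
        nuc_y = r * cell_y + (1.7 if r % 2 == 0 else cell_y - 1.7)
        row_lines.append((zc, nuc_y))
        for x in np.arange(2.5, extent[2] - 1.0, 2.8):
            if min(abs(x - px) for px in pair_x) < 1.0:
                continue
            pos = np.array([zc, nuc_y, x])
            masks["nuclei"] |= _sphere_mask(shape, sp, pos, params.nucleus_radius)
            nuc_centers.append(pos)
            nuc_in_layer.append(True)
    bridge_x = [c * cell_x + 7.3 for c in range(0, cols, 2)]
    for r in range(rows - 1):
        (z0, y0b), (z1, y1b) = row_lines[r], row_lines[r + 1]
        n_b = max(int(np.ceil(abs(y1b - y0b) / 3.0)) - 1, 1)
        for x in bridge_x:
            for t in np.linspace(0, 1, n_b + 2)[1:-1]:
                pos = np.array([z0 + (z1 - z0) * t, y0b + (y1b - y0b) * t, x])
                masks["nuclei"] |= _sphere_mask(shape, sp, pos, params.nucleus_radius)
                nuc_centers.append(pos)
                nuc_in_layer.append(True)

    # stray nuclei off the band: top of the volume above unbridged columns,
    # midway between row lines, clear of the dilated band
    stray_sites = [
        (extent[0] - params.nucleus_radius - 0.2,
         0.5 * (row_lines[r][1] + row_lines[r + 1][1]),
         c * cell_x + 7.3)
        for r in range(rows - 1) for c in range(1, cols, 2)
    ]
    if params.n_stray_nuclei > len(stray_sites):
        raise ValueError(f"at most {len(stray_sites)} stray nuclei fit this layout")
    for pos in stray_sites[: params.n_stray_nuclei]:
        pos = np.asarray(pos)
        masks["nuclei"] |= _sphere_mask(shape, sp, pos, params.nucleus_radius * 0.8)
        nuc_centers.append(pos)
        nuc_in_layer.append(False)

    # puncta intensity field: Gaussian spots at the planted positions
    sigma_vox = params.puncta_sigma / params.spacing
    for row in punc_rows:
        pos_vox = np.array([row["z_um"], row["y_um"], row["x_um"]]) / params.spacing
        idx = np.round(pos_vox).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.asarray(shape)):
            puncta_field[tuple(idx)] += 1.0
            masks["puncta_sites"][tuple(idx)] = True
    puncta_field = ndimage.gaussian_filter(puncta_field, max(sigma_vox, 0.8))
    if puncta_field.max() > 0:
        puncta_field /= puncta_field.max()

    # extra-ciliary receptor pool scaled to the planted ciliary fraction
    receptor_out = np.zeros(shape, dtype=bool)
    rec_rng = np.random.default_rng(geom_ss.spawn(2)[1])
    for k in range(params.n_pairs):
        r, c = divmod(k, cols)
        zc = params.z_levels[r % 2]
        center = np.array([zc + rec_rng.uniform(-1.5, 1.5),
                           r * cell_y + cell_y / 2,
                           c * cell_x + cell_x - 1.2])
        receptor_out |= _sphere_mask(shape, sp, center, 0.4)
    receptor_out &= ~ndimage.binary_dilation(masks["cilia"], iterations=3)
    f = params.receptor_ciliary_fraction
    n_in, n_out = int(receptor_in.sum()), int(receptor_out.sum())
    amp_in = params.amplitude
    amp_out = 0.0
    if 0 < f < 1 and n_out > 0:
        amp_out = amp_in * n_in * (1.0 / f - 1.0) / n_out
    receptor_raster = amp_in * receptor_in + amp_out * receptor_out
    masks["receptor"] = receptor_in | (receptor_out & (amp_out > 0))

    psf_vox = None
    if params.psf_sigma is not None:
        psf_vox = tuple(s / params.spacing for s in params.psf_sigma)

    def finish(raster):
        return _finish_channel(raster, params.amplitude, params.background, psf_vox,
                               None, params.poisson_noise, params.read_noise, noise_rng)

    channels = {
        "nuclei": finish(masks["nuclei"]),
        "cilia": finish(masks["cilia"]),
        "axon": finish(masks["axon"]),
        "puncta": _finish_channel(puncta_field, params.amplitude, params.background,
                                  None, None, params.poisson_noise,
                                  params.read_noise, noise_rng),
        "receptor": _finish_channel(receptor_raster, 1.0, 0.0, psf_vox, None,
                                    params.poisson_noise, params.read_noise, noise_rng),
    }
    mc = MultiChannelVolume({n: VoxelVolume(v, sp, channel=n) for n, v in channels.items()})
    truth = ContactTruth(
        cilia=pd.DataFrame(cil_rows),
        curves=curves,
        axon_curves=axon_curves,
        nuclei_centers=np.asarray(nuc_centers),
        nuclei_in_layer=np.asarray(nuc_in_layer, dtype=bool),
        puncta=pd.DataFrame(punc_rows),
        receptor_ciliary_fraction=f,
        masks=masks,
    )
    return mc, truth


# ---------------------------------------------------------------------------
# ratiometric scene

@dataclass
class RatioSceneParams:
    """Nuclear-staining scene with planted marker/DNA ratios.

    Nucleus centers are sampled in a box extended one radius beyond every
    volume face so the structure density is uniform in z; per-nucleus ratios
    are lognormal around a planted density maximizer (``ratio_mode``), with
    per-voxel lognormal jitter so the voxelwise ratio distribution is itself
    lognormal with a closed-form mode. The marker channel is attenuated with
    depth by exp(-z / attenuation_depth), emulating antibody penetration.
    """

    shape: tuple[int, int, int] = (48, 192, 192)
    spacing: float = 0.15
    xy_sites: tuple[int, int] = (8, 8)
    nuclei_per_site: int = 3
    nucleus_radius: float = 1.8
    ratio_mode: float = 1.10
    ratio_sigma: float = 0.25
    voxel_sigma: float = 0.10
    attenuation_depth: float | None = 8.0
    dna_amplitude: float = 600.0
    background: float = 4.0
    psf_sigma: float = 0.1
    poisson_noise: bool = True
    read_noise: float = 2.0
    seed: int = 0


@dataclass
class RatioTruth:
    nuclei_centers: np.ndarray
    nucleus_ratios: np.ndarray
    ratio_mode: float               # analytic maximizer of the voxel ratio density
    sigma_total: float
    attenuation: np.ndarray | None  # planted per-z multiplicative vector
    dna_clean: np.ndarray
    marker_clean: np.ndarray        # pre-attenuation, pre-noise marker


def make_ratiometric_scene(params: RatioSceneParams | None = None,
                           seed: int | None = None) -> tuple[MultiChannelVolume, RatioTruth]:
    """Generate a two-channel (marker, dna) nuclear staining scene."""
    params = params or RatioSceneParams()
    if seed is not None:
        params = RatioSceneParams(**{**params.__dict__, "seed": seed})
    sp = (params.spacing,) * 3
    shape = np.asarray(params.shape)
    extent = shape * params.spacing
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    # dense, overlap-tolerant placement emulating packed tissue nuclei:
    # jittered xy lattice, z assigned by Latin-hypercube stratification over
    # the extended depth so the structure density is uniform in z (a taper
    # would confound the flat-field estimate with geometry)
    r = params.nucleus_radius
    ny_s, nx_s = params.xy_sites
    n_total = ny_s * nx_s * params.nuclei_per_site
    # lattice inset by one radius: an xy-clipped nucleus would contribute a
    # randomly weighted (hence z-lumpy) cross-section
    step_y = (extent[1] - 2 * r) / ny_s
    step_x = (extent[2] - 2 * r) / nx_s
    site_y = r + (np.arange(ny_s) + 0.5) * step_y
    site_x = r + (np.arange(nx_s) + 0.5) * step_x
    yy, xx = np.meshgrid(site_y, site_x, indexing="ij")
    base_yx = np.repeat(np.stack([yy.ravel(), xx.ravel()], axis=1),
                        params.nuclei_per_site, axis=0)
    jitter = rng.uniform(-0.4, 0.4, size=base_yx.shape) * [step_y, step_x]
    z_ext = extent[0] + 2 * r
    z = -r + (rng.permutation(n_total) + rng.uniform(0, 1, n_total)) / n_total * z_ext
    centers = np.column_stack([z, base_yx + jitter])

    sigma_total = float(np.hypot(params.ratio_sigma, params.voxel_sigma))
    mu = np.log(params.ratio_mode) + sigma_total**2
    # antithetic log-ratio assignment along z: z-adjacent nuclei get mu +/- e
    # so local mean marker intensity stays flat in z (the marginal is still
    # exactly N(mu, sigma) in the log)
    n_c = len(centers)
    e = rng.normal(0.0, params.ratio_sigma, size=(n_c + 1) // 2)
    signed = np.empty(n_c)
    signed[0::2] = e[: len(signed[0::2])]
    signed[1::2] = -e[: len(signed[1::2])]
    order = np.argsort(centers[:, 0])
    log_r = np.empty(n_c)
    log_r[order] = mu + signed
    ratios = np.exp(log_r)

    # additive composition: overlapping nuclei stack intensity in both
    # channels consistently, so per-plane density stays uniform in z and the
    # per-voxel ratio in overlaps is an amplitude-weighted mean of ratios
    dna_clean = np.zeros(params.shape, dtype=float)
    marker_raw = np.zeros(params.shape, dtype=float)
    for c, rr in zip(centers, ratios):
        m = _sphere_mask(params.shape, sp, c, r)
        dna_clean[m] += params.dna_amplitude
        marker_raw[m] += rr * params.dna_amplitude
    if params.psf_sigma > 0:
        sv = params.psf_sigma / params.spacing
        dna_clean = ndimage.gaussian_filter(dna_clean, sv)
        marker_raw = ndimage.gaussian_filter(marker_raw, sv)

    jitter = np.exp(rng.normal(0.0, params.voxel_sigma, size=params.shape))
    marker_clean = marker_raw * jitter

    att = None
    if params.attenuation_depth is not None:
        z_um = np.arange(params.shape[0]) * params.spacing
        att = np.exp(-z_um / params.attenuation_depth)

    dna = dna_clean + params.background
    marker = marker_clean + params.background
    if att is not None:
        marker = marker * att[:, None, None]
    if params.poisson_noise:
        dna = rng.poisson(np.clip(dna, 0, None)).astype(float)
        marker = rng.poisson(np.clip(marker, 0, None)).astype(float)
    if params.read_noise > 0:
        # read noise stays mean-zero (no clipping): truncation would bias
        # the per-plane means the flat-field estimate relies on
        dna = dna + rng.normal(0, params.read_noise, size=params.shape)
        marker = marker + rng.normal(0, params.read_noise, size=params.shape)

    mc = MultiChannelVolume({
        "marker": VoxelVolume(marker, sp, channel="marker"),
        "dna": VoxelVolume(dna, sp, channel="dna"),
    })
    truth = RatioTruth(
        nuclei_centers=centers,
        nucleus_ratios=ratios,
        ratio_mode=float(np.exp(mu - sigma_total**2)),
        sigma_total=sigma_total,
        attenuation=att,
        dna_clean=dna_clean,
        marker_clean=marker_clean,
    )
    return mc, truth


# ---------------------------------------------------------------------------
# FLIM scene

@dataclass
class FlimSceneParams:
    """FLIM volume with a parametric lifetime field.

    ``alpha`` draws lifetimes from a three-parameter alpha distribution
    (closed-form mode recorded in truth); ``two_state`` draws a mixture of
    narrow quenched/unquenched populations at 1.3 and 2.7 ns. A planted
    fraction of voxels receives photon counts below the 50-count filter and
    (optionally) adversarial lifetimes, to exercise the filter contract.
    """

    shape: tuple[int, int, int] = (48, 56, 56)
    spacing: float = 0.3
    field: Literal["alpha", "two_state"] = "alpha"
    alpha_shape: float = 3.0
    alpha_loc: float = 1.2
    alpha_scale: float = 2.0
    quenched_fraction: float = 0.5
    population_sd: float = 0.05
    mean_counts: float = 200.0
    low_count_fraction: float = 0.3
    adversarial_low: bool = True
    adversarial_lifetime: float = 25.0
    seed: int = 0


@dataclass
class FlimTruth:
    mode: float | None
    alpha_params: dict[str, float] | None
    quenched_fraction: float | None
    low_count_mask: np.ndarray
    good_mask: np.ndarray


def make_flim_scene(params: FlimSceneParams | None = None,
                    seed: int | None = None) -> tuple[FlimVolume, FlimTruth]:
    from scipy import stats

    params = params or FlimSceneParams()
    if seed is not None:
        params = FlimSceneParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    shape = params.shape
    n = int(np.prod(shape))

    low = rng.random(n) < params.low_count_fraction
    counts = np.empty(n, dtype=np.int64)
    counts[~low] = np.maximum(rng.poisson(params.mean_counts, size=(~low).sum()), 50)
    counts[low] = rng.integers(1, 50, size=low.sum())

    if params.field == "alpha":
        life = stats.alpha.rvs(params.alpha_shape, params.alpha_loc, params.alpha_scale,
                               size=n, random_state=rng)
        mode = float(params.alpha_loc + params.alpha_scale
                     * (np.sqrt(params.alpha_shape**2 + 8) - params.alpha_shape) / 4)
        alpha_params = {"shape": params.alpha_shape, "loc": params.alpha_loc,
                        "scale": params.alpha_scale}
        qf = None
    elif params.field == "two_state":
        quenched = rng.random(n) < params.quenched_fraction
        life = np.where(quenched, 1.3, 2.7) + rng.normal(0, params.population_sd, size=n)
        life = np.clip(life, 0.05, None)
        mode, alpha_params, qf = None, None, params.quenched_fraction
    else:
        raise ValueError(f"unknown lifetime field {params.field!r}")

    if params.adversarial_low:
        life[low] = params.adversarial_lifetime

    fv = FlimVolume(counts.reshape(shape), life.reshape(shape),
                    (params.spacing,) * 3)
    truth = FlimTruth(mode=mode, alpha_params=alpha_params, quenched_fraction=qf,
                      low_count_mask=low.reshape(shape), good_mask=(~low).reshape(shape))
    return fv, truth


def make_tube_volume(
    length: float,
    radius: float = 0.25,
    spacing: float = 0.189,
    direction: np.ndarray | None = None,
    margin: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Rasterize one straight capped tube of known centerline length.

    Returns the boolean mask and the planted centerline length; used to
    score the skeleton-based length estimator in isolation. A random
    orientation (positive octant) is drawn when ``direction`` is None.
    """
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = np.abs(rng.normal(size=3))
        direction /= np.linalg.norm(direction)
    p0 = np.full(3, margin)
    p1 = p0 + direction * length
    shape = tuple(int(np.ceil((c + margin) / spacing)) for c in p1)
    pts = p0 + np.linspace(0, 1, max(int(length / (spacing / 2)), 2))[:, None] * (p1 - p0)
    return _curve_mask(shape, (spacing,) * 3, pts, radius), float(length)


# ---------------------------------------------------------------------------
# spot field for detector scoring

@dataclass
class SpotSceneParams:
    """Isolated diffraction-limited spots at a controlled signal-to-noise.

    Spot amplitude is ``snr`` times the Gaussian noise SD; spot centers are
    rejection-sampled with a minimum separation of two detection supports
    (8 sigma) so the density stays below one spot per (4 sigma)^3.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 0.189
    n_spots: int = 30
    sigma: float = 0.2
    snr: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0


def make_spot_scene(params: SpotSceneParams | None = None,
                    seed: int | None = None) -> tuple[VoxelVolume, np.ndarray]:
    """Generate a spot volume; returns it with the (n, 3) true centers in um."""
    params = params or SpotSceneParams()
    if seed is not None:
        params = SpotSceneParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    shape = params.shape
    extent = np.asarray(shape) * params.spacing
    pts: list[np.ndarray] = []
    for _ in range(params.n_spots * 200):
        if len(pts) >= params.n_spots:
            break
        c = rng.uniform(1.0, extent - 1.0)
        if all(np.linalg.norm(c - p) >= 8 * params.sigma for p in pts):
            pts.append(c)
    centers = np.asarray(pts)
    vol = np.zeros(shape)
    sv = params.sigma / params.spacing
    grids = np.indices(shape)
    for c in centers:
        cv = c / params.spacing
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, cv))
        vol += np.exp(-d2 / (2 * sv**2))
    img = vol * params.snr * params.noise_sd + rng.normal(0, params.noise_sd, shape)
    return VoxelVolume(img, (params.spacing,) * 3, channel="spots"), centers


# ---------------------------------------------------------------------------
# biosensor traces

@dataclass
class TraceParams:
    """Stimulus-locked sensor traces and titration sets.

    Constants sit at the scales the method targets: activation time constant
    0.19 s, deactivation 8.46 s, EC50 84 nM for the plasma-membrane sensor
    and 28 nM for the cilia-targeted sensor, peak dF/F0 0.15 for
    optogenetic and mean 0.08 for chemogenetic stimulation.
    """

    tau_on: float = 0.19
    tau_off: float = 8.46
    ec50_pm: float = 84e-9
    ec50_cilia: float = 28e-9
    hill: float = 1.0
    top_pm: float = 0.80
    top_cilia: float = 0.40
    peak_dff: float = 0.15
    mean_dff: float = 0.08
    f0: float = 100.0
    background: float = 10.0
    baseline_frames: int = 10
    noise_sd: float = 0.0          # additive noise as a fraction of f0
    doses: tuple[float, ...] = tuple(np.geomspace(1e-9, 1e-5, 9))
    dose_noise: float = 0.0        # multiplicative (fractional) response noise
    seed: int = 0


@dataclass
class TraceTruth:
    tau_on: float
    tau_off: float
    ec50_pm: float
    ec50_cilia: float
    hill: float
    peak_dff: float
    mean_dff: float
    stim_window: tuple[int, int]


def make_traces(params: TraceParams | None = None,
                seed: int | None = None) -> tuple[dict, TraceTruth]:
    """Generate kinetics traces, stimulus traces and Hill titration sets.

    Returns a dict with 'on' and 'off' kinetics traces (raw F), an 'opto'
    trace (1 Hz frames, 10 baseline frames then an exponential-rise response
    peaking at ``peak_dff``), a 'chemo' trace (boxcar of height
    ``mean_dff``), and 'dose_pm' / 'dose_cilia' DoseResponse sets.
    """
    params = params or TraceParams()
    if seed is not None:
        params = TraceParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    f0, bg = params.f0, params.background

    def noisy(f):
        if params.noise_sd > 0:
            return f + rng.normal(0, params.noise_sd * f0, size=f.shape)
        return f

    t_on = np.arange(0, 1.5, 0.01)
    f_on = bg + f0 * (1 + params.peak_dff * (1 - np.exp(-t_on / params.tau_on)))
    t_off = np.arange(0, 45.0, 0.25)
    f_off = bg + f0 * (1 + params.peak_dff * np.exp(-t_off / params.tau_off))

    nb = params.baseline_frames
    stim = (nb, nb + 20)
    t_frames = np.arange(60, dtype=float)
    dff = np.zeros(60)
    rise = 1 - np.exp(-(t_frames[stim[0]:stim[1]] - (stim[0] - 1)) / 3.0)
    dff[stim[0]:stim[1]] = params.peak_dff * rise / rise.max()
    dff[stim[1]:] = params.peak_dff * np.exp(-(t_frames[stim[1]:] - stim[1] + 1) / 8.0)
    f_opto = bg + f0 * (1 + dff)

    t_chemo = np.arange(30, dtype=float) * 10.0
    dff_chemo = np.zeros(30)
    dff_chemo[5:25] = params.mean_dff
    f_chemo = bg + f0 * (1 + dff_chemo)

    doses = np.asarray(params.doses)

    def hill_resp(ec50, top):
        resp = top / (1.0 + (ec50 / doses) ** params.hill)
        if params.dose_noise > 0:
            resp = resp * (1 + rng.normal(0, params.dose_noise, size=resp.shape))
        return resp

    out = {
        "on": Trace(t_on, noisy(f_on)),
        "off": Trace(t_off, noisy(f_off)),
        "opto": Trace(t_frames, noisy(f_opto)),
        "chemo": Trace(t_chemo, noisy(f_chemo)),
        "dose_pm": DoseResponse(doses, hill_resp(params.ec50_pm, params.top_pm)),
        "dose_cilia": DoseResponse(doses, hill_resp(params.ec50_cilia, params.top_cilia)),
    }
    truth = TraceTruth(
        tau_on=params.tau_on, tau_off=params.tau_off,
        ec50_pm=params.ec50_pm, ec50_cilia=params.ec50_cilia, hill=params.hill,
        peak_dff=params.peak_dff, mean_dff=params.mean_dff, stim_window=stim,
    )
    return out, truth
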