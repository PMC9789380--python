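"""Biosensor trace analytics and FRET/FLIM summaries.

Covers the signal side of the pipeline: dF/F0 with background subtraction,
hard-cutoff Fourier low-pass filtering, peak/mean response metrics, Hill
dose-response fits (EC50), single-exponential on/off kinetics, FRET ratio
time series from two-channel xyzt stacks, two-component fixed-lifetime
decay fits (donor lifetimes 1.3 ns quenched / 2.7 ns unquenched), and the
alpha-distribution mode summarizing a cilium's lifetime histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .segmentation import otsu_threshold
from .volumes import FlimVolume

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "DoseResponse",
    "KineticsFit",
    "LifetimeModel",
    "LifetimeSummary",
    "delta_f_over_f",
    "lowpass_fourier",
    "response_metrics",
    "hill_fit",
    "exp_kinetics_fit",
    "fret_ratio_series",
    "flim_fraction_fit",
    "flim_cilium_mode",
    "disk_roi_mean",
]


@dataclass
class Trace:
    """Time-stamped intensity series with optional dF/F0 annotation."""

    t: np.ndarray
    F: np.ndarray
    dff: np.ndarray | None = None
    F0: float | None = None
    baseline_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be matching 1D arrays")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.dff is not None:
            self.dff = np.asarray(self.dff, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def rate(self) -> float:
        """Sampling rate (Hz); requires a uniform time base."""
        dt = np.diff(self.t)
        if len(dt) == 0:
            raise ValueError("cannot infer a rate from a single sample")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform time base")
        return 1.0 / dt[0]


@dataclass
class DoseResponse:
    """Concentration series (molar), responses (dF/F0), optional Hill fit."""

    conc: np.ndarray
    resp: np.ndarray
    fit: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if self.conc.shape != self.resp.shape:
            raise ValueError("conc and resp must share shape")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be > 0")


@dataclass
class KineticsFit:
    tau: float
    direction: str
    amplitude: float
    offset: float
    residual: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.direction not in ("on", "off"):
            raise ValueError("direction must be 'on' or 'off'")


@dataclass
class LifetimeModel:
    """Fixed two-component donor lifetime model (ns)."""

    tau_quenched: float = 1.3
    tau_unquenched: float = 2.7
    quenched_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.tau_quenched < self.tau_unquenched:
            raise ValueError("require 0 < tau_quenched < tau_unquenched")
        if self.quenched_fraction is not None and not 0 <= self.quenched_fraction <= 1:
            raise ValueError("quenched_fraction must lie in [0, 1]")

    @property
    def mean_lifetime(self) -> float:
        if self.quenched_fraction is None:
            raise ValueError("quenched_fraction not fitted yet")
        f = self.quenched_fraction
        return f * self.tau_quenched + (1 - f) * self.tau_unquenched


@dataclass
class LifetimeSummary:
    """Representative lifetime of one cilium: alpha-distribution mode."""

    mode: float
    alpha_params: dict[str, float]
    n_voxels_used: int
    min_counts: int = 50


def delta_f_over_f(
    trace: Trace,
    baseline_window: tuple[int, int],
    background: float = 0.0,
) -> Trace:
    """Compute dF/F0 = (F - F0) / F0 after background subtraction.

    F0 is the mean background-subtracted intensity over the baseline frame
    window [start, stop) — e.g. the 10 time points before photostimulation,
    or the first 5 points before ligand application.
    """
    start, stop = baseline_window
    if not (0 <= start < stop <= len(trace)):
        raise ValueError(f"baseline window {baseline_window} invalid for trace of {len(trace)}")
    if background < 0:
        raise ValueError("background must be >= 0")
    f = trace.F - background
    f0 = float(np.mean(f[start:stop]))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0:.3g} after background subtraction")
    dff = (f - f0) / f0
    return replace(trace, dff=dff, F0=f0, baseline_window=(start, stop))


def lowpass_fourier(trace: Trace, cutoff: float, rate: float | None = None) -> Trace:
    """Hard-cutoff low-pass filter in the Fourier domain.

    Frequency components strictly above ``cutoff`` (Hz) are zeroed; DC (and
    hence the mean) is preserved exactly and the operation is idempotent.
    """
    rate = rate or trace.rate
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff must lie in (0, rate/2) = (0, {rate / 2})")
    n = len(trace)
    spec = np.fft.rfft(trace.F)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[freqs > cutoff * (1 + 1e-12)] = 0.0
    out = np.fft.irfft(spec, n=n)
    dff = None
    if trace.dff is not None:
        dspec = np.fft.rfft(trace.dff)
        dspec[freqs > cutoff * (1 + 1e-12)] = 0.0
        dff = np.fft.irfft(dspec, n=n)
    return replace(trace, F=out, dff=dff)


def response_metrics(trace: Trace, stim_window: tuple[int, int]) -> dict[str, float]:
    """Peak and mean dF/F0 within the stimulation frame window [start, stop)."""
    if trace.dff is None:
        raise ValueError("dF/F0 not computed; call delta_f_over_f first")
    start, stop = stim_window
    if not (0 <= start < stop <= len(trace)):
        raise ValueError(f"stim window {stim_window} invalid for trace of {len(trace)}")
    seg = trace.dff[start:stop]
    return {"peak_dff": float(np.max(seg)), "mean_dff": float(np.mean(seg))}


def _hill(c, bottom, top, log10_ec50, hill):
    return bottom + (top - bottom) / (1.0 + (10.0**log10_ec50 / c) ** hill)


def hill_fit(dr: DoseResponse, fix_bottom: float | None = None) -> DoseResponse:
    """Least-squares Hill fit: resp = bottom + (top-bottom)/(1+(EC50/c)^h).

    EC50 is fitted on a log10 scale for stability. ``fix_bottom`` pins the
    lower asymptote (e.g. 0). A non-monotone dose ordering only triggers a
    warning; non-convergence raises.
    """
    if len(dr.conc) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    order = np.argsort(dr.conc)
    c, r = dr.conc[order], dr.resp[order]
    if np.any(np.diff(r) < -0.25 * (r.max() - r.min() + 1e-30)):
        logger.warning("hill_fit: responses are not monotone in concentration")

    half = 0.5 * (r.min() + r.max())
    ec50_guess = float(np.interp(half, r, c)) if r[-1] > r[0] else float(np.sqrt(c[0] * c[-1]))
    ec50_guess = min(max(ec50_guess, c.min()), c.max())

    if fix_bottom is None:
        def f(cc, bottom, top, log_ec50, hill):
            return _hill(cc, bottom, top, log_ec50, hill)
        p0 = (float(r.min()), float(r.max()), np.log10(ec50_guess), 1.0)
        lb = (-np.inf, -np.inf, np.log10(c.min()) - 3, 0.05)
        ub = (np.inf, np.inf, np.log10(c.max()) + 3, 10.0)
    else:
        def f(cc, top, log_ec50, hill):
            return _hill(cc, fix_bottom, top, log_ec50, hill)
        p0 = (float(r.max()), np.log10(ec50_guess), 1.0)
        lb = (-np.inf, np.log10(c.min()) - 3, 0.05)
        ub = (np.inf, np.log10(c.max()) + 3, 10.0)

    popt, _ = optimize.curve_fit(f, c, r, p0=p0, bounds=(lb, ub), maxfev=20000)
    if fix_bottom is None:
        bottom, top, log_ec50, hill = popt
    else:
        top, log_ec50, hill = popt
        bottom = fix_bottom
    pred = _hill(c, bottom, top, log_ec50, hill)
    fit = {
        "EC50": float(10.0**log_ec50),
        "hill": float(hill),
        "bottom": float(bottom),
        "top": float(top),
        "rss": float(np.sum((r - pred) ** 2)),
    }
    return DoseResponse(dr.conc, dr.resp, fit=fit)


def exp_kinetics_fit(trace: Trace, direction: str) -> KineticsFit:
    """Single-exponential fit of sensor on/off kinetics.

    on:  F(t) = A (1 - exp(-(t - t0)/tau)) + C
    off: F(t) = A exp(-(t - t0)/tau) + C

    with t0 the first sample time. A post-hoc warning fires when the trace
    covers less than 3 tau.
    """
    if direction not in ("on", "off"):
        raise ValueError("direction must be 'on' or 'off'")
    t = trace.t - trace.t[0]
    y = trace.F
    span = float(t[-1])
    amp0 = float(y.max() - y.min()) or 1.0
    tau0 = max(span / 5.0, 1e-6)

    if direction == "on":
        def f(tt, a, tau, c):
            return a * (1 - np.exp(-tt / tau)) + c
        p0 = (amp0, tau0, float(y[0]))
    else:
        def f(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
        p0 = (amp0, tau0, float(y[-1]))

    popt, _ = optimize.curve_fit(
        f, t, y, p0=p0, bounds=((-np.inf, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
        maxfev=20000,
    )
    a, tau, c = popt
    if span < 3 * tau:
        logger.warning("exp_kinetics_fit: trace covers %.3g s < 3 tau (%.3g s)", span, 3 * tau)
    resid = float(np.sum((y - f(t, *popt)) ** 2))
    return KineticsFit(tau=float(tau), direction=direction, amplitude=float(a),
                       offset=float(c), residual=resid)


def disk_roi_mean(frames: np.ndarray, center_yx: tuple[float, float],
                  radius_um: float, pixel_um: float) -> np.ndarray:
    """Mean intensity inside a circular ROI on an (t, y, x) stack.

    Implements the 1-um-circle readout at a contact site: ``radius_um`` is
    the ROI radius, ``center_yx`` the ROI center in pixels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected (t, y, x) frames")
    yy, xx = np.indices(frames.shape[1:])
    r_px = radius_um / pixel_um
    disk = (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= r_px**2
    if not disk.any():
        raise ValueError("ROI does not cover any pixel")
    return frames[:, disk].mean(axis=1)


def fret_ratio_series(
    donor: np.ndarray,
    sensitized: np.ndarray,
    bg_region: tuple[slice, slice],
    rolling_radius: float = 50.0,
    temporal_average: bool = False,
    lowpass_hz: float | None = None,
    rate: float | None = None,
    baseline_frames: int = 25,
) -> dict[str, np.ndarray]:
    """FRET ratio time series from two-channel (t, z, y, x) or (t, y, x) stacks.

    Per frame: maximum-intensity z projection; rolling-ball background
    flattening of the donor for mask creation followed by Otsu thresholding;
    subtraction of the mean of ``bg_region`` (an acellular area, (y, x)
    slices) from both channels; ratio = sum(sensitized in mask) /
    sum(donor in mask). Optional frame-pair temporal averaging and hard
    Fourier low-pass (``lowpass_hz`` at sampling ``rate``). ``dRR`` is the
    fractional change relative to the mean ratio of the first
    ``baseline_frames`` frames. Frames with an empty mask are flagged and
    carry NaN ratios.
    """
    from skimage.restoration import rolling_ball

    donor = np.asarray(donor, dtype=float)
    sensitized = np.asarray(sensitized, dtype=float)
    if donor.shape != sensitized.shape:
        raise ValueError("donor and sensitized stacks must share geometry")
    if donor.ndim == 4:
        donor = donor.max(axis=1)
        sensitized = sensitized.max(axis=1)
    if donor.ndim != 3:
        raise ValueError("expected (t, z, y, x) or (t, y, x) stacks")

    n_frames = donor.shape[0]
    ratio = np.full(n_frames, np.nan)
    flagged = np.zeros(n_frames, dtype=bool)
    for k in range(n_frames):
        d, s = donor[k], sensitized[k]
        flat = d - rolling_ball(d, radius=rolling_radius)
        try:
            thr = otsu_threshold(flat)
        except ValueError:
            flagged[k] = True
            continue
        mask = flat >= thr
        if not mask.any():
            flagged[k] = True
            continue
        bg_d = float(np.mean(d[bg_region]))
        bg_s = float(np.mean(s[bg_region]))
        denom = float(np.sum(d[mask] - bg_d))
        if denom == 0:
            flagged[k] = True
            continue
        ratio[k] = float(np.sum(s[mask] - bg_s)) / denom
    if flagged.any():
        logger.warning("fret_ratio_series: %d frames with empty mask flagged", int(flagged.sum()))

    t = np.arange(n_frames, dtype=float)
    if rate is not None:
        t = t / rate
    if temporal_average:
        m = (n_frames // 2) * 2
        ratio = ratio[:m].reshape(-1, 2).mean(axis=1)
        flagged = flagged[:m].reshape(-1, 2).any(axis=1)
        t = t[:m].reshape(-1, 2).mean(axis=1)
    if lowpass_hz is not None:
        if rate is None:
            raise ValueError("rate required for low-pass filtering")
        eff_rate = rate / 2 if temporal_average else rate
        filt = lowpass_fourier(Trace(t, np.nan_to_num(ratio)), lowpass_hz, rate=eff_rate)
        ratio = filt.F

    nb = min(baseline_frames, len(ratio))
    base = np.nanmean(ratio[:nb])
    drr = (ratio - base) / base
    return {"t": t, "ratio": ratio, "dRR": drr, "flagged": flagged, "baseline": base}


def flim_fraction_fit(
    bin_times: np.ndarray,
    counts: np.ndarray,
    model: LifetimeModel | None = None,
) -> LifetimeModel:
    """Amplitude fit of a fixed two-lifetime decay to an arrival histogram.

    Solves counts ~ a_q exp(-t/tau_q) + a_u exp(-t/tau_u) by non-negative
    least squares with the two lifetimes held fixed; the quenched fraction is
    a_q / (a_q + a_u). Tail fit without instrument-response deconvolution —
    a stated simplification of reconvolution fitting.
    """
    model = model or LifetimeModel()
    t = np.asarray(bin_times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("bin_times and counts must be matching 1D arrays")
    if len(t) < 10:
        raise ValueError("need >= 10 decay bins")
    if t[-1] - t[0] < 2 * model.tau_unquenched:
        raise ValueError("decay must span >= 2x the unquenched lifetime")
    if np.count_nonzero(y) <= 1:
        raise ValueError("degenerate decay: all counts in one bin")
    design = np.column_stack([np.exp(-t / model.tau_quenched),
                              np.exp(-t / model.tau_unquenched)])
    amps, _ = optimize.nnls(design, y)
    total = amps.sum()
    if total <= 0:
        raise ValueError("decay fit degenerate: zero total amplitude")
    return replace(model, quenched_fraction=float(amps[0] / total))


_ALPHA_MIN_VOXELS = 10


def alpha_mode(shape: float, loc: float, scale: float) -> float:
    """Closed-form density maximizer of the three-parameter alpha distribution."""
    return loc + scale * (np.sqrt(shape**2 + 8.0) - shape) / 4.0


def flim_cilium_mode(
    fv: FlimVolume,
    mask: np.ndarray,
    min_counts: int = 50,
) -> LifetimeSummary:
    """Representative lifetime of a cilium: mode of the fitted alpha density.

    Masked voxels with fewer than ``min_counts`` photons are discarded; a
    three-parameter alpha distribution is fitted (maximum likelihood) to the
    remaining lifetimes and its analytic mode returned. All voxels equal is
    handled by a degenerate branch returning that value.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fv.counts.shape:
        raise ValueError("mask must match the FLIM volume shape")
    use = mask & (fv.counts >= min_counts)
    values = fv.arrival[use]
    n = len(values)
    if n == 0:
        raise ValueError("no masked voxels pass the photon-count filter")
    if np.ptp(values) == 0:
        return LifetimeSummary(mode=float(values[0]),
                               alpha_params={"shape": np.nan, "loc": np.nan, "scale": np.nan},
                               n_voxels_used=n, min_counts=min_counts)
    if n < _ALPHA_MIN_VOXELS:
        raise ValueError(f"only {n} usable voxels (< {_ALPHA_MIN_VOXELS}); refusing to fit")
    a, loc, scale = stats.alpha.fit(values)
    mode = alpha_mode(a, loc, scale)
    lo, hi = float(values.min()), float(values.max())
    if not lo <= mode <= hi:
        raise RuntimeError(
            f"alpha fit did not converge to a mode inside the observed range "
            f"[{lo:.3g}, {hi:.3g}] (got {mode:.3g})"
        )
    return LifetimeSummary(
        mode=float(mode),
        alpha_params={"shape": float(a), "loc": float(loc), "scale": float(scale)},
        n_voxels_used=n,
        min_counts=min_counts,
    )
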