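"""Seeded synthetic-data generators for every analysis stage.

Raw single-molecule microscopy data are rarely portable; these generators
produce inputs with exactly the statistical structure the downstream
estimators assume -- Brownian 1D motion with Gaussian localization noise,
double-exponential dwell times with right-censoring, stepwise
photobleaching with optional two-state blinking, trinomially labeled
clusters, kymograms with Gaussian-PSF puncta and RPA tracts, and WLC
force-extension traces -- together with machine-readable ground truth so
every recovery claim is testable.

Every generator is a pure function of its parameters and a seed; one root
seed spawns fixed per-generator child streams, so adding a generator
never perturbs the draws of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from ._utils import child_rng
from .io import Kymogram
from .oligomer import ClusterSizeModel, ColorCounts, LabelModel
from .polymer import TractTrace, WLCModel, wlc_extension
from .stepfind import FluorescenceTrace
from .survival import SurvivalData, SurvivalModel
from .tracking import Trajectory1D

__all__ = [
    "SimConfig",
    "ForceProtocol",
    "sim_lifetimes",
    "sim_diffusion_track",
    "sim_bleach_trace",
    "sim_label_counts",
    "sim_kymogram",
    "sim_wlc_extension",
]


@dataclass(frozen=True)
class SimConfig:
    """Shared acquisition parameters of a simulated experiment."""

    seed: int = 0
    frame_interval: float = 0.1  # s
    pixel_size: float = 0.1  # um
    noise_sd: float = 1.0  # intensity units
    psf_sigma: float = 0.15  # um

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("frame_interval, pixel_size and psf_sigma must be > 0")


@dataclass(frozen=True)
class ForceProtocol:
    """Piecewise-constant force schedule: (duration s, force pN) segments."""

    schedule: tuple

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _ in self.schedule):
            raise ValueError("segment durations must be > 0")

    @property
    def total_time(self) -> float:
        return sum(d for d, _ in self.schedule)

    def force_series(self, n_frames: int, frame_interval: float) -> np.ndarray:
        """Force at each frame time (last segment held if the protocol is
        shorter than the recording)."""
        t = np.arange(n_frames) * frame_interval
        bounds = np.cumsum([d for d, _ in self.schedule])
        idx = np.minimum(np.searchsorted(bounds, t, side="right"),
                         len(self.schedule) - 1)
        return np.array([self.schedule[i][1] for i in idx], dtype=float)


def sim_lifetimes(
    n: int, model: SurvivalModel, censor_time: float, seed: int = 0
) -> SurvivalData:
    """Dwell times from the double-exponential mixture, right-censored at
    ``censor_time`` (the end of the observation window)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    rng = child_rng(seed, "lifetimes")
    is_long = rng.random(n) < model.f_long
    tau = np.where(is_long, model.tau_long, model.tau_short)
    t = rng.exponential(tau)
    censored = t > censor_time
    return SurvivalData(np.where(censored, censor_time, t), censored)


def sim_diffusion_track(
    D: float,
    n_frames: int,
    frame_interval: float,
    loc_noise_sd: float = 0.0,
    seed: int = 0,
    x0: float = 0.0,
) -> Trajectory1D:
    """Brownian 1D track with i.i.d. Gaussian localization noise.

    Increments of the true position are N(0, 2 D dt); reported positions
    add N(0, loc_noise_sd^2).  The noise-free path is kept as ground truth.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if D < 0 or loc_noise_sd < 0:
        raise ValueError("D and loc_noise_sd must be >= 0")
    rng = child_rng(seed, "diffusion")
    steps = rng.normal(0.0, np.sqrt(2 * D * frame_interval), size=n_frames - 1)
    true = x0 + np.concatenate([[0.0], np.cumsum(steps)])
    obs = true + rng.normal(0.0, loc_noise_sd, size=n_frames)
    t = np.arange(n_frames) * frame_interval
    return Trajectory1D(
        t, obs, frame_interval,
        loc_uncertainty=np.full(n_frames, loc_noise_sd),
        true_positions=true,
    )


def sim_bleach_trace(
    n_fluor: int,
    unit_f: float,
    bleach_rate: float,
    n_frames: int,
    frame_interval: float = 0.1,
    noise_sd: float = 0.0,
    blink_off_rate: float = 0.0,
    blink_on_rate: float = 0.0,
    flush_frame: int = 0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Stepwise photobleaching trace of ``n_fluor`` identical fluorophores.

    Each fluorophore emits ``unit_f`` until it bleaches (irreversibly,
    rate ``bleach_rate`` per second while emitting); optional two-state
    blinking (off/on telegraph, default off) interleaves reversible dark
    periods.  F(t) = unit_f * n_emitting(t) + Gaussian noise.  Truth holds
    the per-frame emitting count and bleach frames.
    """
    if n_fluor < 0 or unit_f <= 0 or bleach_rate < 0 or noise_sd < 0:
        raise ValueError("invalid photophysics parameters")
    rng = child_rng(seed, "bleach")
    dt = frame_interval
    p_bleach = -np.expm1(-bleach_rate * dt)
    p_off = -np.expm1(-blink_off_rate * dt)
    p_on = -np.expm1(-blink_on_rate * dt)
    emitting = np.zeros((n_frames, n_fluor), dtype=bool)
    state = np.ones(n_fluor, dtype=int)  # 1 emitting, 0 dark, -1 bleached
    bleach_frames = np.full(n_fluor, -1, dtype=int)
    for k in range(n_frames):
        emitting[k] = state == 1
        u = rng.random(n_fluor)
        on = state == 1
        # bleaching only from the emitting state
        newly_bleached = on & (u < p_bleach)
        state[newly_bleached] = -1
        bleach_frames[newly_bleached & (bleach_frames < 0)] = k
        if p_off > 0:
            blink = on & ~newly_bleached & (rng.random(n_fluor) < p_off)
            state[blink] = 0
        if p_on > 0:
            recover = (state == 0) & (rng.random(n_fluor) < p_on)
            state[recover] = 1
    F = unit_f * emitting.sum(axis=1) + rng.normal(0.0, noise_sd, size=n_frames)
    t = np.arange(n_frames) * dt
    trace = FluorescenceTrace(t, F, dt, flush_frame)
    if return_truth:
        truth = {
            "n_fluor": n_fluor,
            "unit_f": unit_f,
            "n_emitting": emitting.sum(axis=1),
            "bleach_frames": bleach_frames,
        }
        return trace, truth
    return trace


def sim_label_counts(
    n_clusters: int,
    size_model: ClusterSizeModel,
    label_model: LabelModel,
    seed: int = 0,
    return_truth: bool = False,
):
    """Dual-color category counts from trinomially labeled clusters.

    Cluster sizes are drawn from phi(N; mu); each of the N units acquires
    a cyan label (prob pc), a magenta label (pm), or none.  Unlabeled
    clusters (c = m = 0) are undetectable and discarded; the returned
    counts cover detected clusters only.
    """
    rng = child_rng(seed, "labels")
    ns, w = size_model.pmf()
    sizes = rng.choice(ns, size=n_clusters, p=w)
    c = rng.binomial(sizes, label_model.pc)
    rest_p = label_model.pm / max(1.0 - label_model.pc, 1e-300)
    m = rng.binomial(sizes - c, min(rest_p, 1.0))
    detected = (c + m) > 0
    cyan_only = int(np.sum((c > 0) & (m == 0)))
    magenta_only = int(np.sum((c == 0) & (m > 0)))
    dual = int(np.sum((c > 0) & (m > 0)))
    counts = ColorCounts(cyan_only, magenta_only, dual)
    if return_truth:
        return counts, {"sizes": sizes, "c": c, "m": m, "detected": detected}
    return counts


def sim_kymogram(
    tracts,
    puncta,
    config: SimConfig,
    n_frames: int,
    n_pixels: int,
    tract_amplitude: float = 10.0,
    tract_channel: int = 0,
    n_channels: int = 2,
) -> Kymogram:
    """Render a synthetic kymogram: tracts as PSF-convolved top-hats,
    puncta as 1D Gaussians, plus Gaussian camera noise.

    ``tracts``: list of (start, end) um, each either static floats or
    per-frame arrays.  ``puncta``: list of (channel, position series um,
    amplitude).  Out-of-field content is clipped with a warning.  Ground
    truth (per-frame tract edges and punctum positions) rides along on the
    returned ``Kymogram.truth``.
    """
    rng = child_rng(config.seed, "kymogram")
    x = (np.arange(n_pixels) + 0.0) * config.pixel_size
    fov = n_pixels * config.pixel_size
    img = rng.normal(0.0, config.noise_sd, size=(n_channels, n_frames, n_pixels))
    s = config.psf_sigma

    def per_frame(v):
        v = np.asarray(v, dtype=float)
        return np.full(n_frames, float(v)) if v.ndim == 0 else v

    truth_tracts = []
    for lo, hi in tracts:
        lo_t, hi_t = per_frame(lo), per_frame(hi)
        if np.any(lo_t < 0) or np.any(hi_t > fov):
            warnings.warn("tract extends beyond the field of view; clipped",
                          stacklevel=2)
            lo_t, hi_t = np.clip(lo_t, 0, fov), np.clip(hi_t, 0, fov)
        truth_tracts.append(np.stack([lo_t, hi_t], axis=1))
        for k in range(n_frames):
            prof = 0.5 * (
                erf((x - lo_t[k]) / (np.sqrt(2) * s))
                - erf((x - hi_t[k]) / (np.sqrt(2) * s))
            )
            img[tract_channel, k] += tract_amplitude * prof

    truth_puncta = []
    for ch, pos, amp in puncta:
        pos_t = per_frame(pos)
        if np.any((pos_t < 0) | (pos_t > fov)):
            warnings.warn("punctum leaves the field of view; clipped",
                          stacklevel=2)
            pos_t = np.clip(pos_t, 0, fov)
        truth_puncta.append({"channel": ch, "positions": pos_t, "amplitude": amp})
        for k in range(n_frames):
            img[ch, k] += amp * np.exp(-((x - pos_t[k]) ** 2) / (2 * s * s))

    return Kymogram(
        img, config.pixel_size, config.frame_interval,
        truth={"tracts": truth_tracts, "puncta": truth_puncta,
               "tract_amplitude": tract_amplitude, "noise_sd": config.noise_sd},
    )


def sim_wlc_extension(
    L_series,
    force_series,
    model: WLCModel = WLCModel(),
    noise_sd: float = 0.0,
    frame_interval: float = 0.1,
    seed: int = 0,
) -> TractTrace:
    """Extension trace of a WLC tract under a force protocol.

    xi(t) is the forward WLC extension at (L(t), F(t)) plus measurement
    noise; the true contour rides along in the ``L_true`` column, so
    inversion round-trips are directly checkable.
    """
    import pandas as pd

    L = np.atleast_1d(np.asarray(L_series, dtype=float))
    F = np.atleast_1d(np.asarray(force_series, dtype=float))
    if len(L) == 1:
        L = np.full(len(F), L[0])
    if len(L) != len(F):
        raise ValueError("L and force series must match in length")
    if np.any(L <= 0) or np.any(F <= 0):
        raise ValueError("require L > 0 and F > 0")
    rng = child_rng(seed, "wlc")
    xi = np.array([wlc_extension(f, l, model) for f, l in zip(F, L)])
    xi_obs = xi + rng.normal(0.0, noise_sd, size=len(xi))
    t = np.arange(len(xi)) * frame_interval
    return TractTrace(pd.DataFrame({
        "t": t, "left": 0.0, "right": xi_obs, "xi": xi_obs, "F": F,
        "L": np.nan, "masked": False, "L_true": L,
    }))
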