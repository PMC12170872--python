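"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one class of raw data the pipeline consumes —
3D fluorescence stacks of tubular/ellipsoidal/branched mitochondria with
cristae-like internal texture, TEM-style mitochondrion/cristae mask pairs,
dual-channel ratiometric traces with photobleaching, mitochondria-attached
single-channel sweeps under a stepped voltage protocol, immunogold particle
fields around a closed OMM contour, fractionation band-intensity sheets,
and Hill-curve concentration-response sets — and returns the generating
parameters as a :class:`~mitoquant.core.GroundTruth` record so recovery
tests never need external data.

All randomness derives from independent named streams of the master seed
(see :func:`~mitoquant.core.rng_for`): adding a generator never shifts the
randomness of the others, and the same seed reproduces every dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import bessel, sosfiltfilt

from .core import GroundTruth, ImageStack3D, SynthConfig, rng_for
from .fraction import FractionSheet
from .gold import GoldParticleField
from .patch import PatchProtocol, SingleChannelRecording, Sweep

__all__ = [
    "PlacementError",
    "make_mito_stack",
    "make_tem_mito",
    "make_trace_set",
    "make_patch_sweeps",
    "make_gold_field",
    "make_fraction_sheet",
    "make_dose_response",
    "DEFAULT_PO_BY_MV",
]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap ("placement_failed")."""


# ---------------------------------------------------------------------------
# 3D mitochondria stacks


def _ellipsoid_mask(axes_vox: tuple[float, float, float]) -> np.ndarray:
    az, ay, ax = axes_vox
    zz, yy, xx = np.mgrid[
        -int(np.ceil(az)) : int(np.ceil(az)) + 1,
        -int(np.ceil(ay)) : int(np.ceil(ay)) + 1,
        -int(np.ceil(ax)) : int(np.ceil(ax)) + 1,
    ]
    return (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0


def _segment_mask(
    shape: tuple[int, int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (a digital tube)."""
    grid = np.stack(np.mgrid[: shape[0], : shape[1], : shape[2]], axis=-1).astype(float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(grid - p0, axis=-1)
    else:
        t = np.clip(((grid - p0) @ d) / L2, 0.0, 1.0)
        nearest = p0 + t[..., None] * d
        dist = np.linalg.norm(grid - nearest, axis=-1)
    return dist <= radius


def _object_mask(
    shape_spec: str, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    if shape_spec == "ellipsoid":
        axes = (3.0, 6.0, 6.0)
        return _ellipsoid_mask(axes), {"shape": "ellipsoid", "axes_vox": axes}
    if shape_spec == "tube":
        length, radius = 24.0, 3.0
        theta = rng.uniform(0, np.pi)
        local = np.array([9, 31, 31], dtype=float)
        half = np.array([0.0, np.sin(theta), np.cos(theta)]) * length / 2
        box = (19, 63, 63)
        mask = _segment_mask(box, local - half, local + half, radius)
        return mask, {"shape": "tube", "length_vox": length, "radius_vox": radius}
    if shape_spec == "branched":
        radius, arm = 3.0, 14.0
        box = (19, 63, 63)
        center = np.array([9, 31, 31], dtype=float)
        mask = np.zeros(box, dtype=bool)
        params = {"shape": "branched", "arm_vox": arm, "radius_vox": radius}
        for ang in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
            tip = center + np.array([0.0, np.sin(ang), np.cos(ang)]) * arm
            mask |= _segment_mask(box, center, tip, radius)
        return mask, params
    raise ValueError(f"unknown shape_spec {shape_spec!r}")


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def _cristae_texture(
    obj_mask: np.ndarray,
    cristae_spec: str,
    density: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary cristae-like texture inside the (eroded) object interior.

    ``uniform`` draws voxels at constant density; ``central`` weights the
    draw probability linearly toward the object centroid, mimicking
    centrally concentrated cristae.
    """
    if cristae_spec == "none":
        return np.zeros_like(obj_mask)
    interior = ndi.binary_erosion(obj_mask)
    if not interior.any():
        interior = obj_mask
    coords = np.argwhere(interior)
    if cristae_spec == "uniform":
        p = np.full(len(coords), density)
    elif cristae_spec == "central":
        centroid = coords.mean(axis=0)
        d = np.linalg.norm(coords - centroid, axis=1)
        dmax = d.max() if d.max() > 0 else 1.0
        p = np.clip(2.0 * density * (1.0 - d / dmax), 0.0, 1.0)
    else:
        raise ValueError(f"unknown cristae_spec {cristae_spec!r}")
    chosen = rng.random(len(coords)) < p
    tex = np.zeros_like(obj_mask)
    tex[tuple(coords[chosen].T)] = True
    return tex


def make_mito_stack(
    config: SynthConfig,
    n_objects: int = 3,
    shape_spec: str = "tube",
    cristae_spec: str = "none",
    stack_shape: tuple[int, int, int] = (24, 160, 160),
    cristae_density: float = 0.3,
    background: float = 10.0,
    object_intensity: float = 100.0,
    cristae_intensity: float = 180.0,
    max_retries: int = 200,
) -> tuple[ImageStack3D, GroundTruth]:
    """Generate a single-channel 3D stack of non-overlapping mitochondria.

    Objects are placed at random positions away from the stack border;
    placement that still collides after ``max_retries`` attempts raises
    :class:`PlacementError`. The returned ground truth carries the label
    map of true object masks, the cristae texture map, and per-object
    generating parameters.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    rng = rng_for(config, "mito_stack")
    labels = np.zeros(stack_shape, dtype=np.int32)
    cristae_map = np.zeros(stack_shape, dtype=bool)
    objects = []
    for i in range(1, n_objects + 1):
        placed = False
        for _ in range(max_retries):
            mask, params = _object_mask(shape_spec, rng)
            mask = _crop_to_content(mask)
            sz = np.array(mask.shape)
            lim = np.array(stack_shape) - sz - 1
            if np.any(lim < 1):
                raise PlacementError("placement_failed: stack too small for object")
            origin = np.array([rng.integers(1, l + 1) for l in lim])
            region = tuple(slice(o, o + s) for o, s in zip(origin, sz))
            if np.any(labels[region][mask] != 0):
                continue
            labels[region][mask] = i
            tex = _cristae_texture(mask, cristae_spec, cristae_density, rng)
            cristae_map[region] |= tex
            params.update(
                origin_vox=origin.tolist(),
                volume_vox=int(mask.sum()),
                cristae_spec=cristae_spec,
            )
            objects.append(params)
            placed = True
            break
        if not placed:
            raise PlacementError("placement_failed")
    data = np.full(stack_shape, background, dtype=float)
    data[labels > 0] = object_intensity
    data[cristae_map] = cristae_intensity
    if config.gaussian_sd > 0:
        data = data + rng.normal(0.0, config.gaussian_sd * object_intensity, stack_shape)
    if config.poisson_scale > 0:
        data = rng.poisson(np.clip(data, 0, None) * config.poisson_scale) / float(
            config.poisson_scale
        )
    stack = ImageStack3D(
        data=data, voxel_xy_nm=config.voxel_xy_nm, voxel_z_nm=config.voxel_z_nm
    )
    truth = GroundTruth(
        {
            "label_map": labels,
            "cristae_map": cristae_map,
            "objects": objects,
            "background": background,
            "object_intensity": object_intensity,
            "cristae_density": cristae_density,
        }
    )
    return stack, truth


def make_tem_mito(
    config: SynthConfig,
    radius_px: int = 60,
    cristae_spec: str = "uniform",
    cristae_density: float = 0.3,
    central_radius_frac: float = 0.4,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """2D TEM-style mitochondrion and cristae mask pair.

    ``uniform`` scatters cristae pixels at constant density across the
    interior; ``central`` places a solid cristae disk of radius
    ``central_radius_frac * radius_px`` at the centre (a centrally
    concentrated phenotype); ``none`` returns an empty cristae mask.
    """
    rng = rng_for(config, "tem_mito")
    size = 2 * radius_px + 9
    yy, xx = np.mgrid[:size, :size] - size // 2
    r = np.hypot(yy, xx)
    mito = r <= radius_px
    if cristae_spec == "none":
        cristae = np.zeros_like(mito)
    elif cristae_spec == "uniform":
        cristae = mito & (rng.random(mito.shape) < cristae_density)
    elif cristae_spec == "central":
        cristae = r <= central_radius_frac * radius_px
    else:
        raise ValueError(f"unknown cristae_spec {cristae_spec!r}")
    truth = GroundTruth(
        {
            "radius_px": radius_px,
            "cristae_spec": cristae_spec,
            "cristae_density": cristae_density,
            "px_nm": config.tem_px_nm,
        }
    )
    return mito, cristae, truth


# ---------------------------------------------------------------------------
# Ratiometric traces


def make_trace_set(
    config: SynthConfig,
    kinetics: dict | None = None,
    n_cells: int = 10,
    duration_s: float = 300.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dual-channel ratiometric traces with bleaching and a Ca2+ transient.

    The true ratio is flat at ``baseline`` until ``t_on_s``, steps to
    ``baseline + transient_amp`` for ``plateau_s``, and then decays back
    exponentially with time constant ``decay_s``. Both emission channels share the same multiplicative
    exponential photobleaching (time constant ``bleach_tau_s``; None or
    inf disables bleaching), so the ratio itself is bleach-insensitive
    while each channel still requires correction. Additive Gaussian noise
    has SD ``config.gaussian_sd`` x the channel baseline (default 0.05,
    i.e. SNR 20).
    """
    k = {
        "baseline": 1.0,
        "bleach_tau_s": 300.0,
        "transient_amp": 0.5,
        "t_on_s": 90.0,
        "plateau_s": 15.0,
        "decay_s": 40.0,
    }
    if kinetics:
        k.update(kinetics)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    tau = k["bleach_tau_s"]
    if tau is not None and not np.isinf(tau) and tau <= 0:
        raise ValueError("bleach_tau_s must be > 0")
    rng = rng_for(config, "trace_set")
    t = np.arange(0.0, duration_s, config.frame_interval_s)
    bleach = (
        np.ones_like(t)
        if tau is None or np.isinf(tau)
        else np.exp(-t / tau)
    )
    f0 = 1000.0
    frames = []
    per_cell = []
    for cell in range(n_cells):
        amp = k["transient_amp"]
        ratio = np.full_like(t, k["baseline"])
        t_fall = k["t_on_s"] + k["plateau_s"]
        on = (t >= k["t_on_s"]) & (t < t_fall)
        fall = t >= t_fall
        ratio[on] += amp
        ratio[fall] += amp * np.exp(-(t[fall] - t_fall) / k["decay_s"])
        den = f0 * bleach
        num = ratio * den
        noise_sd = config.gaussian_sd * f0
        num = num + rng.normal(0, noise_sd, t.shape)
        den = den + rng.normal(0, noise_sd, t.shape)
        frames.append(
            pd.DataFrame(
                {"cell": cell, "time_s": t, "ch_num": num, "ch_den": den}
            )
        )
        per_cell.append({"cell": cell, "transient_amp": amp})
    truth = GroundTruth(
        {
            "kinetics": dict(k),
            "f0": f0,
            "noise_sd": config.gaussian_sd * f0,
            "cells": per_cell,
        }
    )
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Single-channel sweeps

DEFAULT_PO_BY_MV: dict[float, float] = {
    -60.0: 0.10,
    -80.0: 0.20,
    -100.0: 0.30,
    -120.0: 0.40,
}


def _simulate_gate(
    rng: np.random.Generator,
    n_samples: int,
    fs_hz: float,
    po: float,
    mean_open_s: float,
) -> np.ndarray:
    """Two-state Markov open/closed gating, sampled at fs_hz.

    Dwell times are exponential with mean ``mean_open_s`` in the open
    state and ``mean_open_s * (1 - po) / po`` in the closed state, giving
    stationary open probability ``po``; the initial state is drawn from
    the stationary distribution.
    """
    if po <= 0:
        return np.zeros(n_samples, dtype=bool)
    if po >= 1:
        return np.ones(n_samples, dtype=bool)
    mean_closed_s = mean_open_s * (1.0 - po) / po
    open_now = rng.random() < po
    out = np.zeros(n_samples, dtype=bool)
    i = 0
    while i < n_samples:
        mean = mean_open_s if open_now else mean_closed_s
        dwell = rng.exponential(mean)
        n = max(1, int(round(dwell * fs_hz)))
        if open_now:
            out[i : i + n] = True
        i += n
        open_now = not open_now
    return out


def make_patch_sweeps(
    config: SynthConfig,
    protocol: PatchProtocol | None = None,
    gamma_pS: float = 35.0,
    po_by_mV: dict[float, float] | None = None,
    n_channels: int = 1,
    reversal_mV: float = 0.0,
    mean_open_ms: float = 10.0,
    noise_sd_frac: float = 0.15,
    noise_floor_pA: float = 0.2,
    n_patches: int = 1,
    sweeps_per_potential: int = 5,
    frac_silent: float = 0.0,
    fs_hz: float = 10_000.0,
    filter_hz: float = 1_000.0,
) -> tuple[list[SingleChannelRecording], GroundTruth]:
    """Mitochondria-attached sweep sets with two-state Markov gating.

    The unitary current is i(V) = gamma * (V - reversal); each channel
    gates independently with stationary open probability ``po_by_mV[V]``.
    Gaussian noise with SD ``noise_sd_frac`` x |unitary amplitude| (or
    ``noise_floor_pA`` for zero-conductance controls) is added before a
    4-pole low-pass Bessel filter at ``filter_hz`` emulates the recording
    bandwidth. ``frac_silent`` of the patches contain no channel (rounded
    to a whole number of patches, positions shuffled deterministically).
    """
    if gamma_pS < 0:
        raise ValueError("gamma_pS must be >= 0")
    if fs_hz < 10_000.0:
        raise ValueError("sampling rate must be >= 10 kHz")
    protocol = protocol or PatchProtocol()
    po_by_mV = dict(po_by_mV or DEFAULT_PO_BY_MV)
    for po in po_by_mV.values():
        if not 0.0 <= po <= 1.0:
            raise ValueError("open probabilities must be in [0, 1]")
    rng = rng_for(config, "patch_sweeps")
    n_silent = int(round(frac_silent * n_patches))
    silent_flags = np.array([True] * n_silent + [False] * (n_patches - n_silent))
    rng.shuffle(silent_flags)
    sos = bessel(4, filter_hz, btype="low", fs=fs_hz, output="sos")
    n_samples = int(round(protocol.dur_s * fs_hz))
    recordings = []
    patch_truth = []
    for p in range(n_patches):
        silent = bool(silent_flags[p])
        sweeps = []
        sweep_truth = []
        for v in protocol.test_mV:
            i_unit = gamma_pS * (v - reversal_mV) / 1000.0  # pA
            po = po_by_mV.get(v, 0.0)
            sd = noise_sd_frac * abs(i_unit) if i_unit != 0 else noise_floor_pA
            for _ in range(sweeps_per_potential):
                level = np.zeros(n_samples)
                if not silent and gamma_pS > 0:
                    for _ch in range(n_channels):
                        level += _simulate_gate(
                            rng, n_samples, fs_hz, po, mean_open_ms * 1e-3
                        )
                clean = level * i_unit
                raw = clean + rng.normal(0.0, sd, n_samples)
                filtered = sosfiltfilt(sos, raw)
                sweeps.append(Sweep(test_mV=v, current_pA=filtered))
                sweep_truth.append(
                    {
                        "test_mV": v,
                        "true_open_frac": float(np.mean(level > 0)),
                        "true_level_time_frac": float(np.mean(level)),
                    }
                )
        recordings.append(
            SingleChannelRecording(
                sweeps=sweeps,
                fs_hz=fs_hz,
                filter_hz=filter_hz,
                protocol=protocol,
                pipette={"free_Ca_uM": 10.0, "K_mM": 140.0},
            )
        )
        patch_truth.append({"silent": silent, "sweeps": sweep_truth})
    truth = GroundTruth(
        {
            "gamma_pS": gamma_pS,
            "po_by_mV": po_by_mV,
            "n_channels": n_channels,
            "reversal_mV": reversal_mV,
            "mean_open_ms": mean_open_ms,
            "noise_sd_frac": noise_sd_frac,
            "frac_silent": frac_silent,
            "patches": patch_truth,
        }
    )
    return recordings, truth


# ---------------------------------------------------------------------------
# Immunogold fields


def _circle_contour(center_nm, radius_nm, n_vertices=256) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center_nm[0] + radius_nm * np.cos(ang), center_nm[1] + radius_nm * np.sin(ang)]
    )


def make_gold_field(
    config: SynthConfig,
    omm_contour: np.ndarray | None = None,
    n_particles: int = 200,
    offset_mean_nm: float = 15.0,
    offset_sd_nm: float = 5.0,
    frac_membrane: float = 1.0,
    frac_nucleus: float = 0.0,
    canvas_nm: float = 2000.0,
) -> tuple[GoldParticleField, GroundTruth]:
    """Gold-particle field around a closed OMM contour.

    Membrane-associated particles sit at a random position along the
    contour, displaced along the inward normal by a draw from
    N(``offset_mean_nm``, ``offset_sd_nm``) — positive toward the matrix,
    negative toward the cytosol — and the drawn offset is recorded as the
    true signed distance. The remaining particles scatter uniformly over
    the cytosol (and optionally the nucleus). Compartment masks are
    rasterised at ``config.tem_px_nm``.
    """
    rng = rng_for(config, "gold_field")
    cx = cy = canvas_nm / 2.0
    mito_r = canvas_nm / 6.5
    if omm_contour is None:
        omm_contour = _circle_contour((cx - canvas_nm / 6, cy), mito_r)
    omm_contour = np.asarray(omm_contour, dtype=float)
    # raster compartment masks
    px = config.tem_px_nm
    n_px = int(np.ceil(canvas_nm / px))
    yy, xx = (np.mgrid[:n_px, :n_px] + 0.5) * px
    import shapely
    from shapely.geometry import Polygon as _Poly

    poly = _Poly(omm_contour)
    mito_mask = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(n_px, n_px)
    nuc_center = (cx + canvas_nm / 4.5, cy + canvas_nm / 4.5)
    nuc_r = canvas_nm / 8.0
    nuc_mask = (xx - nuc_center[0]) ** 2 + (yy - nuc_center[1]) ** 2 <= nuc_r**2
    nuc_mask &= ~mito_mask
    cell_r = canvas_nm / 2.05
    cyto_mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= cell_r**2) & ~mito_mask & ~nuc_mask

    n_mem = int(round(frac_membrane * n_particles))
    n_nuc = int(round(frac_nucleus * n_particles))
    n_cyt = n_particles - n_mem - n_nuc
    particles = []
    true_offsets = []
    true_comp = []
    # membrane-associated particles
    seg = rng.integers(0, len(omm_contour), n_mem)
    frac = rng.random(n_mem)
    offsets = rng.normal(offset_mean_nm, offset_sd_nm, n_mem)
    centroid = omm_contour.mean(axis=0)
    for s, f, off in zip(seg, frac, offsets):
        a = omm_contour[s]
        b = omm_contour[(s + 1) % len(omm_contour)]
        point = a + f * (b - a)
        tangent = b - a
        normal = np.array([-tangent[1], tangent[0]])
        normal /= np.linalg.norm(normal)
        if np.dot(normal, centroid - point) < 0:
            normal = -normal  # make it the inward normal
        pos = point + off * normal
        particles.append(pos)
        true_offsets.append(off)
        true_comp.append("membrane")

    def _scatter(mask: np.ndarray, n: int, name: str) -> None:
        coords = np.argwhere(mask)
        idx = rng.integers(0, len(coords), n)
        for r, c in coords[idx]:
            particles.append(np.array([(c + 0.5) * px, (r + 0.5) * px]))
            true_offsets.append(np.nan)
            true_comp.append(name)

    if n_cyt > 0:
        _scatter(cyto_mask, n_cyt, "cytosol")
    if n_nuc > 0:
        _scatter(nuc_mask, n_nuc, "nucleus")

    field = GoldParticleField(
        particles_nm=np.array(particles),
        omm_contours=[omm_contour],
        compartment_masks={
            "mitochondria": mito_mask,
            "nucleus": nuc_mask,
            "cytosol": cyto_mask,
        },
        px_nm=px,
    )
    truth = GroundTruth(
        {
            "offset_mean_nm": offset_mean_nm,
            "offset_sd_nm": offset_sd_nm,
            "true_offsets_nm": np.array(true_offsets),
            "true_compartment": list(true_comp),
            "n_particles": n_particles,
        }
    )
    return field, truth


# ---------------------------------------------------------------------------
# Fractionation sheets


def make_fraction_sheet(
    config: SynthConfig,
    pct_mito: float = 30.0,
    pct_outer_leaflet: float = 70.0,
    D1: dict[str, float] | None = None,
    D2: dict[str, float] | None = None,
    K_pl: float = 1.0,
    K_dm: float = 1.0,
    noise_cv: float = 0.0,
) -> tuple[FractionSheet, GroundTruth]:
    """Band-intensity sheet that inverts the fractionation formulas exactly.

    Scaled amounts are constructed so that the mitochondrial percentage
    (with ``K_pl``) equals ``pct_mito`` and the outer-leaflet percentage
    (with ``K_dm``) equals ``pct_outer_leaflet``; intensities are the
    amounts divided by the per-lane D factors. In noisy mode each
    intensity is additionally multiplied by lognormal noise of the given
    CV.
    """
    if not 0 < pct_mito < 100 or not 0 < pct_outer_leaflet <= 100:
        raise ValueError("percentages must be inside (0, 100]")
    D1 = dict(D1 or {})
    D2 = dict(D2 or {})
    f_m = pct_mito / (100.0 * K_pl)
    if not 0 < f_m < 1:
        raise ValueError("pct_mito incompatible with K_pl")
    a_mito = f_m
    a_cyto = 1.0 - f_m
    f_o = pct_outer_leaflet / (100.0 * K_dm)
    if not 0 < f_o <= 1:
        raise ValueError("pct_outer_leaflet incompatible with K_dm")
    a_pk = a_mito * (1.0 - f_o) / f_o
    amounts = {"cyto": a_cyto, "p_mito": a_mito, "p_mito_PK": a_pk}
    rng = rng_for(config, "fraction_sheet")
    I_blot = {}
    for lane, amount in amounts.items():
        d1 = D1.get(lane, 1.0)
        d2 = D2.get(lane, 1.0)
        noise = (
            rng.lognormal(mean=-0.5 * np.log1p(noise_cv**2), sigma=np.sqrt(np.log1p(noise_cv**2)))
            if noise_cv > 0
            else 1.0
        )
        I_blot[lane] = amount / (d1 * d2) * noise
    sheet = FractionSheet(I_blot=I_blot, D1=D1, D2=D2, K_pl=K_pl, K_dm=K_dm)
    truth = GroundTruth(
        {
            "pct_mito": pct_mito,
            "pct_outer_leaflet": pct_outer_leaflet,
            "K_pl": K_pl,
            "K_dm": K_dm,
            "noise_cv": noise_cv,
        }
    )
    return sheet, truth


# ---------------------------------------------------------------------------
# Concentration-response sets


def make_dose_response(
    config: SynthConfig,
    ec50_uM: float = 1.3,
    hill_n: float = 1.0,
    floor: float = 0.0,
    ceiling: float = 1.0,
    conc_uM: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
    n_cells: int = 50,
    cv: float = 0.10,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell peak responses drawn from a Hill concentration-response curve.

    Each cell at each concentration responds with the Hill-curve value
    multiplied by lognormal noise of coefficient of variation ``cv``
    (mean-one, multiplicative), emulating cell-to-cell variability of peak
    Ca2+ responses.
    """
    rng = rng_for(config, "dose_response")
    rows = []
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * np.log1p(cv**2)
    for c in conc_uM:
        h = floor + (ceiling - floor) / (1.0 + (ec50_uM / c) ** hill_n)
        noise = rng.lognormal(mu, sigma, n_cells) if cv > 0 else np.ones(n_cells)
        for cell, x in enumerate(h * noise):
            rows.append({"conc_uM": c, "cell": cell, "response": x})
    truth = GroundTruth(
        {
            "ec50_uM": ec50_uM,
            "hill_n": hill_n,
            "floor": floor,
            "ceiling": ceiling,
            "cv": cv,
            "n_cells": n_cells,
        }
    )
    return pd.DataFrame(rows), truth
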