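"""Ratiometric Ca2+/FRET/TMRM trace processing and dose-response fitting.

Time-lapse recordings of genetically encoded ratiometric sensors are
background subtracted, corrected for photobleaching by dividing out an
exponential decay extrapolated from the pre-stimulus baseline, converted to
a numerator/denominator emission ratio with a per-sensor convention chosen
so Ca2+ rises are positive-going, and summarised by basal, peak, and delta.
Concentration-response series are fitted with a four-parameter logistic
(Hill) model on log10 concentration with a seeded bootstrap CI for the
EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RawTrace",
    "RatioTrace",
    "DoseResponse",
    "SENSOR_CONVENTIONS",
    "subtract_background",
    "correct_bleach",
    "compute_ratio",
    "tmrm_potential",
    "fit_hill",
]

# numerator/denominator emission (nm) per sensor label, chosen so that a
# Ca2+ rise increases the ratio; Fura-2 uses excitation wavelengths
SENSOR_CONVENTIONS: dict[str, str] = {
    "matrix": "530/480",  # 4mtD3cpv FRET
    "IMS": "480/530",  # GEM-GECO: Ca2+-bound emission in numerator
    "cristae": "480/530",  # GEM-GECO
    "cyto_fura": "340/385",
    "cyto_gcamp": "F/F0",
    "ER": "530/480",  # D1ER FRET (response is a drop on depletion)
    "MICU1_FRET": "530/480",
    "TMRM": "mito/nucleus",
}


class RatioUnreliableError(ValueError):
    """Raised when >10% of ratio samples have a non-positive denominator."""


class DegenerateResponseError(ValueError):
    """Raised for flat concentration-response data ("degenerate_response")."""


class EmptyRoiError(ValueError):
    """Raised when a required mask selects no pixels ("empty_roi")."""


@dataclass
class RawTrace:
    """Two-channel raw time series for one cell."""

    time_s: np.ndarray
    ch_num: np.ndarray
    ch_den: np.ndarray
    bg_num: float | np.ndarray = 0.0
    bg_den: float | np.ndarray = 0.0
    label: str = "matrix"
    flags: list[str] = field(default_factory=list)
    bleach_params: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch_num = np.asarray(self.ch_num, dtype=float)
        self.ch_den = np.asarray(self.ch_den, dtype=float)
        if not (len(self.time_s) == len(self.ch_num) == len(self.ch_den)):
            raise ValueError("time and channel vectors must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class RatioTrace:
    ratio: np.ndarray
    time_s: np.ndarray
    basal: float
    peak: float
    delta: float
    baseline_window: tuple[int, int]
    direction: str = "up"
    bleach_params: dict | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class DoseResponse:
    conc_uM: np.ndarray
    response: np.ndarray
    ec50_uM: float | None = None
    hill_n: float | None = None
    floor: float | None = None
    ceiling: float | None = None
    ci95: tuple[float, float] | None = None
    r2: float | None = None
    flags: list[str] = field(default_factory=list)


def subtract_background(raw: RawTrace) -> RawTrace:
    """Subtract per-channel background (scalar or vector).

    Negative corrected values are permitted (they occur with noisy
    backgrounds) and flagged so downstream ratio masking can report them.
    """
    out_flags = list(raw.flags)
    new_channels = []
    for ch, bg in ((raw.ch_num, raw.bg_num), (raw.ch_den, raw.bg_den)):
        bg_arr = np.asarray(bg, dtype=float)
        if not np.all(np.isfinite(bg_arr)):
            raise ValueError("background must be finite")
        if bg_arr.ndim > 0 and bg_arr.size not in (1, ch.size):
            raise ValueError("length_mismatch: background longer than trace")
        corrected = ch - bg_arr
        new_channels.append(corrected)
    if np.any(new_channels[0] < 0) or np.any(new_channels[1] < 0):
        if "negative_after_bg" not in out_flags:
            out_flags.append("negative_after_bg")
            warnings.warn("negative intensities after background subtraction")
    return replace(
        raw, ch_num=new_channels[0], ch_den=new_channels[1], bg_num=0.0, bg_den=0.0,
        flags=out_flags,
    )


def _exp_decay(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def _fit_bleach(t: np.ndarray, y: np.ndarray) -> tuple[dict, np.ndarray]:
    """Fit y = A exp(-t/tau) + C on the baseline; linear fallback on failure.

    Returns the fit parameters and the fitted curve evaluated over the full
    time axis supplied.
    """
    t0 = t - t[0]
    span = max(t0[-1], 1e-9)
    # log-linear initial guess for the decay constant; A, C >= 0 bounds keep
    # the extrapolation from collapsing into a runaway linear solution
    pos = y > 0
    if pos.sum() >= 3:
        slope = np.polyfit(t0[pos], np.log(y[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < -1e-12 else 2.0 * span
    else:
        tau0 = span
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_decay,
                t0,
                y,
                p0=(max(y[0], 1e-6), tau0, 0.0),
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        A, tau, C = popt
        if tau <= 0 or not np.all(np.isfinite(popt)):
            raise RuntimeError("invalid exponential fit")
        return {"model": "exp", "A": A, "tau": tau, "C": C}, popt
    except RuntimeError:
        slope, intercept = np.polyfit(t0, y, 1)
        return {"model": "linear", "slope": slope, "intercept": intercept}, None


def correct_bleach(
    raw: RawTrace, baseline_window: tuple[int, int]
) -> RawTrace:
    """Divide out photobleaching extrapolated from the pre-stimulus baseline.

    For each channel an exponential decay A exp(-t/tau) + C is fitted on
    ``baseline_window`` (>= 10 samples, before stimulation), extrapolated
    over the full trace, and the trace divided by the fitted curve
    normalised to its value at the first sample. A non-convergent
    exponential falls back to a linear fit, flagged ``bleach_linear_fallback``.
    """
    i0, i1 = baseline_window
    if i1 - i0 < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    t = raw.time_s
    tb = t[i0:i1]
    out = {}
    params: dict[str, dict] = {}
    flags = list(raw.flags)
    for name, ch in (("num", raw.ch_num), ("den", raw.ch_den)):
        info, popt = _fit_bleach(tb, ch[i0:i1])
        t_rel = t - tb[0]
        if info["model"] == "exp":
            fitted = _exp_decay(t_rel, info["A"], info["tau"], info["C"])
        else:
            fitted = info["slope"] * t_rel + info["intercept"]
            if "bleach_linear_fallback" not in flags:
                flags.append("bleach_linear_fallback")
        norm = fitted / fitted[i0]
        # guard against pathological extrapolation to ~0
        norm = np.where(np.abs(norm) < 1e-9, np.nan, norm)
        out[name] = ch / norm
        params[name] = info
    return replace(
        raw, ch_num=out["num"], ch_den=out["den"], flags=flags,
        bleach_params=params,
    )


def _moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    if len(x) < w:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="valid")


def compute_ratio(
    raw: RawTrace,
    baseline_window: tuple[int, int] | None = None,
    direction: str = "up",
) -> RatioTrace:
    """Form the sensor ratio and extract basal, peak, and delta.

    The ratio is ch_num / ch_den with the stored per-label numerator
    convention. Samples with a non-positive denominator are masked (NaN)
    and flagged; more than 10% masked raises ``RatioUnreliableError``. The
    basal level is the mean ratio inside the baseline window (default:
    first 60 s or all samples, whichever is shorter); the peak is the
    extremum of a 5-sample moving average; delta is peak - basal for
    upward responses and basal - nadir for downward ones (``direction``).
    """
    flags = list(raw.flags)
    den = raw.ch_den
    bad = den <= 0
    n_bad = int(bad.sum())
    if n_bad:
        flags.append("masked_samples")
    if n_bad > 0.1 * len(den):
        raise RatioUnreliableError("ratio_unreliable: >10% non-positive denominator")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, raw.ch_num / den)
    if baseline_window is None:
        n_base = int(np.searchsorted(raw.time_s, raw.time_s[0] + 60.0, side="right"))
        baseline_window = (0, max(min(n_base, len(ratio)), 1))
    i0, i1 = baseline_window
    basal = float(np.nanmean(ratio[i0:i1]))
    smooth = _moving_average(np.nan_to_num(ratio, nan=basal), 5)
    if direction == "up":
        peak = float(np.nanmax(smooth))
        delta = peak - basal
    elif direction == "down":
        peak = float(np.nanmin(smooth))
        delta = basal - peak
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return RatioTrace(
        ratio=ratio,
        time_s=raw.time_s,
        basal=basal,
        peak=peak,
        delta=delta,
        baseline_window=baseline_window,
        direction=direction,
        bleach_params=raw.bleach_params,
        flags=flags,
    )


def tmrm_potential(
    frames: np.ndarray,
    mito_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    depol_frame: int | None = None,
):
    """Mitochondria-to-nucleus intensity ratio per frame (TMRM readout).

    ``frames`` is (t, y, x) or a single (y, x) image; the masks must be
    disjoint and non-empty. Returns the per-frame ratio trace and a basal
    scalar (mean before the depolarisation marker, or over all frames when
    no marker is given). With ``depol_frame`` set — e.g. the onset of
    FCCP perfusion (1 uM, 4 min in the reference protocol) — the
    depolarised endpoint is the mean ratio over the final quarter of the
    post-marker segment (plateau).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    mito_mask = np.asarray(mito_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not mito_mask.any() or not nucleus_mask.any():
        raise EmptyRoiError("empty_roi")
    if np.any(mito_mask & nucleus_mask):
        raise ValueError("mito and nucleus masks must be disjoint")
    mito = frames[:, mito_mask].mean(axis=1)
    nuc = frames[:, nucleus_mask].mean(axis=1)
    ratio = mito / nuc
    if depol_frame is None:
        return float(ratio.mean()), ratio
    basal = float(ratio[:depol_frame].mean())
    tail = ratio[depol_frame:]
    plateau = float(tail[-max(len(tail) // 4, 1):].mean())
    return {"basal": basal, "depolarized": plateau}, ratio


def _hill4(logc, ec50_log, hill, floor, ceiling):
    return floor + (ceiling - floor) / (1.0 + 10 ** ((ec50_log - logc) * hill))


def fit_hill(
    conc_uM: np.ndarray,
    response: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> DoseResponse:
    """Four-parameter logistic fit of response vs log10 concentration.

    Requires >= 4 distinct concentrations. Flat data raise
    ``DegenerateResponseError``; a fit with R^2 < 0.5 is flagged
    ``poor_fit``; an EC50 outside the tested span is flagged
    ``extrapolated``. The 95% EC50 CI comes from a seeded nonparametric
    bootstrap over observations (B = ``n_boot``).
    """
    conc = np.asarray(conc_uM, dtype=float)
    resp = np.asarray(response, dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    means = np.array([resp[conc == c].mean() for c in np.unique(conc)])
    if np.ptp(means) < 1e-12 * max(np.abs(means).max(), 1.0):
        raise DegenerateResponseError("degenerate_response")
    logc = np.log10(conc)

    def _fit(logc_s, resp_s):
        lo, hi = resp_s.min(), resp_s.max()
        # initial EC50: concentration nearest half-maximal mean response
        half = (lo + hi) / 2.0
        ec0 = logc_s[np.argmin(np.abs(resp_s - half))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _hill4,
                logc_s,
                resp_s,
                p0=(ec0, 1.0, lo, hi),
                maxfev=10000,
            )
        return popt

    popt = _fit(logc, resp)
    pred = _hill4(logc, *popt)
    ss_res = float(((resp - pred) ** 2).sum())
    ss_tot = float(((resp - resp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    flags = []
    if r2 < 0.5:
        flags.append("poor_fit")
    ec50 = 10 ** popt[0]
    if not (conc.min() <= ec50 <= conc.max()):
        flags.append("extrapolated")
    rng = np.random.default_rng(seed)
    boots = []
    n = len(conc)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(conc[idx]).size < 4:
            continue
        try:
            boots.append(10 ** _fit(logc[idx], resp[idx])[0])
        except RuntimeError:
            continue
    ci = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if boots
        else None
    )
    return DoseResponse(
        conc_uM=conc,
        response=resp,
        ec50_uM=float(ec50),
        hill_n=float(popt[1]),
        floor=float(popt[2]),
        ceiling=float(popt[3]),
        ci95=ci,
        r2=r2,
        flags=flags,
    )
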