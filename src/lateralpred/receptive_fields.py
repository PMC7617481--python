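"""Receptive-field estimation and Gabor parameterization.

Unit receptive fields are estimated by response-weighted averaging (RWA) of
Gaussian white-noise frames: RF_i = sum_t r_i[t] x[t] / sum_t r_i[t].  The
spatiotemporal variant stacks the 7 past frames preceding each response.
Each spatial map is then parameterized by a Gabor function (oriented sinusoid
under an elliptical Gaussian envelope) by nonlinear least squares, and units
whose fit is poor (r < 0.7) or whose fitted envelope is tiny (< 0.5 px) are
excluded from downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .netmodel import NetworkParams, forward
from .synthetic_data import MovieClip

__all__ = [
    "ReceptiveField",
    "GaborFit",
    "response_weighted_average",
    "temporal_summary",
    "gabor",
    "fit_gabor",
    "fit_gabors",
    "apply_inclusion_criteria",
]

N_LAGS = 7  # past frames in the spatiotemporal RWA


@dataclass
class ReceptiveField:
    """RWA estimate for one unit; ``defined`` is False if the unit never responded."""

    map: np.ndarray                      # (H, W)
    spatiotemporal_map: np.ndarray | None = None  # (N_LAGS, H, W), lag 0 = current
    defined: bool = True

    @property
    def temporal_power(self) -> np.ndarray:
        power, _ = temporal_summary(self.spatiotemporal_map)
        return power

    @property
    def temporal_center_of_mass(self) -> float:
        _, com = temporal_summary(self.spatiotemporal_map)
        return com


@dataclass
class GaborFit:
    """Fitted Gabor parameters and goodness of fit for one receptive field."""

    center_x: float
    center_y: float
    sigma_major: float
    sigma_minor: float
    orientation: float      # carrier wave-vector angle, radians mod pi
    spatial_frequency: float
    phase: float
    amplitude: float
    fit_r: float
    included: bool = False

    @property
    def rf_size(self) -> float:
        """Geometric mean of the fitted envelope sigmas, in pixels."""
        return float(np.sqrt(self.sigma_major * self.sigma_minor))

    def to_dict(self) -> dict:
        return {
            "center_x": self.center_x, "center_y": self.center_y,
            "sigma_major": self.sigma_major, "sigma_minor": self.sigma_minor,
            "orientation": self.orientation,
            "spatial_frequency": self.spatial_frequency,
            "phase": self.phase, "amplitude": self.amplitude,
            "fit_r": self.fit_r, "rf_size": self.rf_size,
            "included": self.included,
        }


def response_weighted_average(params: NetworkParams, n_noise_frames: int = 25000,
                              seed: int = 0, spatiotemporal: bool = False,
                              frame_shape: tuple[int, int] | None = None
                              ) -> list[ReceptiveField]:
    """Response-weighted average over Gaussian-noise frames for every unit.

    A single continuous sequence of ``n_noise_frames`` standard-normal frames
    is presented with the recurrent state carried across frames (continuous
    presentation, no reset).  Units with zero summed response get a flagged,
    undefined RF.
    """
    if frame_shape is None:
        side = int(round(np.sqrt(params.n_input)))
        frame_shape = (side, side)
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_noise_frames, h * w))
    state = forward(params, noise)
    resp = state.s  # (T, n_hidden)
    sums = resp.sum(axis=0)
    # sum_t r[t] x[t] for every unit at once
    num = resp.T @ noise  # (n_hidden, h*w)
    st_maps = None
    if spatiotemporal:
        st_maps = np.zeros((params.n_hidden, N_LAGS, h * w))
        for lag in range(N_LAGS):
            st_maps[:, lag] = resp[lag:].T @ noise[: n_noise_frames - lag]
    rfs = []
    for i in range(params.n_hidden):
        if sums[i] <= 0:
            rfs.append(ReceptiveField(np.full((h, w), np.nan), None, defined=False))
            continue
        spat = (num[i] / sums[i]).reshape(h, w)
        st = (st_maps[i] / sums[i]).reshape(N_LAGS, h, w) if spatiotemporal else None
        rfs.append(ReceptiveField(spat, st))
    return rfs


def temporal_summary(spatiotemporal_map: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-lag normalized power and its center of mass.

    power_l = mean over space of map_l^2, normalized to sum to 1;
    center of mass = sum_l l * power_l.
    """
    if spatiotemporal_map is None:
        raise ValueError("no spatiotemporal map")
    m = np.asarray(spatiotemporal_map)
    power = (m ** 2).mean(axis=(1, 2))
    total = power.sum()
    if total == 0:
        raise ValueError("all-zero spatiotemporal map")
    power = power / total
    lags = np.arange(len(power))
    return power, float((lags * power).sum())


def gabor(coords: tuple[np.ndarray, np.ndarray], x0: float, y0: float,
          sigma_major: float, sigma_minor: float, theta: float, sf: float,
          phase: float, amplitude: float) -> np.ndarray:
    """Gabor function on a pixel grid.

    ``theta`` is the angle of the carrier wave vector; the envelope major
    axis lies along the bars (perpendicular to the carrier).
    """
    x, y = coords
    xr = (x - x0) * np.cos(theta) + (y - y0) * np.sin(theta)
    yr = -(x - x0) * np.sin(theta) + (y - y0) * np.cos(theta)
    env = np.exp(-(xr ** 2 / (2 * sigma_minor ** 2)
                   + yr ** 2 / (2 * sigma_major ** 2)))
    return amplitude * env * np.cos(2 * np.pi * sf * xr + phase)


def _initial_guess(rf_map: np.ndarray) -> list[float]:
    h, w = rf_map.shape
    power = rf_map ** 2
    total = power.sum()
    y, x = np.mgrid[0:h, 0:w]
    x0 = (x * power).sum() / total
    y0 = (y * power).sum() / total
    # dominant spatial frequency from the amplitude spectrum
    F = np.fft.fft2(rf_map)
    F[0, 0] = 0
    idx = np.unravel_index(np.argmax(np.abs(F[: h // 2 + 1])), F[: h // 2 + 1].shape)
    fy = np.fft.fftfreq(h)[idx[0]]
    fx = np.fft.fftfreq(w)[idx[1]]
    sf = max(np.hypot(fy, fx), 0.02)
    theta = np.arctan2(fy, fx) % np.pi
    sx = np.sqrt((((x - x0) ** 2) * power).sum() / total) + 0.5
    sy = np.sqrt((((y - y0) ** 2) * power).sum() / total) + 0.5
    sigma = float(np.sqrt(sx * sy))
    amp = rf_map.flat[np.argmax(np.abs(rf_map))]
    return [x0, y0, sigma, sigma, float(theta), float(sf), 0.0, float(amp)]


def fit_gabor(rf: ReceptiveField | np.ndarray, n_starts: int = 3,
              seed: int = 0) -> GaborFit:
    """Nonlinear least-squares Gabor fit with multi-start initialization.

    Starts: a data-driven guess (squared-amplitude centroid, dominant FFT
    frequency/orientation), the same guess rotated 90 degrees, and seeded
    random jitters.  Returns the best fit by residual norm; failures yield
    ``fit_r = nan`` and ``included = False``.
    """
    rf_map = rf.map if isinstance(rf, ReceptiveField) else np.asarray(rf)
    if isinstance(rf, ReceptiveField) and not rf.defined:
        return GaborFit(*([np.nan] * 8), fit_r=np.nan)
    if not np.all(np.isfinite(rf_map)) or np.all(rf_map == 0):
        return GaborFit(*([np.nan] * 8), fit_r=np.nan)
    h, w = rf_map.shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    data = rf_map.ravel()

    def residual(p):
        return gabor((x, y), *p).ravel() - data

    base = _initial_guess(rf_map)
    rng = np.random.default_rng(seed)
    starts = [base, base[:4] + [(base[4] + np.pi / 2) % np.pi] + base[5:]]
    for _ in range(max(0, n_starts - 2)):
        jit = list(base)
        jit[0] += rng.uniform(-2, 2)
        jit[1] += rng.uniform(-2, 2)
        jit[4] = rng.uniform(0, np.pi)
        jit[5] = rng.uniform(0.03, 0.4)
        starts.append(jit)
    lb = [-w, -h, 0.1, 0.1, -np.inf, 0.0, -np.inf, -np.inf]
    ub = [2 * w, 2 * h, 2 * w, 2 * h, np.inf, 0.5, np.inf, np.inf]
    best = None
    for p0 in starts[:n_starts] if n_starts >= 2 else starts[:1]:
        p0 = np.clip(p0, lb, ub)
        try:
            sol = optimize.least_squares(residual, p0, bounds=(lb, ub),
                                         method="trf", max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return GaborFit(*([np.nan] * 8), fit_r=np.nan)
    p = best.x
    model = gabor((x, y), *p).ravel()
    if model.std() == 0 or data.std() == 0:
        fit_r = np.nan
    else:
        fit_r = float(np.corrcoef(model, data)[0, 1])
    # canonicalize: sigma_major >= sigma_minor, orientation mod pi
    x0, y0, s_maj, s_min, theta, sf, phase, amp = p
    if s_min > s_maj:
        s_maj, s_min = s_min, s_maj
    return GaborFit(float(x0), float(y0), float(s_maj), float(s_min),
                    float(theta % np.pi), float(sf), float(phase), float(amp),
                    fit_r)


def fit_gabors(rfs: list[ReceptiveField], n_starts: int = 3,
               seed: int = 0) -> list[GaborFit]:
    return [fit_gabor(rf, n_starts=n_starts, seed=seed + i)
            for i, rf in enumerate(rfs)]


def apply_inclusion_criteria(fits: list[GaborFit], min_size: float = 0.5,
                             min_r: float = 0.7) -> tuple[np.ndarray, dict]:
    """Exclude units with rf_size < 0.5 px or Gabor fit r < 0.7.

    Sets ``included`` on each fit in place and returns (mask, summary) where
    the summary reports each exclusion fraction and their union.
    """
    n = len(fits)
    small = np.array([not (f.rf_size >= min_size) for f in fits])  # NaN -> excluded
    poor = np.array([not (f.fit_r >= min_r) for f in fits])
    excluded = small | poor
    for f, ex in zip(fits, excluded):
        f.included = not ex
    summary = {
        "n_units": n,
        "frac_excluded_size": float(small.mean()) if n else 0.0,
        "frac_excluded_fit": float(poor.mean()) if n else 0.0,
        "frac_excluded_total": float(excluded.mean()) if n else 0.0,
        "n_included": int((~excluded).sum()),
    }
    return ~excluded, summary


def fits_to_frame(fits: list[GaborFit]) -> pd.DataFrame:
    """Tabulate fits (one row per unit) for CSV export."""
    return pd.DataFrame([f.to_dict() for f in fits]).rename_axis("unit").reset_index()
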