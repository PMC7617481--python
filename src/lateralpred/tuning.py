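"""Grating-derived selectivity, modulation ratio and response correlations.

Each unit's preferred grating (temporal frequency, spatial frequency,
direction) is the grid condition maximizing its mean response.  Orientation
and direction selectivity are the standard contrast indices

    OSI = (R_pref - R_orth) / (R_pref + R_orth)
    DSI = (R_pref - R_opp)  / (R_pref + R_opp)

with the orthogonal orientation at +90 degrees and the opposite direction at
+180 degrees.  The modulation ratio F = F1/F0 (fundamental amplitude over
mean response to the preferred drifting grating) classifies units as
simple-like (F > 1) or complex-like (F < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netmodel import NetworkParams, _forward_batch
from .synthetic_data import MovieClip, make_grating

__all__ = [
    "GratingGrid",
    "TuningProfile",
    "ModulationResult",
    "grating_battery",
    "compute_osi_dsi",
    "classify_selectivity",
    "modulation_ratio",
    "response_correlations",
    "tuning_table",
]


@dataclass
class GratingGrid:
    """Grating parameter grid: log-spaced sf/tf, uniform directions.

    Ranges follow the physiology battery convention: tf 0.02-0.25
    cycles/frame, sf 0.03-0.5 cycles/pixel, direction 0-360 degrees.
    """

    tfs: np.ndarray
    sfs: np.ndarray
    directions: np.ndarray

    @classmethod
    def default(cls, n_tf: int = 5, n_sf: int = 6, n_dir: int = 16,
                tf_range=(0.02, 0.25), sf_range=(0.03, 0.5)) -> "GratingGrid":
        return cls(
            tfs=np.geomspace(*tf_range, n_tf),
            sfs=np.geomspace(*sf_range, n_sf),
            directions=np.arange(n_dir) * (2 * np.pi / n_dir),
        )


@dataclass
class TuningProfile:
    """Per-unit grating-derived selectivity."""

    preferred_direction: float   # radians mod 2 pi
    preferred_orientation: float  # radians mod pi (bar axis)
    preferred_sf: float
    preferred_tf: float
    OSI: float
    DSI: float
    R_pref_or: float
    R_orth_or: float
    R_pref_dir: float
    R_opp_dir: float
    tie_flag: bool = False
    selectivity_class: str = "non_selective"


@dataclass
class ModulationResult:
    F0: float
    F1: float
    F: float
    sinusoid_fit_r: float
    cls: str  # simple_like | complex_like | undefined


def grating_battery(params: NetworkParams, grid: GratingGrid | None = None,
                    size: int | None = None, n_frames: int = 50,
                    discard_frames: int = 10) -> tuple[np.ndarray, GratingGrid]:
    """Mean response of every unit to every grating condition.

    Returns (responses, grid) with responses shaped
    (units, n_tf, n_sf, n_dir); the mean discards the first
    ``discard_frames`` onset frames.
    """
    grid = grid or GratingGrid.default()
    if size is None:
        size = int(round(np.sqrt(params.n_input)))
    stims = []
    for tf in grid.tfs:
        for sf in grid.sfs:
            for d in grid.directions:
                stims.append(make_grating(d, sf, tf, size=size,
                                          n_frames=n_frames).flatten())
    U = np.stack(stims)  # (n_cond, T, n_in)
    S, _ = _forward_batch(params, U)
    resp = S[:, discard_frames:].mean(axis=1)  # (n_cond, units)
    resp = resp.T.reshape(params.n_hidden, len(grid.tfs), len(grid.sfs),
                          len(grid.directions))
    return resp, grid


def compute_osi_dsi(r_pref_or: float, r_orth_or: float, r_pref_dir: float,
                    r_opp_dir: float) -> tuple[float, float]:
    """Contrast indices; NaN (flagged) on a zero denominator."""
    if min(r_pref_or, r_orth_or, r_pref_dir, r_opp_dir) < 0:
        raise ValueError("responses must be non-negative")
    osi = (r_pref_or - r_orth_or) / (r_pref_or + r_orth_or) \
        if r_pref_or + r_orth_or > 0 else np.nan
    dsi = (r_pref_dir - r_opp_dir) / (r_pref_dir + r_opp_dir) \
        if r_pref_dir + r_opp_dir > 0 else np.nan
    return osi, dsi


def unit_tuning(resp_unit: np.ndarray, grid: GratingGrid) -> TuningProfile:
    """Tuning profile of one unit from its (tf, sf, dir) response array."""
    n_dir = len(grid.directions)
    flat = resp_unit.ravel()
    tie = np.all(flat == flat[0])
    it, isf, idir = np.unravel_index(int(np.argmax(resp_unit)), resp_unit.shape)
    pref_dir = grid.directions[idir]
    dir_curve = resp_unit[it, isf]  # response vs direction at preferred tf/sf
    opp = (idir + n_dir // 2) % n_dir
    # orientation curve: average the two directions of motion per axis
    ori_curve = 0.5 * (dir_curve + np.roll(dir_curve, -n_dir // 2))
    iori = int(np.argmax(ori_curve[: n_dir // 2])) if not tie else idir % (n_dir // 2)
    iorth = (iori + n_dir // 4) % (n_dir // 2)
    r_pref_or = float(ori_curve[iori])
    r_orth_or = float(ori_curve[iorth])
    r_pref_dir = float(dir_curve[idir])
    r_opp_dir = float(dir_curve[opp])
    osi, dsi = compute_osi_dsi(r_pref_or, r_orth_or, r_pref_dir, r_opp_dir)
    pref_ori = (grid.directions[iori] + np.pi / 2) % np.pi  # bar axis
    return TuningProfile(
        preferred_direction=float(pref_dir), preferred_orientation=float(pref_ori),
        preferred_sf=float(grid.sfs[isf]), preferred_tf=float(grid.tfs[it]),
        OSI=osi, DSI=dsi, R_pref_or=r_pref_or, R_orth_or=r_orth_or,
        R_pref_dir=r_pref_dir, R_opp_dir=r_opp_dir, tie_flag=bool(tie))


def classify_selectivity(profile: TuningProfile,
                         thresholds: str = "ko") -> str:
    """Selectivity class under a named threshold set.

    ``ko``: direction_selective iff OSI > 0.4 and DSI > 0.3;
    orientation_selective iff OSI > 0.4 (and not direction selective);
    otherwise non_selective.  ``rossi``: direction_selective iff DSI > 0.8
    (strict), else weakly_selective.  Tied/flat units are non_selective.
    """
    if profile.tie_flag or not np.isfinite(profile.OSI):
        return "non_selective" if thresholds == "ko" else "weakly_selective"
    if thresholds == "ko":
        if profile.OSI > 0.4 and profile.DSI > 0.3:
            cls = "direction_selective"
        elif profile.OSI > 0.4:
            cls = "orientation_selective"
        else:
            cls = "non_selective"
    elif thresholds == "rossi":
        cls = "direction_selective" if profile.DSI > 0.8 else "weakly_selective"
    else:
        raise ValueError(f"unknown threshold set {thresholds!r}")
    profile.selectivity_class = cls
    return cls


def modulation_ratio(trace: np.ndarray, tf: float,
                     fit_r_threshold: float = 0.9) -> ModulationResult:
    """F1/F0 from a least-squares sinusoid at the stimulus frequency.

    F0 is the trace mean; F1 the amplitude of a free-phase sinusoid at the
    known temporal frequency ``tf`` (cycles/frame) fitted by least squares.
    The ratio is undefined when the sinusoid fit correlates < 0.9 with the
    trace or F0 = 0.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) * tf < 2:
        raise ValueError("trace must span at least 2 stimulus cycles")
    t = np.arange(len(trace))
    X = np.column_stack([np.sin(2 * np.pi * tf * t),
                         np.cos(2 * np.pi * tf * t),
                         np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, trace, rcond=None)
    fitted = X @ coef
    f1 = float(np.hypot(coef[0], coef[1]))
    f0 = float(trace.mean())
    if fitted.std() == 0 or trace.std() == 0:
        fit_r = np.nan
    else:
        fit_r = float(np.corrcoef(fitted, trace)[0, 1])
    if not np.isfinite(fit_r) or fit_r < fit_r_threshold or f0 == 0:
        return ModulationResult(f0, f1, np.nan, fit_r, "undefined")
    ratio = f1 / f0
    return ModulationResult(f0, f1, ratio, fit_r,
                            "simple_like" if ratio > 1 else "complex_like")


def response_correlations(params: NetworkParams, clips: list[MovieClip],
                          n_clips: int = 100, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-clip Pearson correlation matrix of unit response time courses.

    ``n_clips`` clips are sampled (without replacement when possible) from
    the provided validation clips.  Per clip, units with zero response
    variance are skipped for their pairs; returns (corr_matrix,
    valid_clip_counts) where counts give the number of clips entering each
    pair's average.  The diagonal is 1.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(clips), size=min(n_clips, len(clips)),
                     replace=len(clips) < n_clips)
    n = params.n_hidden
    acc = np.zeros((n, n))
    counts = np.zeros((n, n))
    for i in idx:
        U = clips[i].flatten()[None]
        S, _ = _forward_batch(params, U)
        r = S[0].T  # (units, T)
        sd = r.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(r[ok])
        mask = np.outer(ok, ok)
        full = np.zeros((n, n))
        full[np.ix_(ok, ok)] = c
        acc += np.where(mask, full, 0.0)
        counts += mask
    with np.errstate(invalid="ignore"):
        corr = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(corr, 1.0)
    return corr, counts


def tuning_table(profiles: list[TuningProfile]) -> pd.DataFrame:
    """One row per unit: preferred parameters, OSI/DSI, class."""
    rows = []
    for i, p in enumerate(profiles):
        rows.append({
            "unit": i,
            "preferred_direction": p.preferred_direction,
            "preferred_orientation": p.preferred_orientation,
            "preferred_sf": p.preferred_sf, "preferred_tf": p.preferred_tf,
            "OSI": p.OSI, "DSI": p.DSI,
            "class": p.selectivity_class, "tie_flag": p.tie_flag,
        })
    return pd.DataFrame(rows)
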