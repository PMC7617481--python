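"""Ablation experiments, representation clustering and prediction-error units.

Ablation replaces selected recurrent connections with the median weight of
the connected excitatory-to-excitatory subpopulation (rather than zero, so
the manipulation removes tuning-specific structure without changing the
overall excitation level).  Ablation classes are defined by the tuning
relation between pre- and postsynaptic units: co-tuned (similar orientation
preference), orthogonal, and co/anti-tuned (similar or opposite direction
preference).

The silhouette analysis measures how separable hidden representations of
three grating classes (orientation offsets 0, 11.25 and 22.5 degrees) remain
under input noise, with and without ablation.  The oddball analysis detects
units that respond to pattern-violating stimuli but not to either control
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .connectivity import (ConnectivityGraph, fold_direction_difference_deg,
                           fold_orientation_difference_deg,
                           normalize_visual_space, rf_centers,
                           sector_labels_orientation)
from .netmodel import NetworkConfig, NetworkParams, _forward_batch, evaluate_mse
from .synthetic_data import (MovieClip, StimulusSet, add_gaussian_noise_snr,
                             make_grating)
from .tuning import TuningProfile

__all__ = [
    "AblationSpec",
    "ClusteringResult",
    "select_class_edges",
    "median_ee_weight",
    "ablate",
    "ablation_error_curve",
    "silhouette_analysis",
    "bar_dot_deficit",
    "detect_prediction_error_units",
]

ANGULAR_WINDOWS = {
    "co_tuned": ("orientation", lambda d: d < 22.5),
    "orthogonal": ("orientation", lambda d: d > 67.5),
    "co_anti_tuned": ("direction", lambda d: (d < 22.5) | (d > 157.5)),
}


@dataclass
class AblationSpec:
    """Which connections to ablate, how many, and how often to redraw."""

    target_class: str            # co_tuned | orthogonal | co_anti_tuned
    n_ablate: int
    n_repeats: int = 1000
    replacement_value: float | None = None  # default: median E->E connected weight
    seed: int = 0


@dataclass
class ClusteringResult:
    silhouette: float
    snr_condition: float
    network_condition: str  # full | ablated
    base_orientation: float = 0.0


def median_ee_weight(graph: ConnectivityGraph) -> float:
    """Median recurrent weight over connected E->E pairs."""
    exc = graph.excitatory
    mask = graph.adjacency & np.outer(exc, exc)
    if not mask.any():
        raise ValueError("no connected E->E pairs")
    return float(np.median(graph.weight[mask]))


def select_class_edges(graph: ConnectivityGraph,
                       profiles: list[TuningProfile],
                       target_class: str,
                       selective: np.ndarray | None = None) -> np.ndarray:
    """(post, pre) index pairs of connected E->E edges in a tuning class."""
    if target_class not in ANGULAR_WINDOWS:
        raise ValueError(f"unknown ablation class {target_class!r}")
    feature, window = ANGULAR_WINDOWS[target_class]
    exc = graph.excitatory
    ok = graph.included & exc
    if selective is not None:
        ok = ok & np.asarray(selective, bool)
    post, pre = np.nonzero(graph.adjacency & np.outer(ok, ok))
    if feature == "orientation":
        pref = np.array([p.preferred_orientation for p in profiles])
        delta = fold_orientation_difference_deg(pref[post], pref[pre])
    else:
        pref = np.array([p.preferred_direction for p in profiles])
        delta = fold_direction_difference_deg(pref[post], pref[pre])
    keep = window(delta)
    return np.stack([post[keep], pre[keep]], axis=1)


def ablate(W_rec: np.ndarray, edges: np.ndarray, spec: AblationSpec,
           replacement: float):
    """Yield per-repeat weight copies with ``n_ablate`` random edges replaced.

    The original matrix is never modified; only entries in the sampled edge
    set change, all to the replacement value.
    """
    if spec.n_ablate > len(edges):
        raise ValueError(
            f"n_ablate={spec.n_ablate} exceeds {len(edges)} available edges")
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_repeats):
        W = W_rec.copy()
        if spec.n_ablate > 0:
            pick = rng.choice(len(edges), size=spec.n_ablate, replace=False)
            W[edges[pick, 0], edges[pick, 1]] = replacement
        yield W


def _mse_with_weights(params: NetworkParams, W_eff: np.ndarray,
                      clips: list[MovieClip], config: NetworkConfig) -> float:
    """Next-frame MSE with an externally supplied effective recurrent matrix."""
    patched = params.copy()
    # raw magnitudes; the sign reparameterization restores W_eff exactly
    patched.W_rec = np.abs(W_eff)
    return evaluate_mse(patched, clips, config)


def ablation_error_curve(params: NetworkParams, graph: ConnectivityGraph,
                         profiles: list[TuningProfile],
                         clips: list[MovieClip], config: NetworkConfig,
                         n_grid: list[int], classes=("co_tuned", "orthogonal",
                                                     "co_anti_tuned"),
                         n_repeats: int = 20, seed: int = 0,
                         selective: np.ndarray | None = None) -> pd.DataFrame:
    """Mean next-frame MSE versus number of ablated connections per class.

    Ablations act on the effective (sign-constrained) recurrent matrix; the
    replacement value is the median connected E->E weight.  Returns a tidy
    frame (class, n_ablate, mse_mean, mse_sem).  n = 0 reproduces the
    unablated model MSE exactly.
    """
    W_eff = params.w_rec_effective
    replacement = median_ee_weight(graph)
    rows = []
    base_mse = evaluate_mse(params, clips, config)
    for cls_i, target_class in enumerate(classes):
        edges = select_class_edges(graph, profiles, target_class, selective)
        if len(edges) == 0:
            raise ValueError(f"no edges of class {target_class}")
        for n in n_grid:
            if n == 0:
                rows.append({"class": target_class, "n_ablate": 0,
                             "n_edges_available": len(edges),
                             "mse_mean": base_mse, "mse_sem": 0.0})
                continue
            n_eff = min(n, len(edges))
            spec = AblationSpec(target_class, n_eff, n_repeats=n_repeats,
                                seed=seed + 97 * cls_i + n)
            mses = [_mse_with_weights(params, W, clips, config)
                    for W in ablate(W_eff, edges, spec, replacement)]
            rows.append({"class": target_class, "n_ablate": n_eff,
                         "n_edges_available": len(edges),
                         "mse_mean": float(np.mean(mses)),
                         "mse_sem": float(np.std(mses) / np.sqrt(len(mses)))})
    return pd.DataFrame(rows)


def _hidden_points(params: NetworkParams, clips: list[np.ndarray]) -> np.ndarray:
    """Time-averaged hidden activity per presentation (rows = points)."""
    U = np.stack(clips)
    S, _ = _forward_batch(params, U)
    return S.mean(axis=1)


def silhouette_formula(X: np.ndarray, labels: np.ndarray) -> float:
    """Direct (b - a)/max(a, b) silhouette recomputation (oracle-style)."""
    from scipy.spatial.distance import cdist
    D = cdist(X, X)
    vals = []
    for i in range(len(X)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def silhouette_analysis(params: NetworkParams,
                        ablated_w_eff: np.ndarray | None = None,
                        offsets_deg=(0.0, 11.25, 22.5),
                        snr_db: float = 0.0,
                        n_base_orientations: int = 8,
                        n_presentations: int = 8,
                        size: int | None = None, n_frames: int = 20,
                        sf: float = 0.125, tf: float = 0.06,
                        seed: int = 0) -> list[ClusteringResult]:
    """Silhouette score of hidden representations of three grating classes.

    For each base orientation, three classes of drifting gratings at the
    given orientation offsets are presented ``n_presentations`` times with
    independent noise at ``snr_db``; points are time-averaged hidden activity
    in the full hidden space.  Repeated across base orientations spanning
    0-360 degrees.  Pass an ablated effective recurrent matrix to score the
    ablated network.
    """
    if size is None:
        size = int(round(np.sqrt(params.n_input)))
    model = params
    condition = "full"
    if ablated_w_eff is not None:
        model = params.copy()
        model.W_rec = np.abs(ablated_w_eff)
        condition = "ablated"
    results = []
    bases = np.arange(n_base_orientations) * (360.0 / n_base_orientations)
    rng = np.random.default_rng(seed)
    for base in bases:
        clips, labels = [], []
        for k, off in enumerate(offsets_deg):
            direction = np.radians(base + off)
            clean = make_grating(direction, sf, tf, size=size, n_frames=n_frames)
            for _ in range(n_presentations):
                noisy = add_gaussian_noise_snr(clean, snr_db,
                                               seed=int(rng.integers(2 ** 31)))
                clips.append(noisy.flatten())
                labels.append(k)
        X = _hidden_points(model, clips)
        score = float(silhouette_score(X, np.array(labels)))
        results.append(ClusteringResult(score, snr_db, condition, base))
    return results


def silhouette_comparison(full: list[ClusteringResult],
                          ablated: list[ClusteringResult]) -> dict:
    """Paired t test of silhouette across base orientations, full vs ablated."""
    a = np.array([r.silhouette for r in full])
    b = np.array([r.silhouette for r in ablated])
    t, p = stats.ttest_rel(a, b)
    return {"mean_full": float(a.mean()), "mean_ablated": float(b.mean()),
            "t": float(t), "p": float(p)}


def coaxial_cotuned_edges(graph: ConnectivityGraph, fits, profiles,
                          selective: np.ndarray | None = None,
                          max_delta_ori: float = 22.5) -> np.ndarray:
    """Connected E->E edges that are co-tuned AND co-axially displaced."""
    centers = rf_centers(fits)
    pref = np.array([p.preferred_orientation for p in profiles])
    exc = graph.excitatory
    ok = graph.included & exc
    if selective is not None:
        ok &= np.asarray(selective, bool)
    post, pre = np.nonzero(graph.adjacency & np.outer(ok, ok))
    delta = fold_orientation_difference_deg(pref[post], pref[pre])
    keep = delta < max_delta_ori
    post, pre = post[keep], pre[keep]
    coax = []
    for p_i, q_i in zip(post, pre):
        coord = normalize_visual_space(centers[q_i], centers[p_i], pref[p_i])
        coax.append(sector_labels_orientation(coord)[0] == "coaxial")
    coax = np.array(coax, bool) if len(coax) else np.zeros(0, bool)
    return np.stack([post[coax], pre[coax]], axis=1) if coax.any() \
        else np.empty((0, 2), int)


def bar_dot_deficit(params: NetworkParams, ablated_w_eff: np.ndarray,
                    stimuli: StimulusSet, config: NetworkConfig) -> pd.DataFrame:
    """Percent MSE increase of the ablated vs control network per stimulus.

    deficit = 100 * (MSE_ablated - MSE_control) / MSE_control for next-frame
    prediction on each bar/dot stimulus.  Returns a frame with stimulus
    metadata, the two MSEs and the deficit; use ``deficit_area_correlation``
    for the per-type Pearson r against stimulus area.
    """
    ablated = params.copy()
    ablated.W_rec = np.abs(ablated_w_eff)
    rows = []
    for clip, label in stimuli:
        mse_c = evaluate_mse(params, [clip], config)
        mse_a = evaluate_mse(ablated, [clip], config)
        deficit = 100.0 * (mse_a - mse_c) / mse_c if mse_c > 0 else 0.0
        rows.append({**label, "mse_control": mse_c, "mse_ablated": mse_a,
                     "deficit_pct": deficit})
    return pd.DataFrame(rows)


def deficit_area_correlation(deficits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of ablation deficit vs stimulus area, per stimulus type."""
    rows = []
    for cls, sub in deficits.groupby("stimulus_class"):
        if sub.area.nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sub.area, sub.deficit_pct)
        rows.append({"stimulus_class": cls, "r": float(r), "p": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)


def detect_prediction_error_units(params: NetworkParams, stimuli: StimulusSet,
                                  criteria: str = "strict",
                                  eps: float = 1e-12,
                                  min_positions: int = 5) -> pd.DataFrame:
    """Classify units as pure prediction-error, mixed, or none.

    Responses are the hidden activity at the deviant frame.  strict: a unit
    is pure_PE if, for some orientation pair, it is silent (<= eps) in both
    control sequences at every deviant position yet responds (> eps) at >=
    ``min_positions`` deviant positions of the violating sequence; units
    responding to both standard and violating stimuli are mixed.  loose:
    pure_PE requires the mean deviant response to strictly exceed 3x the
    mean control response (and controls may be nonzero); mixed as above.
    """
    if criteria not in ("strict", "loose"):
        raise ValueError("criteria must be 'strict' or 'loose'")
    n = params.n_hidden
    # organize responses[pair][kind] -> (positions, units)
    by_pair: dict = {}
    for clip, label in stimuli:
        key = (label["orientation_a"], label["orientation_b"])
        S, _ = _forward_batch(params, clip.flatten()[None])
        resp = S[0][label["deviant_position"] - 1]  # activity at deviant frame
        by_pair.setdefault(key, {}).setdefault(label["sequence_kind"], []).append(resp)
    classification = np.full(n, "none", dtype=object)
    for key, kinds in by_pair.items():
        viol = np.stack(kinds["violating"])          # (positions, units)
        ctrl_std = np.stack(kinds["control_standard"])
        ctrl_shift = np.stack(kinds["control_shifted"])
        ctrl = np.concatenate([ctrl_std, ctrl_shift])
        if criteria == "strict":
            silent = (ctrl <= eps).all(axis=0)
            responsive = (viol > eps).sum(axis=0) >= min_positions
            pure = silent & responsive
        else:
            pure = viol.mean(axis=0) > 3.0 * ctrl.mean(axis=0)
            pure &= (viol.mean(axis=0) > eps)
        mixed = ((ctrl_std > eps).any(axis=0)) & ((viol > eps).any(axis=0)) & ~pure
        classification[pure & (classification == "none")] = "pure_PE"
        upgrade = mixed & (classification == "none")
        classification[upgrade] = "mixed"
    return pd.DataFrame({"unit": np.arange(n), "class": classification})
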