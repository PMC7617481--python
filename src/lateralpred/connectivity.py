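"""Functional-connectivity graph and motif statistics.

Hidden units are "connected" when the magnitude of their recurrent weight
strictly exceeds the 95th percentile of |w| over all ordered unit pairs
(self-connections excluded).  On the thresholded graph the module computes
the connectivity profiles of the physiology literature: connection
probability versus orientation/direction-preference difference per
population pair (E->E, E->I, I->E, I->I), Cochran-Armitage trend tests over
ordered bins, visual-space-normalized presynaptic ensembles split into
co-axial/co-orthogonal sectors or opposite/ahead half-planes, connection
probability versus response correlation, weight-shuffle null controls, and a
model "connectivity score" (mean Pearson correlation with reference
profiles).

Conventions: ``W_rec[post, pre]`` (row = postsynaptic); receptive-field
coordinates are pixels with 6 degrees of visual angle per pixel; short-range
pairs have RF centers closer than 2.5 px (15 deg), long-range pairs between
5 and 9.17 px (30-55 deg).  Distance cutoffs scale with ``pixel_scale`` so
the same analysis runs on reduced frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .receptive_fields import GaborFit
from .tuning import TuningProfile

__all__ = [
    "ConnectivityGraph",
    "ConnectivityProfile",
    "threshold_connections",
    "probability_by_tuning_difference",
    "cochran_armitage_trend",
    "normalize_visual_space",
    "coaxial_coorthogonal_analysis",
    "presynaptic_density_sectors",
    "correlation_vs_connectivity",
    "shuffle_control",
    "connectivity_score",
    "synthetic_reference_profiles",
]

DEG_PER_PIXEL = 6.0
SHORT_RANGE_PX = 2.5    # < 15 deg
LONG_RANGE_MIN_PX = 5.0  # > 30 deg
LONG_RANGE_MAX_PX = 9.17  # 55 deg screen limit

ORI_BINS = np.array([0.0, 22.5, 67.5, 90.0])
DIR_BINS = np.array([0.0, 22.5, 67.5, 112.5, 157.5, 180.0])


@dataclass
class ConnectivityGraph:
    """Thresholded directed graph over included units.

    ``adjacency[post, pre]`` marks supra-threshold connections; ``weight``
    is the signed recurrent weight.  Matrices are full n_hidden x n_hidden
    but only rows/columns of ``included`` units carry edges.
    """

    adjacency: np.ndarray
    weight: np.ndarray
    excitatory: np.ndarray  # per-unit bool
    included: np.ndarray    # per-unit bool
    threshold: float
    rf_distance: np.ndarray | None = None  # pairwise, px

    @property
    def n_units(self) -> int:
        return self.adjacency.shape[0]

    def edge_table(self) -> pd.DataFrame:
        post, pre = np.nonzero(self.adjacency)
        rows = {
            "pre": pre, "post": post,
            "weight": self.weight[post, pre],
            "pre_population": np.where(self.excitatory[pre], "E", "I"),
            "post_population": np.where(self.excitatory[post], "E", "I"),
        }
        if self.rf_distance is not None:
            d = self.rf_distance[post, pre]
            rows["rf_distance"] = d
            rows["range_class"] = np.select(
                [d < SHORT_RANGE_PX,
                 (d > LONG_RANGE_MIN_PX) & (d <= LONG_RANGE_MAX_PX)],
                ["short", "long"], default="excluded")
        return pd.DataFrame(rows)


@dataclass
class ConnectivityProfile:
    """Per-bin connection probability over an ordered tuning-difference axis."""

    bin_edges: np.ndarray
    connected_counts: np.ndarray
    candidate_counts: np.ndarray
    label: str = ""

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.connected_counts / self.candidate_counts
        return np.where(self.candidate_counts > 0, p, np.nan)

    def relative_to_mean(self) -> np.ndarray:
        p = self.probability
        m = np.nanmean(p)
        return p / m if m else p


def rf_centers(fits: list[GaborFit]) -> np.ndarray:
    return np.array([[f.center_x, f.center_y] for f in fits])


def rf_distance_matrix(fits: list[GaborFit]) -> np.ndarray:
    c = rf_centers(fits)
    return np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])


def threshold_connections(W_rec: np.ndarray, excitatory: np.ndarray,
                          included: np.ndarray | None = None,
                          percentile: float = 95.0,
                          fits: list[GaborFit] | None = None
                          ) -> ConnectivityGraph:
    """Edges where |w| strictly exceeds the given percentile of |w|.

    The percentile (linear-interpolation convention) is taken over all
    ordered pairs of included units, self-connections and zero-weight pairs
    included in the pool.  ``W_rec`` must already be sign-constrained.
    """
    n = W_rec.shape[0]
    included = np.ones(n, bool) if included is None else np.asarray(included, bool)
    absw = np.abs(W_rec)
    off_diag = ~np.eye(n, dtype=bool)
    pool_mask = off_diag & np.outer(included, included)
    if not pool_mask.any():
        raise ValueError("fewer than 2 included units: no unit pairs to threshold")
    thr = float(np.percentile(absw[pool_mask], percentile))
    adjacency = (absw > thr) & pool_mask
    return ConnectivityGraph(
        adjacency=adjacency, weight=W_rec.copy(),
        excitatory=np.asarray(excitatory, bool), included=included,
        threshold=thr,
        rf_distance=rf_distance_matrix(fits) if fits is not None else None)


def fold_orientation_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|delta orientation| folded to [0, 90] degrees (inputs radians mod pi)."""
    d = np.abs(np.degrees(a) - np.degrees(b)) % 180.0
    return np.minimum(d, 180.0 - d)


def fold_direction_difference_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|delta direction| folded to [0, 180] degrees (inputs radians mod 2 pi)."""
    d = np.abs(np.degrees(a) - np.degrees(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def _population_pair_mask(graph: ConnectivityGraph, pair: str) -> np.ndarray:
    """(post, pre) candidate mask for 'EE', 'EI', 'IE', 'II' (pre->post order)."""
    exc = graph.excitatory
    pre_is_e = pair[0] == "E"
    post_is_e = pair[1] == "E"
    pre_mask = exc if pre_is_e else ~exc
    post_mask = exc if post_is_e else ~exc
    return np.outer(post_mask, pre_mask)


def probability_by_tuning_difference(graph: ConnectivityGraph,
                                     profiles: list[TuningProfile],
                                     feature: str = "orientation",
                                     pair: str = "EE",
                                     selective: np.ndarray | None = None,
                                     bins: np.ndarray | None = None,
                                     range_class: str | None = None
                                     ) -> ConnectivityProfile:
    """Connection probability per tuning-difference bin for a population pair.

    Candidate pairs are ordered (pre != post) pairs of included units that
    are selective for the feature (caller-supplied mask) and match the
    requested population pair; ``range_class`` optionally restricts to
    'short' or 'long' RF distances.  Delta orientation is folded to [0, 90]
    degrees, delta direction to [0, 180].
    """
    n = graph.n_units
    if bins is None:
        bins = ORI_BINS if feature == "orientation" else DIR_BINS
    pref = np.array([p.preferred_orientation if feature == "orientation"
                     else p.preferred_direction for p in profiles])
    fold = fold_orientation_difference_deg if feature == "orientation" \
        else fold_direction_difference_deg
    delta = fold(pref[:, None], pref[None, :])  # (post, pre) symmetric
    ok = np.ones(n, bool) if selective is None else np.asarray(selective, bool)
    ok = ok & graph.included
    cand = np.outer(ok, ok) & ~np.eye(n, dtype=bool)
    cand &= _population_pair_mask(graph, pair)
    if range_class is not None:
        if graph.rf_distance is None:
            raise ValueError("graph has no RF distances")
        d = graph.rf_distance
        if range_class == "short":
            cand &= d < SHORT_RANGE_PX
        elif range_class == "long":
            cand &= (d > LONG_RANGE_MIN_PX) & (d <= LONG_RANGE_MAX_PX)
        else:
            raise ValueError("range_class must be 'short' or 'long'")
    connected = cand & graph.adjacency
    cand_counts = np.empty(len(bins) - 1)
    conn_counts = np.empty(len(bins) - 1)
    for k in range(len(bins) - 1):
        lo, hi = bins[k], bins[k + 1]
        in_bin = (delta >= lo) & (delta < hi) if k < len(bins) - 2 \
            else (delta >= lo) & (delta <= hi)
        cand_counts[k] = (cand & in_bin).sum()
        conn_counts[k] = (connected & in_bin).sum()
    return ConnectivityProfile(np.asarray(bins, float), conn_counts, cand_counts,
                               label=f"{pair}_{feature}"
                                     + (f"_{range_class}" if range_class else ""))


def cochran_armitage_trend(profile: ConnectivityProfile,
                           scores: np.ndarray | None = None
                           ) -> tuple[float, float]:
    """Cochran-Armitage test for a linear trend in proportions across bins.

    Uses integer scores by default.  Returns (z statistic, two-sided p).
    Degenerate margins (all connected, none connected, or a single bin)
    give p = 1.
    """
    r = np.asarray(profile.connected_counts, float)
    n = np.asarray(profile.candidate_counts, float)
    keep = n > 0
    r, n = r[keep], n[keep]
    if len(n) < 2:
        return 0.0, 1.0
    t = np.arange(len(n), dtype=float) if scores is None \
        else np.asarray(scores, float)[keep]
    N = n.sum()
    pbar = r.sum() / N
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    num = (t * (r - n * pbar)).sum()
    var = pbar * (1 - pbar) * ((n * t ** 2).sum() - (n * t).sum() ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def normalize_visual_space(pre_centers: np.ndarray, post_center: np.ndarray,
                           theta: float) -> np.ndarray:
    """Translate then rotate RF centers into the postsynaptic unit's frame.

    Centers are translated so the postsynaptic RF sits at the origin, then
    rotated by R(theta - pi/2) where theta is the postsynaptic preferred
    orientation; afterwards the preferred-orientation axis is vertical.
    Distances are preserved exactly.
    """
    pre = np.atleast_2d(np.asarray(pre_centers, float)) - np.asarray(post_center, float)
    a = theta - np.pi / 2
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pre @ rot.T


def sector_labels_orientation(coords: np.ndarray) -> np.ndarray:
    """'coaxial' (|y|>|x|), 'coorthogonal' (|x|>|y|) or 'boundary'."""
    x, y = coords[:, 0], coords[:, 1]
    return np.select([np.abs(y) > np.abs(x), np.abs(x) > np.abs(y)],
                     ["coaxial", "coorthogonal"], default="boundary")


def central_bounds_mask(fits: list[GaborFit], frame_size: int,
                        central_fraction: float = 16.0 / 36.0) -> np.ndarray:
    """Units whose RF center lies within the central box of the visual field."""
    half = frame_size * central_fraction / 2.0
    c = rf_centers(fits)
    mid = (frame_size - 1) / 2.0
    return (np.abs(c[:, 0] - mid) <= half) & (np.abs(c[:, 1] - mid) <= half)


def coaxial_coorthogonal_analysis(graph: ConnectivityGraph,
                                  fits: list[GaborFit],
                                  profiles: list[TuningProfile],
                                  selective: np.ndarray,
                                  frame_size: int,
                                  bins: np.ndarray = ORI_BINS,
                                  pixel_scale: float = 1.0,
                                  n_permutations: int = 1000,
                                  seed: int = 0) -> dict:
    """Long-range connection probability by sector of normalized visual space.

    For each postsynaptic included, selective unit with an RF center inside
    the central bounds, long-range candidate presynaptic partners
    (RF distance in (5, 9.17] px, scaled) are placed in the postsynaptic
    unit's normalized frame and labelled co-axial (|y| > |x|) or
    co-orthogonal (|x| > |y|); boundary points are excluded.  Returns the
    two orientation-difference profiles and a label-permutation test on the
    difference of (first bin - last bin) probability between sectors.
    """
    if graph.rf_distance is None:
        raise ValueError("graph needs RF distances")
    centers = rf_centers(fits)
    pref_ori = np.array([p.preferred_orientation for p in profiles])
    ok_post = graph.included & selective & central_bounds_mask(fits, frame_size)
    ok_pre = graph.included & selective
    lo = LONG_RANGE_MIN_PX * pixel_scale
    hi = LONG_RANGE_MAX_PX * pixel_scale
    rows = []  # (delta_ori, sector, connected)
    for post in np.nonzero(ok_post)[0]:
        d = graph.rf_distance[post]
        cand = ok_pre & (d > lo) & (d <= hi)
        cand[post] = False
        pres = np.nonzero(cand)[0]
        if len(pres) == 0:
            continue
        coords = normalize_visual_space(centers[pres], centers[post],
                                        pref_ori[post])
        sectors = sector_labels_orientation(coords)
        delta = fold_orientation_difference_deg(pref_ori[pres], pref_ori[post])
        conn = graph.adjacency[post, pres]
        for dd, sec, cc in zip(delta, sectors, conn):
            if sec != "boundary":
                rows.append((dd, sec, bool(cc)))
    if not rows:
        raise ValueError("no long-range candidate pairs")
    table = pd.DataFrame(rows, columns=["delta_ori", "sector", "connected"])

    def profile_for(sub: pd.DataFrame, label: str) -> ConnectivityProfile:
        conn_c, cand_c = [], []
        for k in range(len(bins) - 1):
            lo_b, hi_b = bins[k], bins[k + 1]
            sel = (sub.delta_ori >= lo_b) & (
                (sub.delta_ori < hi_b) if k < len(bins) - 2 else (sub.delta_ori <= hi_b))
            cand_c.append(int(sel.sum()))
            conn_c.append(int(sub.connected[sel].sum()))
        return ConnectivityProfile(bins, np.array(conn_c, float),
                                   np.array(cand_c, float), label=label)

    def statistic(tab: pd.DataFrame) -> float:
        pa = profile_for(tab[tab.sector == "coaxial"], "coaxial").probability
        po = profile_for(tab[tab.sector == "coorthogonal"], "coorthogonal").probability
        with np.errstate(invalid="ignore"):
            return float((pa[0] - pa[-1]) - (po[0] - po[-1]))

    observed = statistic(table)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    labels = table.sector.to_numpy().copy()
    for i in range(n_permutations):
        table_perm = table.copy()
        table_perm["sector"] = rng.permutation(labels)
        null[i] = statistic(table_perm)
    null = null[np.isfinite(null)]
    p_perm = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (len(null) + 1)) \
        if np.isfinite(observed) and len(null) else np.nan
    return {
        "coaxial": profile_for(table[table.sector == "coaxial"], "coaxial"),
        "coorthogonal": profile_for(table[table.sector == "coorthogonal"],
                                    "coorthogonal"),
        "statistic": observed,
        "p_permutation": p_perm,
        "pair_table": table,
    }


def presynaptic_density_sectors(graph: ConnectivityGraph,
                                fits: list[GaborFit],
                                profiles: list[TuningProfile],
                                post_selective: np.ndarray,
                                max_distance_px: float | None = None,
                                ) -> pd.DataFrame:
    """Opposite/ahead presynaptic density per direction-selective unit.

    Presynaptic RF centers are rotated so the postsynaptic preferred
    direction points along +x; 'ahead' is the x > 0 half-plane, 'opposite'
    x < 0 (x = 0 excluded).  Densities are fractions of each unit's
    presynaptic ensemble, split by presynaptic population (E/I).  Returns a
    tidy frame (post unit, pre population, n_pre, density_opposite,
    density_ahead); empty ensembles are skipped.
    """
    centers = rf_centers(fits)
    pref_dir = np.array([p.preferred_direction for p in profiles])
    rows = []
    for post in np.nonzero(graph.included & post_selective)[0]:
        pre_mask = graph.adjacency[post] & graph.included
        if max_distance_px is not None and graph.rf_distance is not None:
            pre_mask &= graph.rf_distance[post] <= max_distance_px
        pres = np.nonzero(pre_mask)[0]
        if len(pres) == 0:
            continue
        # rotate preferred direction onto +x
        a = -pref_dir[post]
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        coords = (centers[pres] - centers[post]) @ rot.T
        for pop, mask in (("E", graph.excitatory[pres]),
                          ("I", ~graph.excitatory[pres])):
            sub = coords[mask]
            sub = sub[sub[:, 0] != 0]
            if len(sub) == 0:
                continue
            ahead = float((sub[:, 0] > 0).mean())
            rows.append({"post": int(post), "pre_population": pop,
                         "n_pre": int(len(sub)),
                         "density_opposite": 1.0 - ahead,
                         "density_ahead": ahead})
    return pd.DataFrame(rows)


def density_sector_tests(density: pd.DataFrame) -> pd.DataFrame:
    """Per-population t test of opposite-vs-ahead density (paired across units)."""
    out = []
    for pop, sub in density.groupby("pre_population"):
        if len(sub) < 2:
            continue
        t, p = stats.ttest_rel(sub.density_opposite, sub.density_ahead)
        out.append({"pre_population": pop, "n_post": len(sub),
                    "mean_opposite": sub.density_opposite.mean(),
                    "mean_ahead": sub.density_ahead.mean(),
                    "t": float(t), "p": float(p)})
    return pd.DataFrame(out)


def correlation_vs_connectivity(corr_matrix: np.ndarray,
                                graph: ConnectivityGraph,
                                bins: np.ndarray | None = None) -> pd.DataFrame:
    """P(connected) and mean |weight| among connected pairs per correlation bin."""
    if bins is None:
        bins = np.linspace(-0.2, 0.6, 9)
    n = graph.n_units
    ok = graph.included
    pair_mask = np.outer(ok, ok) & ~np.eye(n, dtype=bool)
    c = corr_matrix[pair_mask]
    conn = graph.adjacency[pair_mask]
    w = np.abs(graph.weight)[pair_mask]
    finite = np.isfinite(c)
    c, conn, w = c[finite], conn[finite], w[finite]
    rows = []
    for k in range(len(bins) - 1):
        sel = (c >= bins[k]) & ((c < bins[k + 1]) if k < len(bins) - 2
                                else (c <= bins[k + 1]))
        n_cand = int(sel.sum())
        n_conn = int(conn[sel].sum())
        rows.append({
            "bin_low": bins[k], "bin_high": bins[k + 1],
            "n_candidates": n_cand, "n_connected": n_conn,
            "p_connected": n_conn / n_cand if n_cand else np.nan,
            "mean_strength": float(w[sel & conn].mean()) if n_conn else np.nan,
        })
    return pd.DataFrame(rows)


def shuffle_control(W_rec: np.ndarray, unit_subset: np.ndarray,
                    downstream_op, n_shuffles: int = 1000, seed: int = 0,
                    percentiles=(2.5, 97.5)) -> dict:
    """Null distribution of a connectivity statistic under weight shuffling.

    Permutes the recurrent weights among ordered pairs of the subset
    (off-diagonal entries only, multiset of weights preserved exactly) and
    re-runs ``downstream_op(W_shuffled)`` per shuffle.  The op must return an
    array-like; returns its per-element mean and percentile bands over
    shuffles.  Shuffled weights are used only for connectivity measurement,
    never to generate responses.
    """
    rng = np.random.default_rng(seed)
    subset = np.asarray(unit_subset)
    sub_idx = np.ix_(subset, subset)
    results = []
    for _ in range(n_shuffles):
        W = W_rec.copy()
        block = W[sub_idx]
        m = ~np.eye(len(subset), dtype=bool)
        vals = block[m]
        block[m] = rng.permutation(vals)
        W[sub_idx] = block
        results.append(np.asarray(downstream_op(W), float))
    arr = np.stack(results)
    return {
        "mean": np.nanmean(arr, axis=0),
        "bands": {p: np.nanpercentile(arr, p, axis=0) for p in percentiles},
        "samples": arr,
    }


def connectivity_score(model_profiles: list[np.ndarray],
                       reference_profiles: list[np.ndarray]) -> float:
    """Mean Pearson r between matched model and reference profiles."""
    if len(model_profiles) != len(reference_profiles):
        raise ValueError("profile lists must align")
    rs = []
    for m, ref in zip(model_profiles, reference_profiles):
        m = np.asarray(m, float)
        ref = np.asarray(ref, float)
        if m.shape != ref.shape:
            raise ValueError("profile length mismatch")
        keep = np.isfinite(m) & np.isfinite(ref)
        rs.append(float(np.corrcoef(m[keep], ref[keep])[0, 1]))
    return float(np.mean(rs))


def synthetic_reference_profiles() -> dict[str, np.ndarray]:
    """Synthetic stand-ins for published V1 connectivity profiles.

    These are NOT the published values (which were digitized from figures
    and are not printed numerically); they are qualitative monotone profiles
    with the reported like-to-like shape, for exercising the connectivity
    score.  Keys match the profile labels produced by this module.
    """
    return {
        "EE_orientation_short": np.array([0.55, 0.30, 0.15]),
        "EE_direction_short": np.array([0.40, 0.22, 0.12, 0.20, 0.35]),
        "coaxial": np.array([0.28, 0.16, 0.10]),
        "coorthogonal": np.array([0.14, 0.15, 0.13]),
    }


def load_reference_profiles(path) -> dict[str, np.ndarray]:
    """Reference profiles from CSV with columns: label, bin_index, value."""
    df = pd.read_csv(path)
    return {label: sub.sort_values("bin_index").value.to_numpy()
            for label, sub in df.groupby("label")}
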