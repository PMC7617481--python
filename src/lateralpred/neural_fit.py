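"""Linear-nonlinear neural-response prediction with noise-ceiling scoring.

Model hidden activity is reduced to its first 200 principal components
(fitted on the training segments), mapped to each neuron's trial-averaged
rate by Lasso regression, and passed through a rectified sigmoid output
nonlinearity

    r_hat(x) = max(0, a / (1 + exp((c - x)/b)) + d)

fitted by nonlinear least squares.  The Lasso strength alpha is selected
from 40 log-spaced values in [1e-5, 10] by k-fold cross-validation to
maximize the mean validation CC_norm of the combined mapping.

CC_norm is the correlation between prediction and trial-averaged response
divided by the noise ceiling CC_max = sqrt(SP / var(mean response)), with
the signal power SP from the standard across-trial decomposition
(N var(mean) - mean var) / (N - 1).  Neurons whose noise-to-signal power
ratio is 60 or more are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso

from .synthetic_data import signal_noise_power

__all__ = [
    "LNReadout",
    "FitScore",
    "alpha_grid",
    "noise_power_filter",
    "cc_norm",
    "fit_ln",
    "predict_ln",
]

N_COMPONENTS = 200
NOISE_POWER_CUTOFF = 60.0


def alpha_grid(n: int = 40, low: float = 1e-5, high: float = 1e1) -> np.ndarray:
    """The Lasso regularization-strength grid: 40 log-spaced values in [1e-5, 10]."""
    return np.geomspace(low, high, n)


@dataclass
class LNReadout:
    """Fitted PCA + Lasso + rectified-sigmoid readout for one neuron."""

    pca: PCA
    linear_weights: np.ndarray
    intercept: float
    alpha: float
    sigmoid: tuple[float, float, float, float] | None  # (a, b, c, d)
    cv_scheme: str = "5-fold"
    sigmoid_used: bool = True


@dataclass
class FitScore:
    cc_abs: float
    cc_norm: float
    cc_max: float
    n_trials: int
    flagged: bool = False


def noise_power_filter(responses: np.ndarray,
                       cutoff: float = NOISE_POWER_CUTOFF) -> np.ndarray:
    """Keep neurons whose noise-to-signal power ratio is below the cutoff.

    ``responses`` is (neurons, trials, time).  Neurons with non-positive
    signal power (no repeatable signal) are excluded.
    """
    responses = np.asarray(responses, float)
    if responses.shape[1] < 2:
        raise ValueError("noise/signal decomposition needs >= 2 trials")
    sp, npow = signal_noise_power(responses)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sp > 0, npow / sp, np.inf)
    return ratio < cutoff


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cc_norm(prediction: np.ndarray, trial_responses: np.ndarray) -> FitScore:
    """Normalized correlation coefficient against multi-trial responses.

    ``trial_responses`` is (trials, time).  cc_abs is the Pearson r between
    the prediction and the trial mean; cc_max = sqrt(SP / var(mean));
    cc_norm = cc_abs / cc_max.  Flagged (NaN) when the prediction has zero
    variance or the signal-power estimate is non-positive.
    """
    trial_responses = np.asarray(trial_responses, float)
    n_trials = trial_responses.shape[0]
    if n_trials < 2:
        raise ValueError("cc_norm needs >= 2 trials")
    mean_resp = trial_responses.mean(axis=0)
    sp, _ = signal_noise_power(trial_responses[None])
    sp = float(sp[0])
    var_mean = mean_resp.var()
    ccabs = _pearson(np.asarray(prediction, float), mean_resp)
    if not np.isfinite(ccabs) or sp <= 0 or var_mean == 0:
        return FitScore(ccabs, np.nan, np.nan, n_trials, flagged=True)
    ccmax = float(np.sqrt(sp / var_mean))
    return FitScore(ccabs, ccabs / ccmax, ccmax, n_trials)


def _rect_sigmoid(x, a, b, c, d):
    return np.maximum(0.0, a / (1.0 + np.exp(np.clip((c - x) / b, -500, 500))) + d)


def _fit_sigmoid(x: np.ndarray, y: np.ndarray):
    """Least-squares rectified sigmoid; None if the optimizer fails."""
    spread = x.std() or 1.0
    p0 = [y.max() - y.min() or 1.0, spread / 4, np.median(x), y.min()]
    try:
        popt, _ = curve_fit(_rect_sigmoid, x, y, p0=p0, maxfev=4000)
        return tuple(float(v) for v in popt)
    except Exception:
        return None


def _contiguous_clips(n_time: int, n_clips: int = 15) -> list[np.ndarray]:
    """Split the time axis into contiguous clip index blocks."""
    return [np.arange(n_time)[b] for b in
            np.array_split(np.arange(n_time), n_clips)]


def fit_ln(hidden_activity: np.ndarray, trial_responses: np.ndarray,
           n_clips: int = 15, n_test_clips: int = 3, k_folds: int = 5,
           alphas: np.ndarray | None = None, n_components: int = N_COMPONENTS,
           sigmoid_tolerance: float = 0.05, seed: int = 0
           ) -> tuple[LNReadout, FitScore]:
    """Fit the LN readout for one neuron and score it on held-out data.

    ``hidden_activity`` is (time, units); ``trial_responses`` (trials, time).
    The time axis is cut into ``n_clips`` contiguous clips; ``n_test_clips``
    representative clips are held out for the final score and the rest are
    k-folded for alpha selection by mean validation CC_norm of the combined
    linear-nonlinear mapping.  If the sigmoid degrades validation CC_norm by
    more than ``sigmoid_tolerance`` the linear stage alone is used (logged on
    the readout).  Returns (readout, held-out FitScore).
    """
    X = np.asarray(hidden_activity, float)
    R = np.asarray(trial_responses, float)
    if X.shape[0] != R.shape[1]:
        raise ValueError("time bases must align")
    y = R.mean(axis=0)
    if y.std() == 0 or X.std() == 0:
        raise ValueError("degenerate variance in responses or activity")
    alphas = alpha_grid() if alphas is None else np.asarray(alphas)
    clips = _contiguous_clips(X.shape[0], n_clips)
    rng = np.random.default_rng(seed)
    # representative test clips: evenly spaced across the recording
    test_ids = np.linspace(0, n_clips - 1, n_test_clips).round().astype(int)
    train_ids = np.array([i for i in range(n_clips) if i not in test_ids])
    test_idx = np.concatenate([clips[i] for i in test_ids])
    folds = np.array_split(rng.permutation(train_ids), k_folds)

    def fit_eval(alpha, tr_idx, va_idx):
        pca = PCA(n_components=min(n_components, len(tr_idx), X.shape[1]),
                  random_state=0)
        Z_tr = pca.fit_transform(X[tr_idx])
        lasso = Lasso(alpha=alpha, max_iter=5000)
        lasso.fit(Z_tr, y[tr_idx])
        lin_tr = lasso.predict(Z_tr)
        sig = _fit_sigmoid(lin_tr, y[tr_idx])
        lin_va = lasso.predict(pca.transform(X[va_idx]))
        pred_va = _rect_sigmoid(lin_va, *sig) if sig is not None else lin_va
        score = cc_norm(pred_va, R[:, va_idx])
        lin_score = cc_norm(lin_va, R[:, va_idx])
        return score.cc_norm, lin_score.cc_norm

    mean_scores = np.full(len(alphas), -np.inf)
    mean_lin_scores = np.full(len(alphas), -np.inf)
    for ai, alpha in enumerate(alphas):
        ln_scores, lin_scores = [], []
        for k in range(k_folds):
            va_ids = folds[k]
            tr_ids = np.concatenate([folds[j] for j in range(k_folds) if j != k])
            tr_idx = np.concatenate([clips[i] for i in tr_ids])
            va_idx = np.concatenate([clips[i] for i in va_ids])
            s_ln, s_lin = fit_eval(alpha, tr_idx, va_idx)
            if np.isfinite(s_ln):
                ln_scores.append(s_ln)
            if np.isfinite(s_lin):
                lin_scores.append(s_lin)
        if ln_scores:
            mean_scores[ai] = np.mean(ln_scores)
        if lin_scores:
            mean_lin_scores[ai] = np.mean(lin_scores)
    best = int(np.argmax(mean_scores))
    alpha = float(alphas[best])
    use_sigmoid = mean_scores[best] >= mean_lin_scores[best] - sigmoid_tolerance

    # final fit on all training clips, score on held-out test clips
    tr_idx = np.concatenate([clips[i] for i in train_ids])
    pca = PCA(n_components=min(n_components, len(tr_idx), X.shape[1]),
              random_state=0)
    Z_tr = pca.fit_transform(X[tr_idx])
    lasso = Lasso(alpha=alpha, max_iter=5000)
    lasso.fit(Z_tr, y[tr_idx])
    sig = _fit_sigmoid(lasso.predict(Z_tr), y[tr_idx]) if use_sigmoid else None
    readout = LNReadout(pca=pca, linear_weights=lasso.coef_.copy(),
                        intercept=float(lasso.intercept_), alpha=alpha,
                        sigmoid=sig, cv_scheme=f"{k_folds}-fold",
                        sigmoid_used=sig is not None)
    pred_test = predict_ln(readout, X[test_idx])
    score = cc_norm(pred_test, R[:, test_idx])
    return readout, score


def predict_ln(readout: LNReadout, hidden_activity: np.ndarray) -> np.ndarray:
    lin = readout.pca.transform(np.asarray(hidden_activity, float)) \
        @ readout.linear_weights + readout.intercept
    if readout.sigmoid is not None:
        return _rect_sigmoid(lin, *readout.sigmoid)
    return lin
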