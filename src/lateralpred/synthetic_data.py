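"""Stimulus and surrogate-data generators.

Everything the analysis pipeline consumes can be produced here: naturalistic
movie surrogates (advected bandpass sparse-edge textures), drifting
sinusoidal gratings, moving bar / random-dot stimulus pairs with exactly
matched lit area, oddball / omission sequences with their two control sets,
masked and noise-corrupted variants, and repeated-trial reference "neurons"
with a known signal/noise decomposition.

All generators are pure functions of their parameters and an integer seed:
the same call yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MovieClip",
    "MovieGenParams",
    "StimulusSet",
    "ReferenceNeuronSet",
    "generate_movie_corpus",
    "add_gaussian_noise_snr",
    "make_grating",
    "make_bar_dot_stimuli",
    "make_oddball_sequences",
    "mask_patches",
    "simulate_reference_neurons",
]


@dataclass
class MovieClip:
    """A grayscale spatiotemporal stimulus.

    frames has shape (T, H, W) and is zero-mean over the whole clip for
    generated naturalistic surrogates; ``role`` marks whether the clip is a
    network input or a prediction target.
    """

    frames: np.ndarray
    frame_rate: float = 25.0
    role: str = "input"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frames.shape[0] < 2:
            raise ValueError("a clip needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def flatten(self) -> np.ndarray:
        """Frames as (T, H*W) vectors, the network's native input layout."""
        t = self.frames.shape[0]
        return self.frames.reshape(t, -1)

    def copy(self) -> "MovieClip":
        return MovieClip(self.frames.copy(), self.frame_rate, self.role)


@dataclass
class MovieGenParams:
    """Parameters of the naturalistic-surrogate generator.

    The surrogate emulates the statistics the model cares about: spatially
    bandpass-filtered grayscale structure that translates coherently from
    frame to frame.  ``bandpass_band`` is (low, high) in cycles/pixel;
    ``drift_speed_range`` is (min, max) pixels/frame; ``texture_scale`` sets
    the knee of the 1/f-like amplitude fall-off inside the band.
    """

    n_clips: int = 200
    clip_length: int = 50
    patch_size: int = 16
    bandpass_band: tuple[float, float] = (0.05, 0.35)
    drift_speed_range: tuple[float, float] = (0.5, 2.0)
    texture_scale: float = 8.0
    frame_jitter: float = 0.02
    validation_fraction: float = 0.1
    frame_rate: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.clip_length < 2:
            raise ValueError("clip_length must be >= 2")
        lo, hi = self.bandpass_band
        if not (0 <= lo < hi):
            raise ValueError("bandpass_band must satisfy 0 <= low < high")
        if self.n_clips <= 0 or self.patch_size <= 0 or self.texture_scale <= 0:
            raise ValueError("counts and scales must be positive")
        if min(self.drift_speed_range) < 0:
            raise ValueError("drift speeds must be non-negative")


@dataclass
class StimulusSet:
    """A list of clips with aligned per-clip metadata labels."""

    clips: list[MovieClip]
    labels: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels and len(self.labels) != len(self.clips):
            raise ValueError("labels must align one-to-one with clips")

    def __len__(self) -> int:
        return len(self.clips)

    def __iter__(self):
        return iter(zip(self.clips, self.labels))


@dataclass
class ReferenceNeuronSet:
    """Synthetic repeated-trial responses with known ground truth.

    rates: (neurons, trials, time) non-negative firing rates.
    ground_truth_filters: the linear readouts generating the signal.
    noise_to_signal_power: per-neuron empirical ratio from the standard
    across-trial signal/noise power decomposition.
    """

    rates: np.ndarray
    ground_truth_filters: np.ndarray
    noise_to_signal_power: np.ndarray


def _bandpass_mask(n: int, band: tuple[float, float]) -> np.ndarray:
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fy, fx)
    lo, hi = band
    return (r >= lo) & (r < hi)


def _texture_spectrum(rng: np.random.Generator, n: int,
                      band: tuple[float, float], knee: float,
                      n_elements: int = 8) -> np.ndarray:
    """Fourier coefficients of a bandpass sparse-edge texture.

    The texture is a sparse superposition of randomly placed, randomly
    oriented line elements (edge-like, kurtotic statistics, as in natural
    scenes), projected onto the bandpass annulus with a 1/f-like amplitude
    weighting.  A Gaussian field with the same spectrum would carry no
    higher-order structure; the sparse elements keep the surrogate's
    statistics closer to the natural movies it stands in for.
    """
    mask = _bandpass_mask(n, band)
    if not mask.any():
        raise ValueError(
            f"patch_size={n} supports no Fourier mode inside bandpass band {band}"
        )
    elem_len = max(3, int(round(knee)))
    field = np.zeros((n, n))
    for _ in range(n_elements):
        cy, cx = rng.uniform(0, n, 2)
        theta = rng.uniform(0, np.pi)
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        for s in np.linspace(-elem_len / 2, elem_len / 2, 2 * elem_len):
            y = int(round(cy + s * np.sin(theta))) % n
            x = int(round(cx + s * np.cos(theta))) % n
            field[y, x] += amp
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fy, fx)
    weight = np.where(mask, 1.0 / (1.0 + r * knee), 0.0)
    return np.fft.fft2(field) * weight


def _advect_clip(coef: np.ndarray, n: int, t_frames: int,
                 velocity: tuple[float, float]) -> np.ndarray:
    """Translate a periodic texture by per-frame subpixel Fourier phase shifts."""
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    vy, vx = velocity
    frames = np.empty((t_frames, n, n))
    for t in range(t_frames):
        phase = np.exp(-2j * np.pi * (fy * vy * t + fx * vx * t))
        frames[t] = np.fft.ifft2(coef * phase).real
    return frames


def _make_clip(rng: np.random.Generator, p: MovieGenParams) -> MovieClip:
    coef = _texture_spectrum(rng, p.patch_size, p.bandpass_band, p.texture_scale)
    speed = rng.uniform(*p.drift_speed_range)
    angle = rng.uniform(0, 2 * np.pi)
    vel = (speed * np.sin(angle), speed * np.cos(angle))
    frames = _advect_clip(coef, p.patch_size, p.clip_length, vel)
    frames /= max(frames.std(), 1e-12)
    if p.frame_jitter > 0:
        frames = frames + p.frame_jitter * rng.standard_normal(frames.shape)
    frames -= frames.mean()
    return MovieClip(frames, frame_rate=p.frame_rate)


def generate_movie_corpus(params: MovieGenParams) -> tuple[list[MovieClip], list[MovieClip]]:
    """Generate a (training, validation) corpus of drifting-texture clips.

    Each clip is an independently seeded bandpass Gaussian texture advected at
    a velocity drawn from ``drift_speed_range``, unit variance, zero mean.
    The split is disjoint by construction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    clips = [_make_clip(rng, params) for _ in range(params.n_clips)]
    n_val = int(round(params.n_clips * params.validation_fraction))
    n_val = min(max(n_val, 1 if params.n_clips > 1 else 0), params.n_clips - 1)
    return clips[: params.n_clips - n_val], clips[params.n_clips - n_val:]


def add_gaussian_noise_snr(clip: MovieClip, snr_db: float, seed: int = 0) -> MovieClip:
    """Add white Gaussian noise at a given signal-to-noise ratio in dB.

    SNR is defined as 10*log10(var(signal)/var(noise)) over the whole clip.
    ``snr_db=np.inf`` is the no-noise sentinel and returns an untouched copy.
    """
    if np.isposinf(snr_db):
        return clip.copy()
    sig_power = clip.frames.var()
    if sig_power == 0:
        raise ValueError("SNR undefined for an all-zero clip")
    noise_power = sig_power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = np.sqrt(noise_power) * rng.standard_normal(clip.frames.shape)
    return MovieClip(clip.frames + noise, clip.frame_rate, clip.role)


def make_grating(direction: float, sf: float, tf: float, phase: float = 0.0,
                 size: int = 16, n_frames: int = 50,
                 frame_rate: float = 25.0) -> MovieClip:
    """Full-field drifting sinusoidal grating with amplitude +/-1.

    ``direction`` (radians) is the direction of motion; the wave vector points
    along it, so the bars (the grating's orientation axis) lie at
    ``direction + pi/2``.  ``sf`` is cycles/pixel, ``tf`` cycles/frame; the
    phase advances ``tf`` cycles per frame along ``direction``.
    """
    if not (0 < sf <= 0.5):
        raise ValueError("spatial frequency beyond Nyquist (0, 0.5] cycles/pixel")
    if not (0 <= tf <= 0.5):
        raise ValueError("temporal frequency beyond Nyquist [0, 0.5] cycles/frame")
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    proj = x * np.cos(direction) + y * np.sin(direction)
    t = np.arange(n_frames)[:, None, None]
    frames = np.sin(2 * np.pi * (sf * proj[None] - tf * t) + phase)
    return MovieClip(frames, frame_rate=frame_rate)


def grating_orientation(direction: float) -> float:
    """Orientation (bar axis, radians mod pi) of a grating drifting along ``direction``."""
    return (direction + np.pi / 2) % np.pi


def _place_dots(rng: np.random.Generator, size: int, n_dots: int,
                dot: int) -> list[tuple[int, int]]:
    """Non-overlapping dot positions on a coarse grid (toroidal frame)."""
    n_cells = size // dot
    if n_dots > n_cells * n_cells:
        raise ValueError("requested dot area exceeds the frame")
    cells = rng.choice(n_cells * n_cells, size=n_dots, replace=False)
    return [((c // n_cells) * dot, (c % n_cells) * dot) for c in cells]


def make_bar_dot_stimuli(bar_lengths: Sequence[int], direction: float,
                         speed: float, size: int = 16, n_frames: int = 50,
                         bar_width: int = 2, seed: int = 0) -> StimulusSet:
    """Area-matched moving bar and random-dot stimulus pairs.

    For every bar (length L, width w) a dot stimulus of exactly L*w lit
    pixels is produced (L/w dots of w x w pixels, non-overlapping).  Both
    translate along ``direction`` with the same integer-rounded pixel shifts
    on a toroidal frame, so lit area is conserved on every frame.
    """
    rng = np.random.default_rng(seed)
    clips: list[MovieClip] = []
    labels: list[dict] = []
    dy = np.sin(direction)
    dx = np.cos(direction)
    for length in bar_lengths:
        if length % bar_width != 0:
            raise ValueError("bar length must be a multiple of bar width")
        if length > size or length * bar_width > size * size:
            raise ValueError("bar does not fit the frame")
        # bar: oriented perpendicular to motion, centered
        base_bar = np.zeros((size, size))
        r0 = (size - length) // 2
        c0 = (size - bar_width) // 2
        base_bar[r0:r0 + length, c0:c0 + bar_width] = 1.0
        # rotate the template so the bar axis is perpendicular to `direction`
        rot_deg = -np.degrees(direction)
        if rot_deg % 360 != 0:
            base_bar = ndimage.rotate(base_bar, rot_deg, reshape=False, order=0)
        n_dots = length // bar_width
        base_dots = np.zeros((size, size))
        for (ry, rx) in _place_dots(rng, size, n_dots, bar_width):
            base_dots[ry:ry + bar_width, rx:rx + bar_width] = 1.0
        for name, base in (("bar", base_bar), ("dots", base_dots)):
            frames = np.empty((n_frames, size, size))
            for t in range(n_frames):
                sy = int(round(dy * speed * t))
                sx = int(round(dx * speed * t))
                frames[t] = np.roll(base, (sy, sx), axis=(0, 1))
            clips.append(MovieClip(frames))
            labels.append({
                "stimulus_class": name,
                "direction": direction,
                "bar_length": int(length),
                "area": int(base.sum()),
            })
    return StimulusSet(clips, labels)


def make_oddball_sequences(orientation_pairs: Sequence[tuple[float, float]],
                           paradigm: str = "oddball",
                           deviant_positions: Sequence[int] = tuple(range(5, 26)),
                           n_frames: int = 25, size: int = 16,
                           sf: float = 0.125) -> StimulusSet:
    """Oddball / omission sequences plus their two matched controls.

    A and B full-field static gratings alternate one frame per element for
    ``n_frames`` frames.  For each deviant position p (1-indexed) three
    sequences are emitted: ``violating`` (the expected element at p replaced
    by the deviant), ``control_standard`` (the uninterrupted ABAB... pattern)
    and ``control_shifted`` (the BABA... pattern, which shows the same frame
    at p as the violating sequence without breaking its own pattern).  In the
    omission paradigm the deviant frame is blank.
    """
    if paradigm not in ("oddball", "omission"):
        raise ValueError("paradigm must be 'oddball' or 'omission'")
    clips: list[MovieClip] = []
    labels: list[dict] = []
    for ori_a, ori_b in orientation_pairs:
        frame_a = make_grating(ori_a + np.pi / 2, sf, 0.0, size=size, n_frames=2).frames[0]
        frame_b = make_grating(ori_b + np.pi / 2, sf, 0.0, size=size, n_frames=2).frames[0]
        blank = np.zeros_like(frame_a)
        if paradigm == "omission":
            frame_b = blank
        standard = np.stack([frame_a if t % 2 == 0 else frame_b
                             for t in range(n_frames)])
        shifted = np.stack([frame_b if t % 2 == 0 else frame_a
                            for t in range(n_frames)])
        for pos in deviant_positions:
            if not (1 <= pos <= n_frames):
                raise ValueError(f"deviant position {pos} outside sequence")
            expected_a = (pos - 1) % 2 == 0
            if paradigm == "omission":
                deviant_frame = blank if expected_a else frame_a
            else:
                deviant_frame = frame_b if expected_a else frame_a
            violating = standard.copy()
            violating[pos - 1] = deviant_frame
            for kind, frames in (("violating", violating),
                                 ("control_standard", standard.copy()),
                                 ("control_shifted", shifted.copy())):
                clips.append(MovieClip(frames))
                labels.append({
                    "stimulus_class": paradigm,
                    "sequence_kind": kind,
                    "orientation_a": ori_a,
                    "orientation_b": ori_b,
                    "deviant_position": int(pos),
                })
    return StimulusSet(clips, labels)


def mask_patches(clip: MovieClip, n_patches: int = 8, patch: int = 8,
                 seed: int = 0, mask_value: float = 0.0) -> MovieClip:
    """Blank ``n_patches`` randomly placed square patches on every frame.

    The mask value defaults to 0, the data mean.  Patches may overlap; the
    input clip is left untouched.
    """
    t_frames, h, w = clip.frames.shape
    if patch > min(h, w):
        raise ValueError("patch larger than frame")
    frames = clip.frames.copy()
    if n_patches == 0:
        return MovieClip(frames, clip.frame_rate, clip.role)
    rng = np.random.default_rng(seed)
    for t in range(t_frames):
        ys = rng.integers(0, h - patch + 1, size=n_patches)
        xs = rng.integers(0, w - patch + 1, size=n_patches)
        for y0, x0 in zip(ys, xs):
            frames[t, y0:y0 + patch, x0:x0 + patch] = mask_value
    return MovieClip(frames, clip.frame_rate, clip.role)


def signal_noise_power(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial signal/noise power decomposition.

    ``rates`` is (neurons, trials, time).  Signal power is the standard
    unbiased estimate (N*var(trial mean) - mean per-trial var)/(N-1); noise
    power is the mean per-trial variance minus the signal power.
    """
    n_trials = rates.shape[1]
    if n_trials < 2:
        raise ValueError("signal/noise decomposition needs >= 2 trials")
    mean_resp = rates.mean(axis=1)
    var_mean = mean_resp.var(axis=-1)
    mean_var = rates.var(axis=-1).mean(axis=1)
    signal_power = (n_trials * var_mean - mean_var) / (n_trials - 1)
    noise_power = mean_var - signal_power
    return signal_power, noise_power


def simulate_reference_neurons(hidden_activity: np.ndarray, n_neurons: int = 20,
                               noise_level: float = 0.1, n_trials: int = 5,
                               seed: int = 0) -> ReferenceNeuronSet:
    """Synthetic repeated-trial neurons driven by model hidden activity.

    Each neuron's clean rate is a rectified sigmoid of a random linear readout
    of the hidden activity; each trial adds independent Gaussian noise (std =
    ``noise_level`` times the clean-rate std) before rectification at zero.
    """
    if n_trials < 2:
        raise ValueError("need >= 2 trials (noise ceiling undefined otherwise)")
    x = np.asarray(hidden_activity, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("hidden activity must be finite")
    t_steps, n_hidden = x.shape
    rng = np.random.default_rng(seed)
    filters = rng.standard_normal((n_neurons, n_hidden)) / np.sqrt(n_hidden)
    drive = x @ filters.T  # (T, neurons)
    drive = (drive - drive.mean(axis=0)) / np.maximum(drive.std(axis=0), 1e-12)
    clean = np.maximum(0.0, 1.0 / (1.0 + np.exp(-2.0 * drive)) - 0.2).T  # (neurons, T)
    scale = np.maximum(clean.std(axis=-1, keepdims=True), 1e-12)
    trials = clean[:, None, :] + noise_level * scale[:, None, :] * \
        rng.standard_normal((n_neurons, n_trials, t_steps))
    trials = np.maximum(trials, 0.0)
    if noise_level == 0:
        ratio = np.zeros(n_neurons)
    else:
        sp, npow = signal_noise_power(trials)
        ratio = np.where(sp > 0, npow / np.maximum(sp, 1e-300), np.inf)
    return ReferenceNeuronSet(trials, filters, ratio)
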