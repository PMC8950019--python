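"""Synthetic two-class motor-imagery EEG.

The generator emulates the statistical structure that sensorimotor-rhythm
classifiers exploit: a small number of cortical sources, each a band-limited
stochastic oscillation in the mu (8-12 Hz) or beta (13-22 Hz) band, whose
*variance* depends on the imagined movement class (event-related
desynchronization / synchronization).  Sources are mixed into the EEG
channels by a subject-specific mixing matrix and buried in broadband sensor
noise.  Between-subject differences — the domain shift that alignment must
undo — are modelled as a random rotation plus per-channel gain perturbation
of the mixing matrix.

Sources are band-pass-filtered Gaussian noise rather than sinusoids: real
mu/beta rhythms are stochastic, and pure tones would make trial covariances
degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal

from .trials import CLASS1, CLASS2, Trial, TrialSet

__all__ = [
    "MU_BAND",
    "BETA_BAND",
    "SubjectModel",
    "ShiftSpec",
    "default_subject_model",
    "simulate_subject",
    "apply_shift",
    "make_transfer_benchmark",
    "strong_shift_benchmark",
    "separable_fixture",
    "STRONG_SHIFT",
]

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 22.0)


@dataclass
class SubjectModel:
    """Generative model of one subject's epoched EEG.

    Parameters
    ----------
    mixing : ndarray (n_channels, n_sources)
        Source-to-channel gains; must have full column rank.
    bands : list of (low, high)
        Pass band of each source in Hz.
    class_power : ndarray (n_sources, 2)
        Per-source signal variance (uV^2) under class1 (column 0) and
        class2 (column 1).  At least one source must differ between
        columns, otherwise the classes are indistinguishable.
    noise_sd : float
        Standard deviation (uV) of white sensor noise added per channel.
    fs : float
        Sampling rate in Hz.
    """

    mixing: np.ndarray
    bands: list
    class_power: np.ndarray
    noise_sd: float = 1.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        self.class_power = np.asarray(self.class_power, dtype=np.float64)
        m, s = self.mixing.shape
        if np.linalg.matrix_rank(self.mixing) < s:
            raise ValueError("mixing matrix must have full column rank")
        if len(self.bands) != s or self.class_power.shape != (s, 2):
            raise ValueError("bands and class_power must match n_sources")
        if (self.class_power < 0).any():
            raise ValueError("source variances must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in self.bands:
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"band ({lo}, {hi}) invalid for fs={self.fs}")

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_sources(self) -> int:
        return self.mixing.shape[1]


@dataclass
class ShiftSpec:
    """Domain-shift specification: how a subject's mixing deviates.

    ``rotation_strength`` is the magnitude (radians) of a random rotation
    applied in channel space; ``gain_spread`` >= 1 is the multiplicative
    dispersion of per-channel gains (each channel's gain is drawn uniformly
    on [1/gain_spread, gain_spread] in log scale).
    """

    rotation_strength: float = 0.0
    gain_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_strength < 0:
            raise ValueError("rotation_strength must be >= 0")
        if self.gain_spread < 1:
            raise ValueError("gain_spread must be >= 1")


def default_subject_model(
    n_channels: int = 15, fs: float = 100.0, seed: int = 12345
) -> SubjectModel:
    """The standard test-bed subject: 15 channels, 3 sources at 100 Hz.

    One mu-band source shows desynchronization for class1 (variance drops
    from 4 to 1 uV^2), one beta-band source shows the opposite contrast, and
    one mu-band distractor is class-independent.  Broadband noise sd 1 uV.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_channels, 3))
    # orthonormalize columns: well-conditioned, unit-gain mixing
    mixing, _ = np.linalg.qr(a)
    return SubjectModel(
        mixing=mixing,
        bands=[MU_BAND, BETA_BAND, MU_BAND],
        class_power=np.array([[1.0, 4.0], [4.0, 1.0], [2.0, 2.0]]),
        noise_sd=1.0,
        fs=fs,
    )


def _band_limited_noise(rng, band, n_samples, fs):
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    lo, hi = band
    x = rng.standard_normal(n_samples)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    if sd > 0:
        y = y / sd
    return y


def simulate_subject(
    model: SubjectModel,
    n_trials_per_class: int,
    trial_len_s: float,
    seed: int,
    subject: str = "S01",
) -> TrialSet:
    """Generate labeled trials for one subject.

    Produces ``2 * n_trials_per_class`` trials (classes interleaved) of
    ``trial_len_s`` seconds.  Each source signal is band-pass-filtered white
    noise scaled to its class-conditional variance, mixed into channels, plus
    white sensor noise.  Fully reproducible from ``seed``.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    n_samples = int(round(trial_len_s * model.fs))
    if n_samples < model.n_channels:
        raise ValueError("trial too short for the channel count")
    if np.allclose(model.class_power[:, 0], model.class_power[:, 1]):
        warnings.warn(
            "all source variances are class-independent; classes will be "
            "statistically indistinguishable"
        )
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials_per_class):
        for cls_idx, label in enumerate((CLASS1, CLASS2)):
            sources = np.empty((model.n_sources, n_samples))
            for s in range(model.n_sources):
                amp = np.sqrt(model.class_power[s, cls_idx])
                sources[s] = amp * _band_limited_noise(
                    rng, model.bands[s], n_samples, model.fs
                )
            x = model.mixing @ sources
            if model.noise_sd > 0:
                x = x + model.noise_sd * rng.standard_normal(x.shape)
            trials.append(Trial(data=x, label=label, subject=subject, fs=model.fs))
    return TrialSet(trials=trials)


def apply_shift(model: SubjectModel, spec: ShiftSpec) -> SubjectModel:
    """Return a copy of ``model`` with a shifted mixing matrix.

    The new mixing is ``diag(g) @ R @ mixing`` where R = expm(theta * K) for
    a random unit-norm skew-symmetric K (theta = rotation_strength) and g are
    per-channel gains with dispersion ``gain_spread``.  Band powers and noise
    are unchanged; deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = model.n_channels
    a = rng.standard_normal((m, m))
    k = a - a.T
    norm = np.linalg.norm(k, 2)
    if norm > 0 and spec.rotation_strength > 0:
        rot = linalg.expm((spec.rotation_strength / norm) * k)
    else:
        rot = np.eye(m)
    if spec.gain_spread > 1:
        log_g = rng.uniform(-1.0, 1.0, size=m) * np.log(spec.gain_spread)
        gains = np.exp(log_g)
    else:
        gains = np.ones(m)
    new_mixing = (gains[:, None] * rot) @ model.mixing
    return replace(model, mixing=new_mixing)


def make_transfer_benchmark(
    n_source_subjects: int,
    n_target_subjects: int,
    shift: ShiftSpec,
    base: SubjectModel,
    n_trials_per_class: int,
    trial_len_s: float = 4.0,
    seed: int = 0,
):
    """Build a multi-subject source/target benchmark with controlled shift.

    Every subject receives an independently shifted copy of ``base`` (shift
    seeds derived from ``shift.seed``) and an independent trial realization
    (seeds derived from ``seed``).  Target labels are included — they are for
    evaluation only; the transfer pipeline never trains on them.

    Returns
    -------
    (TrialSet, TrialSet)
        Source and target sets with roles assigned.
    """
    if n_source_subjects < 1 or n_target_subjects < 1:
        raise ValueError("subject counts must be >= 1")
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(n_source_subjects + n_target_subjects)]
    shift_ss = np.random.SeedSequence(shift.seed)
    shift_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   shift_ss.spawn(n_source_subjects + n_target_subjects)]

    def _make(idx: int, sid: str) -> TrialSet:
        spec_i = replace(shift, seed=shift_seeds[idx])
        model_i = apply_shift(base, spec_i)
        return simulate_subject(
            model_i, n_trials_per_class, trial_len_s, trial_seeds[idx], subject=sid
        )

    src_trials, tgt_trials = [], []
    for i in range(n_source_subjects):
        src_trials.extend(_make(i, f"S{i + 1:02d}").trials)
    for j in range(n_target_subjects):
        idx = n_source_subjects + j
        tgt_trials.extend(_make(idx, f"S{idx + 1:02d}").trials)
    source = TrialSet(trials=src_trials, role="source")
    target = TrialSet(trials=tgt_trials, role="target")
    return source, target


# Canonical "strong shift" for the transfer benchmark: a 1.2 rad random
# channel-space rotation plus 3x per-channel gain dispersion.  Large enough
# that a source-trained pipeline degrades clearly without alignment, yet
# within what whitening the mean covariance can compensate; much beyond this
# the class-discriminative subspace itself is scrambled and no second-order
# method can recover it.
STRONG_SHIFT = ShiftSpec(rotation_strength=1.2, gain_spread=3.0, seed=0)


def strong_shift_benchmark(
    seed: int,
    n_source_subjects: int = 10,
    n_target_subjects: int = 4,
    n_trials_per_class: int = 50,
    trial_len_s: float = 4.0,
):
    """The standard strong-shift transfer benchmark.

    10 source + 4 target subjects, 50 trials per class each, 4 s trials of
    the 15-channel default subject model, with independently drawn
    STRONG_SHIFT mixing perturbations per subject.  Both the shift draws and
    the trial noise derive from ``seed``.
    """
    base = default_subject_model()
    shift = replace(STRONG_SHIFT, seed=seed + 100)
    return make_transfer_benchmark(
        n_source_subjects, n_target_subjects, shift, base,
        n_trials_per_class, trial_len_s=trial_len_s, seed=seed,
    )


def separable_fixture(seed: int, n_trials_per_class: int = 50):
    """A small, strongly separable two-subject-source / one-subject-target
    benchmark for sanity checks: 9:1 class variance contrast on both
    discriminative sources, halved sensor noise, mild shift.
    """
    base = default_subject_model()
    sep = replace(
        base,
        class_power=np.array([[1.0, 9.0], [9.0, 1.0], [2.0, 2.0]]),
        noise_sd=0.5,
    )
    shift = ShiftSpec(rotation_strength=0.3, gain_spread=1.2, seed=seed + 100)
    return make_transfer_benchmark(2, 1, shift, sep, n_trials_per_class,
                                   seed=seed)
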