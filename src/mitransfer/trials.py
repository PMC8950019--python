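"""Trial data model for epoched multichannel EEG.

A :class:`Trial` is one epoched recording — a channels x samples matrix in
microvolts together with its class label, subject id and sampling rate.  A
:class:`TrialSet` is an ordered collection of trials sharing channel geometry
and sampling rate; it is the unit on which alignment, spatial filtering and
classification operate, and plays the role of a *domain* (source or target)
in transfer learning.

Sample indices are 0-based and epoch windows are half-open ``[start,
start + n_samples)`` so that adjacent windows concatenate without overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLASS1",
    "CLASS2",
    "UNLABELED",
    "LABEL_CODES",
    "Trial",
    "TrialSet",
    "extract_epoch",
    "split_domains",
]

# Fixed label dialect: class tags and their integer file encoding.
CLASS1 = "class1"
CLASS2 = "class2"
UNLABELED = "unlabeled"
LABEL_CODES = {CLASS1: 0, CLASS2: 1, UNLABELED: -1}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class Trial:
    """One epoched EEG trial.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        Signal in microvolts.  Requires ``n_channels >= 2`` and
        ``n_samples >= n_channels`` so that covariance-based operations are
        well posed, and no non-finite values.
    label : str
        One of ``"class1"``, ``"class2"``, ``"unlabeled"``.
    subject : str
        Subject identifier.
    fs : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    label: str = UNLABELED
    subject: str = "unknown"
    fs: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"trial data must be 2D, got shape {self.data.shape}")
        m, n = self.data.shape
        if m < 2:
            raise ValueError(f"need at least 2 channels, got {m}")
        if n < m:
            raise ValueError(
                f"need at least as many samples ({n}) as channels ({m})"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains non-finite values")
        if self.label not in LABEL_CODES:
            raise ValueError(
                f"unknown label {self.label!r}; allowed: {sorted(LABEL_CODES)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Trial":
        return replace(self, data=self.data.copy())


@dataclass
class TrialSet:
    """Ordered collection of trials forming a domain.

    All trials must share channel count, channel names and sampling rate.
    ``role`` tags the set as source or target domain (or unassigned).
    """

    trials: list = field(default_factory=list)
    channel_names: list = field(default_factory=list)
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if self.role not in ("source", "target", "unassigned"):
            raise ValueError(f"invalid role {self.role!r}")
        if not self.trials:
            return
        m = self.trials[0].n_channels
        fs = self.trials[0].fs
        for i, t in enumerate(self.trials):
            if t.n_channels != m:
                raise ValueError(
                    f"trial {i} has {t.n_channels} channels, expected {m}"
                )
            if t.fs != fs:
                raise ValueError(f"trial {i} has fs={t.fs}, expected {fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(m)]
        if len(self.channel_names) != m:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {m} channels"
            )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return replace(self, trials=self.trials[idx])
        return self.trials[idx]

    @property
    def n_channels(self) -> int:
        if not self.trials:
            raise ValueError("empty TrialSet has no channel count")
        return self.trials[0].n_channels

    @property
    def fs(self) -> float:
        if not self.trials:
            raise ValueError("empty TrialSet has no sampling rate")
        return self.trials[0].fs

    @property
    def labels(self) -> np.ndarray:
        """Integer label codes (0, 1, or -1) in trial order."""
        return np.array([LABEL_CODES[t.label] for t in self.trials])

    @property
    def subjects(self) -> list:
        return [t.subject for t in self.trials]

    def subject_ids(self) -> list:
        """Distinct subject ids in order of first appearance."""
        seen: dict = {}
        for t in self.trials:
            seen.setdefault(t.subject, None)
        return list(seen)

    def as_array(self) -> np.ndarray:
        """Stack trials to an (n_trials, n_channels, n_samples) array.

        Requires all trials to share the same sample count.
        """
        lens = {t.n_samples for t in self.trials}
        if len(lens) != 1:
            raise ValueError(f"trials have differing sample counts: {sorted(lens)}")
        return np.stack([t.data for t in self.trials])

    def subset(self, indices) -> "TrialSet":
        return replace(self, trials=[self.trials[i] for i in indices])

    def for_subject(self, subject: str) -> "TrialSet":
        return replace(
            self, trials=[t for t in self.trials if t.subject == subject]
        )

    def with_role(self, role: str) -> "TrialSet":
        return replace(self, role=role)

    def copy(self) -> "TrialSet":
        return replace(self, trials=[t.copy() for t in self.trials])


def extract_epoch(
    continuous: np.ndarray,
    cue_sample: int,
    offset_s: float,
    duration_s: float,
    fs: float,
    label: str = UNLABELED,
    subject: str = "unknown",
) -> Trial:
    """Cut one epoch from a continuous recording.

    The epoch starts ``offset_s`` seconds after the cue sample and lasts
    ``duration_s`` seconds: samples ``[cue + round(offset*fs),
    cue + round(offset*fs) + round(duration*fs))``, half-open.

    Parameters
    ----------
    continuous : ndarray (n_channels, n_total_samples)
    cue_sample : int
        0-based index of the cue within the recording.
    offset_s, duration_s : float
        Non-negative window offset and length in seconds.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    Trial
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous recording must be 2D (channels x samples)")
    if offset_s < 0 or duration_s < 0:
        raise ValueError("offset_s and duration_s must be non-negative")
    if cue_sample < 0:
        raise ValueError("cue_sample must be non-negative")
    start = cue_sample + int(round(offset_s * fs))
    n = int(round(duration_s * fs))
    total = continuous.shape[1]
    if start + n > total:
        raise IndexError(
            f"epoch for subject {subject!r} overruns recording by "
            f"{start + n - total} samples (window [{start}, {start + n}), "
            f"recording has {total})"
        )
    return Trial(
        data=continuous[:, start : start + n].copy(),
        label=label,
        subject=subject,
        fs=fs,
    )


def split_domains(ts: TrialSet, source_subjects, target_subjects):
    """Partition a TrialSet into source and target domains by subject id.

    The two id lists must be disjoint and contain only subjects present in
    ``ts``.  Trial order within each domain is preserved.

    Returns
    -------
    (TrialSet, TrialSet)
        Source and target sets with roles set accordingly.
    """
    source_subjects = list(source_subjects)
    target_subjects = list(target_subjects)
    overlap = set(source_subjects) & set(target_subjects)
    if overlap:
        raise ValueError(f"subjects in both source and target lists: {sorted(overlap)}")
    present = set(ts.subject_ids())
    unknown = (set(source_subjects) | set(target_subjects)) - present
    if unknown:
        raise ValueError(f"unknown subject ids: {sorted(unknown)}")
    if not target_subjects:
        warnings.warn("target subject list is empty; target TrialSet will be empty")
    src = [t for t in ts.trials if t.subject in source_subjects]
    tgt = [t for t in ts.trials if t.subject in target_subjects]
    source = TrialSet(trials=src, channel_names=list(ts.channel_names), role="source")
    target = TrialSet(trials=tgt, channel_names=list(ts.channel_names), role="target")
    return source, target
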