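"""Serialization of trial sets.

The native container is a single HDF5 file with one group per subject::

    /subjects/<id>/data     float64, (n_channels, n_samples, n_trials)
    /subjects/<id>/labels   int64,   (n_trials,)   0=class1, 1=class2, -1=unlabeled
    /                        attrs: fs, channel_names, role, format_version

The per-subject 3D layout mirrors the conventional channels x samples x
trials arrangement of epoched motor-imagery recordings.  Round trips are
bit-exact for data and lossless for all metadata.

A one-trial-per-file CSV import (rows = channels) is provided for toy
examples, and :func:`load_raw_eeg` is a thin optional adapter over ``mne``
for vendor formats (GDF/EDF); the core package never requires it.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .trials import CODE_LABELS, LABEL_CODES, UNLABELED, Trial, TrialSet

__all__ = ["save_trialset", "load_trialset", "load_trial_csv", "load_raw_eeg"]

_FORMAT_VERSION = 1


def save_trialset(ts: TrialSet, path, overwrite: bool = False):
    """Write a TrialSet to the HDF5 container.

    Refuses to clobber an existing file unless ``overwrite=True``.
    Returns the path written.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite=True to replace it"
        )
    # group trials by subject, preserving within-subject order
    by_subject: dict = {}
    for t in ts.trials:
        by_subject.setdefault(t.subject, []).append(t)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["role"] = ts.role
        f.attrs["channel_names"] = [str(c) for c in ts.channel_names]
        if ts.trials:
            f.attrs["fs"] = float(ts.fs)
        subj_grp = f.create_group("subjects")
        f.attrs["subject_order"] = list(by_subject)
        for sid, trials in by_subject.items():
            g = subj_grp.create_group(str(sid))
            lens = {t.n_samples for t in trials}
            if len(lens) != 1:
                raise ValueError(
                    f"subject {sid!r} has trials with differing sample counts"
                )
            data = np.stack([t.data for t in trials], axis=-1)  # (M, N, n)
            g.create_dataset("data", data=data)
            g.create_dataset(
                "labels", data=np.array([LABEL_CODES[t.label] for t in trials])
            )
    return path


def load_trialset(path, format_tag: str = "container") -> TrialSet:
    """Read a TrialSet back from disk.

    Parameters
    ----------
    path : path-like
    format_tag : {"container", "csv_matrix"}
        ``container`` reads the native HDF5 layout; ``csv_matrix`` reads a
        single CSV trial (rows = channels) as a one-trial set with fs=1.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format_tag == "csv_matrix":
        trial = load_trial_csv(path)
        return TrialSet(trials=[trial])
    if format_tag != "container":
        raise ValueError(
            f"unknown format_tag {format_tag!r}; allowed: container, csv_matrix"
        )
    trials = []
    with h5py.File(path, "r") as f:
        role = str(f.attrs.get("role", "unassigned"))
        channel_names = [str(c) for c in f.attrs.get("channel_names", [])]
        fs = float(f.attrs.get("fs", 1.0))
        order = [str(s) for s in f.attrs.get("subject_order", sorted(f["subjects"]))]
        n_channels = None
        for sid in order:
            g = f["subjects"][sid]
            data = np.asarray(g["data"], dtype=np.float64)
            labels = np.asarray(g["labels"], dtype=np.int64)
            if data.ndim != 3:
                raise ValueError(f"subject {sid!r}: data is not 3D")
            if n_channels is None:
                n_channels = data.shape[0]
            elif data.shape[0] != n_channels:
                raise ValueError(
                    f"inconsistent channel counts across subjects: "
                    f"{data.shape[0]} vs {n_channels}"
                )
            if data.shape[2] != labels.shape[0]:
                raise ValueError(
                    f"subject {sid!r}: {data.shape[2]} trials but "
                    f"{labels.shape[0]} labels"
                )
            for k in range(data.shape[2]):
                code = int(labels[k])
                if code not in CODE_LABELS:
                    raise ValueError(
                        f"unknown label code {code}; allowed codes: "
                        f"{dict(sorted(CODE_LABELS.items()))}"
                    )
                trials.append(
                    Trial(data=data[:, :, k], label=CODE_LABELS[code],
                          subject=sid, fs=fs)
                )
    return TrialSet(trials=trials, channel_names=channel_names, role=role)


def load_trial_csv(path, fs: float = 1.0, label: str = UNLABELED,
                   subject: str = "unknown") -> Trial:
    """Read one trial from a CSV file with one row per channel."""
    data = np.loadtxt(os.fspath(path), delimiter=",", ndmin=2)
    return Trial(data=data, label=label, subject=subject, fs=fs)


def load_raw_eeg(path):
    """Optional adapter: read a continuous vendor-format recording (GDF/EDF).

    Returns ``(data, fs, channel_names)`` with data in channels x samples.
    Requires the optional ``mne`` dependency; epoching is then done with
    :func:`mitransfer.trials.extract_epoch`.
    """
    try:
        import mne  # noqa: delayed import, optional dependency
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading GDF/EDF requires the optional 'mne' dependency "
            "(pip install mitransfer[eegio])"
        ) from exc
    raw = mne.io.read_raw(os.fspath(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
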