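"""Reading and writing recordings, matrices and tables.

Recordings travel either as EDF (European Data Format) or as delimited
text: one header row of 10-20 channel labels, then one column per
channel, one row per sample.  Connectivity matrices are square
delimited tables with a label header; cohort and result tables are
plain CSV handled by pandas.

EDF reading goes through :mod:`mne`.  Writing uses a small built-in
EDF writer (fixed-layout 16-bit EDF, one data record per second),
sufficient for round-tripping multichannel scalp EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import validate_labels


@dataclass
class Recording:
    """A labeled multichannel signal.

    Parameters
    ----------
    channel_labels
        Ordered 10-20 electrode names, unique.
    fs
        Sampling frequency in Hz, positive.
    data
        Array of shape ``(n_channels, n_samples)``, amplitudes in µV.
    """

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def write_recording_text(rec: Recording, path: str | Path, fs_comment: bool = True) -> None:
    """Write a recording as TSV: header of labels, one row per sample.

    The sampling rate is kept in a ``# fs=<Hz>`` comment on the first
    line so the file is self-describing.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if fs_comment:
            fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")


def read_recording_text(path: str | Path, fs: float | None = None) -> Recording:
    """Read a delimited recording written by :func:`write_recording_text`.

    ``fs`` overrides (or supplies, if absent) the ``# fs=`` comment.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        file_fs = None
        if first.startswith("#"):
            for tok in first.lstrip("#").split():
                if tok.startswith("fs="):
                    file_fs = float(tok[3:])
            header = fh.readline().strip()
        else:
            header = first
        labels = tuple(header.split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    use_fs = fs if fs is not None else file_fs
    if use_fs is None:
        raise ValueError(f"{path}: no sampling rate in file and none supplied")
    return Recording(channel_labels=labels, fs=use_fs, data=data.T)


def write_matrix(values: np.ndarray, labels, path: str | Path) -> None:
    """Write a square labeled matrix as TSV with a header row/column."""
    df = pd.DataFrame(np.asarray(values), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(df.columns)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (via mne).

    Channel labels are normalised to bare 10-20 names (no ``EEG``
    prefix / reference suffix).  Polygraphic channels (EOG, ECG,
    respiration) are read but carried through unchanged; montage
    selection happens downstream.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(_normalize_label(ch) for ch in raw.ch_names)
    # mne scales EEG to volts internally; back to microvolts
    return Recording(channel_labels=labels, fs=float(raw.info["sfreq"]),
                     data=raw.get_data() * 1e6)


def _normalize_label(name: str) -> str:
    name = name.strip()
    for prefix in ("EEG ", "EEG"):
        if name.startswith(prefix):
            name = name[len(prefix):]
    return name.split("-")[0].strip()


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF.

    One data record per second (``fs`` samples per record per channel);
    the signal is truncated to a whole number of records.  Each channel
    gets its own physical min/max so quantisation error is at most
    half of span/65536.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                    # samples per record per channel
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    # widen slightly, then use the values exactly as serialized (8 ASCII
    # chars) so read-back gains match the file header
    span = pmax - pmin
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in pmin - 0.001 * span])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in pmax + 0.001 * span])
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.rint((data - pmin[:, None]) * gain[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),                                  # version
        pad("X X X X", 80),                           # patient id (anonymous)
        pad("Startdate X X X X", 80),                 # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),       # date, time
        pad(str(256 * (nch + 1)), 8),                 # header bytes
        pad("", 44),                                  # reserved
        pad(str(n_rec), 8),
        pad("1", 8),                                  # record duration (s)
        pad(str(nch), 4),
    ])
    header += b"".join(pad(f"EEG {lab}", 16) for lab in rec.channel_labels)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(nch))
    header += b"".join(pad("uV", 8) for _ in range(nch))
    header += b"".join(pad(f"{v:.6g}"[:8], 8) for v in pmin)
    header += b"".join(pad(f"{v:.6g}"[:8], 8) for v in pmax)
    header += b"".join(pad(str(dmin), 8) for _ in range(nch))
    header += b"".join(pad(str(dmax), 8) for _ in range(nch))
    header += b"".join(pad("", 80) for _ in range(nch))
    header += b"".join(pad(str(spr), 8) for _ in range(nch))
    header += b"".join(pad("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
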