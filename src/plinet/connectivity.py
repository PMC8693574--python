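"""Phase Lag Index (PLI) connectivity.

The PLI between two signals is the absolute value of the mean sign of
their wrapped instantaneous phase difference,

    PLI = | < sign( Δφ(t) ) >_t |,   Δφ wrapped into (−π, π].

It is 0 when neither signal consistently leads the other — in
particular for identical signals (Δφ ≡ 0), which makes the index
relatively insensitive to volume conduction — and 1 when one signal
always leads.  The sign is taken as ``sign(sin(Δφ))``, the sign of the
principal wrapped difference: exact in-phase (Δφ = 0) and exact
anti-phase (Δφ = ±π) both contribute 0, since neither carries lead/lag
direction evidence; this also makes PLI(i, j) = PLI(j, i) an exact
identity rather than an almost-everywhere one.

Matrices are computed per epoch and per band over all 120 unordered
channel pairs; scalar network metrics are averaged across epochs
downstream (metric averaging, not matrix averaging, feeds statistics —
the per-entry mean matrix is exported for diagnostics only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import PhaseEpochs


@dataclass
class ConnectivityMatrix:
    """Symmetric per-epoch (or epoch-mean) PLI matrix with labels."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band_name: str = ""
    epoch_id: int | str = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.channel_labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """The n(n−1)/2 unique off-diagonal entries, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (−π, π]."""
    out = np.mod(-np.asarray(dphi) + np.pi, 2 * np.pi)
    return -(out - np.pi)


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI between two equal-length phase series."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ValueError(
            f"phase series lengths differ: {phase_i.shape} vs {phase_j.shape}"
        )
    if phase_i.size < 2:
        raise ValueError("phase series must have at least 2 samples")
    return float(abs(np.mean(np.sign(np.sin(phase_i - phase_j)))))


def pli_matrix(ph: PhaseEpochs, epoch_id: int) -> ConnectivityMatrix:
    """PLI over all unordered channel pairs of one epoch.

    Edge samples are trimmed per ``ph.edge_trim`` before averaging.
    """
    if not 0 <= epoch_id < ph.n_epochs:
        raise IndexError(f"epoch {epoch_id} out of range (n={ph.n_epochs})")
    phase = ph.trimmed(epoch_id)                   # (channels, samples)
    n = phase.shape[0]
    # sign of the principal pairwise differences, vectorized over pairs
    signs = np.sign(np.sin(phase[:, None, :] - phase[None, :, :]))
    values = np.abs(signs.mean(axis=-1))
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)             # exact symmetry
    return ConnectivityMatrix(values=values, channel_labels=ph.channel_labels,
                              band_name=ph.band_name, epoch_id=epoch_id)


def pli_matrices(ph: PhaseEpochs) -> list[ConnectivityMatrix]:
    """One PLI matrix per epoch."""
    return [pli_matrix(ph, e) for e in range(ph.n_epochs)]


def mean_matrix(cms: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entry-wise epoch-mean matrix (diagnostic export only)."""
    if not cms:
        raise ValueError("no matrices to average")
    values = np.mean([cm.values for cm in cms], axis=0)
    return ConnectivityMatrix(values=values, channel_labels=cms[0].channel_labels,
                              band_name=cms[0].band_name, epoch_id="mean")


def mean_pli(cm: ConnectivityMatrix) -> float:
    """Arithmetic mean of the upper-triangle PLI entries."""
    return float(cm.upper_triangle().mean())


def aggregate_epochs(per_epoch_values: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each scalar metric across epochs.

    Applies uniformly to PLI, weighted-network and MST measures: the
    per-epoch metric values are averaged, one mean per metric.
    """
    if not per_epoch_values:
        raise ValueError("need at least one epoch of metrics")
    keys = set(per_epoch_values[0])
    for d in per_epoch_values[1:]:
        if set(d) != keys:
            raise ValueError(
                f"inconsistent metric sets across epochs: {sorted(keys)} vs {sorted(d)}"
            )
    return {k: float(np.mean([d[k] for d in per_epoch_values])) for k in keys}
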