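"""Phase Lag Index (PLI) functional connectivity.

The PLI between two signals is the absolute time-average of the sign of the
sine of their instantaneous phase difference:

    PLI = | < sign( sin(phi_a(t) - phi_b(t)) ) > |

It ranges from 0 (no consistent phase lead/lag) to 1 (one signal always
leads the other) and is insensitive to zero-lag coupling — a phase
difference of exactly zero, the signature of volume conduction or a shared
reference, contributes sign(0) = 0. Phases come from the analytic signal
(Hilbert transform) of band-filtered data; a margin at each epoch end is
excluded from the average to suppress filter and Hilbert edge transients.
Matrices are computed per epoch and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from qeeg.bands import Band, ALPHA_BAND
from qeeg.preprocess import bandpass
from qeeg.recording import EpochSet

#: Seconds discarded at each epoch edge before averaging the lag signs.
DEFAULT_EDGE_MARGIN_S = 0.25


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels PLI matrix, zero diagonal."""

    values: np.ndarray
    channel_labels: list[str]
    band: Band
    n_epochs_averaged: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 0:
            raise ValueError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_labels,
                            columns=self.channel_labels)


def instantaneous_phase(signal: np.ndarray, fs: float,
                        edge_margin_s: float = DEFAULT_EDGE_MARGIN_S
                        ) -> tuple[np.ndarray, slice]:
    """Phase of the analytic signal, plus the slice that survives the edge margin.

    The caller is expected to band-limit the signal first; a (near-)constant
    signal has no defined phase and raises.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("instantaneous_phase expects a single channel")
    if np.std(x) == 0:
        raise ValueError("phase undefined for a constant signal")
    phase = np.angle(sps.hilbert(x))
    margin = round(edge_margin_s * fs)
    if 2 * margin >= x.size:
        raise ValueError("edge margins leave no samples")
    return phase, slice(margin, x.size - margin)


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI of two equal-length phase series (edge margins already removed)."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series lengths differ: {a.shape} vs {b.shape}")
    return float(np.abs(np.mean(np.sign(np.sin(a - b)))))


def pli_matrix(epochs: EpochSet, band: Band = ALPHA_BAND,
               edge_margin_s: float = DEFAULT_EDGE_MARGIN_S) -> ConnectivityMatrix:
    """All-pairs PLI: band-filter, phase-extract, sign-average per epoch,
    then average the per-epoch matrices."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    filtered = bandpass(epochs, band)
    n_ch = epochs.n_channels
    acc = np.zeros((n_ch, n_ch))
    for e in range(filtered.n_epochs):
        phases = []
        keep = None
        for c in range(n_ch):
            ph, keep = instantaneous_phase(filtered.epochs[e, c], epochs.fs,
                                           edge_margin_s)
            phases.append(ph[keep])
        phases = np.asarray(phases)
        # sign of sin of all pairwise phase differences, vectorized
        sin_diff = np.sin(phases[:, None, :] - phases[None, :, :])
        acc += np.abs(np.mean(np.sign(sin_diff), axis=-1))
    values = acc / filtered.n_epochs
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against float noise
    return ConnectivityMatrix(values, list(epochs.channel_labels), band,
                              filtered.n_epochs)


def pli_features(matrix: ConnectivityMatrix) -> dict[str, float]:
    """Lowest / mean / highest PLI over the upper triangle."""
    tri = matrix.upper_triangle()
    return {"lowest": float(tri.min()), "mean": float(tri.mean()),
            "highest": float(tri.max())}
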