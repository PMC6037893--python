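import numpy as np
import pytest

from qeeg.bands import ALPHA1, DEFAULT_BANDS
from qeeg.recording import EEGRecording, EpochSet


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


def sine_epochs(freq, fs=500.0, n_epochs=4, epoch_s=8.0, n_channels=1,
                amplitude=1.0, phase=0.0):
    """EpochSet of identical pure sinusoids."""
    t = np.arange(round(epoch_s * fs)) / fs
    sig = amplitude * np.sin(2 * np.pi * freq * t + phase)
    epochs = np.tile(sig, (n_epochs, n_channels, 1))
    labels = [f"ch{i}" for i in range(n_channels)]
    return EpochSet(epochs, fs, labels)


def noise_epochs(rng, fs=500.0, n_epochs=4, epoch_s=8.0, n_channels=1, sd=1.0):
    n = round(epoch_s * fs)
    epochs = sd * rng.standard_normal((n_epochs, n_channels, n))
    labels = [f"ch{i}" for i in range(n_channels)]
    return EpochSet(epochs, fs, labels)


def brute_force_pli(phase_a, phase_b):
    """Literal sample-by-sample PLI oracle (loop, no vectorization)."""
    total = 0.0
    for pa, pb in zip(phase_a, phase_b):
        s = np.sin(pa - pb)
        total += int(s > 0) - int(s < 0)
    return abs(total / len(phase_a))


def prufer_tree_edges(seq, n):
    """Decode a Prufer sequence into the labelled tree's edge set."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append(tuple(sorted((leaf, v))))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    last = [v for v in range(n) if degree[v] == 1]
    edges.append(tuple(sorted(last)))
    return edges


def max_tree_weight_exhaustive(w):
    """Maximum spanning-tree weight by enumerating all n^(n-2) labelled trees."""
    from itertools import product

    n = w.shape[0]
    best = -np.inf
    for seq in product(range(n), repeat=n - 2):
        weight = sum(w[i, j] for i, j in prufer_tree_edges(seq, n))
        best = max(best, weight)
    return best
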