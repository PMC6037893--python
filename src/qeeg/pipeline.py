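"""End-to-end per-subject pipeline: recording -> 25 qEEG features.

The canonical stages, in order: Hjorth source derivation on the analysis
montage; extraction of four 8-s artifact-free epochs; spectral summary
(Welch spectra, relative band power, peak frequency and its 2-s sub-epoch
variability, theta/alpha ratio); alpha-band (8-13 Hz) PLI matrix;
maximum-weight spanning tree and its topology metrics; assembly of the
ordered 25-feature vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from qeeg.bands import ALPHA_BAND, Band
from qeeg.connectivity import ConnectivityMatrix, pli_matrix
from qeeg.features import FeatureVector, build_feature_vector, features_to_frame
from qeeg.montage import Montage
from qeeg.network import TreeTopology, spanning_tree
from qeeg.preprocess import apply_source_derivation, extract_epochs
from qeeg.recording import EEGRecording
from qeeg.spectral import SpectralSummary, spectral_summary


def subject_features(
    recording: EEGRecording,
    montage: Montage | None = None,
    epoch_length_s: float = 8.0,
    n_epochs: int = 4,
    pli_band: Band = ALPHA_BAND,
    group_label: str = "",
    source_derivation: bool = True,
) -> tuple[FeatureVector, SpectralSummary, ConnectivityMatrix, TreeTopology]:
    """Run the full pipeline on one recording.

    Returns the 25-feature vector plus the intermediate spectral,
    connectivity and tree results (which carry quantities, like gamma power
    and tree diameter, that are reported but not classified on).
    """
    if source_derivation:
        recording = apply_source_derivation(recording, montage)
    epochs = extract_epochs(recording, epoch_length_s=epoch_length_s, n_epochs=n_epochs)
    spec = spectral_summary(epochs)
    conn = pli_matrix(epochs, band=pli_band)
    tree = spanning_tree(conn)
    fv = build_feature_vector(spec, conn, tree,
                              subject_id=recording.subject_id,
                              group_label=group_label)
    return fv, spec, conn, tree


def cohort_feature_table(
    recordings: list[EEGRecording],
    group_label: str = "",
    **kwargs,
) -> pd.DataFrame:
    """Feature table for a list of recordings from one group."""
    feats = [subject_features(r, group_label=group_label, **kwargs)[0]
             for r in recordings]
    return features_to_frame(feats)


def subject_summary_row(
    fv: FeatureVector,
    spec: SpectralSummary,
    conn: ConnectivityMatrix,
    tree: TreeTopology,
) -> dict:
    """One-row-per-subject summary mirroring the conventional qEEG table:
    channel-mean band powers, peak frequency and variability, theta/alpha
    ratio, mean PLI and all four tree metrics (including diameter)."""
    row = {"subject_id": fv.subject_id, "group": fv.group_label}
    for band, frac in spec.rel_power.items():
        row[f"{band}_power"] = float(np.mean(frac))
    row["peak_frequency"] = spec.global_peak_freq
    row["peak_frequency_variability"] = spec.peak_freq_variability
    row["theta_alpha_ratio"] = spec.theta_alpha_ratio
    row["pli_mean"] = float(conn.upper_triangle().mean())
    row.update({f"mst_{k}": v for k, v in tree.metrics.items()})
    return row
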