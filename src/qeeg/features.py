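"""The ordered 25-feature qEEG representation of a subject.

Feature order is fixed and bit-stable: lowest/mean/highest relative power
across channels for delta, theta, alpha-1, alpha-2 and beta (15), lowest/
mean/highest peak frequency (3), theta/alpha ratio (1), lowest/mean/highest
alpha-band PLI over the matrix upper triangle (3), and the three tree
metrics — highest degree, leaf number, tree hierarchy (3). Gamma power and
the tree diameter are computed elsewhere in the pipeline but deliberately
excluded from the classifier feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qeeg.connectivity import ConnectivityMatrix, pli_features
from qeeg.network import TreeTopology
from qeeg.spectral import SpectralSummary

_POWER_BANDS = ("delta", "theta", "alpha1", "alpha2", "beta")
_REDUCTIONS = ("lowest", "mean", "highest")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{red} {band} power" for band in _POWER_BANDS for red in _REDUCTIONS
) + (
    "lowest peak frequency", "mean peak frequency", "highest peak frequency",
    "theta/alpha ratio",
    "lowest PLI", "mean PLI", "highest PLI",
    "highest degree", "leaf number", "tree hierarchy",
)
assert len(FEATURE_NAMES) == 25


@dataclass
class FeatureVector:
    """25 ordered qEEG features for one subject."""

    values: np.ndarray
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (25,):
            raise ValueError(f"expected 25 features, got shape {self.values.shape}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def _reduce(x: np.ndarray) -> tuple[float, float, float]:
    return float(np.min(x)), float(np.mean(x)), float(np.max(x))


def build_feature_vector(
    spectral: SpectralSummary,
    connectivity: ConnectivityMatrix,
    tree: TreeTopology,
    subject_id: str = "",
    group_label: str = "",
) -> FeatureVector:
    """Assemble the 25-feature vector from the three analysis blocks.

    Lowest/mean/highest reductions run over channels (powers, peak
    frequency) or over the PLI matrix upper triangle.
    """
    missing = [name for name, obj in
               [("spectral summary", spectral), ("connectivity matrix", connectivity),
                ("spanning tree", tree)] if obj is None]
    if missing:
        raise ValueError(f"missing feature components: {missing}")

    vals: list[float] = []
    for band in _POWER_BANDS:
        if band not in spectral.rel_power:
            raise ValueError(f"spectral summary lacks band {band!r}")
        vals.extend(_reduce(spectral.rel_power[band]))
    vals.extend(_reduce(spectral.peak_freq_per_channel))
    vals.append(spectral.theta_alpha_ratio)
    pli = pli_features(connectivity)
    vals.extend([pli["lowest"], pli["mean"], pli["highest"]])
    m = tree.metrics
    vals.extend([m["degree_max_norm"], m["leaf_fraction"], m["tree_hierarchy"]])
    return FeatureVector(np.asarray(vals), subject_id, group_label)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Feature table with the fixed 25-column header plus identifiers."""
    df = pd.DataFrame([f.values for f in features], columns=list(FEATURE_NAMES))
    df.insert(0, "subject_id", [f.subject_id for f in features])
    df.insert(1, "group", [f.group_label for f in features])
    return df


def frame_to_features(df: pd.DataFrame) -> list[FeatureVector]:
    return [
        FeatureVector(row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                      subject_id=str(row.get("subject_id", i)),
                      group_label=str(row.get("group", "")))
        for i, row in df.iterrows()
    ]
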