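"""10-20 montage and the Hjorth source-derivation neighbour table.

The recording montage is the 21-electrode 10-20 set (including the ear
electrodes A1/A2). The default *analysis* montage drops A1/A2: ear
electrodes sit outside the scalp neighbour lattice and are conventionally
excluded from Laplacian-style referencing. The neighbour table below is the
standard nearest-neighbour adjacency on the 10-20 grid; Hjorth weights are
an unweighted mean over neighbours. Both the table and the exclusion are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

#: The 21 recording channels in fixed order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp2", "Fp1", "F8", "F7", "F4", "F3", "A2", "A1", "T4", "T3",
    "C4", "C3", "T6", "T5", "P4", "P3", "O2", "O1", "Fz", "Cz", "Pz",
)

#: The 19 scalp channels (ears excluded), in recording order.
SCALP_CHANNELS: tuple[str, ...] = tuple(c for c in CHANNELS_1020 if c not in ("A1", "A2"))

# Nearest-neighbour adjacency on the 10-20 scalp grid (symmetric).
_SCALP_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}


@dataclass
class Montage:
    """An ordered channel set with a symmetric neighbour relation.

    ``labels`` fixes the channel order of any source-derived output;
    ``neighbors`` maps each label to its Hjorth reference neighbours.
    """

    labels: tuple[str, ...]
    neighbors: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        for lab in self.labels:
            nbrs = self.neighbors.get(lab, ())
            if len(nbrs) < 2:
                raise ValueError(f"channel {lab!r} has fewer than 2 neighbours")
        # symmetry over the label set
        for lab in self.labels:
            for nb in self.neighbors[lab]:
                if nb in self.neighbors and lab not in self.neighbors[nb]:
                    raise ValueError(f"neighbour relation not symmetric: {lab!r} -> {nb!r}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @classmethod
    def standard_scalp(cls) -> "Montage":
        """The default 19-channel analysis montage (A1/A2 excluded)."""
        return cls(labels=SCALP_CHANNELS, neighbors=dict(_SCALP_NEIGHBORS))

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            labels=tuple(data["labels"]),
            neighbors={k: tuple(v) for k, v in data["neighbors"].items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"labels": list(self.labels),
                 "neighbors": {k: list(v) for k, v in self.neighbors.items()}},
                fh,
            )
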