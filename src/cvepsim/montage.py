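"""Electrode montages for occipito-parietal VEP recordings.

Two montages are built in: the 16-electrode occipito-parietal set used for
baseline recording and the 6-electrode subset retained after electrode
reduction.  Approximate 2-D scalp coordinates (10-10 system, head seen from
above, x to the right, y toward the front) are included so the synthetic EEG
generator can draw spatially smooth response topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "FULL16", "REDUCED6"]

# Approximate normalized 10-10 scalp positions for the electrodes used here.
_COORDS: dict[str, tuple[float, float]] = {
    "P7": (-0.80, -0.30), "P3": (-0.45, -0.35), "Pz": (0.00, -0.38),
    "P4": (0.45, -0.35), "P8": (0.80, -0.30),
    "PO7": (-0.60, -0.58), "PO3": (-0.32, -0.62), "POz": (0.00, -0.64),
    "PO4": (0.32, -0.62), "PO8": (0.60, -0.58),
    "O1": (-0.28, -0.85), "Oz": (0.00, -0.88), "O2": (0.28, -0.85),
    "O9": (-0.35, -1.00), "Iz": (0.00, -1.03), "O10": (0.35, -1.00),
}


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrode labels with reference and ground."""

    names: tuple[str, ...]
    reference: str = "Cz"
    ground: str = "AFz"

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        if name not in self.names:
            raise ValueError(f"electrode {name!r} not in montage {self.names}")
        return self.names.index(name)

    def indices_of(self, subset: "Montage") -> np.ndarray:
        """Row indices of ``subset``'s electrodes within this montage.

        The returned order follows this montage (original relative order is
        preserved when restricting data).
        """
        missing = [n for n in subset.names if n not in self.names]
        if missing:
            raise ValueError(f"electrodes {missing} not present in montage")
        return np.array([i for i, n in enumerate(self.names) if n in subset.names])

    def issubset(self, other: "Montage") -> bool:
        return set(self.names) <= set(other.names)

    def coordinates(self) -> np.ndarray:
        """Approximate 2-D scalp coordinates, one row per electrode."""
        try:
            return np.array([_COORDS[n] for n in self.names])
        except KeyError as exc:  # pragma: no cover
            raise ValueError(f"no stored coordinates for electrode {exc}") from exc


#: Baseline 16-electrode occipito-parietal montage (reference Cz, ground AFz).
FULL16 = Montage(
    names=("P7", "P3", "Pz", "P4", "P8", "PO7", "PO3", "POz", "PO4", "PO8",
           "O1", "Oz", "O2", "O9", "Iz", "O10"),
)

#: Reduced 6-electrode subset kept after electrode removal.
REDUCED6 = Montage(names=("PO3", "POz", "PO4", "O1", "Oz", "O2"))
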