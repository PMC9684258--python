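"""Electrode montage conventions for low-density scalp EEG.

A :class:`Montage` fixes the set and the *order* of electrodes for every
matrix in the package: rows of an EEG data matrix, columns of a template
set, entries of a scalp map. Positions are 2-D projections of the scalp
onto the unit disc (nose up, right ear at +x) and are used only to build
synthetic dipolar topographies and the canonical A-D reference maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Electrode order of the builtin 19-channel international 10/20 montage.
STANDARD_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# 2-D projected scalp coordinates, head radius 1, +y anterior, +x right.
_1020_POSITIONS = {
    "Fp1": (-0.28, 0.86), "Fp2": (0.28, 0.86),
    "F7": (-0.73, 0.53), "F3": (-0.40, 0.45), "Fz": (0.0, 0.45),
    "F4": (0.40, 0.45), "F8": (0.73, 0.53),
    "T3": (-0.90, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T4": (0.90, 0.0),
    "T5": (-0.73, -0.53), "P3": (-0.40, -0.45), "Pz": (0.0, -0.45),
    "P4": (0.40, -0.45), "T6": (0.73, -0.53),
    "O1": (-0.28, -0.86), "O2": (0.28, -0.86),
}


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with projected 2-D scalp positions.

    Parameters
    ----------
    names
        Unique electrode labels; their order is the canonical channel order.
    positions
        ``(n_channels, 2)`` array of coordinates inside the unit disc.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("electrode labels must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must have shape ({len(names)}, 2), got {pos.shape}"
            )
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii > 1.0 + 1e-12):
            bad = names[int(np.argmax(radii))]
            raise ValueError(f"electrode {bad!r} lies outside the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Channel index of an electrode label (case-insensitive)."""
        lowered = [n.lower() for n in self.names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage") from None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


def standard_1020_19() -> Montage:
    """The builtin 19-channel 10/20 montage used throughout."""
    pos = np.array([_1020_POSITIONS[n] for n in STANDARD_1020_19])
    return Montage(names=STANDARD_1020_19, positions=pos)


_BUILTIN = {"standard-1020-19": standard_1020_19}


def get_montage(name: str) -> Montage:
    """Look up a builtin montage by name."""
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise KeyError(
            f"unknown montage {name!r}; available: {sorted(_BUILTIN)}"
        ) from None
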