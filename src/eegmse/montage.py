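"""Scalp montage to 2-D grid embedding.

Electrode labels from the international 10-20 system carry an
anterior-posterior row (Fp, AF, F, FC, C, CP, P, PO/O) and a lateral
position (odd numbers left, even numbers right, ``z`` on the midline).
The 32 channels of the DEAP layout are embedded into an inner 8 x 8
grid; a one-cell ring of zero-filled border cells surrounds it, giving
the 10 x 10 planes used by the spatial feature tensors, so that edge
electrodes are never flush against the tensor boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["DEAP_CHANNELS", "DEAP_GRID", "MontageGrid"]

#: DEAP preprocessed channel order (32 EEG channels).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

# Rows run front -> back (Fp row 0 ... O row 7).  Columns run left ->
# right through the lateral order 7, 5, 3, 1, z, 2, 4, 6, 8 compressed
# into eight columns; "z" and "2" share a column index but never occur
# in the same row, keeping the mapping injective.
DEAP_GRID: dict[str, tuple[int, int]] = {
    "Fp1": (0, 3), "Fp2": (0, 5),
    "AF3": (1, 2), "AF4": (1, 5),
    "F7": (2, 0), "F3": (2, 2), "Fz": (2, 4), "F4": (2, 5), "F8": (2, 7),
    "FC5": (3, 1), "FC1": (3, 3), "FC2": (3, 5), "FC6": (3, 6),
    "T7": (4, 0), "C3": (4, 2), "Cz": (4, 4), "C4": (4, 5), "T8": (4, 7),
    "CP5": (5, 1), "CP1": (5, 3), "CP2": (5, 5), "CP6": (5, 6),
    "P7": (6, 0), "P3": (6, 2), "Pz": (6, 4), "P4": (6, 5), "P8": (6, 7),
    "PO3": (7, 2), "O1": (7, 3), "Oz": (7, 4), "O2": (7, 5), "PO4": (7, 6),
}


@dataclass(frozen=True)
class MontageGrid:
    """Injective mapping from channel labels to inner-grid cells.

    Parameters
    ----------
    mapping
        ``{channel: (row, col)}`` on the *inner* grid (border excluded).
    inner_shape
        Shape of the inner grid; the output planes add a one-cell
        zero border on every side.
    """

    mapping: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEAP_GRID)
    )
    inner_shape: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        rows, cols = self.inner_shape
        for name, (r, c) in self.mapping.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"channel {name!r} maps to ({r}, {c}), outside the "
                    f"{rows} x {cols} inner grid"
                )
            if (r, c) in seen:
                raise ValueError(f"grid cell ({r}, {c}) assigned twice")
            seen.add((r, c))

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Output shape including the zero border ring."""
        return (self.inner_shape[0] + 2, self.inner_shape[1] + 2)

    def cell(self, channel: str) -> tuple[int, int]:
        """Bordered-grid coordinate of ``channel``."""
        try:
            r, c = self.mapping[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel!r} has no grid coordinate; known channels: "
                f"{sorted(self.mapping)}"
            ) from None
        return r + 1, c + 1

    def __contains__(self, channel: str) -> bool:
        return channel in self.mapping

    @classmethod
    def from_json(cls, path: str) -> "MontageGrid":
        """Load a ``{channel: [row, col]}`` mapping from a JSON file."""
        with open(path) as fh:
            raw = json.load(fh)
        mapping = {str(k): (int(v[0]), int(v[1])) for k, v in raw.items()}
        rows = 1 + max(r for r, _ in mapping.values())
        cols = 1 + max(c for _, c in mapping.values())
        return cls(mapping=mapping, inner_shape=(max(rows, 8), max(cols, 8)))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(v) for k, v in self.mapping.items()}, fh, indent=1)
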