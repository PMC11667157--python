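"""Electrode montage and the 2D scalp topology grid.

The 64-channel montage follows the BCI2000 / PhysioNet motor-imagery
recording order (international 10-10 placement, 64 sites).  For imaging,
each channel is assigned a cell of an 11 x 10 grid whose rows run
anterior -> posterior (frontopolar line first) and whose columns run
left -> right with the midline at column 5.  Cells without an electrode
are zero-cells.

The grid is shipped as data (JSON round-trip supported) rather than
hard-coded logic, so alternative montages or corrected placements can be
swapped in without touching code.  The inferior temporal sites T9/T10 do
not fit on the 10-column sensorimotor ring and are placed on their own
row just below it; these two cells are the least certain part of the
default layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "PHYSIONET_64_CHANNELS",
    "MontageLayout",
    "default_layout",
]

#: Channel order of the 64-electrode BCI2000 montage (10-10 system).
PHYSIONET_64_CHANNELS: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2",
    "IZ",
)

# channel index (1-based, montage order above) -> (row, col), 1-based.
# Rows anterior->posterior, midline electrodes at column 5.
_DEFAULT_PLACEMENT: dict[int, tuple[int, int]] = {}


def _row(row: int, start_col: int, channels: list[int]) -> None:
    for offset, ch in enumerate(channels):
        _DEFAULT_PLACEMENT[ch] = (row, start_col + offset)


_row(1, 4, [22, 23, 24])                                # Fp1 Fpz Fp2
_row(2, 3, [25, 26, 27, 28, 29])                        # AF7..AF8
_row(3, 1, [30, 31, 32, 33, 34, 35, 36, 37, 38])        # F7..F8
_row(4, 1, [39, 1, 2, 3, 4, 5, 6, 7, 40])               # FT7, FC5..FC6, FT8
_row(5, 1, [41, 8, 9, 10, 11, 12, 13, 14, 42])          # T7, C5..C6, T8
_row(6, 1, [43])                                        # T9 (inferior temporal)
_row(6, 9, [44])                                        # T10
_row(7, 1, [45, 15, 16, 17, 18, 19, 20, 21, 46])        # TP7, CP5..CP6, TP8
_row(8, 1, [47, 48, 49, 50, 51, 52, 53, 54, 55])        # P7..P8
_row(9, 3, [56, 57, 58, 59, 60])                        # PO7..PO8
_row(10, 4, [61, 62, 63])                               # O1 Oz O2
_row(11, 5, [64])                                       # Iz


@dataclass(frozen=True)
class MontageLayout:
    """Assignment of 64 channels to cells of a rows x cols scalp grid.

    Parameters
    ----------
    grid_shape
        (rows, cols) of the topology matrix; default (11, 10).
    placement
        Mapping from 1-based channel index to 1-based (row, col) cell.
    channel_names
        Channel labels in montage order; ``placement`` keys index into
        this tuple.
    """

    grid_shape: tuple[int, int] = (11, 10)
    placement: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_PLACEMENT)
    )
    channel_names: tuple[str, ...] = PHYSIONET_64_CHANNELS

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if len(self.placement) != len(self.channel_names):
            raise ValueError(
                f"placement has {len(self.placement)} channels, "
                f"montage lists {len(self.channel_names)}"
            )
        seen: set[tuple[int, int]] = set()
        for ch, (r, c) in self.placement.items():
            if not (1 <= ch <= len(self.channel_names)):
                raise ValueError(f"channel index {ch} outside montage")
            if not (1 <= r <= rows and 1 <= c <= cols):
                raise ValueError(f"channel {ch} placed outside grid at {(r, c)}")
            if (r, c) in seen:
                raise ValueError(f"grid cell {(r, c)} assigned twice")
            seen.add((r, c))

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "channel_names": list(self.channel_names),
            "placement": {str(k): list(v) for k, v in self.placement.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MontageLayout":
        payload = json.loads(Path(path).read_text())
        return cls(
            grid_shape=tuple(payload["grid_shape"]),
            placement={int(k): tuple(v) for k, v in payload["placement"].items()},
            channel_names=tuple(payload["channel_names"]),
        )

    def channel_index(self, name: str) -> int:
        """0-based index of a channel name (case/punctuation tolerant)."""
        key = _normalize(name)
        for i, ch in enumerate(self.channel_names):
            if _normalize(ch) == key:
                return i
        raise KeyError(f"channel {name!r} not in montage")


def _normalize(name: str) -> str:
    return name.replace(".", "").replace(" ", "").upper()


def default_layout() -> MontageLayout:
    """The stock 11 x 10 layout for the 64-channel 10-10 montage."""
    return MontageLayout()
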