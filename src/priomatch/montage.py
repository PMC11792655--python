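"""30-channel 10/20 montage: schematic 2D positions and electrode aliases.

Positions are top-view schematic coordinates (x: left -> right, y: back ->
front, unit head radius ~1) sufficient for spatial adjacency and topographic
weighting; they are not digitized electrode locations.

Older nomenclature used in parts of the literature (T3/T4/T5/T6) is mapped to
the modern 10/20 names (T7/T8/P7/P8) via ``ALIASES``.
"""

from __future__ import annotations

import json

# channel -> (x, y)
MONTAGE_30 = {
    "FP1": (-0.35, 0.80), "FP2": (0.35, 0.80),
    "F7": (-0.80, 0.40), "F3": (-0.40, 0.40), "FZ": (0.00, 0.40),
    "F4": (0.40, 0.40), "F8": (0.80, 0.40),
    "FT7": (-0.80, 0.20), "FC3": (-0.40, 0.20), "FCZ": (0.00, 0.20),
    "FC4": (0.40, 0.20), "FT8": (0.80, 0.20),
    "T7": (-0.80, 0.00), "C3": (-0.40, 0.00), "CZ": (0.00, 0.00),
    "C4": (0.40, 0.00), "T8": (0.80, 0.00),
    "TP7": (-0.80, -0.20), "CP3": (-0.40, -0.20), "CPZ": (0.00, -0.20),
    "CP4": (0.40, -0.20), "TP8": (0.80, -0.20),
    "P7": (-0.80, -0.40), "P3": (-0.40, -0.40), "PZ": (0.00, -0.40),
    "P4": (0.40, -0.40), "P8": (0.80, -0.40),
    "O1": (-0.35, -0.80), "OZ": (0.00, -0.80), "O2": (0.35, -0.80),
}

# old 10/20 temporal names -> modern names
ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

CHANNELS = list(MONTAGE_30)


def resolve_channel(name: str) -> str:
    """Normalize a channel name (case-insensitive, old temporal aliases)."""
    up = name.upper()
    up = ALIASES.get(up, up)
    if up not in MONTAGE_30:
        raise KeyError(f"unknown channel {name!r} (resolved to {up!r})")
    return up


def resolve_cluster(names) -> list[str]:
    """Normalize a list of channel names, preserving order."""
    return [resolve_channel(n) for n in names]


def write_montage_json(path) -> None:
    with open(path, "w") as fh:
        json.dump({ch: list(xy) for ch, xy in MONTAGE_30.items()}, fh, indent=1)


def read_montage_json(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {resolve_channel(ch): tuple(xy) for ch, xy in raw.items()}
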