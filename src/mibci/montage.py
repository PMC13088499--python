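"""Fixed 24-channel 10-20 montage used by the simulator and spatial heuristics.

Coordinates are schematic 2-D scalp positions (head radius 1, nose up), good
enough for distance weighting of simulated artifact topographies; they are not
digitized electrode locations.
"""

from __future__ import annotations

import numpy as np

# name -> (x, y); x: left(-) to right(+), y: back(-) to front(+)
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.0, 0.58),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.67, 0.28), "FC1": (-0.22, 0.30), "FC2": (0.22, 0.30),
    "FC6": (0.67, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.52, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.52, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.67, -0.28), "CP1": (-0.22, -0.30), "CP2": (0.22, -0.30),
    "CP6": (0.67, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.58),
    "P4": (0.43, -0.55),
}

DEFAULT_CHANNELS: list[str] = list(CHANNEL_POSITIONS)

FRONTAL_REFERENCE = (0.0, 1.0)   # virtual Fpz: blink source
TEMPORAL_LEFT = (-1.0, 0.0)      # muscle-burst sources
TEMPORAL_RIGHT = (1.0, 0.0)


def spatial_weights(channels: list[str], source_xy: tuple[float, float],
                    falloff: float = 0.6) -> np.ndarray:
    """Exponential distance falloff of a scalp source over ``channels``.

    Weight 1 at the source position, exp(-d/falloff) at distance d. Channels
    missing from the montage table get weight 0.
    """
    w = np.zeros(len(channels))
    sx, sy = source_xy
    for i, name in enumerate(channels):
        pos = CHANNEL_POSITIONS.get(name)
        if pos is None:
            continue
        d = float(np.hypot(pos[0] - sx, pos[1] - sy))
        w[i] = np.exp(-d / falloff)
    return w
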