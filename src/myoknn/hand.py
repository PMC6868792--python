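"""Virtual-hand state and ranges of motion.

The controllable plant is a 3-DOF virtual hand: forearm pronation/supination
(0–180 deg), wrist flexion/extension (−60 to 70 deg) and hand open/close
aperture (0–100 %).  DOF order everywhere in this package is
``[pronation, wrist, aperture]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Lower ROM bound per DOF (deg, deg, %).
ROM_MIN = np.array([0.0, -60.0, 0.0])
#: Upper ROM bound per DOF (deg, deg, %).
ROM_MAX = np.array([180.0, 70.0, 100.0])
#: ROM span per DOF.
ROM_SPAN = ROM_MAX - ROM_MIN

DOF_NAMES = ("pronation", "wrist", "aperture")


@dataclass(frozen=True)
class HandState:
    """One posture of the 3-DOF virtual hand.

    Attributes
    ----------
    pronation : float
        Forearm pronation/supination angle in degrees, within [0, 180].
    wrist : float
        Wrist flexion/extension angle in degrees, within [-60, 70].
    aperture : float
        Hand open/close in percent of full aperture, within [0, 100].
    """

    pronation: float
    wrist: float
    aperture: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < ROM_MIN - 1e-9) or np.any(arr > ROM_MAX + 1e-9):
            raise ValueError(
                f"hand state {arr.tolist()} outside ROM "
                f"[{ROM_MIN.tolist()}, {ROM_MAX.tolist()}]"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.pronation, self.wrist, self.aperture], dtype=float)

    @staticmethod
    def from_array(arr) -> "HandState":
        arr = np.asarray(arr, dtype=float)
        return HandState(float(arr[0]), float(arr[1]), float(arr[2]))


def neutral_posture() -> HandState:
    """Midpoint of every ROM: [90 deg, 5 deg, 50 %]."""
    return HandState.from_array((ROM_MIN + ROM_MAX) / 2.0)


def clip_to_rom(arr: np.ndarray) -> np.ndarray:
    """Saturate a raw [pronation, wrist, aperture] vector to the ROM box."""
    return np.clip(np.asarray(arr, dtype=float), ROM_MIN, ROM_MAX)


def to_rom_fraction(arr: np.ndarray) -> np.ndarray:
    """Map physical DOF values to the unit cube (0 = min, 1 = max of ROM)."""
    return (np.asarray(arr, dtype=float) - ROM_MIN) / ROM_SPAN
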