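"""Electrode montages for the standard 10-20 system.

A :class:`Montage` holds channel names, unit-sphere electrode positions and
the pair of mastoid reference labels.  Positions are taken from the template
10-20 layout shipped with MNE-Python and renormalized so every electrode
sits exactly on the unit sphere; only relative angular geometry matters here
(great-circle distances drive bad-channel interpolation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

#: The classic 10-20 scalp set plus Oz (the midline occipital site the ERP
#: analyses report), in cap order.
SCALP_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Default frontal / parieto-occipital channel groups used when injecting
#: and measuring ERP components.
FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
PARIETO_OCCIPITAL = ("P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2")

MASTOIDS = ("M1", "M2")


@dataclass(frozen=True)
class Montage:
    """Channel names, unit-sphere positions and mastoid reference labels."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows
    mastoid_labels: tuple[str, str] = MASTOIDS
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions must be ({len(names)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode positions must have unit norm")
        missing = set(self.mastoid_labels) - set(names)
        if missing:
            raise ValueError(f"mastoid labels {sorted(missing)} not in montage")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in montage; available: "
                f"{list(self.channel_names)}"
            ) from None

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        """Channels entering analyses: everything except the mastoids."""
        return tuple(n for n in self.channel_names if n not in self.mastoid_labels)

    def great_circle_distances(self, name: str) -> np.ndarray:
        """Great-circle distance (radians) from ``name`` to every channel."""
        p = self.positions[self.index(name)]
        cosang = np.clip(self.positions @ p, -1.0, 1.0)
        return np.arccos(cosang)

    def to_json(self, path) -> None:
        payload = {
            "mastoid_labels": list(self.mastoid_labels),
            "positions": {
                n: self.positions[i].tolist()
                for i, n in enumerate(self.channel_names)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        names = tuple(payload["positions"])
        pos = np.array([payload["positions"][n] for n in names], dtype=float)
        return cls(names, pos, tuple(payload["mastoid_labels"]))


def _template_positions(names: tuple[str, ...]) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        tpl = mne.channels.make_standard_montage("standard_1020")
    pos = tpl.get_positions()["ch_pos"]
    out = np.empty((len(names), 3))
    for i, n in enumerate(names):
        v = np.asarray(pos[n], dtype=float)
        out[i] = v / np.linalg.norm(v)
    return out


def standard_montage(
    channels: tuple[str, ...] = SCALP_1020, mastoids: tuple[str, str] = MASTOIDS
) -> Montage:
    """Build the default 10-20 montage (19 scalp channels + both mastoids)."""
    names = tuple(channels) + tuple(m for m in mastoids if m not in channels)
    return Montage(names, _template_positions(names), tuple(mastoids))
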