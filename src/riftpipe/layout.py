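"""64-channel BioSemi layout and the fixed spatial profiles of the simulator.

Channel names and 3-D scalp positions come from MNE's standard ``biosemi64``
montage.  The forward model of the generator is deliberately simple: each
tagged hemifield location projects onto a Gaussian-weighted set of posterior
channels centred lateral to POz in the *contralateral* hemisphere, and alpha
sources project onto left/right parieto-occipital patches (centred near
PO7/PO8).  These profiles are fixed constants of the package, not fitted to
any data.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=1)
def _montage_positions() -> tuple[tuple[str, ...], np.ndarray]:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    names = tuple(pos)
    xyz = np.array([pos[name] for name in names], dtype=float)
    return names, xyz


class ChannelLayout:
    """Names, positions and derived channel groups of the 64-channel cap."""

    def __init__(self) -> None:
        self.names, self.pos = _montage_positions()
        self.n_channels = len(self.names)
        self._index = {name: i for i, name in enumerate(self.names)}

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def x(self) -> np.ndarray:
        """Lateral coordinate (m); > 0 is the right hemisphere."""
        return self.pos[:, 0]

    @property
    def y(self) -> np.ndarray:
        """Anterior-posterior coordinate (m); < 0 is posterior."""
        return self.pos[:, 1]

    def hemisphere(self, name: str) -> str:
        """'left', 'right' or 'midline' based on the lateral coordinate."""
        x = self.x[self.index(name)]
        if abs(x) < 1e-6:
            return "midline"
        return "right" if x > 0 else "left"

    def posterior_channels(self, y_max: float = -0.05) -> list[str]:
        """Parieto-occipital channels (default: y below -5 cm)."""
        return [n for n, y in zip(self.names, self.y) if y < y_max]

    def _gaussian_profile(self, center: np.ndarray, sigma: float) -> np.ndarray:
        d2 = np.sum((self.pos - center) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * sigma**2))

    def tag_profile(self, stimulus_side: str, sigma: float = 0.035) -> np.ndarray:
        """Projection weights (max 1) of the tag at one hemifield location.

        A stimulus in the left hemifield drives the right occipito-parietal
        cortex and vice versa; the profile is centred 3.5 cm lateral to POz
        on the contralateral side.
        """
        poz = self.pos[self.index("POz")]
        shift = 0.035 if stimulus_side == "left" else -0.035
        center = poz + np.array([shift, 0.0, -0.01])
        w = self._gaussian_profile(center, sigma)
        return w / w.max()

    def alpha_profile(self, hemisphere: str, sigma: float = 0.045) -> np.ndarray:
        """Projection weights of the left or right posterior alpha source."""
        anchor = "PO7" if hemisphere == "left" else "PO8"
        center = self.pos[self.index(anchor)]
        w = self._gaussian_profile(center, sigma)
        return w / w.max()
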