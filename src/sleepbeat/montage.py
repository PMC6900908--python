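"""19-channel 10-10 montage and its seven-region grouping.

The analysis aggregates channel band powers into seven scalp regions.  The
midline channels (Fz, Cz, Pz) belong both to their lobe region and to the
Midline region, so the region map is a cover, not a partition.  Hemisphere
sets for the alpha laterality index take only the lateralized members of the
prefrontal + frontal regions; midline channels are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Channel order used throughout (rows of every recording matrix).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Seven scalp regions and their member channels.
REGIONS: dict[str, tuple[str, ...]] = {
    "Prefrontal": ("Fp1", "Fp2", "F7", "F8"),
    "Frontal": ("F3", "Fz", "F4"),
    "Central": ("C3", "Cz", "C4"),
    "Temporal": ("T7", "T8", "P7", "P8"),
    "Parietal": ("P3", "Pz", "P4"),
    "Occipital": ("O1", "O2"),
    "Midline": ("Fz", "Cz", "Pz"),
}

#: Lateralized prefrontal+frontal channels used for the alpha laterality index.
LI_LEFT: tuple[str, ...] = ("Fp1", "F7", "F3")
LI_RIGHT: tuple[str, ...] = ("Fp2", "F8", "F4")


@dataclass(frozen=True)
class Montage:
    """Channel labels plus the region map.

    The default instance is the standard 19-channel layout; a restricted
    montage (fewer channels) can be built with :meth:`subset`, which keeps
    only regions whose members all survive — used by scaled-down simulations.
    """

    channels: tuple[str, ...] = CHANNELS
    regions: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(REGIONS))

    def __post_init__(self) -> None:
        unknown = [c for chs in self.regions.values() for c in chs if c not in self.channels]
        if unknown:
            raise ValueError(f"region channels not in montage: {sorted(set(unknown))}")
        covered = {c for chs in self.regions.values() for c in chs}
        missing = [c for c in self.channels if c not in covered]
        if missing:
            raise ValueError(f"channels not assigned to any region: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def region_indices(self, region: str) -> list[int]:
        return [self.channels.index(c) for c in self.regions[region]]

    def subset(self, channels: tuple[str, ...]) -> "Montage":
        keep = tuple(c for c in self.channels if c in channels)
        regions = {
            name: chs
            for name, chs in self.regions.items()
            if all(c in keep for c in chs)
        }
        return Montage(channels=keep, regions=regions)


def default_montage() -> Montage:
    return Montage()
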