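"""Intraurethral catheter electrode configurations.

Twelve catalogue entries: eight simulated along the whole urethra (monopolar
1 mm and 2 mm rings, a short and a long 90° sector, narrow/wide bipolar
sector pairs, and 1 mm / 2 mm bipolar ring pairs) plus four multi-contact
configurations used in the DNP branch analysis at 2 cm (3- and 5-sector
arrays, 3- and 5-ring arrays).  Ring contacts span the full 360°; sector
contacts are half-shells (180° arc — at 0.5 mm voxels the catheter surface
carries only ~8 angular positions, and a narrower pad would collapse to two
voxels and exaggerate focality) rotated toward the nerves (dorsal) by
default.  Multi-contact arrays use 1 mm contacts at 3.5 mm centre-to-centre
spacing ("spaced 3.5 mm apart"), matching the in vivo 3-ring catheter.

Axial offsets are relative to the configuration centre, which is placed at
the stimulation depth; polarity "cathode" contacts share the (negative)
regulated current, "anode" contacts return it for bipolar configurations.
Monopolar configurations return current through the grounded outer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass


class ElectrodeError(ValueError):
    """Invalid electrode configuration."""


@dataclass(frozen=True)
class Contact:
    """One metal contact on the catheter surface."""

    offset_mm: float  # axial centre, relative to the configuration centre
    length_mm: float
    arc_deg: float  # 360 = full ring
    polarity: str  # cathode | anode | off

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ElectrodeError("contact length must be > 0")
        if not 0 < self.arc_deg <= 360:
            raise ElectrodeError("contact arc must be in (0, 360] degrees")
        if self.polarity not in ("cathode", "anode", "off"):
            raise ElectrodeError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class ElectrodeConfig:
    """A named set of contacts."""

    name: str
    contacts: tuple[Contact, ...]

    def __post_init__(self):
        if not any(c.polarity == "cathode" for c in self.contacts):
            raise ElectrodeError("configuration needs at least one cathode")
        # contacts must not overlap axially within the same angular sector
        spans = [
            (c.offset_mm - c.length_mm / 2, c.offset_mm + c.length_mm / 2)
            for c in self.contacts
            if c.polarity != "off"
        ]
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if b0 < a1 - 1e-9:
                raise ElectrodeError(f"{self.name}: contacts overlap axially")

    @property
    def is_bipolar(self) -> bool:
        return any(c.polarity == "anode" for c in self.contacts)

    @property
    def is_rotationally_symmetric(self) -> bool:
        return all(c.arc_deg >= 360 for c in self.contacts if c.polarity != "off")

    @property
    def span_mm(self) -> float:
        lo = min(c.offset_mm - c.length_mm / 2 for c in self.contacts)
        hi = max(c.offset_mm + c.length_mm / 2 for c in self.contacts)
        return hi - lo


def _rings(n: int, length: float, pitch: float, polarity: str = "cathode"):
    start = -pitch * (n - 1) / 2
    return tuple(
        Contact(start + k * pitch, length, 360.0, polarity) for k in range(n)
    )


def _sectors(n: int, length: float, pitch: float, arc: float = 180.0):
    start = -pitch * (n - 1) / 2
    return tuple(
        Contact(start + k * pitch, length, arc, "cathode") for k in range(n)
    )


def _bipolar(length: float, gap: float, arc: float):
    pitch = length + gap
    return (
        Contact(-pitch / 2, length, arc, "cathode"),  # distal cathode
        Contact(+pitch / 2, length, arc, "anode"),
    )


# pitch of the multi-contact arrays: contacts "spaced 3.5 mm apart" read as
# centre-to-centre spacing, matching the in vivo 3-ring catheter
_PITCH = 3.5

CATALOGUE: dict[str, ElectrodeConfig] = {
    cfg.name: cfg
    for cfg in [
        ElectrodeConfig("ring-1mm", _rings(1, 1.0, _PITCH)),
        ElectrodeConfig("ring-2mm", _rings(1, 2.0, _PITCH)),
        ElectrodeConfig("short", _sectors(1, 1.0, _PITCH)),
        ElectrodeConfig("long", _sectors(1, 4.0, _PITCH)),
        ElectrodeConfig("bipolar-narrow", _bipolar(1.0, 1.0, 180.0)),
        ElectrodeConfig("bipolar-wide", _bipolar(1.0, 4.0, 180.0)),
        ElectrodeConfig("bipolar-ring-1mm", _bipolar(1.0, 2.0, 360.0)),
        ElectrodeConfig("bipolar-ring-2mm", _bipolar(2.0, 2.0, 360.0)),
        ElectrodeConfig("3-contact", _sectors(3, 1.0, _PITCH)),
        ElectrodeConfig("5-contact", _sectors(5, 1.0, _PITCH)),
        ElectrodeConfig("3-ring", _rings(3, 1.0, _PITCH)),
        ElectrodeConfig("5-ring", _rings(5, 1.0, _PITCH)),
    ]
}

#: the eight configurations swept over 1-7 cm
SWEEP_CONFIGS: tuple[str, ...] = (
    "ring-1mm",
    "ring-2mm",
    "short",
    "long",
    "bipolar-narrow",
    "bipolar-wide",
    "bipolar-ring-1mm",
    "bipolar-ring-2mm",
)

#: all twelve, used in the branch Monte-Carlo at 2 cm
BRANCH_CONFIGS: tuple[str, ...] = SWEEP_CONFIGS + (
    "3-contact",
    "5-contact",
    "3-ring",
    "5-ring",
)


def get_config(name: str | ElectrodeConfig) -> ElectrodeConfig:
    if isinstance(name, ElectrodeConfig):
        return name
    try:
        return CATALOGUE[name]
    except KeyError:
        raise ElectrodeError(
            f"unknown electrode configuration {name!r}; "
            f"known: {sorted(CATALOGUE)}"
        ) from None
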