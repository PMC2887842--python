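"""Tissue electrical conductivities for the urethral volume-conductor model.

All tissues are isotropic.  Values are the literature conductivities used for
the male cat lower urinary tract: skeletal/urethral muscle 0.291 S/m,
erectile tissue (corpus cavernosum/spongiosum) 0.6 S/m, glandular tissue
0.4 S/m, connective tissue and the surrounding bath 0.05 S/m, and a
practically insulating catheter body at 0.1 nS/m.  Urine (1.55 S/m) appears
only in the shrunk-catheter perturbation study, where the annular gap between
a half-diameter catheter and the urethral wall is fluid-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: tissue-class -> conductivity (S/m)
_DEFAULTS: dict[str, float] = {
    "Urethral catheter": 1e-10,  # 0.1 nS/m
    "Muscle tissue": 0.291,
    "Erectile tissue": 0.6,
    "Glands": 0.4,
    "Connective tissue": 0.05,
    "urine": 1.55,
    "bath": 0.05,
}

#: anatomical compartment -> tissue class
COMPARTMENT_CLASS: Mapping[str, str] = MappingProxyType(
    {
        "catheter": "Urethral catheter",
        "inner urethral muscle": "Muscle tissue",
        "outer urethral muscle": "Muscle tissue",
        "bulbospongiosus muscle": "Muscle tissue",
        "ischiocavernosus muscle": "Muscle tissue",
        "corpus spongiosum": "Erectile tissue",
        "corpus cavernosum": "Erectile tissue",
        "bulbocavernosus glands": "Glands",
        "prostate": "Glands",
        "prepuce": "Connective tissue",
        "bath": "bath",
        "urine": "urine",
    }
)


class ConductivityError(ValueError):
    """Unknown compartment/class name or non-positive conductivity."""


@dataclass(frozen=True)
class ConductivityTable:
    """Map from tissue class to isotropic conductivity (S/m)."""

    entries: Mapping[str, float]

    def __post_init__(self):
        for name, sigma in self.entries.items():
            if name not in _DEFAULTS:
                raise ConductivityError(f"unknown tissue class: {name!r}")
            if not sigma > 0:
                raise ConductivityError(
                    f"conductivity for {name!r} must be > 0, got {sigma}"
                )
        missing = set(_DEFAULTS) - set(self.entries)
        if missing:
            raise ConductivityError(f"missing tissue classes: {sorted(missing)}")
        object.__setattr__(self, "entries", MappingProxyType(dict(self.entries)))

    def __getitem__(self, tissue_class: str) -> float:
        return self.entries[tissue_class]

    def for_compartment(self, compartment: str) -> float:
        """Conductivity of a named anatomical compartment."""
        try:
            return self.entries[COMPARTMENT_CLASS[compartment]]
        except KeyError:
            raise ConductivityError(f"unknown compartment: {compartment!r}") from None


def build_conductivity_table(
    overrides: Mapping[str, float] | None = None,
) -> ConductivityTable:
    """The default conductivity table with optional per-class overrides.

    ``overrides`` may be keyed by tissue class ("Muscle tissue", ...) or by
    compartment name ("prostate", ...); compartment keys override the class
    the compartment belongs to.
    """
    entries = dict(_DEFAULTS)
    for name, sigma in (overrides or {}).items():
        key = name if name in entries else COMPARTMENT_CLASS.get(name)
        if key is None:
            raise ConductivityError(f"unknown compartment or tissue class: {name!r}")
        if not sigma > 0:
            raise ConductivityError(f"conductivity for {name!r} must be > 0")
        entries[key] = float(sigma)
    return ConductivityTable(entries)
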