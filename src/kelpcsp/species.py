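"""Species codes for the three Northeast Atlantic *Laminaria* kelps.

Two cold-temperate species (*L. digitata*, *L. hyperborea*) and one
warm-temperate species (*L. ochroleuca*) co-occur in the study system.
*L. digitata* occupies the upper ~20% of the vertical forest band
(lower eulittoral); the other two share the lower ~80% (upper
infralittoral), which is where the default zone weights come from.
"""

from __future__ import annotations

import enum


class Species(str, enum.Enum):
    DIGITATA = "digitata"
    HYPERBOREA = "hyperborea"
    OCHROLEUCA = "ochroleuca"

    @property
    def thermal_affinity(self) -> str:
        """'cold' for the boreal species, 'warm' for *L. ochroleuca*."""
        return "warm" if self is Species.OCHROLEUCA else "cold"

    @property
    def zone_weight(self) -> float:
        """Default proportion of the vertical forest band occupied."""
        return 0.2 if self is Species.DIGITATA else 0.8

    @classmethod
    def parse(cls, value: "str | Species") -> "Species":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("l. ", "").replace("laminaria ", "")
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown species code: {value!r}") from None


ALL_SPECIES = (Species.DIGITATA, Species.HYPERBOREA, Species.OCHROLEUCA)
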