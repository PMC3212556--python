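"""Provisioning arithmetic: arthropod biomass a nesting pair must deliver.

A brood of five nestlings needs about 78 g of arthropods per day (each
nestling burns roughly 65 kJ/day at 9-12 days old), and each adult needs
about 23 g/day on top of that, so a pair with a full brood of five
consumes 78 + 2 x 23 = 124 g of arthropods daily.  The requirement is
linear: per-nestling mass is brood5_mass / 5 = 15.6 g/day.  The kJ figure
is carried as metadata only; no energy-to-mass conversion is exposed.
"""

from __future__ import annotations

import dataclasses

__all__ = ["EnergeticsParams", "daily_requirement"]


@dataclasses.dataclass(frozen=True)
class EnergeticsParams:
    nestling_energy_kj: float = 65.0   # metadata: kJ/day per mid-age nestling
    brood5_mass_g: float = 78.0        # g/day delivered to a brood of five
    adult_mass_g: float = 23.0         # g/day per adult

    def __post_init__(self) -> None:
        if min(self.nestling_energy_kj, self.brood5_mass_g, self.adult_mass_g) <= 0:
            raise ValueError("all energetics parameters must be positive")

    @property
    def per_nestling_mass_g(self) -> float:
        return self.brood5_mass_g / 5.0


def daily_requirement(n_nestlings: int, n_adults: int,
                      params: EnergeticsParams = EnergeticsParams()) -> float:
    """Grams of arthropods per day for a nest with the given occupants."""
    if n_nestlings < 0 or n_adults < 0:
        raise ValueError("occupant counts must be non-negative")
    return params.per_nestling_mass_g * n_nestlings + params.adult_mass_g * n_adults
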