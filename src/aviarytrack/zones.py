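"""Aviary zones and their adjacency structure.

A commercial multi-tier aviary pen is divided into five functional zones:
three stacked tiers (top tier, nest box, lower tier), the littered floor
underneath, and a covered outdoor winter garden reachable from the litter
through a pop hole.  Hens move between vertically or horizontally bordering
zones only, so the zone graph is the path

    TOP_TIER — NEST_BOX — LOWER_TIER — LITTER — WINTER_GARDEN
"""

from __future__ import annotations

from enum import Enum


class Zone(str, Enum):
    """One of the five aviary zones."""

    TOP_TIER = "TOP_TIER"
    NEST_BOX = "NEST_BOX"
    LOWER_TIER = "LOWER_TIER"
    LITTER = "LITTER"
    WINTER_GARDEN = "WINTER_GARDEN"

    def __str__(self) -> str:  # plain value in CSV / repr contexts
        return self.value


#: Canonical zone order, top of the aviary to the outside.
ZONES: tuple[Zone, ...] = (
    Zone.TOP_TIER,
    Zone.NEST_BOX,
    Zone.LOWER_TIER,
    Zone.LITTER,
    Zone.WINTER_GARDEN,
)

#: Stable integer code per zone (index into ZONES).
ZONE_INDEX: dict[Zone, int] = {z: i for i, z in enumerate(ZONES)}

#: Zone adjacency: the path graph along the aviary cross-section.
ADJACENCY: dict[Zone, tuple[Zone, ...]] = {
    Zone.TOP_TIER: (Zone.NEST_BOX,),
    Zone.NEST_BOX: (Zone.TOP_TIER, Zone.LOWER_TIER),
    Zone.LOWER_TIER: (Zone.NEST_BOX, Zone.LITTER),
    Zone.LITTER: (Zone.LOWER_TIER, Zone.WINTER_GARDEN),
    Zone.WINTER_GARDEN: (Zone.LITTER,),
}


def are_adjacent(a: Zone | str, b: Zone | str) -> bool:
    """True if a hen can move directly between zones ``a`` and ``b``."""
    return Zone(b) in ADJACENCY[Zone(a)]


def as_zone(value: Zone | str) -> Zone:
    """Coerce a string or Zone to a Zone, raising ValueError otherwise."""
    return Zone(value)
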