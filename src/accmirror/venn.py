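"""Three-set Venn bookkeeping for the mirror taxonomy.

Channels/cells are classified by which of three contrasts reach
significance: *social* (HighShockObs > CtrlShockObs), *laser*
(HighLaser > CtrlLaser), and *cs* (CS > baseline). The seven exclusive
regions of the resulting Venn diagram are the common currency of the
channel- and cell-level analyses; "mirror" means social AND (laser OR cs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("s", "l", "c", "sl", "sc", "lc", "slc")


@dataclass
class VennCounts:
    """Exclusive counts of the 7 regions of the social/laser/cs Venn.

    Region keys: "s", "l", "c" (exactly one contrast), "sl", "sc", "lc"
    (exactly two), "slc" (all three). ``n_responsive`` is the number of
    units that passed the responsiveness screen (it may exceed the region
    sum when responsive units fall in no region).
    """

    regions: dict[str, int] = field(default_factory=lambda: dict.fromkeys(REGIONS, 0))
    n_responsive: int = 0

    def __post_init__(self) -> None:
        for k in REGIONS:
            self.regions.setdefault(k, 0)
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown Venn regions: {sorted(unknown)}")
        if any(v < 0 for v in self.regions.values()):
            raise ValueError("region counts must be non-negative")

    # -- inclusive set sizes -------------------------------------------
    @property
    def social(self) -> int:
        r = self.regions
        return r["s"] + r["sl"] + r["sc"] + r["slc"]

    @property
    def laser(self) -> int:
        r = self.regions
        return r["l"] + r["sl"] + r["lc"] + r["slc"]

    @property
    def cs(self) -> int:
        r = self.regions
        return r["c"] + r["sc"] + r["lc"] + r["slc"]

    @property
    def social_and_laser(self) -> int:
        return self.regions["sl"] + self.regions["slc"]

    @property
    def social_and_cs(self) -> int:
        return self.regions["sc"] + self.regions["slc"]

    @property
    def all_three(self) -> int:
        return self.regions["slc"]

    # -- mirror taxonomy ----------------------------------------------
    @property
    def mirror(self) -> int:
        """social AND (laser OR cs) = |s∩l| + |s∩c| − |s∩l∩c|."""
        return self.social_and_laser + self.social_and_cs - self.all_three

    @property
    def pain_mirror(self) -> int:
        """social AND laser AND NOT cs."""
        return self.regions["sl"]

    @property
    def fear_mirror(self) -> int:
        """social AND cs AND NOT laser."""
        return self.regions["sc"]

    @property
    def unselective_mirror(self) -> int:
        """social AND laser AND cs."""
        return self.regions["slc"]

    def mirror_share(self) -> float:
        """Fraction of social units with mirror properties."""
        return self.mirror / self.social if self.social else np.nan

    def selective_share(self) -> float:
        """Fraction of responsive units that are selective (pain or fear) mirrors."""
        if not self.n_responsive:
            return np.nan
        return (self.pain_mirror + self.fear_mirror) / self.n_responsive

    def as_vector(self) -> np.ndarray:
        return np.array([self.regions[k] for k in REGIONS], dtype=float)

    def to_dict(self) -> dict:
        return {
            "regions": dict(self.regions),
            "n_responsive": self.n_responsive,
            "mirror": self.mirror,
            "pain_mirror": self.pain_mirror,
            "fear_mirror": self.fear_mirror,
            "unselective_mirror": self.unselective_mirror,
        }

    @classmethod
    def from_intersections(
        cls,
        social: int,
        laser: int,
        cs: int,
        social_laser: int,
        social_cs: int,
        laser_cs: int,
        all_three: int,
        n_responsive: int | None = None,
    ) -> "VennCounts":
        """Build from inclusive set and pairwise-intersection sizes."""
        regions = {
            "slc": all_three,
            "sl": social_laser - all_three,
            "sc": social_cs - all_three,
            "lc": laser_cs - all_three,
        }
        regions["s"] = social - regions["sl"] - regions["sc"] - all_three
        regions["l"] = laser - regions["sl"] - regions["lc"] - all_three
        regions["c"] = cs - regions["sc"] - regions["lc"] - all_three
        return cls(regions=regions, n_responsive=n_responsive or sum(regions.values()))

    @classmethod
    def from_flags(cls, social, laser, cs, responsive=None) -> "VennCounts":
        """Tabulate from per-unit boolean flags (brute-force enumeration)."""
        social = np.asarray(social, dtype=bool)
        laser = np.asarray(laser, dtype=bool)
        cs = np.asarray(cs, dtype=bool)
        responsive = (
            np.ones_like(social) if responsive is None else np.asarray(responsive, bool)
        )
        s, l, c = social & responsive, laser & responsive, cs & responsive
        regions = {
            "s": int(np.sum(s & ~l & ~c)),
            "l": int(np.sum(~s & l & ~c)),
            "c": int(np.sum(~s & ~l & c)),
            "sl": int(np.sum(s & l & ~c)),
            "sc": int(np.sum(s & ~l & c)),
            "lc": int(np.sum(~s & l & c)),
            "slc": int(np.sum(s & l & c)),
        }
        return cls(regions=regions, n_responsive=int(responsive.sum()))
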