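"""Retention-index calibration against an n-alkane ladder.

Under a linear temperature program the retention index of a compound is
interpolated linearly in retention time between the bracketing n-alkanes
(van den Dool-Kratz convention); the alkane with n carbons defines
RI = 100 n.  Outside the ladder the terminal segment is extrapolated and
the result flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = ["AlkaneLadder", "RIValue", "compute_ri", "delta_ri", "read_ladder"]


@dataclass(frozen=True)
class RIValue:
    ri: float
    extrapolated: bool = False


class AlkaneLadder:
    """Sorted (carbon_number, rt_min) anchors; rt strictly increasing."""

    def __init__(self, anchors: Sequence[tuple[int, float]]):
        pts = sorted((int(c), float(rt)) for c, rt in anchors)
        if len(pts) < 2:
            raise ValueError("an alkane ladder needs at least two anchors")
        carbons = [c for c, _ in pts]
        rts = [rt for _, rt in pts]
        if len(set(carbons)) != len(carbons):
            raise ValueError("duplicate carbon numbers in ladder")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must increase strictly with carbon number")
        if carbons[0] < 1:
            raise ValueError("carbon numbers must be positive")
        self.carbons = carbons
        self.rts = rts

    def __len__(self) -> int:
        return len(self.carbons)

    @classmethod
    def merge(cls, *ladders: "AlkaneLadder") -> "AlkaneLadder":
        """Union of anchors; shared carbon numbers must agree in rt."""
        seen: dict[int, float] = {}
        for lad in ladders:
            for c, rt in zip(lad.carbons, lad.rts):
                if c in seen and abs(seen[c] - rt) > 1e-9:
                    raise ValueError(f"conflicting rt for C{c} across ladders")
                seen[c] = rt
        return cls(sorted(seen.items()))


def read_ladder(path: str | Path) -> AlkaneLadder:
    """Read a 2-column CSV (carbon_number, rt_min)."""
    df = pd.read_csv(path)
    required = {"carbon_number", "rt_min"}
    if not required <= set(df.columns):
        raise ValueError(f"ladder file must have columns {sorted(required)}")
    return AlkaneLadder(list(zip(df["carbon_number"], df["rt_min"])))


def compute_ri(rt: float, ladder: AlkaneLadder) -> RIValue:
    """Linear (temperature-programmed) retention index at retention time rt.

    Between anchors n and m (m the next alkane above n):
    RI = 100 n + 100 (m - n) (rt - rt_n) / (rt_m - rt_n).
    Beyond either end the terminal anchor pair is extrapolated linearly and
    the value is flagged ``extrapolated``.
    """
    c, t = ladder.carbons, ladder.rts
    if rt < t[0]:
        lo, hi, extrapolated = 0, 1, True
    elif rt > t[-1]:
        lo, hi, extrapolated = len(t) - 2, len(t) - 1, True
    else:
        # rightmost segment whose left anchor rt <= rt
        lo = max(i for i in range(len(t) - 1) if t[i] <= rt)
        hi, extrapolated = lo + 1, False
    ri = 100.0 * c[lo] + 100.0 * (c[hi] - c[lo]) * (rt - t[lo]) / (t[hi] - t[lo])
    return RIValue(ri=ri, extrapolated=extrapolated)


def delta_ri(calculated: RIValue, library_ri: Optional[float]) -> Optional[float]:
    """|calculated - library| RI units, or None when no library RI exists.

    A missing library RI makes the retention-index criterion vacuous: the
    candidate is then judged on the remaining criteria alone.
    """
    if library_ri is None:
        return None
    return abs(calculated.ri - library_ri)
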