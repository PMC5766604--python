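"""Joint-group structure over vectorized trials.

A trial is stored time-major: the hand configuration at time t occupies
positions (t-1)*s + 1 ... t*s (1-based), so the coordinates of a single
joint-angle sensor j are {j, s+j, 2s+j, ...}.  Grouping those coordinates
lets a structured penalty switch whole joints on or off within an atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GroupStructure:
    """Partition of the p = s*len vectorized coordinates into s joint groups.

    ``groups[j]`` holds the 0-based coordinate indices of sensor j; each
    group has exactly ``length`` members and the groups partition range(p).
    """

    s: int
    length: int
    groups: tuple = field(repr=False, default=())

    @property
    def p(self) -> int:
        return self.s * self.length

    def groups_1based(self) -> list[np.ndarray]:
        """The 1-based index view of each group (documentation convention)."""
        return [g + 1 for g in self.groups]


def build_joint_groups(s: int, length: int) -> GroupStructure:
    """Build the s joint groups with stride-s index arithmetic.

    Sensor j (0-based) owns the coordinates j, s+j, 2s+j, ..., (length-1)*s+j.
    """
    if s < 1 or length < 1:
        raise ValueError(f"need s >= 1 and length >= 1, got s={s}, length={length}")
    groups = tuple(np.arange(length) * s + j for j in range(s))
    return GroupStructure(s=s, length=length, groups=groups)
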