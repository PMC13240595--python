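"""Chain roles and region definitions for TCR-pMHC complexes.

A complex is described by up to five chain roles: the TCR alpha and beta
variable domains (``TCRA``, ``TCRB``), the antigenic peptide (``PEPTIDE``)
and the peptide-binding domain(s) of the MHC (``MHC_A`` alone for class I,
``MHC_A`` + ``MHC_B`` for class II).

Regions of interest are expressed as :class:`RegionSpec` objects: either a
whole chain (``ALL`` window) or an inclusive IMGT-number window on a TCR
chain.  The complementarity-determining regions use the standard IMGT
windows by default (CDR1 27-38, CDR2 56-65, CDR3 105-117); the windows are
configurable because numbering conventions occasionally differ between
tools.  ``CDR3`` denotes the union of the alpha- and beta-chain CDR3 loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Tuple


class Role(str, Enum):
    """Chain role within a TCR-pMHC complex."""

    TCRA = "TCRA"
    TCRB = "TCRB"
    PEPTIDE = "PEPTIDE"
    MHC_A = "MHC_A"
    MHC_B = "MHC_B"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TCR_ROLES: Tuple[Role, ...] = (Role.TCRA, Role.TCRB)
MHC_ROLES: Tuple[Role, ...] = (Role.MHC_A, Role.MHC_B)
MANDATORY_ROLES: Tuple[Role, ...] = (Role.TCRA, Role.TCRB, Role.PEPTIDE, Role.MHC_A)

#: Default IMGT windows for the CDR loops (inclusive bounds).
DEFAULT_CDR_WINDOWS: Mapping[str, Tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

#: IMGT positions of the CDR3 key residues used for mutation scanning.
CDR3_KEY_POSITIONS: Tuple[int, int] = (109, 113)


@dataclass(frozen=True)
class Window:
    """One selection window: a whole chain, or an IMGT interval on it."""

    role: Role
    start: Optional[int] = None  # None => whole chain
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValueError("window must set both bounds or neither")
        if self.start is not None and self.start > self.end:  # type: ignore[operator]
            raise ValueError(f"window start {self.start} > end {self.end}")

    @property
    def whole_chain(self) -> bool:
        return self.start is None


@dataclass(frozen=True)
class RegionSpec:
    """A named region: non-empty list of windows."""

    name: str
    windows: Tuple[Window, ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("RegionSpec needs at least one window")

    @property
    def is_cdr(self) -> bool:
        return self.name.startswith("CDR")

    @property
    def roles(self) -> Tuple[Role, ...]:
        seen = []
        for w in self.windows:
            if w.role not in seen:
                seen.append(w.role)
        return tuple(seen)


def default_regions(
    cdr_windows: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> dict[str, RegionSpec]:
    """Build the standard region catalogue.

    Returns specs for CDR1A..CDR3B, the pooled CDR3, and the whole-chain
    TCR / PEPTIDE / MHC regions.  MHC covers both MHC chains; for class I
    complexes the MHC_B window is simply vacuous.
    """
    cw = dict(DEFAULT_CDR_WINDOWS)
    if cdr_windows:
        cw.update(cdr_windows)
    regions: dict[str, RegionSpec] = {}
    for loop in ("CDR1", "CDR2", "CDR3"):
        lo, hi = cw[loop]
        regions[f"{loop}A"] = RegionSpec(f"{loop}A", (Window(Role.TCRA, lo, hi),))
        regions[f"{loop}B"] = RegionSpec(f"{loop}B", (Window(Role.TCRB, lo, hi),))
    lo, hi = cw["CDR3"]
    regions["CDR3"] = RegionSpec(
        "CDR3", (Window(Role.TCRA, lo, hi), Window(Role.TCRB, lo, hi))
    )
    regions["TCR"] = RegionSpec("TCR", (Window(Role.TCRA), Window(Role.TCRB)))
    regions["PEPTIDE"] = RegionSpec("PEPTIDE", (Window(Role.PEPTIDE),))
    regions["MHC"] = RegionSpec("MHC", (Window(Role.MHC_A), Window(Role.MHC_B)))
    return regions
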