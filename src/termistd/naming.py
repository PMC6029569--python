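"""Strain-name grammar for the collection register.

Virus names follow ``P.HHH.L_SITE.DAY.CODE.WELL`` (e.g. ``1.008.O_10N.286.54.E5``)
and host names ``SITE.DAY.CODE.WELL`` (e.g. ``10N.222.45.E8``), where

* ``P`` numbers the plaque isolated from a host,
* ``HHH`` is the opaque zero-padded working id of the host strain,
* ``L`` is the lineage letter (``O`` single lineage; ``A``, ``B``, ... for
  sub-lineages purified from the same plaque; ``X`` technical replicate),
* ``SITE`` encodes year and site (``10N`` = 2010, Nahant),
* ``DAY`` is the ordinal day of sampling,
* ``CODE`` encodes the water-column size fraction and water sample,
* ``WELL`` is the storage well.

The register prints two cosmetic variants that the parser preserves for exact
re-serialization: an optional ``"<Genus> phage "`` prefix and a trailing dot
after the lineage letter (``1.003.O._10N...``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormatError

#: size-fraction code -> pore size in micrometres
CODE_TO_FRACTION_UM = {
    45: 0.2, 46: 0.2, 47: 0.2,
    48: 1.0, 49: 1.0, 50: 1.0,
    51: 5.0, 52: 5.0, 53: 5.0,
    54: 63.0, 55: 63.0, 56: 63.0,
}

#: size-fraction code -> water sample letter.  The printed mapping lists
#: A: 45,51,54 / B: 46,52,55 / C: 47,53,56; the 1-um codes 48-50 follow the
#: same first/second/third-of-triple pattern and are mapped accordingly.
CODE_TO_SAMPLE = {c: "ABC"[(c - 45) % 3] for c in CODE_TO_FRACTION_UM}

_VIRUS_RE = re.compile(
    r"^(?:(?P<prefix>[A-Za-z]+ phage) )?"
    r"(?P<plaque>\d+)\.(?P<host>\d+)\.(?P<lineage>[A-Z])(?P<ldot>\.)?"
    r"_(?P<site>\d+[A-Z])\.(?P<day>\d+)\.(?P<code>\d+)\.(?P<well>[A-H]\d+)$"
)
_HOST_RE = re.compile(
    r"^(?P<site>\d+[A-Z])\.(?P<day>\d+)\.(?P<code>\d+)\.(?P<well>[A-H]\d+)$"
)


@dataclass
class StrainName:
    """Decomposed strain identifier (virus or host)."""

    year_site: str
    ordinal_day: int
    size_fraction_code: int
    well: str
    # virus-only components (None for host names)
    plaque_id: int | None = None
    host_working_id: str | None = None
    lineage: str | None = None
    # cosmetic variants preserved for byte-exact round-trips
    prefix: str | None = None
    lineage_trailing_dot: bool = False
    # derived
    size_fraction_um: float = field(init=False)
    water_sample: str = field(init=False)

    def __post_init__(self) -> None:
        code = self.size_fraction_code
        if code not in CODE_TO_FRACTION_UM:
            raise FormatError(f"unknown size-fraction code {code}")
        if not 1 <= self.ordinal_day <= 366:
            raise FormatError(f"ordinal day {self.ordinal_day} outside [1, 366]")
        self.size_fraction_um = CODE_TO_FRACTION_UM[code]
        self.water_sample = CODE_TO_SAMPLE[code]

    @property
    def is_virus(self) -> bool:
        return self.plaque_id is not None

    def __str__(self) -> str:
        tail = f"{self.year_site}.{self.ordinal_day}.{self.size_fraction_code}.{self.well}"
        if not self.is_virus:
            return tail
        dot = "." if self.lineage_trailing_dot else ""
        name = f"{self.plaque_id}.{self.host_working_id}.{self.lineage}{dot}_{tail}"
        return f"{self.prefix} {name}" if self.prefix else name


def parse_strain_name(name: str) -> StrainName:
    """Parse a virus or host strain name; raises :class:`FormatError`.

    ``str()`` of the result reproduces the input exactly.
    """
    m = _VIRUS_RE.match(name)
    if m:
        return StrainName(
            year_site=m["site"],
            ordinal_day=int(m["day"]),
            size_fraction_code=int(m["code"]),
            well=m["well"],
            plaque_id=int(m["plaque"]),
            host_working_id=m["host"],
            lineage=m["lineage"],
            prefix=m["prefix"],
            lineage_trailing_dot=m["ldot"] is not None,
        )
    m = _HOST_RE.match(name)
    if m:
        return StrainName(
            year_site=m["site"],
            ordinal_day=int(m["day"]),
            size_fraction_code=int(m["code"]),
            well=m["well"],
        )
    raise FormatError(f"malformed strain name {name!r}")
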