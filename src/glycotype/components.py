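"""Glycan array component taxonomy.

Each array feature is a neoglycoprotein: a blood-group glycan determinant
(A, B, H or something else entirely, e.g. the Forssman disaccharide)
presented on a carrier chain of type 1-6, through a chemical linker
(``Oct`` or ``Sp``), at a given average glycan density per carrier
molecule.  Densities below 8 glycans/carrier are conventionally "low
density"; 8 and above are "high density".

Component names are treated as opaque keys when matching typing methods
against profile matrices (exact string match after whitespace stripping);
parsing only extracts structured covariates for ranking and simulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Determinant(str, Enum):
    A = "A"
    B = "B"
    H = "H"
    OTHER = "other"


class Linker(str, Enum):
    OCT = "Oct"
    SP = "Sp"
    OTHER = "other"


class DensityClass(str, Enum):
    LOW = "low"
    HIGH = "high"


#: densities strictly below this average number of glycans per carrier
#: protein are classed as low density
LOW_DENSITY_CUTOFF = 8.0


def normalize_name(name: str) -> str:
    """Canonicalise a component name for exact-key matching.

    Printed component tables contain spacing variants such as
    ``"BG-B2-Sp - 05"`` for ``"BG-B2-Sp-05"``; matching is case-sensitive
    but insensitive to whitespace around hyphens and to repeated spaces.
    """
    collapsed = " ".join(str(name).split())
    return re.sub(r"\s*-\s*", "-", collapsed)


@dataclass(frozen=True)
class GlycanComponent:
    """One array feature (a neoglycoprotein spot family).

    Attributes
    ----------
    name:
        Verbatim component identifier (whitespace-stripped), the join key
        used everywhere else in the package.
    determinant:
        Blood-group determinant class carried by the glycan.
    chain_type:
        Carrier chain type 1-6 when the name encodes one.
    linker:
        Conjugation linker.
    density:
        Average glycans per carrier protein, when encoded in the name.
    """

    name: str
    determinant: Determinant = Determinant.OTHER
    chain_type: Optional[int] = None
    linker: Linker = Linker.OTHER
    density: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chain_type is not None and self.chain_type not in range(1, 7):
            raise ValueError(
                f"chain_type must be in 1..6, got {self.chain_type!r}"
            )

    @property
    def density_class(self) -> Optional[DensityClass]:
        if self.density is None:
            return None
        return (
            DensityClass.LOW
            if self.density < LOW_DENSITY_CUTOFF
            else DensityClass.HIGH
        )


# Canonical pattern: BG-<det><chain>-<linker>-<density>, tolerating the
# spacing variants that occur in printed component tables
# (e.g. "BG-B2-Sp - 05").  Globo A/B, 2'F-A/B and A-LeB entries carry an
# A/B determinant without the BG- prefix.
_BG_RE = re.compile(
    r"""^BG-(?P<det>[ABH])(?P<chain>[1-6])?(?:_?(?P<suffix>tri|penta|hexa)_?)?
        \s*-?\s*(?:(?P<linker>Oct|Sp)\s*-?\s*)?
        (?P<density>\d+(?:\.\d+)?)?\s*$""",
    re.VERBOSE,
)
_GLOBO_RE = re.compile(
    r"^Globo\s*(?P<det>[AB])\s*-\s*(?P<density>\d+(?:\.\d+)?)\s*$"
)
_2F_RE = re.compile(
    r"""^2[′']F-(?P<det>[AB])\s*type\s*(?P<chain>[1-6])
        \s*-\s*(?P<linker>Oct|Sp)\s*-\s*(?P<density>\d+(?:\.\d+)?)\s*$""",
    re.VERBOSE,
)
_ALEB_RE = re.compile(
    r"^(?P<det>A)-LeB\s*\w*\s*-\s*(?P<density>\d+(?:\.\d+)?)\s*$"
)


def parse_component_name(name: str) -> GlycanComponent:
    """Parse an array component name into structured covariates.

    Total and deterministic: any name that does not follow a recognised
    blood-group naming pattern falls back to ``determinant=other`` with
    the structural fields absent; parsing never raises on content.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValueError("component name must be non-empty text")
    clean = normalize_name(name)

    m = _BG_RE.match(clean)
    if m:
        chain = m.group("chain")
        density = m.group("density")
        linker = m.group("linker")
        return GlycanComponent(
            name=clean,
            determinant=Determinant(m.group("det")),
            chain_type=int(chain) if chain else None,
            linker=Linker(linker) if linker else Linker.OTHER,
            density=float(density) if density is not None else None,
        )
    for pattern, default_linker in (
        (_GLOBO_RE, Linker.OTHER),
        (_2F_RE, None),
        (_ALEB_RE, Linker.OTHER),
    ):
        m = pattern.match(clean)
        if m:
            groups = m.groupdict()
            linker = groups.get("linker")
            chain = groups.get("chain")
            return GlycanComponent(
                name=clean,
                determinant=Determinant(groups["det"]),
                chain_type=int(chain) if chain else None,
                linker=Linker(linker) if linker else default_linker or Linker.OTHER,
                density=float(groups["density"]),
            )
    return GlycanComponent(name=clean)


#: The ten components of the two-stage flow-chart typing method: anti-A
#: evidence is the average IgG over four A glycans plus IgM on one A
#: component; anti-B evidence is the mirror-image set.
FLOWCHART_A_IGG = (
    "BG-A2-Sp-17",
    "BG-A2-Oct-16",
    "BG-A3-Oct-14",
    "Globo A-09",
)
FLOWCHART_A_IGM = "BG-A2-Sp-17"
FLOWCHART_B_IGG = (
    "BG-B2-Sp-20",
    "BG-B2-Oct-17",
    "BG-B3-Oct-17",
    "Globo B-12",
)
FLOWCHART_B_IGM = "BG-B2-Sp-05"

#: Published component listings disagree on one quadruplet member
#: (BG-A2-Oct-16 vs BG-A2-Oct-17); the -16 reading is canonical here and
#: supplying the variant emits a warning (see typing module).
FLOWCHART_NAME_VARIANTS = {"BG-A2-Oct-17": "BG-A2-Oct-16"}


def default_components() -> list[GlycanComponent]:
    """A compact default component panel for simulation and examples.

    Contains the ten flow-chart components, the A/B trisaccharides, an H
    determinant and the Forssman disaccharide.
    """
    names = sorted(
        {
            *FLOWCHART_A_IGG,
            FLOWCHART_A_IGM,
            *FLOWCHART_B_IGG,
            FLOWCHART_B_IGM,
            "BG-A_tri_-19",
            "BG-B_tri_-13",
            "BG-H2-Oct-15",
            "Forssman-di",
        }
    )
    return [parse_component_name(n) for n in names]
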