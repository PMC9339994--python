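"""Core domain types shared across the pipeline.

The experimental unit is a jar of calcareous soil (0.25 kg dry weight)
incubated 118 days at 25 deg C under one of four amendment treatments:

* ``Control`` -- fertilizer only,
* ``W``       -- wood ash, 12 g per kg dry soil,
* ``S``       -- wheat straw, 10 g per kg dry soil,
* ``SW``      -- both amendments combined.

All treatments receive the same mineral fertilization (159 mg N and
185 mg P2O5 per kg dry soil). Wheat straw is a C3 material
(delta-13C approx. -27.5 permil) added to a soil developed under long-term
C4 (maize) cropping (delta-13C approx. -19.5 permil); that isotopic contrast
is what makes two-end-member source partitioning possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TREATMENTS",
    "TreatmentSpec",
    "EndMembers",
    "default_treatments",
    "SOC_INITIAL",
]

#: Canonical treatment order used for tables, letters and tie-breaks.
TREATMENTS = ("Control", "W", "S", "SW")

#: Pre-incubation soil organic carbon, g C per kg dry soil.
SOC_INITIAL = 8.9


@dataclass(frozen=True)
class TreatmentSpec:
    """One amendment treatment: doses of straw and wood ash plus fertilizer.

    Parameters
    ----------
    code : str
        One of ``Control``, ``W``, ``S``, ``SW``.
    straw_dose : float
        Wheat straw added, g per kg dry soil.
    ash_dose : float
        Wood ash added, g per kg dry soil.
    n_fert, p_fert : float
        Mineral N (mg N per kg soil) and P (mg P2O5 per kg soil).
    """

    code: str
    straw_dose: float = 0.0
    ash_dose: float = 0.0
    n_fert: float = 159.0
    p_fert: float = 185.0

    def __post_init__(self) -> None:
        if self.code not in TREATMENTS:
            raise ValueError(f"unknown treatment code {self.code!r}; expected one of {TREATMENTS}")
        if self.straw_dose < 0 or self.ash_dose < 0:
            raise ValueError("amendment doses must be nonnegative")
        if self.code == "Control" and (self.straw_dose or self.ash_dose):
            raise ValueError("Control treatment carries no amendments")

    @property
    def has_straw(self) -> bool:
        return self.straw_dose > 0

    @property
    def has_ash(self) -> bool:
        return self.ash_dose > 0


def default_treatments() -> list[TreatmentSpec]:
    """The 2 x 2 factorial design: straw (0 / 10 g kg-1) x ash (0 / 12 g kg-1)."""
    return [
        TreatmentSpec("Control"),
        TreatmentSpec("W", ash_dose=12.0),
        TreatmentSpec("S", straw_dose=10.0),
        TreatmentSpec("SW", straw_dose=10.0, ash_dose=12.0),
    ]


@dataclass(frozen=True)
class EndMembers:
    """Isotopic end members and C contents of soil, straw and wood ash.

    ``delta_soc_b`` is the baseline (pre-incubation) soil organic carbon
    delta-13C; ``delta_straw`` / ``delta_ash`` are the amendment signatures.
    ``straw_c_content`` and ``ash_organic_c`` are organic-C contents of the
    dry amendments (g C per kg material); the organic pool is what enters the
    isotope mixing calculation. ``ash_sic`` is the carbonate carbon the ash
    dose contributes directly to the soil inorganic pool (mg C per kg soil)
    and is excluded from organic mixing but subtracted in the SIC balance.
    """

    delta_soc_b: float = -19.5
    delta_straw: float = -27.5
    delta_ash: float = -26.4
    straw_c_content: float = 456.1
    ash_organic_c: float = 3.2
    ash_sic: float = 432.0
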