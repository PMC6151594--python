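"""Domain types, constants, and batch-design vocabulary for wine ICP-MS profiling.

This module fixes the shared vocabulary of the pipeline: the registry of the 43
monitored isotope channels with their collision/reaction-cell acquisition
modes, the four sample-preparation methods and their dilution factors, the
internal-standard channels, natural isotopic-abundance constants for the
multi-isotope analytes (Cu, Pb), and the record types that every downstream
stage consumes.

Concentrations are in µg/L throughout; masses of solutions in g (density
taken as 1 g/mL, so gravimetric mass ratios equal volume ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "IsotopeChannel",
    "PrepMethod",
    "SampleMeta",
    "MeasurementRecord",
    "IDParams",
    "DetectionLimits",
    "default_channels",
    "channel_mode",
    "channel_abundance",
    "internal_standard_for",
    "dilution_factor",
    "DILUTION_FACTORS",
    "WINES",
    "METHODS",
    "DIRECT_METHODS",
    "ROLES",
    "CU_B63",
    "CU_B65",
    "ATOMIC_WEIGHT_CU",
    "ATOMIC_MASS_CU63",
    "ATOMIC_MASS_CU65",
    "VinomicsError",
    "UnknownMethodError",
    "InstrumentFaultError",
    "DegenerateDesignError",
    "SingularityError",
    "UnbalancedDesignError",
    "MissingDataError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class VinomicsError(Exception):
    """Base class for all package errors."""


class UnknownMethodError(VinomicsError, ValueError):
    """An unrecognised sample-preparation method code."""


class InstrumentFaultError(VinomicsError, ValueError):
    """A physically impossible instrument reading (e.g. nonpositive IS signal)."""


class DegenerateDesignError(VinomicsError, ValueError):
    """A calibration or statistical design with no usable information."""


class SingularityError(VinomicsError, ZeroDivisionError):
    """The isotope-dilution mixing equation is at its pole."""


class UnbalancedDesignError(VinomicsError, ValueError):
    """The factorial layout required for the balanced ANOVA is violated."""


class MissingDataError(VinomicsError, ValueError):
    """A required input block (blanks, calibration level, LOD) is absent."""


# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: Natural isotopic abundances of copper (fractions).
CU_B63 = 0.6915
CU_B65 = 0.3085

#: Standard atomic weight of natural copper, g/mol.
ATOMIC_WEIGHT_CU = 63.546
#: Isotopic masses of the two copper isotopes, g/mol.
ATOMIC_MASS_CU63 = 62.929597
ATOMIC_MASS_CU65 = 64.927790

#: Natural abundances of the two monitored lead isotopes (Pb also has 204/207,
#: which are not monitored, so these do not sum to 1).
PB_B206 = 0.241
PB_B208 = 0.524

#: Standard atomic weight of natural lead and isotopic masses, g/mol.
ATOMIC_WEIGHT_PB = 207.2
ATOMIC_MASS_PB206 = 205.974465
ATOMIC_MASS_PB208 = 207.976897

WINES = ("C", "PN", "S", "T")
METHODS = ("DD", "FA", "AF", "MW")
DIRECT_METHODS = ("DD", "FA", "AF")

ROLES = (
    "calibration_standard",
    "continuing_calibration_blank",
    "qc_standard",
    "method_blank",
    "sample",
    "spiked_sample",
)

#: Overall dilution factors from wine to at-instrument solution.  "Diluted 1:3"
#: is read as 1 part wine in 3 parts total (12–15% ethanol wine lands on the
#: 4% ethanol matrix-matched calibration blank); microwave digestion is 2 mL
#: wine + 2 mL acid followed by a 1:5 dilution with ultrapure water, i.e. 10×.
#: Both are configurable at the call sites for users who read "1:3" as 1+3.
DILUTION_FACTORS = {"DD": 3.0, "FA": 3.0, "AF": 3.0, "MW": 10.0}

MODE_NO_GAS = "no-gas"
MODE_HELIUM = "helium"
MODE_HEHE = "high-energy-helium"
_MODES = (MODE_NO_GAS, MODE_HELIUM, MODE_HEHE)

# The 43 monitored isotope channels, in acquisition-table order.  Li, Mo and
# Te run with no cell gas; As and Se in high-energy helium; everything else in
# helium mode.
_CHANNEL_TABLE: tuple[tuple[str, int], ...] = (
    ("Li", 7), ("Al", 27), ("Ti", 47), ("V", 51), ("Cr", 52), ("Mn", 55),
    ("Co", 59), ("Ni", 60), ("Cu", 63), ("Cu", 65), ("Zn", 66), ("Ga", 71),
    ("As", 75), ("Se", 78), ("Rb", 85), ("Sr", 88), ("Nb", 93), ("Mo", 98),
    ("Ru", 101), ("Rh", 103), ("Ag", 107), ("Cd", 111), ("Sb", 123),
    ("Te", 125), ("Cs", 133), ("Ba", 137), ("Ce", 140), ("Pr", 141),
    ("Nd", 146), ("Sm", 147), ("Eu", 153), ("Gd", 157), ("Dy", 163),
    ("Ho", 165), ("Er", 166), ("Tm", 169), ("Yb", 172), ("Ta", 181),
    ("W", 182), ("Tl", 205), ("Pb", 206), ("Pb", 208), ("U", 238),
)

_NO_GAS_ELEMENTS = {"Li", "Mo", "Te"}
_HEHE_ELEMENTS = {"As", "Se"}

#: Internal-standard channels fed continuously into the sample stream.
INTERNAL_STANDARDS: tuple[tuple[str, int], ...] = (
    ("Li", 6), ("Sc", 45), ("Ge", 72), ("Y", 89), ("In", 115),
    ("Tb", 159), ("Bi", 209),
)

#: Per-channel natural-abundance weight used when an element is monitored at
#: more than one mass.  Mono-isotopically monitored elements carry weight 1
#: (the abundance is absorbed into the channel sensitivity and cancels between
#: calibration and sample).
_CHANNEL_ABUNDANCE = {
    ("Cu", 63): CU_B63,
    ("Cu", 65): CU_B65,
    ("Pb", 206): PB_B206,
    ("Pb", 208): PB_B208,
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeChannel:
    """One measured m/z: an element, a mass number, and a cell-gas mode."""

    element: str
    mass_number: int
    mode: str

    def __post_init__(self) -> None:
        if self.mass_number <= 0:
            raise ValueError(f"mass_number must be positive, got {self.mass_number}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown acquisition mode {self.mode!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.element, self.mass_number)

    @property
    def label(self) -> str:
        """Conventional isotope label, e.g. ``'63Cu'``."""
        return f"{self.mass_number}{self.element}"


def channel_mode(element: str, mass_number: int) -> str:
    """Default cell-gas mode for a channel (no-gas Li/Mo/Te, HEHe As/Se, else He)."""
    if element in _NO_GAS_ELEMENTS:
        return MODE_NO_GAS
    if element in _HEHE_ELEMENTS:
        return MODE_HEHE
    return MODE_HELIUM


def default_channels() -> list[IsotopeChannel]:
    """The 43 monitored isotope channels with their default mode assignments.

    Deterministic and order-stable; (element, mass) pairs are unique.
    """
    return [
        IsotopeChannel(element, mass, channel_mode(element, mass))
        for element, mass in _CHANNEL_TABLE
    ]


def channel_abundance(element: str, mass_number: int) -> float:
    """Natural-abundance weight of a channel within its element (1 if mono-monitored)."""
    return _CHANNEL_ABUNDANCE.get((element, mass_number), 1.0)


def internal_standard_for(mass_number: int) -> tuple[str, int]:
    """Nearest-mass internal-standard channel for an analyte mass.

    The pairing of analytes to the seven IS channels is a laboratory
    convention; nearest mass is the default here, with ties broken toward the
    lighter IS.
    """
    return min(INTERNAL_STANDARDS, key=lambda ch: (abs(ch[1] - mass_number), ch[1]))


@dataclass(frozen=True)
class PrepMethod:
    """A sample-preparation treatment and its wine-to-instrument dilution factor."""

    code: str
    dilution_factor: float

    def __post_init__(self) -> None:
        if self.code not in METHODS:
            raise UnknownMethodError(f"unknown prep method {self.code!r}")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")

    @classmethod
    def from_code(cls, code: str, factors: Optional[dict] = None) -> "PrepMethod":
        return cls(code, dilution_factor(code, factors))


def dilution_factor(code: str, factors: Optional[dict] = None) -> float:
    """Overall dilution factor for a prep-method code (DD/FA/AF → 3, MW → 10)."""
    table = DILUTION_FACTORS if factors is None else factors
    try:
        return float(table[code])
    except KeyError:
        raise UnknownMethodError(
            f"unknown prep method {code!r}; expected one of {sorted(table)}"
        ) from None


@dataclass
class SampleMeta:
    """Identity and bookkeeping of one analysed solution.

    ``mass_sample``/``spike_mass`` are gravimetric masses in g; ``spike_mass``
    refers to the enriched-Cu spike solution (0 for unspiked solutions) and
    ``spike_mass_pb`` to the enriched-Pb spike.  ``standard_conc`` carries the
    gravimetric concentration of calibration/QC standards and ``material``
    whether a standard was prepared from natural-abundance or isotopically
    enriched stock.
    """

    sample_id: str
    wine: str  # C | PN | S | T | BLANK
    role: str
    method: str = ""  # prep-method code, "direct"/"MW" for CCBs, "" for standards
    replicate: int = 1
    run: int = 1
    mass_sample: float = 0.0
    spike_mass: float = 0.0
    spike_mass_pb: float = 0.0
    standard_conc: float = float("nan")
    material: str = ""  # natural | enriched | ""
    acq_index: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.role == "spiked_sample" and self.spike_mass <= 0:
            raise ValueError("spiked samples must carry spike_mass > 0")


@dataclass
class MeasurementRecord:
    """One (sample × channel) raw response with its internal-standard response."""

    meta: SampleMeta
    channel: IsotopeChannel
    response: float
    is_response: float

    def __post_init__(self) -> None:
        if self.response < 0:
            raise ValueError("response must be >= 0")
        if self.is_response <= 0:
            raise InstrumentFaultError("internal-standard response must be > 0")


@dataclass
class IDParams:
    """All symbols of the isotope-dilution mixing equation for copper.

    c_spike is the concentration of the enriched spike solution as added
    (µg/L); m_spike and m_sample the gravimetric masses of spike solution and
    sample (g); w_nat/w_spk the atomic weights of natural and spike copper
    (g/mol); a63/a65 the spike isotopic abundances and b63/b65 the natural
    abundances (fractions).  If ``w_spk`` is omitted it is computed from the
    spike abundances and the isotopic masses.
    """

    c_spike: float
    m_spike: float
    m_sample: float
    a63: float
    a65: float
    b63: float = CU_B63
    b65: float = CU_B65
    w_nat: float = ATOMIC_WEIGHT_CU
    w_spk: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("c_spike", "m_spike", "m_sample", "w_nat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a63", "a65", "b63", "b65"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if abs(self.a63 + self.a65 - 1.0) > 1e-6:
            raise ValueError("spike abundances a63 + a65 must sum to 1")
        if abs(self.b63 + self.b65 - 1.0) > 1e-6:
            raise ValueError("natural abundances b63 + b65 must sum to 1")
        if self.w_spk is None:
            self.w_spk = self.a63 * ATOMIC_MASS_CU63 + self.a65 * ATOMIC_MASS_CU65
        elif self.w_spk <= 0:
            raise ValueError("w_spk must be positive")


@dataclass
class DetectionLimits:
    """Blank-based detection (t × SD) and quantitation (10 × SD) limits, µg/L."""

    channel: IsotopeChannel
    lod: float
    loq: float
    n_blanks: int
    t_value: float

    def __post_init__(self) -> None:
        if self.lod < 0 or self.loq < 0:
            raise ValueError("lod and loq must be >= 0")


#: Fixed column vocabulary of the canonical long-format CSV.
CSV_COLUMNS = [
    "sample_id", "wine", "role", "method", "replicate", "run",
    "element", "mass", "mode", "response", "is_response",
    "standard_conc", "material", "mass_sample", "spike_mass",
    "spike_mass_pb", "acq_index",
]
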