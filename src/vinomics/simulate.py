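"""Synthetic instrument-data generator for complete analytical batches.

Emulates the measurement campaign end to end: six-point external calibration
series (natural and isotopically enriched stock), continuing calibration
blanks, periodic QC standards, triplicate method blanks and wines for each of
the four preparation treatments, and gravimetrically spiked aliquots carrying
enriched 65Cu and 206Pb.

Forward model for one record (sample s, channel c)::

    response = sens_c * conc_c(s) * matrix(m, c) * prep(s) * drift(s)
             + background_c * drift(s)
    response *= LogNormal(cv = instrument_cv)          # mean-1 noise
    is_response = is_sens * drift(s)**is_coupling * LogNormal(instrument_cv)

where ``conc_c(s)`` sums every copper/lead source present in the solution
weighted by that source's isotopic abundance at the channel mass, ``prep(s)``
is a per-sample lognormal preparation factor at the method CV (shared across
channels — dilution and handling errors scale all elements together), and
``drift(s)`` is a bounded random walk over acquisition order shared between
analyte and internal standard, so IS normalization cancels it.

Method effects are additive contamination (blank levels of Table-magnitude
defaults, randomised per replicate for microwave digestion), multiplicative
filtration retention on the channels prone to loss of organically complexed
metals, and the per-method noise CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ATOMIC_MASS_CU63,
    ATOMIC_MASS_CU65,
    ATOMIC_MASS_PB206,
    ATOMIC_MASS_PB208,
    ATOMIC_WEIGHT_CU,
    ATOMIC_WEIGHT_PB,
    CSV_COLUMNS,
    DILUTION_FACTORS,
    IDParams,
    IsotopeChannel,
    MissingDataError,
    channel_abundance,
    default_channels,
    dilution_factor,
    internal_standard_for,
    METHODS,
    WINES,
)

__all__ = [
    "RangeSpec",
    "TruthTable",
    "MethodEffectParams",
    "InstrumentParams",
    "SpikeParams",
    "BatchDesign",
    "generate_truth",
    "apply_prep_effects",
    "simulate_batch",
    "default_range_spec",
    "TABLE_BLANK_CONTAMINATION",
    "FILTRATION_LOSS_CHANNELS",
    "AF_EXTRA_LOSS_CHANNELS",
]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

#: Default per-element concentration ranges in undiluted wine, µg/L.  Spanning
#: ~3 ng/L for rare earths to above 1 mg/L for Mn and Rb, with typical table
#: wine levels for the rest.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Li": (5.0, 50.0), "Al": (100.0, 1200.0), "Ti": (10.0, 100.0),
    "V": (0.5, 20.0), "Cr": (2.0, 30.0), "Mn": (1050.0, 3000.0),
    "Co": (1.0, 10.0), "Ni": (10.0, 100.0), "Cu": (50.0, 500.0),
    "Zn": (300.0, 2000.0), "Ga": (0.5, 5.0), "As": (1.0, 20.0),
    "Se": (1.0, 10.0), "Rb": (1050.0, 3000.0), "Sr": (300.0, 1500.0),
    "Nb": (0.01, 0.5), "Mo": (1.0, 30.0), "Ru": (0.005, 0.1),
    "Rh": (0.005, 0.1), "Ag": (0.01, 0.5), "Cd": (0.1, 2.0),
    "Sb": (0.5, 5.0), "Te": (0.005, 0.1), "Cs": (1.0, 20.0),
    "Ba": (20.0, 300.0), "Ce": (0.01, 0.5), "Pr": (0.003, 0.1),
    "Nd": (0.01, 0.3), "Sm": (0.003, 0.1), "Eu": (0.003, 0.05),
    "Gd": (0.003, 0.1), "Dy": (0.003, 0.1), "Ho": (0.003, 0.05),
    "Er": (0.003, 0.05), "Tm": (0.003, 0.05), "Yb": (0.003, 0.1),
    "Ta": (0.005, 0.1), "W": (0.05, 1.0), "Tl": (0.05, 2.0),
    "Pb": (5.0, 50.0), "U": (0.05, 2.0),
}


@dataclass
class RangeSpec:
    """Per-element (low, high) concentration ranges for truth generation."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for element, (lo, hi) in self.ranges.items():
            if lo <= 0 or hi <= 0 or hi < lo:
                raise ValueError(f"invalid range for {element}: ({lo}, {hi})")


def default_range_spec() -> RangeSpec:
    return RangeSpec(dict(_DEFAULT_RANGES))


class TruthTable:
    """True concentrations of each element in each undiluted wine, µg/L."""

    def __init__(self, values: dict[tuple[str, str], float]):
        for (wine, element), v in values.items():
            if v < 0:
                raise ValueError(f"negative truth for ({wine}, {element})")
        self._values = dict(values)

    def value(self, wine: str, element: str) -> float:
        return self._values[(wine, element)]

    def items(self):
        return self._values.items()

    @property
    def wines(self) -> list[str]:
        return sorted({w for w, _ in self._values})

    @property
    def elements(self) -> list[str]:
        return sorted({e for _, e in self._values})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"wine": w, "element": e, "concentration": v}
            for (w, e), v in sorted(self._values.items())
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, TruthTable) and self._values == other._values


def generate_truth(
    seed: int,
    wines: Sequence[str] = WINES,
    elements: Optional[Sequence[str]] = None,
    range_spec: Optional[RangeSpec] = None,
) -> TruthTable:
    """Draw a reproducible truth table with wines differing element-wise.

    Each (wine, element) value is drawn log-uniformly within the element's
    range, independently per wine, so elemental profiles are separable.
    """
    spec = range_spec or default_range_spec()
    if elements is None:
        elements = sorted({ch.element for ch in default_channels()})
    if len(elements) == 0:
        raise ValueError("element list must not be empty")
    rng = np.random.default_rng(seed)
    values: dict[tuple[str, str], float] = {}
    for wine in wines:
        for element in elements:
            lo, hi = spec.ranges[element]
            values[(wine, element)] = float(
                math.exp(rng.uniform(math.log(lo), math.log(hi)))
            )
    return TruthTable(values)


# ---------------------------------------------------------------------------
# Method effects
# ---------------------------------------------------------------------------

#: Measured method-blank concentrations (µg/L at instrument) used as default
#: additive-contamination means; 0 where the blank was below detection.
#: Keyed (element, mass) → {AF, DD, FA, MW}.
TABLE_BLANK_CONTAMINATION: dict[tuple[str, int], dict[str, float]] = {
    ("Li", 7): {"AF": 1.23, "DD": 1.77, "FA": 1.50, "MW": 0.962},
    ("Al", 27): {"AF": 0.0, "DD": 1.84, "FA": 0.0, "MW": 13.7},
    ("Ti", 47): {"AF": 0.611, "DD": 0.0, "FA": 0.0, "MW": 2.27},
    ("V", 51): {"AF": 0.013, "DD": 0.020, "FA": 0.015, "MW": 0.029},
    ("Cr", 52): {"AF": 0.0, "DD": 1.04, "FA": 0.0, "MW": 5.07},
    ("Mn", 55): {"AF": 0.0, "DD": 0.772, "FA": 0.0, "MW": 20.1},
    ("Co", 59): {"AF": 0.0, "DD": 0.026, "FA": 0.0, "MW": 1.36},
    ("Ni", 60): {"AF": 0.0, "DD": 0.600, "FA": 0.0, "MW": 5.22},
    ("Cu", 63): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.248},
    ("Cu", 65): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.045},
    ("Zn", 66): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 1.16},
    ("Ga", 71): {"AF": 0.007, "DD": 0.006, "FA": 0.010, "MW": 0.0},
    ("As", 75): {"AF": 0.056, "DD": 0.154, "FA": 0.116, "MW": 0.106},
    ("Se", 78): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.280},
    ("Rb", 85): {"AF": 0.467, "DD": 0.558, "FA": 0.279, "MW": 0.130},
    ("Sr", 88): {"AF": 0.065, "DD": 0.0, "FA": 0.0, "MW": 0.050},
    ("Nb", 93): {"AF": 0.0, "DD": 0.018, "FA": 0.0, "MW": 0.524},
    ("Mo", 98): {"AF": 0.0, "DD": 0.0, "FA": 0.099, "MW": 1.96},
    ("Ru", 101): {"AF": 0.009, "DD": 0.0, "FA": 0.0, "MW": 0.0},
    ("Rh", 103): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.034},
    ("Ag", 107): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.138},
    ("Cd", 111): {"AF": 0.040, "DD": 0.0, "FA": 0.040, "MW": 0.0},
    ("Sb", 123): {"AF": 0.0, "DD": 0.060, "FA": 0.0, "MW": 0.732},
    ("Te", 125): {"AF": 0.0, "DD": 0.007, "FA": 0.004, "MW": 0.005},
    ("Cs", 133): {"AF": 0.029, "DD": 0.033, "FA": 0.074, "MW": 0.033},
    ("Ba", 137): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.124},
    ("Ce", 140): {"AF": 0.003, "DD": 0.0, "FA": 0.0, "MW": 0.0},
    ("Pr", 141): {"AF": 0.0, "DD": 0.003, "FA": 0.0, "MW": 0.0},
    ("Nd", 146): {"AF": 0.005, "DD": 0.002, "FA": 0.002, "MW": 0.003},
    ("Sm", 147): {"AF": 0.002, "DD": 0.004, "FA": 0.0, "MW": 0.0},
    ("Eu", 153): {"AF": 0.0, "DD": 0.001, "FA": 0.0, "MW": 0.0},
    ("Gd", 157): {"AF": 0.0, "DD": 0.004, "FA": 0.0, "MW": 0.0},
    ("Dy", 163): {"AF": 0.0, "DD": 0.0, "FA": 0.0, "MW": 0.0},
    ("Ho", 165): {"AF": 0.001, "DD": 0.0004, "FA": 0.0, "MW": 0.0},
    ("Er", 166): {"AF": 0.0, "DD": 0.003, "FA": 0.0, "MW": 0.0},
    ("Tm", 169): {"AF": 0.0, "DD": 0.001, "FA": 0.0, "MW": 0.0},
    ("Yb", 172): {"AF": 0.008, "DD": 0.004, "FA": 0.005, "MW": 0.005},
    ("Ta", 181): {"AF": 0.0, "DD": 0.032, "FA": 0.0, "MW": 1.94},
    ("W", 182): {"AF": 0.0, "DD": 0.189, "FA": 0.122, "MW": 1.27},
    ("Tl", 205): {"AF": 0.005, "DD": 0.007, "FA": 0.008, "MW": 0.0},
    ("Pb", 206): {"AF": 0.0, "DD": 0.140, "FA": 0.0, "MW": 0.030},
    ("Pb", 208): {"AF": 0.017, "DD": 0.130, "FA": 0.0, "MW": 0.043},
    ("U", 238): {"AF": 0.009, "DD": 0.0, "FA": 0.009, "MW": 0.0},
}

#: Channels subject to filtration loss (retention < 1 in FA and AF): isotopes
#: of metals that form organically complexed species retained on 0.45 µm
#: filters.
FILTRATION_LOSS_CHANNELS: tuple[tuple[str, int], ...] = (
    ("Li", 7), ("Co", 59), ("Cu", 63), ("Cu", 65), ("Rb", 85), ("Sr", 88),
    ("Nb", 93), ("Cs", 133), ("W", 182), ("Tl", 205), ("Pb", 206), ("Pb", 208),
)

#: Channels additionally reduced in AF relative to FA.
AF_EXTRA_LOSS_CHANNELS: tuple[tuple[str, int], ...] = (
    ("Al", 27), ("Mn", 55), ("Ni", 60), ("Zn", 66), ("As", 75), ("Se", 78),
    ("Ru", 101),
)


@dataclass
class MethodEffectParams:
    """Contamination / retention / noise structure of the four prep methods.

    contamination: method → channel → additive at-instrument mean, µg/L.
    retention:     method → channel → multiplicative fraction in (0, 1].
    prep_cv:       method → per-sample lognormal preparation CV (fraction).
    contam_cv:     method → lognormal CV of the per-replicate contamination
                   draw (0 means deterministic contamination).
    matrix_factor: method → dimensionless response factor near 1.
    """

    contamination: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    retention: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    prep_cv: dict[str, float] = field(default_factory=dict)
    contam_cv: dict[str, float] = field(default_factory=dict)
    matrix_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for method, table in self.retention.items():
            for ch, r in table.items():
                if not 0.0 < r <= 1.0:
                    raise ValueError(
                        f"retention must lie in (0, 1], got {r} for {method}/{ch}"
                    )
        for method, cv in self.prep_cv.items():
            if cv < 0:
                raise ValueError(f"negative prep CV for {method}")

    def get_contamination(self, method: str, key: tuple[str, int]) -> float:
        return self.contamination.get(method, {}).get(key, 0.0)

    def get_retention(self, method: str, key: tuple[str, int]) -> float:
        return self.retention.get(method, {}).get(key, 1.0)

    def get_prep_cv(self, method: str) -> float:
        return self.prep_cv.get(method, 0.0)

    def get_contam_cv(self, method: str) -> float:
        return self.contam_cv.get(method, 0.0)

    def get_matrix(self, method: str) -> float:
        return self.matrix_factor.get(method, 1.0)

    @classmethod
    def default(cls) -> "MethodEffectParams":
        """Study-condition defaults: table-magnitude contamination, filtration
        retention 0.85 (plus 0.92 on the AF-specific channels), method CVs
        29.5% MW and 13–18% for the direct treatments."""
        contamination = {
            m: {k: v[m] for k, v in TABLE_BLANK_CONTAMINATION.items() if v[m] > 0}
            for m in METHODS
        }
        retention: dict[str, dict[tuple[str, int], float]] = {
            "FA": {k: 0.85 for k in FILTRATION_LOSS_CHANNELS},
            "AF": {k: 0.85 for k in FILTRATION_LOSS_CHANNELS},
        }
        retention["AF"].update({k: 0.92 for k in AF_EXTRA_LOSS_CHANNELS})
        return cls(
            contamination=contamination,
            retention=retention,
            prep_cv={"DD": 0.13, "FA": 0.15, "AF": 0.18, "MW": 0.295},
            contam_cv={"MW": 0.3},
        )

    @classmethod
    def null(cls, cv: float = 0.15) -> "MethodEffectParams":
        """Identical distributions across methods (no contamination, no loss,
        one common CV): the null hypothesis of the method-effect tests."""
        return cls(prep_cv={m: cv for m in METHODS})

    @classmethod
    def noise_free(cls) -> "MethodEffectParams":
        """No contamination, no loss, no preparation noise."""
        return cls()


@dataclass
class InstrumentParams:
    """Per-channel response model of the simulated instrument.

    sensitivity is in counts per µg/L (equal across isotope channels of one
    element by default, i.e. no mass bias); background in counts; the drift
    multiplier follows a bounded random walk over acquisition order and is
    shared with the internal standards through ``is_coupling`` (1 means the IS
    tracks analyte drift perfectly and normalization cancels it exactly).
    """

    sensitivity: float = 5000.0
    background: float = 200.0
    instrument_cv: float = 0.02
    drift_step: float = 0.01
    drift_lo: float = 0.8
    drift_hi: float = 1.2
    is_coupling: float = 1.0
    is_sensitivity: float = 1.0e5
    sensitivity_overrides: dict[tuple[str, int], float] = field(default_factory=dict)
    background_overrides: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sensitivity <= 0 or self.is_sensitivity <= 0:
            raise ValueError("sensitivities must be positive")
        if not 0 < self.drift_lo <= 1.0 <= self.drift_hi:
            raise ValueError("drift bounds must bracket 1")

    def channel_sensitivity(self, key: tuple[str, int]) -> float:
        return self.sensitivity_overrides.get(key, self.sensitivity)

    def channel_background(self, key: tuple[str, int]) -> float:
        return self.background_overrides.get(key, self.background)

    @classmethod
    def noise_free(cls, **kwargs) -> "InstrumentParams":
        kwargs.setdefault("instrument_cv", 0.0)
        return cls(**kwargs)


@dataclass
class SpikeParams:
    """Gravimetric enriched-isotope spikes added to wine/blank aliquots.

    Levels are the added concentration in the (undiluted) sample; the
    c_spike values are the spike-solution concentrations from which the spike
    masses follow gravimetrically.  The isotopic abundances are synthetic
    placeholders for a highly enriched material (a65, a206 near 1), not
    certificate values; supply the certificate abundances for real data.
    """

    cu_level: float = 100.0  # µg/L added 65Cu spike in the sample
    pb_level: float = 5.0  # µg/L added 206Pb spike in the sample
    c_spike_cu: float = 10000.0  # µg/L of the Cu spike solution
    c_spike_pb: float = 1000.0  # µg/L of the Pb spike solution
    a63: float = 0.01
    a65: float = 0.99
    a206: float = 0.99
    a208: float = 0.01
    mass_sample: float = 5.0  # g of wine aliquot taken for spiking

    def cu_mole_factor(self) -> float:
        """Ion-count yield of spike Cu relative to natural Cu per unit mass
        concentration (ratio of atomic weights); the ICP ion current counts
        atoms, so a heavier enriched material gives proportionally fewer."""
        w_spk = self.a63 * ATOMIC_MASS_CU63 + self.a65 * ATOMIC_MASS_CU65
        return ATOMIC_WEIGHT_CU / w_spk

    def pb_mole_factor(self) -> float:
        w_spk = self.a206 * ATOMIC_MASS_PB206 + self.a208 * ATOMIC_MASS_PB208
        return ATOMIC_WEIGHT_PB / w_spk

    def cu_spike_mass(self) -> float:
        """Spike-solution mass (g) delivering cu_level in mass_sample grams."""
        return self.cu_level * self.mass_sample / self.c_spike_cu

    def pb_spike_mass(self) -> float:
        return self.pb_level * self.mass_sample / self.c_spike_pb

    def cu_id_params(self, m_spike: float, m_sample: float, **kwargs) -> IDParams:
        return IDParams(
            c_spike=self.c_spike_cu,
            m_spike=m_spike,
            m_sample=m_sample,
            a63=self.a63,
            a65=self.a65,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Batch design
# ---------------------------------------------------------------------------

@dataclass
class BatchDesign:
    """Cardinality and layout of one simulated analytical batch."""

    wines: tuple[str, ...] = WINES
    methods: tuple[str, ...] = METHODS
    replicates: int = 3
    calibration_levels: tuple[float, ...] = (0.0, 1.0, 10.0, 50.0, 100.0, 500.0)
    qc_every: int = 15
    qc_level: float = 10.0
    ccb_direct_runs: int = 2
    ccb_per_run: int = 6
    ccb_mw: int = 8
    include_method_blanks: bool = True
    include_spikes: bool = True
    include_ccb: bool = True
    include_qc: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(set(self.calibration_levels)) < 2:
            raise ValueError("need at least two distinct calibration levels")

    def sample_metas(self, spikes: Optional[SpikeParams]) -> list[dict]:
        """The ordered list of solutions in the batch (acquisition order)."""
        metas: list[dict] = []

        def add(**kw):
            kw.setdefault("method", "")
            kw.setdefault("replicate", 1)
            kw.setdefault("run", 1)
            kw.setdefault("mass_sample", 0.0)
            kw.setdefault("spike_mass", 0.0)
            kw.setdefault("spike_mass_pb", 0.0)
            kw.setdefault("standard_conc", float("nan"))
            kw.setdefault("material", "")
            metas.append(kw)

        for i, level in enumerate(self.calibration_levels, 1):
            add(sample_id=f"CAL_NAT_{i}", wine="BLANK", role="calibration_standard",
                standard_conc=float(level), material="natural")
        if self.include_spikes:
            for i, level in enumerate(self.calibration_levels, 1):
                add(sample_id=f"CAL_ENR_{i}", wine="BLANK",
                    role="calibration_standard", standard_conc=float(level),
                    material="enriched")
        if self.include_ccb:
            for run in range(1, self.ccb_direct_runs + 1):
                for rep in range(1, self.ccb_per_run + 1):
                    add(sample_id=f"CCB_DIR_R{run}_{rep}", wine="BLANK",
                        role="continuing_calibration_blank", method="direct",
                        replicate=rep, run=run, standard_conc=0.0,
                        material="natural")
            for rep in range(1, self.ccb_mw + 1):
                add(sample_id=f"CCB_MW_{rep}", wine="BLANK",
                    role="continuing_calibration_blank", method="MW",
                    replicate=rep, standard_conc=0.0, material="natural")

        # Analysis sequence with periodic QC insertions.
        analysis: list[dict] = []

        def add_analysis(**kw):
            analysis.append(kw)

        m_sample = spikes.mass_sample if spikes else 5.0
        for method in self.methods:
            if self.include_method_blanks:
                for rep in range(1, self.replicates + 1):
                    add_analysis(sample_id=f"BLK_{method}_{rep}", wine="BLANK",
                                 role="method_blank", method=method,
                                 replicate=rep, mass_sample=m_sample)
            for wine in self.wines:
                for rep in range(1, self.replicates + 1):
                    add_analysis(sample_id=f"{wine}_{method}_{rep}", wine=wine,
                                 role="sample", method=method, replicate=rep,
                                 mass_sample=m_sample)
            if self.include_spikes and spikes is not None:
                targets = ["BLANK"] if self.include_method_blanks else []
                targets += list(self.wines)
                for wine in targets:
                    for rep in range(1, self.replicates + 1):
                        add_analysis(
                            sample_id=f"SPK_{wine}_{method}_{rep}", wine=wine,
                            role="spiked_sample", method=method, replicate=rep,
                            mass_sample=m_sample,
                            spike_mass=spikes.cu_spike_mass(),
                            spike_mass_pb=spikes.pb_spike_mass(),
                        )

        qc_count = 0
        for i, kw in enumerate(analysis):
            if self.include_qc and i > 0 and i % self.qc_every == 0:
                qc_count += 1
                d = dict(sample_id=f"QC_{qc_count}", wine="BLANK",
                         role="qc_standard", standard_conc=self.qc_level,
                         material="natural")
                add(**d)
            add(**kw)

        for i, kw in enumerate(metas):
            kw["acq_index"] = i
        return metas

    def n_samples(self, spikes: Optional[SpikeParams] = None) -> int:
        return len(self.sample_metas(spikes))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def apply_prep_effects(
    truth: TruthTable,
    wine: str,
    method: str,
    effects: MethodEffectParams,
    channels: Optional[Sequence[IsotopeChannel]] = None,
    dilution_factors: Optional[dict] = None,
) -> dict[tuple[str, int], float]:
    """Expected at-instrument concentration per channel for one prepared wine.

    value = truth / dilution_factor × retention × abundance + contamination,
    with the natural-abundance split applied to the truth contribution of
    multi-isotope elements and contamination given per channel.  When no
    channel list is given, the default channels covered by the truth table
    are used.
    """
    if channels is None:
        known = set(truth.elements)
        channels = [ch for ch in default_channels() if ch.element in known]
    else:
        channels = list(channels)
    df = dilution_factor(method, dilution_factors)
    out: dict[tuple[str, int], float] = {}
    for ch in channels:
        key = ch.key
        base = truth.value(wine, ch.element) / df
        base *= effects.get_retention(method, key)
        base *= channel_abundance(*key)
        out[key] = base + effects.get_contamination(method, key)
    return out


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal factors with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=sigma, size=size)


def _drift_walk(rng: np.random.Generator, n: int, p: InstrumentParams) -> np.ndarray:
    """Bounded random-walk drift multipliers over acquisition order."""
    drift = np.empty(n)
    x = 1.0
    for i in range(n):
        x = float(np.clip(x + rng.normal(0.0, p.drift_step), p.drift_lo, p.drift_hi))
        drift[i] = x
    return drift


def simulate_batch(
    design: BatchDesign,
    truth: TruthTable,
    effects: MethodEffectParams,
    instrument: InstrumentParams,
    seed: Optional[int],
    channels: Optional[Sequence[IsotopeChannel]] = None,
    spikes: Optional[SpikeParams] = None,
    dilution_factors: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate one full batch; returns the canonical long-format table.

    A seed is mandatory (reproducibility contract).  Every source of
    randomness — drift walk, preparation factors, contamination draws, and
    instrument noise — is drawn from one generator seeded here.
    """
    if seed is None:
        raise ValueError("simulate_batch requires an explicit seed")
    rng = np.random.default_rng(seed)
    channels = list(channels) if channels is not None else default_channels()
    if spikes is None and design.include_spikes:
        spikes = SpikeParams()

    elements = np.array([ch.element for ch in channels])
    masses = np.array([ch.mass_number for ch in channels])
    modes = np.array([ch.mode for ch in channels])
    keys = [ch.key for ch in channels]
    abund = np.array([channel_abundance(*k) for k in keys])
    sens = np.array([instrument.channel_sensitivity(k) for k in keys])
    bg = np.array([instrument.channel_background(k) for k in keys])
    n_ch = len(channels)

    cu63 = np.array([k == ("Cu", 63) for k in keys])
    cu65 = np.array([k == ("Cu", 65) for k in keys])
    pb206 = np.array([k == ("Pb", 206) for k in keys])
    pb208 = np.array([k == ("Pb", 208) for k in keys])

    metas = design.sample_metas(spikes)
    n_samples = len(metas)
    drift = _drift_walk(rng, n_samples, instrument)

    # Cache of deterministic natural at-instrument channel concentrations for
    # prepared wines, excluding the (possibly random) contamination term.
    prep_cache: dict[tuple[str, str], np.ndarray] = {}

    def natural_vector(wine: str, method: str) -> np.ndarray:
        key = (wine, method)
        if key not in prep_cache:
            df = dilution_factor(method, dilution_factors)
            vec = np.empty(n_ch)
            for j, ch in enumerate(channels):
                base = 0.0
                if wine != "BLANK":
                    base = truth.value(wine, ch.element) / df
                    base *= effects.get_retention(method, ch.key)
                    base *= abund[j]
                vec[j] = base
            prep_cache[key] = vec
        return prep_cache[key]

    rows: dict[str, list] = {c: [] for c in CSV_COLUMNS}

    for i, meta in enumerate(metas):
        role = meta["role"]
        method = meta["method"]
        prep_factor = 1.0
        matrix = 1.0
        conc = np.zeros(n_ch)

        if role == "calibration_standard":
            level = meta["standard_conc"]
            if meta["material"] == "natural":
                conc = level * abund
            else:  # enriched stock contributes only at the spike channels
                sp = spikes or SpikeParams()
                conc = level * (
                    sp.cu_mole_factor() * (cu63 * sp.a63 + cu65 * sp.a65)
                    + sp.pb_mole_factor() * (pb206 * sp.a206 + pb208 * sp.a208)
                )
        elif role == "qc_standard":
            conc = meta["standard_conc"] * abund
        elif role == "continuing_calibration_blank":
            conc = np.zeros(n_ch)
        elif role in ("method_blank", "sample", "spiked_sample"):
            matrix = effects.get_matrix(method)
            prep_factor = float(
                _lognormal_factors(rng, effects.get_prep_cv(method), 1)[0]
            )
            conc = natural_vector(meta["wine"], method).copy()
            contam_cv = effects.get_contam_cv(method)
            for j, ch in enumerate(channels):
                mean = effects.get_contamination(method, ch.key)
                if mean > 0:
                    conc[j] += mean * float(
                        _lognormal_factors(rng, contam_cv, 1)[0]
                    )
            if role == "spiked_sample" and spikes is not None:
                df = dilution_factor(method, dilution_factors)
                # Spikes are not subject to filtration retention: the ionic
                # spike added immediately before preparation does not
                # equilibrate with the organically complexed matrix species.
                conc = conc + (spikes.cu_level / df) * spikes.cu_mole_factor() * (
                    cu63 * spikes.a63 + cu65 * spikes.a65
                )
                conc = conc + (spikes.pb_level / df) * spikes.pb_mole_factor() * (
                    pb206 * spikes.a206 + pb208 * spikes.a208
                )
        else:  # pragma: no cover - roles are closed
            raise ValueError(f"unhandled role {role}")

        signal = sens * conc * matrix * prep_factor * drift[i] + bg * drift[i]
        signal = signal * _lognormal_factors(rng, instrument.instrument_cv, n_ch)
        is_resp = (
            instrument.is_sensitivity
            * drift[i] ** instrument.is_coupling
            * _lognormal_factors(rng, instrument.instrument_cv, n_ch)
        )

        rows["sample_id"].extend([meta["sample_id"]] * n_ch)
        rows["wine"].extend([meta["wine"]] * n_ch)
        rows["role"].extend([role] * n_ch)
        rows["method"].extend([method] * n_ch)
        rows["replicate"].extend([meta["replicate"]] * n_ch)
        rows["run"].extend([meta["run"]] * n_ch)
        rows["element"].extend(elements.tolist())
        rows["mass"].extend(masses.tolist())
        rows["mode"].extend(modes.tolist())
        rows["response"].extend(signal.tolist())
        rows["is_response"].extend(is_resp.tolist())
        rows["standard_conc"].extend([meta["standard_conc"]] * n_ch)
        rows["material"].extend([meta["material"]] * n_ch)
        rows["mass_sample"].extend([meta["mass_sample"]] * n_ch)
        rows["spike_mass"].extend([meta["spike_mass"]] * n_ch)
        rows["spike_mass_pb"].extend([meta["spike_mass_pb"]] * n_ch)
        rows["acq_index"].extend([meta["acq_index"]] * n_ch)

    return pd.DataFrame(rows, columns=CSV_COLUMNS)
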