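"""Run configuration: a JSON-compatible description of the batch design,
effect/instrument parameters, statistical settings and seeds.

The config file is plain JSON.  Every section is optional and overlays the
study-condition defaults; channel keys inside JSON use isotope labels such as
``"63Cu"``.  A config hash (SHA-256 of the canonical serialization) is stamped
into every output manifest so a run is reproducible end to end from
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .core import DILUTION_FACTORS, IsotopeChannel, channel_mode, default_channels
from .simulate import (
    BatchDesign,
    InstrumentParams,
    MethodEffectParams,
    RangeSpec,
    SpikeParams,
    default_range_spec,
)

__all__ = ["RunConfig", "load_config", "parse_channel_label"]

_LABEL_RE = re.compile(r"^(\d+)([A-Z][a-z]?)$")


def parse_channel_label(label: str) -> tuple[str, int]:
    """``"63Cu"`` → ``("Cu", 63)``."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse isotope label {label!r}")
    return m.group(2), int(m.group(1))


def _labelled(d: dict) -> dict:
    """JSON channel-keyed dict → (element, mass)-keyed dict."""
    return {parse_channel_label(k): v for k, v in d.items()}


_EFFECT_PRESETS = {
    "default": MethodEffectParams.default,
    "null": MethodEffectParams.null,
    "noise_free": MethodEffectParams.noise_free,
}


@dataclass
class RunConfig:
    """Everything needed to simulate, quantify and compare one batch."""

    seed: Optional[int] = None
    alpha: float = 0.05
    lod_confidence: float = 0.99
    design: BatchDesign = field(default_factory=BatchDesign)
    effects: MethodEffectParams = field(default_factory=MethodEffectParams.default)
    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    spikes: SpikeParams = field(default_factory=SpikeParams)
    range_spec: RangeSpec = field(default_factory=default_range_spec)
    channels: Optional[list[tuple[str, int]]] = None
    dilution_factors: dict = field(default_factory=lambda: dict(DILUTION_FACTORS))
    manova_channels: Optional[list[tuple[str, int]]] = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        known = {ch.key for ch in default_channels()}
        for group in (self.channels, self.manova_channels):
            for key in group or []:
                if tuple(key) not in known:
                    raise ValueError(f"unknown channel {key}")

    def channel_objects(self) -> list[IsotopeChannel]:
        if self.channels is None:
            return default_channels()
        return [
            IsotopeChannel(e, m, channel_mode(e, m)) for e, m in self.channels
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        effects_cfg = d.get("effects", {})
        if isinstance(effects_cfg, str):
            effects_cfg = {"preset": effects_cfg}
        preset = effects_cfg.get("preset", "default")
        effects = _EFFECT_PRESETS[preset]()
        if "prep_cv" in effects_cfg:
            effects.prep_cv.update(effects_cfg["prep_cv"])
        if "contam_cv" in effects_cfg:
            effects.contam_cv.update(effects_cfg["contam_cv"])
        if "matrix_factor" in effects_cfg:
            effects.matrix_factor.update(effects_cfg["matrix_factor"])
        for method, table in effects_cfg.get("retention", {}).items():
            effects.retention.setdefault(method, {}).update(_labelled(table))
        for method, table in effects_cfg.get("contamination", {}).items():
            effects.contamination.setdefault(method, {}).update(_labelled(table))

        design_kwargs = dict(d.get("design", {}))
        for tuple_field in ("wines", "methods", "calibration_levels"):
            if tuple_field in design_kwargs:
                design_kwargs[tuple_field] = tuple(design_kwargs[tuple_field])
        instrument_kwargs = dict(d.get("instrument", {}))
        for over in ("sensitivity_overrides", "background_overrides"):
            if over in instrument_kwargs:
                instrument_kwargs[over] = _labelled(instrument_kwargs[over])

        ranges = d.get("truth_ranges")
        range_spec = (
            RangeSpec({e: tuple(v) for e, v in ranges.items()})
            if ranges
            else default_range_spec()
        )
        channels = d.get("channels")
        if channels is not None:
            channels = [
                parse_channel_label(c) if isinstance(c, str) else (c[0], int(c[1]))
                for c in channels
            ]
        manova_channels = d.get("manova_channels")
        if manova_channels is not None:
            manova_channels = [
                parse_channel_label(c) if isinstance(c, str) else (c[0], int(c[1]))
                for c in manova_channels
            ]
        return cls(
            seed=d.get("seed"),
            alpha=d.get("alpha", 0.05),
            lod_confidence=d.get("lod_confidence", 0.99),
            design=BatchDesign(**design_kwargs),
            effects=effects,
            instrument=InstrumentParams(**instrument_kwargs),
            spikes=SpikeParams(**d.get("spikes", {})),
            range_spec=range_spec,
            channels=channels,
            dilution_factors={
                **DILUTION_FACTORS,
                **d.get("dilution_factors", {}),
            },
            manova_channels=manova_channels,
            raw=d,
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def canonical_json(self) -> str:
        return json.dumps(self.raw, sort_keys=True, separators=(",", ":"))

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    return RunConfig.load(path)
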