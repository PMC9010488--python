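"""Pipeline configuration: one structured file drives the whole run.

The YAML/JSON config has four blocks — `protocol`, `phantom`,
`processing`, `cohort` — plus a global `seed` and `output_dir`.  Unknown
keys raise a schema error that lists every offending key, so typos fail
loudly before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from crcest.protocol import AcquisitionProtocol

__all__ = ["PipelineConfig", "PhantomConfig", "ProcessingConfig",
           "CohortConfig", "ConfigSchemaError"]


class ConfigSchemaError(ValueError):
    """Configuration violates the schema (unknown keys or bad values)."""


@dataclass
class PhantomConfig:
    """Synthetic-session block: field amplitudes, noise, WASSR grid."""

    b0_amplitude_ppm: float = 0.1
    b1_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.0
    # WASSR sampling is a protocol decision not fixed by the acquisition
    # description; defaults: ±1 ppm, 21 points
    wassr_span_ppm: float = 1.0
    wassr_n_offsets: int = 21


@dataclass
class ProcessingConfig:
    """Reconstruction conventions and kinetic-fit settings."""

    denominator: str = "S_neg"          # or "S0"
    apply_b1_correction: bool = True
    tau_fit_bounds_s: tuple[float, float] = (1.0, 5000.0)
    plausibility_lo_s: float = 24.0
    plausibility_hi_s: float = 1000.0

    def validate(self) -> None:
        if self.denominator not in ("S_neg", "S0"):
            raise ConfigSchemaError(
                f"denominator must be 'S_neg' or 'S0', got {self.denominator!r}"
            )
        if self.plausibility_lo_s >= self.plausibility_hi_s:
            raise ConfigSchemaError(
                "plausibility_lo_s must be smaller than plausibility_hi_s"
            )
        if self.tau_fit_bounds_s[0] >= self.tau_fit_bounds_s[1]:
            raise ConfigSchemaError("tau_fit_bounds_s must be increasing")


@dataclass
class CohortConfig:
    """Which model suites the cohort stage runs."""

    mixed_outcomes: tuple[str, ...] = ("resting_pct",)
    per_muscle_outcomes: tuple[str, ...] = ("delta_pct", "tau_s")


@dataclass
class PipelineConfig:
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    output_dir: str = "crcest_out"

    def __post_init__(self) -> None:
        self.processing.validate()

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"] = self.protocol.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known_top = {"protocol", "phantom", "processing", "cohort", "seed",
                     "output_dir"}
        bad = sorted(set(raw) - known_top)
        blocks = {}
        for key, klass in (
            ("protocol", AcquisitionProtocol),
            ("phantom", PhantomConfig),
            ("processing", ProcessingConfig),
            ("cohort", CohortConfig),
        ):
            sub = dict(raw.get(key) or {})
            fields = (
                klass.__dataclass_fields__.keys()
                if hasattr(klass, "__dataclass_fields__")
                else ()
            )
            bad += [f"{key}.{k}" for k in sorted(set(sub) - set(fields))]
            sub = {k: v for k, v in sub.items() if k in fields}
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            if key == "protocol":
                blocks[key] = AcquisitionProtocol.from_dict(sub)
            else:
                blocks[key] = klass(**sub)
        if bad:
            raise ConfigSchemaError(
                "unknown configuration key(s): " + ", ".join(bad)
            )
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "crcest_out")),
            **blocks,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})
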