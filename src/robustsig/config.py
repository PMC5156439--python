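"""Pipeline configuration: defaults, validation, flat key=value file format."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    out_dir: str = "robustsig_out"
    seed: int = 0
    strains: tuple = ("S1", "S2", "S3", "S4")

    # simulation sizes
    n_genes: int = 1000
    planted_per_stress: int = 20
    probes_per_gene: int = 3

    # statistical thresholds
    alpha: float = 0.05
    product_threshold: float = 5e-5
    generic_p_threshold: float = 0.2
    ttest_alpha: float = 0.05
    top_k: int = 10

    # preprocessing
    lowess_span: float = 0.3
    scale: str = "per-array"

    # simulation noise / signal
    dynamic_range_target: float = 5.0
    robustness_noise_sd: float = 0.3
    expression_noise_sd: float = 0.5
    probe_noise_sd: float = 0.05
    dye_bias_amplitude: float = 0.4

    # assay timepoints (minutes); first entry = reference timepoint
    heat_timepoints: tuple = (10, 30)
    oxidative_timepoints: tuple = (30, 60)

    def __post_init__(self):
        for name in ("alpha", "product_threshold", "generic_p_threshold",
                     "ttest_alpha", "lowess_span"):
            val = getattr(self, name)
            if not 0 < val < 1 and not (name == "lowess_span" and val == 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {val}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def timepoints(self) -> dict:
        return {"heat": tuple(self.heat_timepoints),
                "oxidative": tuple(self.oxidative_timepoints)}

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; *overrides* win."""
        types = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, types[key].default)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _coerce(value: str, default):
    if isinstance(default, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    if isinstance(default, tuple):
        items = [v.strip() for v in value.split(",") if v.strip()]
        if default and isinstance(default[0], int):
            return tuple(int(v) for v in items)
        return tuple(items)
    return value
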