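"""Run configuration: one YAML document tying a reproducible run together."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .filterbank import FilterBankSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a run needs: bank geometry, training source, readout, seeds."""

    bank: FilterBankSpec = field(default_factory=FilterBankSpec)
    training_source: str = "pink_texture"  # white_noise | pink_texture | image_directory
    image_directory: str | None = None
    n_training_patches: int = 10000
    noise_scale: float = 0.1
    c: float = 15.0
    readout_variant: str = "modulus"
    n_samples: int = 400
    n_boot: int = 1000
    seed: int = 0
    diameters_deg: tuple = (0.34, 0.55, 0.90, 2.4, 3.8)
    surround_orientations_deg: tuple = (0.0, 22.5, 45.0, 67.5, 90.0)
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bank"] = self.bank.to_dict()
        d["diameters_deg"] = list(self.diameters_deg)
        d["surround_orientations_deg"] = list(self.surround_orientations_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bank" in d:
            d["bank"] = FilterBankSpec.from_dict(d["bank"])
        for key in ("diameters_deg", "surround_orientations_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
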