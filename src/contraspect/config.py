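"""Pipeline configuration: flag/YAML merging and the provenance digest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .cohort import Sidedness
from .contrast import AcfMode
from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    catalog_path: str = ""
    output_dir: str = "."
    metric: str = "rms"
    sidedness: Sidedness = Sidedness.TWO_SIDED
    acf_mode: AcfMode = AcfMode.CIRCULAR
    crop_fraction: float = 0.0
    max_dim: Optional[int] = None
    linearize_srgb: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.metric not in ("variance", "rms"):
            raise ValidationError(f"metric must be 'variance' or 'rms', got {self.metric!r}")
        if not 0.0 <= self.crop_fraction < 0.5:
            raise ValidationError("crop_fraction must lie in [0, 0.5)")
        if self.max_dim is not None and self.max_dim < 2:
            raise ValidationError("max_dim must be >= 2")
        object.__setattr__(self, "sidedness", Sidedness(self.sidedness))
        object.__setattr__(self, "acf_mode", AcfMode(self.acf_mode))

    def digest(self) -> str:
        """Short stable hash of the analysis-relevant settings.

        File locations and logging verbosity do not affect the numbers, so
        they are excluded: the same analysis in a different directory keeps
        the same digest (and byte-identical outputs).
        """
        payload = asdict(self)
        for key in ("catalog_path", "output_dir", "log_level"):
            payload.pop(key)
        payload["sidedness"] = self.sidedness.value
        payload["acf_mode"] = self.acf_mode.value
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_sources(cls, yaml_path: Optional[str] = None, **overrides) -> "PipelineConfig":
        """Build a config from an optional YAML file plus explicit overrides.

        Unknown keys in the YAML are rejected; overrides win over file values.
        """
        known = {f.name for f in fields(cls)}
        merged: dict = {}
        if yaml_path:
            loaded = yaml.safe_load(Path(yaml_path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValidationError(f"{yaml_path}: config must be a mapping")
            unknown = set(loaded) - known
            if unknown:
                raise ValidationError(f"{yaml_path}: unknown config keys {sorted(unknown)}")
            merged.update(loaded)
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**merged)
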