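"""Pipeline configuration: a validated, YAML-round-trippable settings object.

All randomness in a run flows from the single ``seed`` here; there is no
hidden global state.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .variography import FIT_WEIGHTINGS, SDI_MODEL_FACTORS, SDI_THRESHOLDS, VARIOGRAM_KINDS


@dataclass
class PipelineConfig:
    """Settings for an end-to-end run.

    ``input_csv`` of None means the survey is simulated from the built-in
    reference structure. ``attributes`` is the variography/kriging subset
    (None = a compact default set); band edges of the region delineation
    are inclusive.
    """

    input_csv: str | None = None
    attributes: list[str] | None = None
    candidate_kinds: list[str] = field(default_factory=lambda: ["spherical", "exponential"])
    bin_width: float | None = None
    max_lag: float | None = None
    weighting: str = "pair_counts"
    sdi_model_factors: dict[str, float] = field(default_factory=lambda: dict(SDI_MODEL_FACTORS))
    sdi_thresholds: tuple[float, float] = SDI_THRESHOLDS
    krige_attribute: str = "FCO2"
    cell_size: float = 2.0
    low_band: tuple[float, float] = (1.9, 2.7)
    high_band: tuple[float, float] = (2.9, 4.2)
    alpha: float = 0.01
    depth_cm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for kind in self.candidate_kinds:
            if kind not in VARIOGRAM_KINDS:
                raise ValueError(f"unknown variogram kind {kind!r}")
        if self.weighting not in FIT_WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.sdi_thresholds = tuple(self.sdi_thresholds)  # type: ignore[assignment]
        self.low_band = tuple(self.low_band)  # type: ignore[assignment]
        self.high_band = tuple(self.high_band)  # type: ignore[assignment]

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sdi_thresholds"] = list(self.sdi_thresholds)
        d["low_band"] = list(self.low_band)
        d["high_band"] = list(self.high_band)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        """Stable content hash used as run provenance."""
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
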