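"""Pipeline configuration: every tunable in one audited, serialisable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline tunables with their defaults.

    alpha
        Projection-peak multiplier for ROI boundary adjustment; a side is
        present when its half-profile max reaches ``alpha`` times the
        central value.
    beta
        Correlation-peak acceptance ratio in the detection search.
    delta
        Cubic-fit outlier tolerance in pixels for contour smoothing.
    spacing_frac
        Band half-width as a fraction of the smaller ROI side (min 3 px).
    k_clusters
        Number of intensity clusters for the lateral line rules.
    canny_sigma
        Gaussian width of the Canny edge detector.
    max_bodies
        Hard cap on detected vertebrae.
    max_extend / step_frac
        Boundary-adjustment growth limit and step, as side-length fractions.
    seed
        Seed for every stochastic component (k-means restarts).
    """

    alpha: float = 3.0
    beta: float = 0.6
    delta: float = 3.0
    spacing_frac: float = 0.08
    k_clusters: int = 10
    canny_sigma: float = 1.4
    max_bodies: int = 8
    max_extend: float = 0.5
    step_frac: float = 0.1
    seed: int = 0
    disc_refine: bool = True

    def __post_init__(self) -> None:
        checks = [
            (self.alpha > 1, "alpha must exceed 1"),
            (0 < self.beta < 1, "beta must lie in (0, 1)"),
            (self.delta > 0, "delta must be positive"),
            (0 < self.spacing_frac <= 0.25, "spacing_frac must lie in (0, 0.25]"),
            (2 <= self.k_clusters <= 64, "k_clusters must lie in [2, 64]"),
            (self.canny_sigma > 0, "canny_sigma must be positive"),
            (2 <= self.max_bodies <= 32, "max_bodies must lie in [2, 32]"),
            (0 < self.max_extend <= 1, "max_extend must lie in (0, 1]"),
            (0 < self.step_frac <= 0.5, "step_frac must lie in (0, 0.5]"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid PipelineConfig: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
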