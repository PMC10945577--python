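"""Analysis configuration.

All tunable knobs of the behavioral pipeline live in one dataclass with the
assay's published defaults: 10-s averaging intervals, a roaming speed cutoff
constrained to the 7-12 um/s band, bouts strictly longer than five intervals,
ROUT outlier filtering at Q = 1%, and a 3.5 mm exploration grid.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .errors import ConfigurationError


@dataclasses.dataclass
class AnalysisConfig:
    """Parameters of the roaming/dwelling and exploration analyses.

    Attributes
    ----------
    interval_s:
        Length of the averaging window for speed and bending angle, seconds.
    cutoff_bounds_um_s:
        Closed interval the roaming speed cutoff is clipped into (um/s).
        The cutoff itself is placed from the control-condition speed
        distribution; see :func:`roamdwell.states.select_speed_cutoff`.
    min_bout_intervals:
        Minimum run length (in intervals) for a state run to count as a bout.
        The default 6 implements "strictly longer than five intervals".
    rout_q:
        False-discovery level Q of the ROUT outlier filter.
    grid_mm:
        Side length of the exploration-assay grid squares, millimetres.
    min_interval_coverage:
        Fraction of the nominal frames-per-interval an interval must contain
        to be retained (guards against dropped-frame gaps).
    tie_rule:
        How interval speeds exactly at the cutoff are labelled. Only
        ``"above_is_roam"`` is defined: strictly above -> roaming.
    rng_seed:
        Seed for any stochastic step; ``None`` leaves seeding to the caller.
    """

    interval_s: float = 10.0
    cutoff_bounds_um_s: tuple[float, float] = (7.0, 12.0)
    min_bout_intervals: int = 6
    rout_q: float = 0.01
    grid_mm: float = 3.5
    min_interval_coverage: float = 0.5
    tie_rule: str = "above_is_roam"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ConfigurationError("interval_s must be positive")
        lo, hi = self.cutoff_bounds_um_s
        if not lo < hi:
            raise ConfigurationError(
                f"cutoff_bounds_um_s lower bound must be < upper, got ({lo}, {hi})"
            )
        if self.min_bout_intervals < 1:
            raise ConfigurationError("min_bout_intervals must be a positive integer")
        if not 0 < self.rout_q < 0.5:
            raise ConfigurationError("rout_q must lie in (0, 0.5)")
        if self.grid_mm <= 0:
            raise ConfigurationError("grid_mm must be positive")
        if not 0 < self.min_interval_coverage <= 1:
            raise ConfigurationError("min_interval_coverage must lie in (0, 1]")
        if self.tie_rule != "above_is_roam":
            raise ConfigurationError(f"unknown tie_rule {self.tie_rule!r}")

    @property
    def cutoff_midpoint(self) -> float:
        lo, hi = self.cutoff_bounds_um_s
        return 0.5 * (lo + hi)

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cutoff_bounds_um_s"] = list(self.cutoff_bounds_um_s)
        return d

    @classmethod
    def from_toml(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        """Load a config from TOML; keyword overrides win over file values."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cutoff_bounds_um_s" in raw:
            raw["cutoff_bounds_um_s"] = tuple(raw["cutoff_bounds_um_s"])
        raw.update(overrides)
        return cls(**raw)
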