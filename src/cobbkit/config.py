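"""Pipeline configuration.

The defaults encode the operating point of the measurement workflow:
masks are normalised to a height of 2000 px, grid rows are spaced
50 px apart, and the severity scale breaks at 10/20/40 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the Cobb-angle measurement pipeline.

    Attributes
    ----------
    grid_interval : int
        Vertical spacing (px) between grid rows at which boundary
        midpoints are sampled, at the normalised image height.
    rescale_height : int or None
        Height (px) every input mask is resampled to before measurement;
        ``None`` disables resampling.
    apex_threshold : float
        Minimum lateral displacement (px) from the vertical reference
        line for a local extremum to count as an apex candidate when
        deciding between simple and complex curvature.
    severity_bounds : tuple of float
        Strictly increasing angle cut points (degrees) between the four
        severity classes.
    min_midpoints : int
        Minimum number of grid midpoints required to fit a midline
        (guarantees at least three interior inclination estimates).
    """

    grid_interval: int = 50
    rescale_height: int | None = 2000
    apex_threshold: float = 20.0
    severity_bounds: tuple[float, float, float] = (10.0, 20.0, 40.0)
    min_midpoints: int = 5

    def __post_init__(self) -> None:
        if self.grid_interval < 1:
            raise ConfigError("grid_interval must be >= 1")
        if self.rescale_height is not None and self.rescale_height < 1:
            raise ConfigError("rescale_height must be >= 1 (or None)")
        b = self.severity_bounds
        if len(b) != 3 or not (b[0] < b[1] < b[2]):
            raise ConfigError("severity_bounds must be three strictly increasing values")
        if self.min_midpoints < 4:
            raise ConfigError("min_midpoints must be >= 4")


_PARSERS = {
    "grid_interval": int,
    "rescale_height": lambda s: None if s.lower() in ("none", "") else int(s),
    "apex_threshold": float,
    "severity_bounds": lambda s: tuple(float(v) for v in s.split(",")),
    "min_midpoints": int,
}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a ``key = value`` text file.

    Unspecified keys take their defaults; unknown keys raise a warning,
    not an error. Keyword overrides are applied last (``None`` values are
    ignored so CLI flags can pass through unset options).
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _PARSERS:
                warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)
                continue
            try:
                values[key] = _PARSERS[key](val)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"cannot parse value for {key}: {val!r}") from exc
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in _PARSERS:
            raise ConfigError(f"unknown configuration key {key!r}")
        values[key] = val
    return PipelineConfig(**values)
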