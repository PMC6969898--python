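"""Run configuration shared by the CLI and the batch entry points.

Every tunable of the pipeline lives here with its default, and a stable hash
of the configuration is embedded in result files so any output can be traced
back to the exact settings (and seed) that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

#: sha256 checksums pinning the shipped colour lookup-table fixtures.
TABLE_SHA256 = {
    "uniform_lightness_synthetic.csv": "04d5a41a906258ada962656cdc659a0b83bb623f594c97ce879719ecd2dd73b0",
    "uniform_ab_grid_synthetic.csv": "1ef56e633e68b9ea74b322e04f91b48acd2f6d2bd7fb703114c40a80045209c1",
}


@dataclass
class RunConfig:
    """Pipeline settings with logged defaults.

    Attributes
    ----------
    colour_mode : {"lab2000hl", "cielab"}
        Working colour space for feature extraction; ``cielab`` is the
        documented fallback without the uniformisation tables.
    intercept : bool
        Add an intercept to the detection-time regression (the three-feature
        model has none by default).
    ue_mode : {"squared_mean", "mean_of_squares"}
        Pooling of per-observer sequence indices into the experience feature.
    kde_grid_step : float
        Resolution in seconds of the density grid over [0, 60].
    fp_dilation_radius : int
        Pixels by which the change region is dilated before a click is
        counted as correct; clicks outside count as false positives.
    t_crit_default : float
        Fallback easy/hard boundary (seconds) when the mode distribution is
        unimodal and no density minimum can be located.
    max_time : float
        Trial limit in seconds; undetected trials are censored here.
    seed : int
        Seed for every stochastic step.
    """

    colour_mode: str = "lab2000hl"
    intercept: bool = False
    ue_mode: str = "squared_mean"
    kde_grid_step: float = 0.1
    fp_dilation_radius: int = 20
    t_crit_default: float = 36.0
    max_time: float = 60.0
    seed: int = 0
    alpha_flatten: bool = field(default=False)  # flatten alpha against white instead of rejecting

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable sha256 hash of the full configuration (first 12 hex digits)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
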