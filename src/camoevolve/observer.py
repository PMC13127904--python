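"""Synthetic predator: camouflage metrics -> stochastic detection time.

A surrogate for the human visual-search players.  Each stimulus gets a
saliency score - a weighted sum of z-scored camouflage metrics (edge
disruption enters as 1 - gabrat, so disruption lowers saliency) - and the
detection (survival) time is drawn log-normally with median
``t0 * exp(-beta * saliency)``, capped at the 15 s timeout.  Hard-to-see
targets (low saliency) therefore survive longer in expectation, giving
the genetic algorithm a selection gradient with the qualitative structure
of human search: survival time rises as luminance, colour and pattern
difference fall and as edge disruption rises.

This is an explicit surrogate: it makes no claim to human effect sizes,
and the response-vs-capture hybrid of interactive play is collapsed into
a single detection time.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_KEYS = ("luminance_difference", "colour_difference",
               "pattern_difference", "gabrat")

TIMEOUT_MS = 15_000.0


def _transform(key: str, value):
    """Metrics enter saliency so that larger = more visible."""
    return 1.0 - np.asarray(value) if key == "gabrat" else np.asarray(value)


@dataclasses.dataclass
class ObserverParams:
    weights: dict[str, float] = dataclasses.field(
        default_factory=lambda: {k: 1.0 for k in METRIC_KEYS})
    t0: float = 800.0  # ms; baseline median detection time
    beta: float = 0.5  # log-time change per saliency unit
    noise_sd: float = 0.4  # SD of log-normal detection noise
    timeout: float = TIMEOUT_MS
    means: dict[str, float] | None = None  # z-normalization reference
    sds: dict[str, float] | None = None

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not self.timeout > self.t0 > 0:
            raise ValueError("require timeout > t0 > 0")

    @property
    def calibrated(self) -> bool:
        return self.means is not None and self.sds is not None


@dataclasses.dataclass
class Trial:
    survival_time: float  # ms, in (0, timeout]
    timed_out: bool
    fitness: float  # = survival time (timeouts score the timeout value)


def calibrate(params: ObserverParams, table: pd.DataFrame) -> ObserverParams:
    """Fix the z-normalization reference from a calibration batch of
    metrics (random genomes across the scene library).  Zero-variance
    metrics are disabled with a warning."""
    if len(table) < 2:
        raise ValueError("calibration table needs >= 2 rows")
    means, sds, weights = {}, {}, dict(params.weights)
    for k in METRIC_KEYS:
        vals = _transform(k, table[k].to_numpy(dtype=float))
        m, s = float(vals.mean()), float(vals.std())
        means[k], sds[k] = m, s
        if s <= 1e-12:
            logger.warning("metric %s has zero variance; weight disabled", k)
            weights[k] = 0.0
            sds[k] = 1.0
    return dataclasses.replace(params, means=means, sds=sds, weights=weights)


def saliency(metrics: dict[str, float], params: ObserverParams) -> float:
    if not params.calibrated:
        raise RuntimeError("observer not calibrated")
    s = 0.0
    for k in METRIC_KEYS:
        z = (float(_transform(k, metrics[k])) - params.means[k]) / params.sds[k]
        s += params.weights[k] * z
    return s


def detect(metrics: dict[str, float], params: ObserverParams,
           rng: np.random.Generator) -> Trial:
    """Draw one detection time for a stimulus from its metrics."""
    s = saliency(metrics, params)
    t = params.t0 * np.exp(-params.beta * s + params.noise_sd * rng.normal())
    timed_out = t >= params.timeout
    t = min(float(t), params.timeout)
    return Trial(survival_time=t, timed_out=bool(timed_out), fitness=t)
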