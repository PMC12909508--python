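"""Seeded sequential hyperparameter search.

A small trial-based optimizer with the usual study interface: define a
search space of (log-)uniform and categorical parameters, evaluate an
objective per trial, keep a trial log, return the best set.  After a
random warm-up, half of the draws are local perturbations of the best
point so far (a simple exploit/explore schedule), which is enough for
the low-dimensional spaces tuned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Uniform", "LogUniform", "Categorical", "Trial", "tune"]


@dataclass
class Uniform:
    low: float
    high: float

    def sample(self, rng):
        return float(rng.uniform(self.low, self.high))

    def neighbor(self, value, rng, frac=0.2):
        span = (self.high - self.low) * frac
        return float(np.clip(value + rng.normal(0, span), self.low, self.high))


@dataclass
class LogUniform:
    low: float
    high: float

    def sample(self, rng):
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def neighbor(self, value, rng, frac=0.2):
        span = (np.log(self.high) - np.log(self.low)) * frac
        logv = np.clip(np.log(value) + rng.normal(0, span), np.log(self.low), np.log(self.high))
        return float(np.exp(logv))


@dataclass
class Categorical:
    choices: tuple

    def sample(self, rng):
        return self.choices[int(rng.integers(len(self.choices)))]

    def neighbor(self, value, rng, frac=0.2):
        return self.sample(rng)


@dataclass
class Trial:
    number: int
    params: dict
    value: float


def tune(objective, space, trials=50, seed=0, warmup=None):
    """Minimize `objective(params)` over `space`; returns (best_params, log).

    `space` maps parameter names to distributions.  The log has exactly
    `trials` entries.  A single-point space returns that point after one
    evaluation per trial (all draws coincide).
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    warmup = warmup if warmup is not None else max(5, trials // 5)
    log = []
    best = None
    for t in range(trials):
        if best is not None and t >= warmup and rng.random() < 0.5:
            params = {
                k: dist.neighbor(best.params[k], rng) for k, dist in space.items()
            }
        else:
            params = {k: dist.sample(rng) for k, dist in space.items()}
        value = float(objective(params))
        trial = Trial(number=t, params=params, value=value)
        log.append(trial)
        if best is None or value < best.value:
            best = trial
    return dict(best.params), log
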