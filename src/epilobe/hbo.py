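"""SVGL-HBO: honey-badger wrapper feature selection with stochastic
variance-reduced gradient Langevin exploration.

Agents are continuous positions in [0, 1]^d; a feature is selected when
its coordinate exceeds 0.5 (the standard continuous relaxation of a
wrapper mask).  Fitness is the cross-validated accuracy of a fixed,
cheap probe classifier on the masked features.  Each iteration every
agent takes, with equal probability, either

* an exploration step — a Langevin update ``q - w*g + sqrt(2w)*N(0,I)``
  whose gradient surrogate ``g`` is a variance-reduced two-point
  (simultaneous-perturbation) estimate of the probe's cross-entropy on
  the continuous relaxation: the same perturbation is evaluated at the
  agent and at a periodically refreshed snapshot, and the snapshot's
  averaged gradient is the control variate; or
* an exploitation (honey-phase) step toward/away from the prey (best)
  position, scaled by the time-adaptive density factor, with greedy
  acceptance.

Positions are clipped to bounds after every update and the best-so-far
fitness trace is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = ["HBOConfig", "HBOState", "fitness", "exploration_step", "exploitation_step", "run"]


@dataclass
class HBOConfig:
    population: int = 30
    iterations: int = 100
    b_low: float = 0.0
    b_high: float = 1.0
    step_size: float = 0.05  # Langevin step, decays as 1/sqrt(iteration)
    theta: float = 2.0  # density-time constant
    explore_prob: float = 0.5
    snapshot_every: int = 10
    spsa_delta: float = 0.1
    cv_folds: int = 3
    seed: int = 0
    count_penalty: float = 0.0  # optional |mask|/d penalty, off by default


@dataclass
class HBOState:
    positions: np.ndarray  # population x d
    fitness: np.ndarray  # chi per agent
    best_position: np.ndarray  # prey
    best_fitness: float
    iteration: int = 0
    trace: list = field(default_factory=list)  # (iteration, best chi, mean chi)
    snapshot: np.ndarray | None = None
    snapshot_grad: np.ndarray | None = None


def _probe_cv_accuracy(x, y, folds, seed):
    """Mean stratified CV accuracy of the fixed probe (logistic regression)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        clf = LogisticRegression(max_iter=200)
        xs = StandardScaler().fit(x[tr])
        clf.fit(xs.transform(x[tr]), y[tr])
        accs.append(float(clf.score(xs.transform(x[te]), y[te])))
    return float(np.mean(accs))


def fitness(mask, features, labels, config=None, _cache=None):
    """chi = mean cross-validated probe accuracy on the masked features.

    An empty mask scores 0 rather than raising, so a degenerate agent
    never crashes the search.
    """
    cfg = config or HBOConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    key = mask.tobytes()
    if _cache is not None and key in _cache:
        return _cache[key]
    chi = _probe_cv_accuracy(np.asarray(features)[:, mask], np.asarray(labels), cfg.cv_folds, cfg.seed)
    if cfg.count_penalty:
        chi -= cfg.count_penalty * mask.mean()
    if _cache is not None:
        _cache[key] = chi
    return chi


class _SurrogateLoss:
    """Probe cross-entropy on the continuous relaxation (features scaled
    by the position vector), evaluated on a fixed stratified holdout.

    The probe here is an L2-regularized logistic regression fitted by a
    few IRLS (Newton) steps in plain numpy — thousands of two-point
    gradient evaluations per search make the fit cost the bottleneck.
    The discrete fitness chi keeps the full cross-validated probe.
    """

    def __init__(self, features, labels, cfg):
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels)
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        tr, te = next(iter(skf.split(x, y)))
        self.xtr, self.xte = x[tr], x[te]
        self.ytr = (y[tr] == np.max(y)).astype(float)
        self.yte = (y[te] == np.max(y)).astype(float)

    def __call__(self, q):
        w = np.clip(q, 0.0, 1.0)[None, :]
        xtr, xte = self.xtr * w, self.xte * w
        mu = xtr.mean(axis=0)
        sd = xtr.std(axis=0)
        sd[sd == 0] = 1.0
        xtr = np.hstack([(xtr - mu) / sd, np.ones((len(xtr), 1))])
        xte = np.hstack([(xte - mu) / sd, np.ones((len(xte), 1))])
        beta = np.zeros(xtr.shape[1])
        lam = 1e-2
        for _ in range(12):
            p = 1.0 / (1.0 + np.exp(-xtr @ beta))
            wgt = np.maximum(p * (1 - p), 1e-6)
            grad = xtr.T @ (p - self.ytr) + lam * beta
            hess = (xtr * wgt[:, None]).T @ xtr + lam * np.eye(xtr.shape[1])
            step = np.linalg.solve(hess, grad)
            beta -= step
            if np.abs(step).max() < 1e-5:
                break
        pte = np.clip(1.0 / (1.0 + np.exp(-xte @ beta)), 1e-12, 1 - 1e-12)
        return float(-np.mean(self.yte * np.log(pte) + (1 - self.yte) * np.log(1 - pte)))


def _spsa_grad(q, eps, loss_fn, cfg):
    """Two-point gradient estimate with shared Gaussian perturbation `eps`."""
    c = cfg.spsa_delta
    return (loss_fn(q + c * eps) - loss_fn(q - c * eps)) / (2.0 * c) * eps


def exploration_step(state, config, features, labels, rng, agents=None, loss_fn=None):
    """Langevin update of each agent's position,
    ``q - w*g_vr + sqrt(2w)*hbar``, with variance-reduced SPSA gradient."""
    cfg = config
    d = state.positions.shape[1]
    if loss_fn is None:
        loss_fn = _SurrogateLoss(features, labels, cfg)
    step = cfg.step_size / np.sqrt(max(state.iteration, 1))
    if state.snapshot is None or state.iteration % cfg.snapshot_every == 1:
        state.snapshot = state.best_position.copy()
        grads = [
            _spsa_grad(state.snapshot, rng.standard_normal(d), loss_fn, cfg)
            for _ in range(3)
        ]
        state.snapshot_grad = np.mean(grads, axis=0)
    for i in agents if agents is not None else range(len(state.positions)):
        eps = rng.standard_normal(d)
        g = _spsa_grad(state.positions[i], eps, loss_fn, cfg)
        g_snap = _spsa_grad(state.snapshot, eps, loss_fn, cfg)
        g_vr = g - g_snap + state.snapshot_grad
        hbar = rng.standard_normal(d)
        state.positions[i] = np.clip(
            state.positions[i] - step * g_vr + np.sqrt(2.0 * step) * hbar,
            cfg.b_low,
            cfg.b_high,
        )
    return state


def exploitation_step(state, config, features, labels, rng, cache, agents=None):
    """Honey-phase move toward/away from the prey with greedy acceptance."""
    cfg = config
    density = cfg.theta * state.iteration / cfg.iterations  # -> theta at the end
    for i in agents if agents is not None else range(len(state.positions)):
        x2 = rng.random()
        mu = 1.0 if x2 <= 0.5 else -1.0
        phi = np.abs(state.best_position - state.positions[i])
        candidate = np.clip(
            state.best_position + mu * x2 * density * phi, cfg.b_low, cfg.b_high
        )
        chi = fitness(candidate > 0.5, features, labels, cfg, cache)
        if chi > state.fitness[i]:
            state.positions[i] = candidate
            state.fitness[i] = chi
    return state


def run(features, labels, config=None):
    """Full SVGL-HBO search; returns (selected indices, state).

    Selected features are those with best-position coordinate > 0.5; if
    none crosses the threshold the single largest coordinate is taken so
    the selected set is never empty.
    """
    cfg = config or HBOConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with at least one column")
    d = x.shape[1]
    rng = np.random.default_rng(cfg.seed)
    cache = {}
    # init: x1 drawn per dimension in [0,1], scaled to the bounds
    x1 = rng.random((cfg.population, d))
    positions = cfg.b_low + x1 * (cfg.b_high - cfg.b_low)
    chis = np.array([fitness(p > 0.5, x, y, cfg, cache) for p in positions])
    best = int(np.argmax(chis))
    state = HBOState(
        positions=positions,
        fitness=chis,
        best_position=positions[best].copy(),
        best_fitness=float(chis[best]),
    )
    loss_fn = _SurrogateLoss(x, y, cfg)
    for it in range(1, cfg.iterations + 1):
        state.iteration = it
        explore_mask = rng.random(cfg.population) < cfg.explore_prob
        explorers = np.flatnonzero(explore_mask)
        exploiters = np.flatnonzero(~explore_mask)
        if len(explorers):
            exploration_step(state, cfg, x, y, rng, agents=explorers, loss_fn=loss_fn)
            for i in explorers:
                state.fitness[i] = fitness(state.positions[i] > 0.5, x, y, cfg, cache)
        if len(exploiters):
            exploitation_step(state, cfg, x, y, rng, cache, agents=exploiters)
        i_best = int(np.argmax(state.fitness))
        if state.fitness[i_best] > state.best_fitness:
            state.best_fitness = float(state.fitness[i_best])
            state.best_position = state.positions[i_best].copy()
        state.trace.append((it, state.best_fitness, float(state.fitness.mean())))
    mask = state.best_position > 0.5
    if not mask.any():
        mask[int(np.argmax(state.best_position))] = True
    return np.flatnonzero(mask), state


def exhaustive_best(features, labels, config=None):
    """Brute-force optimum over all non-empty masks (small d only)."""
    cfg = config or HBOConfig()
    x = np.asarray(features)
    y = np.asarray(labels)
    d = x.shape[1]
    if d > 16:
        raise ValueError("exhaustive search is limited to d <= 16")
    cache = {}
    best_chi, best_mask = -np.inf, None
    for bits in range(1, 2**d):
        mask = np.array([(bits >> k) & 1 for k in range(d)], dtype=bool)
        chi = fitness(mask, x, y, cfg, cache)
        if chi > best_chi:
            best_chi, best_mask = chi, mask
    return np.flatnonzero(best_mask), best_chi
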