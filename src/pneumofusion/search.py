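"""Hyperparameter search with a tree-structured Parzen estimator (TPE).

The search space mirrors the training-time tunables: batch size in
{8, 16, 32}, dropout in [0.2, 0.5], L2 coefficient in [1e-4, 1e-2] (log
scale), learning rate in [1e-5, 1e-3] (log scale), 20 trials.

The sampler is a compact TPE: after a random startup phase, observed
trials are split at the top-gamma quantile of the objective; continuous
dimensions model the "good" and "bad" sets with Gaussian KDEs and pick
the candidate maximizing the density ratio l(x)/g(x); categorical
dimensions use smoothed empirical frequencies.  Failed trials are recorded
and skipped, and the search continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.stats import gaussian_kde


@dataclass(frozen=True)
class SearchSpace:
    batch_size: tuple[int, ...] = (8, 16, 32)
    dropout: tuple[float, float] = (0.2, 0.5)
    l2_coeff: tuple[float, float] = (1e-4, 1e-2)  # log scale
    learning_rate: tuple[float, float] = (1e-5, 1e-3)  # log scale
    n_trials: int = 20

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for lo, hi in (self.dropout, self.l2_coeff, self.learning_rate):
            if not lo <= hi:
                raise ValueError("range bounds must satisfy lo <= hi")

    def dimensions(self) -> dict[str, dict[str, Any]]:
        return {
            "batch_size": {"kind": "categorical",
                           "choices": self.batch_size},
            "dropout": {"kind": "continuous", "bounds": self.dropout,
                        "log": False},
            "l2_coeff": {"kind": "continuous", "bounds": self.l2_coeff,
                         "log": True},
            "learning_rate": {"kind": "continuous",
                              "bounds": self.learning_rate, "log": True},
        }


@dataclass
class Trial:
    number: int
    params: dict[str, Any]
    value: float | None
    state: str  # "complete" | "failed"


@dataclass
class SearchResult:
    best_params: dict[str, Any]
    best_value: float
    trials: list[Trial] = field(default_factory=list)


class TPESampler:
    """Independent per-dimension TPE suggestion engine (maximization)."""

    def __init__(self, dimensions: dict[str, dict[str, Any]], seed: int = 0,
                 n_startup: int = 8, gamma: float = 0.25,
                 n_candidates: int = 64):
        self.dimensions = dimensions
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # -- random draws ---------------------------------------------------
    def _random_value(self, dim: dict[str, Any]):
        if dim["kind"] == "categorical":
            return dim["choices"][self.rng.integers(len(dim["choices"]))]
        lo, hi = dim["bounds"]
        if dim["log"]:
            value = float(np.exp(self.rng.uniform(np.log(lo), np.log(hi))))
        else:
            value = float(self.rng.uniform(lo, hi))
        return min(max(value, lo), hi)

    # -- TPE ------------------------------------------------------------
    def _split(self, history: list[Trial]) -> tuple[list[Trial], list[Trial]]:
        complete = [t for t in history if t.state == "complete"]
        complete.sort(key=lambda t: t.value, reverse=True)
        n_good = max(1, int(np.ceil(self.gamma * len(complete))))
        return complete[:n_good], complete[n_good:]

    def _suggest_continuous(self, name: str, dim: dict[str, Any],
                            good: list[Trial], bad: list[Trial]):
        lo, hi = dim["bounds"]
        transform = np.log if dim["log"] else (lambda v: v)
        inverse = np.exp if dim["log"] else (lambda v: v)
        good_x = np.array([transform(t.params[name]) for t in good])
        bad_x = np.array([transform(t.params[name]) for t in bad])
        span = transform(hi) - transform(lo)
        n_random = self.n_candidates // 4
        candidates = np.array([
            transform(self._random_value(dim)) for _ in range(n_random)])
        if good_x.size:  # exploit: propose tightly around past good values
            jitter = max(0.5 * float(good_x.std()), span / 20.0, 1e-12)
            near = self.rng.choice(good_x,
                                   size=self.n_candidates - n_random) + \
                self.rng.normal(0, jitter, self.n_candidates - n_random)
            candidates = np.concatenate([candidates, near])
        candidates = np.clip(candidates, transform(lo), transform(hi))

        uniform = 1.0 / max(span, 1e-12)

        def density(samples: np.ndarray, at: np.ndarray) -> np.ndarray:
            # KDE mixed with one pseudo-count of uniform prior; the prior
            # keeps the density ratio from exploding at the box edges
            if samples.size < 2 or np.ptp(samples) == 0:
                kde = np.full_like(at, uniform)
            else:
                kde = gaussian_kde(samples, bw_method=0.2)(at)
            n = samples.size
            return (n * kde + uniform) / (n + 1)

        score = density(good_x, candidates) / \
            np.maximum(density(bad_x, candidates), 1e-12)
        best = float(inverse(candidates[int(np.argmax(score))]))
        return min(max(best, lo), hi)

    def _suggest_categorical(self, name: str, dim: dict[str, Any],
                             good: list[Trial], bad: list[Trial]):
        choices = dim["choices"]
        good_counts = np.array([
            sum(1 for t in good if t.params[name] == c) for c in choices],
            dtype=np.float64) + 1.0
        bad_counts = np.array([
            sum(1 for t in bad if t.params[name] == c) for c in choices],
            dtype=np.float64) + 1.0
        score = (good_counts / good_counts.sum()) / \
            (bad_counts / bad_counts.sum())
        return choices[int(np.argmax(score))]

    def suggest(self, history: list[Trial]) -> dict[str, Any]:
        complete = [t for t in history if t.state == "complete"]
        if len(complete) < self.n_startup:
            return {name: self._random_value(dim)
                    for name, dim in self.dimensions.items()}
        good, bad = self._split(history)
        params = {}
        for name, dim in self.dimensions.items():
            if dim["kind"] == "categorical":
                params[name] = self._suggest_categorical(name, dim, good, bad)
            else:
                params[name] = self._suggest_continuous(name, dim, good, bad)
        return params


def hyperparameter_search(space: SearchSpace,
                          objective: Callable[[dict[str, Any]], float],
                          seed: int = 0,
                          n_trials: int | None = None) -> SearchResult:
    """Run TPE-guided trials maximizing ``objective``; failures continue."""
    n_trials = n_trials if n_trials is not None else space.n_trials
    sampler = TPESampler(space.dimensions(), seed=seed)
    trials: list[Trial] = []
    for number in range(n_trials):
        params = sampler.suggest(trials)
        try:
            value = float(objective(params))
            trials.append(Trial(number, params, value, "complete"))
        except Exception:
            trials.append(Trial(number, params, None, "failed"))
    complete = [t for t in trials if t.state == "complete"]
    if not complete:
        raise RuntimeError("every search trial failed")
    best = max(complete, key=lambda t: t.value)
    return SearchResult(best_params=best.params, best_value=best.value,
                        trials=trials)
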