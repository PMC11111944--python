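"""A compact Tree-structured Parzen Estimator for hyperparameter search.

Sequential model-based optimization: after a short random start-up
phase, completed trials are split at the gamma-quantile of the
objective into a "good" and a "bad" set.  For each dimension a Parzen
(kernel) density is built over the good values (l) and the bad values
(g); candidates are drawn from l and the one maximizing the density
ratio l/g is proposed.  Dimensions are treated independently; floats
and ints support log-scaled ranges, categoricals use Laplace-smoothed
frequency weights.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["Float", "Int", "Categorical", "TPESampler", "minimize"]


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"empty range [{self.low}, {self.high}]")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled range requires low > 0")

    def to_unit(self, x):
        lo, hi = self._bounds()
        return (self._tf(x) - lo) / (hi - lo)

    def from_unit(self, u):
        lo, hi = self._bounds()
        x = lo + np.clip(u, 0.0, 1.0) * (hi - lo)
        return float(np.exp(x)) if self.log else float(x)

    def _tf(self, x):
        return np.log(x) if self.log else np.asarray(x, dtype=float)

    def _bounds(self):
        return (
            (np.log(self.low), np.log(self.high))
            if self.log
            else (self.low, self.high)
        )


@dataclass(frozen=True)
class Int(Float):
    def from_unit(self, u):
        return int(round(super().from_unit(u)))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ValueError("empty choice list")


class TPESampler:
    """Propose configurations given the history of completed trials."""

    def __init__(
        self,
        space: dict,
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.15,
        n_candidates: int = 24,
    ):
        if not space:
            raise ValueError("search space must be non-empty")
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def _random_config(self) -> dict:
        config = {}
        for name, spec in self.space.items():
            if isinstance(spec, Categorical):
                config[name] = spec.choices[self.rng.integers(len(spec.choices))]
            else:
                config[name] = spec.from_unit(self.rng.random())
        return config

    def ask(self, history: Sequence[tuple[dict, float]]) -> dict:
        finite = [(p, v) for p, v in history if np.isfinite(v)]
        if len(finite) < self.n_startup:
            return self._random_config()
        values = np.array([v for _, v in finite])
        n_good = max(2, int(np.ceil(self.gamma * len(finite))))
        order = np.argsort(values, kind="stable")
        good = [finite[i][0] for i in order[:n_good]]  # best first
        bad = [finite[i][0] for i in order[n_good:]] or good
        config = {}
        for name, spec in self.space.items():
            if isinstance(spec, Categorical):
                config[name] = self._ask_categorical(spec, good, bad, name)
            else:
                config[name] = self._ask_numeric(spec, good, bad, name)
        return config

    def _ask_categorical(self, spec, good, bad, name):
        # sample from the Laplace-smoothed "good" distribution rather
        # than taking an argmax, so unexplored choices keep a chance
        k = len(spec.choices)
        counts_g = np.ones(k)
        index = {c: i for i, c in enumerate(spec.choices)}
        for p in good:
            counts_g[index[p[name]]] += 1
        probs = counts_g / counts_g.sum()
        return spec.choices[int(self.rng.choice(k, p=probs))]

    @staticmethod
    def _rank_weights(n: int) -> np.ndarray:
        """Linearly decaying kernel weights; the best trial counts most."""
        w = np.linspace(2.0, 1.0, n)
        return w / w.sum()

    def _ask_numeric(self, spec, good, bad, name):
        ug = np.array([spec.to_unit(p[name]) for p in good])  # best first
        ub = np.array([spec.to_unit(p[name]) for p in bad])
        wg = self._rank_weights(len(ug))
        # the "good" density carries a uniform prior component so the
        # search keeps exploring even after an unlucky start-up phase
        from_prior = self.rng.random(self.n_candidates) < 1.0 / (len(ug) + 1)
        centers = ug[self.rng.choice(len(ug), size=self.n_candidates, p=wg)]
        cand = np.where(
            from_prior,
            self.rng.random(self.n_candidates),
            np.clip(
                centers + self.rng.normal(0.0, self._bw(ug), size=self.n_candidates),
                0.0,
                1.0,
            ),
        )
        lg = self._parzen(cand, ug, wg)
        lb = self._parzen(cand, ub, self._rank_weights(len(ub)))
        best = cand[int(np.argmax(lg / np.maximum(lb, 1e-12)))]
        return spec.from_unit(best)

    @staticmethod
    def _bw(u: np.ndarray) -> float:
        spread = max(float(np.std(u)), 1e-3)
        return max(1.06 * spread * len(u) ** -0.2, 0.15)

    def _parzen(self, x: np.ndarray, centers: np.ndarray, weights: np.ndarray) -> np.ndarray:
        bw = self._bw(centers)
        z = (x[:, None] - centers[None, :]) / bw
        kernels = (np.exp(-0.5 * z**2) @ weights) / (bw * np.sqrt(2 * np.pi))
        # mixture of the weighted kernel estimate and a uniform prior
        n = len(centers)
        return (n * kernels + 1.0) / (n + 1)


def minimize(
    objective: Callable[[dict], float],
    space: dict,
    n_trials: int,
    seed: int = 0,
    sampler_kwargs: dict | None = None,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Run ``n_trials`` TPE iterations; returns (best_params, best_value,
    trial history).  ``n_trials`` must be >= 1."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = TPESampler(space, seed=seed, **(sampler_kwargs or {}))
    history: list[tuple[dict, float]] = []
    best: tuple[dict, float] | None = None
    for _ in range(n_trials):
        params = sampler.ask(history)
        value = float(objective(params))
        history.append((params, value))
        if best is None or value < best[1]:
            best = (params, value)
    return best[0], best[1], history
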