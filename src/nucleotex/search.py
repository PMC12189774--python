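"""Tree-structured Parzen estimator (TPE) over categorical search spaces.

Sequential model-based optimization in the standard TPE formulation:
after a random startup phase, trials are split at a score quantile into
a "good" set and a "bad" set; for every parameter a smoothed categorical
density is estimated from each set (l for good, g for bad), candidates
are drawn from l, and the candidate maximizing the likelihood ratio
l(x)/g(x) is evaluated next. All parameters here are categorical —
numeric hyperparameters enter as small grids — which keeps the density
model exact rather than kernel-based.

Conditional parameters (e.g. per-classifier hyperparameters) are handled
through an activity predicate: inactive parameters contribute nothing to
a trial's likelihood ratio and are not recorded for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Mapping, Sequence

import numpy as np

ActiveFn = Callable[[str, Mapping[str, Any]], bool]


def _always_active(name: str, params: Mapping[str, Any]) -> bool:
    return True


@dataclass
class TPESampler:
    """Categorical TPE sampler.

    Parameters
    ----------
    seed : seeds candidate generation; identical (seed, history) sequences
        reproduce identical suggestions.
    n_startup : trials drawn uniformly at random before the density model
        is used.
    gamma : fraction of trials treated as "good".
    n_candidates : candidates scored per suggestion.
    prior_weight : Dirichlet smoothing added to every choice's count.
    """

    seed: int = 0
    n_startup: int = 10
    gamma: float = 0.25
    n_candidates: int = 24
    prior_weight: float = 1.0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    # -- internals ---------------------------------------------------------

    def _random_params(self, space: Mapping[str, Sequence[Hashable]],
                       is_active: ActiveFn) -> dict[str, Any]:
        params: dict[str, Any] = {}
        for name, choices in space.items():
            if is_active(name, params):
                params[name] = choices[self._rng.integers(len(choices))]
        return params

    @staticmethod
    def _smoothed(counts: Mapping[Hashable, float],
                  choices: Sequence[Hashable], prior: float) -> dict[Hashable, float]:
        total = sum(counts.get(c, 0.0) for c in choices) + prior * len(choices)
        return {c: (counts.get(c, 0.0) + prior) / total for c in choices}

    def suggest(
        self,
        space: Mapping[str, Sequence[Hashable]],
        history: Sequence[tuple[Mapping[str, Any], float]],
        is_active: ActiveFn = _always_active,
    ) -> dict[str, Any]:
        """Propose the next parameter assignment given (params, score) history.

        Scores are maximized. Until ``n_startup`` trials exist the
        suggestion is uniform random; afterwards candidates sampled from
        the good-density l are ranked by Σ log l/g over active parameters.
        """
        if len(history) < self.n_startup:
            return self._random_params(space, is_active)

        scores = np.array([s for _, s in history], dtype=np.float64)
        order = np.argsort(-scores, kind="stable")
        n_good = max(1, int(np.ceil(self.gamma * len(history))))
        good_idx = set(order[:n_good].tolist())
        good = [history[i][0] for i in range(len(history)) if i in good_idx]
        bad = [history[i][0] for i in range(len(history)) if i not in good_idx]

        densities: dict[str, tuple[dict, dict]] = {}
        for name, choices in space.items():
            gc: dict[Hashable, float] = {}
            bc: dict[Hashable, float] = {}
            for p in good:
                if name in p:
                    gc[p[name]] = gc.get(p[name], 0.0) + 1.0
            for p in bad:
                if name in p:
                    bc[p[name]] = bc.get(p[name], 0.0) + 1.0
            densities[name] = (
                self._smoothed(gc, choices, self.prior_weight),
                self._smoothed(bc, choices, self.prior_weight),
            )

        best_params: dict[str, Any] | None = None
        best_score = -np.inf
        for _ in range(self.n_candidates):
            cand: dict[str, Any] = {}
            llr = 0.0
            for name, choices in space.items():
                if not is_active(name, cand):
                    continue
                l_d, g_d = densities[name]
                probs = np.array([l_d[c] for c in choices])
                probs = probs / probs.sum()
                choice = choices[self._rng.choice(len(choices), p=probs)]
                cand[name] = choice
                llr += np.log(l_d[choice]) - np.log(g_d[choice])
            if llr > best_score:
                best_score = llr
                best_params = cand
        assert best_params is not None
        return best_params
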