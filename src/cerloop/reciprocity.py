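"""Probability that zero reciprocal connections appear among n connected
PC / PC-MLI pairs if each connection is reciprocal with probability p.

Pairs are assumed independent, so the analytic value is the binomial
(1 - p)^n; a Monte Carlo estimate is provided alongside for parity with
simulation-based phrasing of the same calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ReciprocityModel:
    n_pairs: int = 10
    p_reciprocal: float = 0.5
    n_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (0.0 <= self.p_reciprocal <= 1.0):
            raise ValueError("p_reciprocal must be in [0, 1]")


def prob_no_reciprocal(model: ReciprocityModel, seed: int = 0) -> dict:
    """Analytic (1-p)^n and a Monte Carlo estimate with its standard error."""
    analytic = (1.0 - model.p_reciprocal) ** model.n_pairs
    rng = np.random.default_rng(seed)
    draws = rng.random((model.n_draws, model.n_pairs)) < model.p_reciprocal
    none = ~draws.any(axis=1)
    mc = float(none.mean())
    se = float(np.sqrt(max(mc * (1 - mc), 0.0) / model.n_draws))
    return {"analytic": float(analytic), "monte_carlo": mc,
            "mc_standard_error": se, "n_draws": model.n_draws}
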