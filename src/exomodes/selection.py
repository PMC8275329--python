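"""Model selection over the number of binding modes by BIC.

For each candidate mode count the sampler is run (with restarts), hill
climbed, and scored; BIC = K ln(n) - 2 ln(P-hat) with K counting three free
parameters per PWM column, one per read-window position, and two offsets
per mode.  The minimum-BIC model wins; ties break toward fewer modes.
``n`` is the number of datapoints the marginal likelihood is computed over,
i.e. the reverse-complement-augmented count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DataCache, FittedModel, Priors
from .sampler import SamplerConfig, estimate_parameters, hill_climb, run_chain

logger = logging.getLogger(__name__)


def count_free_parameters(fitted: FittedModel) -> int:
    """K = sum over modes of (3*w + w_pos + w_neg + 2)."""
    return int(
        sum(3 * md.w + md.w_pos + md.w_neg + 2 for md in fitted.modes)
    )


def bic(fitted: FittedModel, n: int) -> float:
    """Bayesian information criterion at the MAP estimate."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return count_free_parameters(fitted) * float(np.log(n)) - 2.0 * fitted.log_posterior


@dataclass
class SweepResult:
    table: pd.DataFrame           # per-m: m, K, log_posterior, bic, seed, failed
    models: dict[int, FittedModel]
    chosen_m: int

    @property
    def best(self) -> FittedModel:
        return self.models[self.chosen_m]


def fit_single(
    cache: DataCache,
    m: int,
    priors: Priors,
    config: SamplerConfig,
    seed: int,
) -> tuple[FittedModel, int]:
    """Fit one mode count with independent restarts; best posterior wins.

    Returns the fitted model and the seed of the winning restart.
    """
    best: FittedModel | None = None
    best_seed = seed
    for r in range(max(1, config.restarts)):
        chain_seed = seed + 1000 * r
        state, _trace = run_chain(cache, m, priors, config, chain_seed)
        state = hill_climb(state, cache, priors, config)
        fitted = estimate_parameters(state, cache, priors)
        fitted.seed = chain_seed
        if best is None or fitted.log_posterior > best.log_posterior:
            best = fitted
            best_seed = chain_seed
    assert best is not None
    return best, best_seed


def model_sweep(
    cache: DataCache,
    m_values: list[int] | range,
    priors: Priors | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> SweepResult:
    """Fit every candidate mode count and select the minimum-BIC model."""
    m_values = sorted(set(int(m) for m in m_values))
    if not m_values:
        raise ValueError("m_values must be nonempty")
    priors = priors or Priors()
    config = config or SamplerConfig()
    n = cache.n
    rows = []
    models: dict[int, FittedModel] = {}
    for m in m_values:
        try:
            fitted, win_seed = fit_single(cache, m, priors, config, seed + m)
        except Exception:
            logger.warning("fit failed for m=%d; excluded from selection", m,
                           exc_info=True)
            rows.append({"m": m, "K": np.nan, "log_posterior": np.nan,
                         "bic": np.nan, "seed": np.nan, "failed": True})
            continue
        b = bic(fitted, n)
        fitted.bic = b
        models[m] = fitted
        rows.append({"m": m, "K": count_free_parameters(fitted),
                     "log_posterior": fitted.log_posterior, "bic": b,
                     "seed": win_seed, "failed": False})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("every candidate mode count failed to fit")
    # ties break toward smaller m (table is sorted by m; idxmin takes first)
    chosen = int(ok.loc[ok["bic"].idxmin(), "m"])
    table["chosen"] = table["m"] == chosen
    return SweepResult(table=table, models=models, chosen_m=chosen)
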