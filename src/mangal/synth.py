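"""Synthetic generators for the inputs the analysis needs but no archive holds.

The raw expert responses behind the Delphi figures (ranking vote tables,
impact intensity/scale scores, recovery-timeframe choices) were never
deposited, so these generators emulate their statistical structure: Likert
vote-count matrices whose mode shifts with a latent option quality, impact
(I, S) pairs on the unit square with an optional dominant "development"
impact, categorical timeframe votes over the four offered bins, and random
stand fixtures matching target density and diameter moments.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .delphi import RESTORATION_MODES, TIMEFRAME_BINS, VoteTable
from .impacts import IMPACT_NAMES, ImpactSpec
from .stand import Stand


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def gen_vote_table(n_options: int, n_experts: int,
                   preference_strength: float = 1.0,
                   seed: int = 0) -> VoteTable:
    """Likert vote-count matrix with a latent-quality preference model.

    Each option draws a quality ~ U(0,1); each expert's vote level is
    ``1 + floor(5 * sigmoid(strength*(quality - 1/2) + eps))`` with
    logistic noise ``eps``, clipped to 1..5.  At ``preference_strength=0``
    the sigmoid of logistic noise is exactly uniform, so levels are uniform
    on 1..5; larger strengths shift the mode towards 5 (high quality) or 1
    (low quality).  Row sums equal ``n_experts``.
    """
    if n_options < 1 or n_experts < 1:
        raise ValueError("need at least one option and one expert")
    if preference_strength < 0:
        raise ValueError("preference_strength must be non-negative")
    rng = _rng(seed)
    quality = rng.uniform(size=n_options)
    eps = rng.logistic(size=(n_options, n_experts))
    z = preference_strength * (quality[:, None] - 0.5) + eps
    u = 1.0 / (1.0 + np.exp(-z))
    levels = np.clip(1 + np.floor(5.0 * u).astype(np.int64), 1, 5)
    counts = np.stack([(levels == k).sum(axis=1) for k in range(1, 6)], axis=1)
    names = tuple(f"option_{i + 1}" for i in range(n_options))
    return VoteTable(names, counts)


def gen_impact_set(n_impacts: int = 10, seed: int = 0,
                   make_dominant: bool = True,
                   formula_mode: str = "literal") -> list[ImpactSpec]:
    """Impact (intensity, spatial scale) pairs on the unit square.

    With ``make_dominant`` the "development" impact receives the
    componentwise maximum of all drawn (I, S) pairs, mirroring its role as
    the dominant threat in the elicitation.
    """
    if n_impacts < 1:
        raise ValueError("need at least one impact")
    rng = _rng(seed)
    names = [IMPACT_NAMES[i % len(IMPACT_NAMES)] if i < len(IMPACT_NAMES)
             else f"impact_{i + 1}" for i in range(n_impacts)]
    I = rng.uniform(size=n_impacts)
    S = rng.uniform(size=n_impacts)
    if make_dominant:
        try:
            k = names.index("development")
        except ValueError:
            k = 0
        I[k] = I.max()
        S[k] = S.max()
    return [ImpactSpec(nm, float(i), float(s), formula_mode)
            for nm, i, s in zip(names, I, S)]


def gen_timeframe_responses(n_experts: int,
                            country_pool: list[str],
                            bin_probs=(0.25, 0.25, 0.25, 0.25),
                            seed: int = 0,
                            p_natural: float = 0.5) -> pd.DataFrame:
    """Categorical recovery-timeframe votes over the four offered bins.

    Returns a DataFrame with columns expert, country, mode, bin; countries
    are sampled uniformly from ``country_pool``.
    """
    bin_probs = np.asarray(bin_probs, dtype=float)
    if bin_probs.shape != (4,) or not np.isclose(bin_probs.sum(), 1.0):
        raise ValueError("bin_probs must be 4 probabilities summing to 1")
    if not country_pool:
        raise ValueError("country_pool must be non-empty")
    rng = _rng(seed)
    bins = rng.choice(TIMEFRAME_BINS, size=n_experts, p=bin_probs)
    countries = rng.choice(country_pool, size=n_experts)
    modes = rng.choice(RESTORATION_MODES, size=n_experts,
                       p=(p_natural, 1.0 - p_natural))
    return pd.DataFrame({"expert": np.arange(1, n_experts + 1),
                         "country": countries, "mode": modes, "bin": bins})


def gen_fixture_stand(density: float = 1344.0, dbh_mean: float = 17.4,
                      dbh_sd: float = 3.0, seed: int = 0,
                      domain_side: float = 120.0, sample_origin: float = 10.0,
                      sample_side: float = 100.0) -> Stand:
    """Random stand: Poisson tree count, uniform positions, truncated-normal dbh.

    ``density`` is stems per hectare over the *full* domain, so the inner
    sample hectare matches it in expectation.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = _rng(seed)
    area_ha = domain_side**2 / 1e4
    n = rng.poisson(density * area_ha)
    x = rng.uniform(0.0, domain_side, n)
    y = rng.uniform(0.0, domain_side, n)
    a = (0.5 - dbh_mean) / dbh_sd  # truncate just above zero
    dbh = stats.truncnorm.rvs(a, np.inf, loc=dbh_mean, scale=dbh_sd,
                              size=n, random_state=rng)
    return Stand(x=x, y=y, dbh=dbh, domain_side=domain_side,
                 sample_origin=sample_origin, sample_side=sample_side,
                 rng_seed=seed)
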