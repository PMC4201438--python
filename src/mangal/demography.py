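"""Annual stand update: competition, growth, memory, mortality, recruitment.

The yearly cycle applies, in order: neighbourhood competition for every
tree, diameter growth (reduced inside an impacted zone), the push of the
relative increment into each tree's 5-year memory, suppression mortality,
random-dispersal recruitment and finally ageing.  The update is a pure
function of the input stand and the random generator state.
"""

from __future__ import annotations

import numpy as np

from .stand import (MEMORY_YEARS, SpeciesParams, Stand, Tree,
                    competition_indices, diameter_increment,
                    fon_sum_at_points, DEFAULT_RESOLUTION)

#: Seedling recruitment rate of the unimpacted stand (stems / ha / yr).
DEFAULT_RECRUITMENT = 390.0


def update_growth_memory(tree: Tree, ddbh: float) -> Tree:
    """Push the relative increment ``ddbh/dbh`` into the 5-slot memory.

    The oldest entry is evicted once the buffer is full.
    """
    if ddbh < 0:
        raise ValueError("ddbh must be non-negative")
    memory = tree.growth_memory + (ddbh / tree.dbh,)
    return Tree(tree.x, tree.y, tree.dbh, tree.age, memory[-MEMORY_YEARS:])


def _push_memory(stand: Stand, rel_inc: np.ndarray) -> None:
    """Vectorised ring-buffer push of per-tree relative increments."""
    if stand.n == 0:
        return
    slot = stand.mem_ptr % MEMORY_YEARS
    stand.mem[np.arange(stand.n), slot] = rel_inc
    stand.mem_ptr += 1


def mean_relative_increment(stand: Stand) -> np.ndarray:
    """5-year mean relative increment; NaN while the buffer is not yet full."""
    out = np.full(stand.n, np.nan)
    full = stand.mem_ptr >= MEMORY_YEARS
    if np.any(full):
        out[full] = stand.mem[full].mean(axis=1)
    return out


def mortality_step(stand: Stand, params: SpeciesParams,
                   rng: np.random.Generator) -> Stand:
    """Remove suppressed trees stochastically (and optionally over-aged ones).

    A tree whose 5-year mean relative increment is below the suppression
    threshold dies with probability ``p_die_suppressed`` this year.  Trees
    whose memory is not yet full are not exposed.  Removal is the only
    state change.
    """
    s = stand.copy()
    if s.n == 0:
        return s
    mean_inc = mean_relative_increment(s)
    suppressed = np.where(np.isnan(mean_inc), False,
                          mean_inc < params.suppression_threshold)
    dies = suppressed & (rng.random(s.n) < params.p_die_suppressed)
    if params.max_age is not None:
        dies |= s.age >= params.max_age
    return _keep(s, ~dies)


def _keep(stand: Stand, mask: np.ndarray) -> Stand:
    stand.x = stand.x[mask]
    stand.y = stand.y[mask]
    stand.dbh = stand.dbh[mask]
    stand.age = stand.age[mask]
    stand.mem = stand.mem[mask]
    stand.mem_ptr = stand.mem_ptr[mask]
    return stand


def recruitment_step(stand: Stand, base_rate: float, params: SpeciesParams,
                     rng: np.random.Generator) -> Stand:
    """Random-dispersal recruitment thinned by zone factors and canopy FON.

    Candidate positions arrive as a Poisson process over the whole domain
    at ``base_rate`` (stems/ha/yr), are thinned by the recruit factor of the
    zone containing them, and establish with probability
    ``max(0, 1 - sum_of_FON_intensities)`` at their location.  Established
    saplings enter with the configured seedling dbh and an empty memory.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    s = stand.copy()
    area_ha = s.domain_side**2 / 1e4
    n_cand = rng.poisson(base_rate * area_ha)
    if n_cand == 0:
        return s
    px = rng.uniform(0.0, s.domain_side, n_cand)
    py = rng.uniform(0.0, s.domain_side, n_cand)
    if s.zone is not None:
        keep = rng.random(n_cand) < s.zone.recruit_at(px)
        px, py = px[keep], py[keep]
    if px.size == 0:
        return s
    sigma = fon_sum_at_points(s, px, py, params)
    establish = rng.random(px.size) < np.clip(1.0 - sigma, 0.0, 1.0)
    px, py = px[establish], py[establish]
    k = px.size
    if k == 0:
        return s
    s.x = np.concatenate([s.x, px])
    s.y = np.concatenate([s.y, py])
    s.dbh = np.concatenate([s.dbh, np.full(k, params.seedling_dbh)])
    s.age = np.concatenate([s.age, np.zeros(k, dtype=np.int64)])
    s.mem = np.vstack([s.mem, np.zeros((k, MEMORY_YEARS))])
    s.mem_ptr = np.concatenate([s.mem_ptr, np.zeros(k, dtype=np.int64)])
    return s


def step_year(stand: Stand, params: SpeciesParams, rng: np.random.Generator,
              base_rate: float = DEFAULT_RECRUITMENT,
              resolution: float = DEFAULT_RESOLUTION) -> Stand:
    """Advance the stand by one year; the input stand is left untouched."""
    s = stand.copy()
    if s.n:
        F = competition_indices(s, params, resolution)
        gf = s.zone.growth_at(s.x) if s.zone is not None else 1.0
        dd = diameter_increment(s.dbh, F, gf, params)
        rel = dd / s.dbh
        s.dbh = np.minimum(s.dbh + dd, params.d_max)
        _push_memory(s, rel)
    s = mortality_step(s, params, rng)
    s = recruitment_step(s, base_rate, params, rng)
    s.age += 1
    s.year += 1
    return s
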