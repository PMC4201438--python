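"""Aggregation arithmetic for Delphi expert surveys.

Implements the scoring used to summarise a two-round expert elicitation on
mangrove ecosystems: weighted Likert rankings converted to a percentage
scale, strict-majority consensus listing, plurality choice among candidate
definitions, and the stratification of recovery-timeframe votes into
short/long term by country development level.

Bundled reference tables (loaded with :func:`load_species_votes` and
:func:`load_hdi_countries`) hold the published consensus species-vote
fractions and the HD/LD country classification of the respondents.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Likert levels used throughout (weight == level).
LIKERT_LEVELS = (1, 2, 3, 4, 5)

#: The four offered recovery-timeframe bins (years).
TIMEFRAME_BINS = ("0-10", "10-20", "20-30", ">30")

#: Bins aggregated as "short term" (< 20 years); the rest are long term.
SHORT_BINS = ("0-10", "10-20")

RESTORATION_MODES = ("natural", "human-assisted")


@dataclass(frozen=True)
class VoteTable:
    """Option x Likert-level vote counts for one ranking question."""

    options: tuple[str, ...]
    counts: np.ndarray  # shape (n_options, 5), nonnegative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.options), len(LIKERT_LEVELS)):
            raise ValueError("counts must be options x 5 Likert levels")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VoteTable":
        cols = [f"l{k}" for k in LIKERT_LEVELS]
        return cls(tuple(df["option"]), df[cols].to_numpy(dtype=np.int64))

    @classmethod
    def from_csv(cls, path) -> "VoteTable":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.counts,
                           columns=[f"l{k}" for k in LIKERT_LEVELS])
        out.insert(0, "option", self.options)
        return out


def weighted_likert_scores(table: VoteTable,
                           normalization: str = "max_attainable") -> pd.DataFrame:
    """Weighted Likert scores per option, converted to a percentage scale.

    Each vote contributes its Likert level as weight, so
    ``score = sum(level * count)``.  With the default normalisation the
    percentage is ``100 * score / (5 * votes)`` — 100% means every expert
    gave the top rank, 20% is the floor of a unanimous bottom rank.  The
    ``share_of_total`` alternative expresses each option's score as a share
    of the summed scores of all options.

    Returns a DataFrame indexed like the table's options with columns
    ``votes``, ``score``, ``percentage``, ``rank`` and ``tied``; options
    without votes get a missing percentage and no rank.  Rank ties are
    broken alphabetically and flagged in ``tied``.
    """
    if normalization not in ("max_attainable", "share_of_total"):
        raise ValueError("unknown normalization")
    counts = table.counts
    votes = counts.sum(axis=1)
    score = counts @ np.array(LIKERT_LEVELS)
    with np.errstate(divide="ignore", invalid="ignore"):
        if normalization == "max_attainable":
            pct = np.where(votes > 0,
                           100.0 * score / (LIKERT_LEVELS[-1] * votes), np.nan)
        else:
            total = score.sum()
            pct = (100.0 * score / total if total > 0
                   else np.full(len(score), np.nan))
            pct = np.where(votes > 0, pct, np.nan)
    df = pd.DataFrame({"option": table.options, "votes": votes,
                       "score": score, "percentage": pct})
    ranked = df.dropna(subset=["percentage"]).sort_values(
        ["percentage", "option"], ascending=[False, True])
    rank = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index)
    df["rank"] = rank
    dup = df["percentage"].value_counts(dropna=True).gt(1)
    df["tied"] = df["percentage"].map(dup).astype("boolean").fillna(
        False).astype(bool)
    return df


def consensus_list(vote_fractions: Mapping[str, float] | pd.Series,
                   threshold: float = 50.0) -> list[str]:
    """Items with strictly more than ``threshold`` percent yes-votes.

    Input order is preserved; an item at exactly the threshold is excluded
    (the consensus rule is "more than", not "at least").
    """
    if isinstance(vote_fractions, pd.Series):
        items = vote_fractions.items()
    else:
        items = vote_fractions.items()
    out = []
    for name, frac in items:
        if not 0.0 <= frac <= 100.0:
            raise ValueError(f"vote fraction for {name!r} outside [0, 100]")
        if frac > threshold:
            out.append(name)
    return out


@dataclass(frozen=True)
class PluralityResult:
    """Outcome of a plurality vote; ties are reported, never broken."""

    winner: str | None
    tied: tuple[str, ...]
    counts: dict

    @property
    def is_tie(self) -> bool:
        return len(self.tied) > 1


def plurality_choice(counts: Mapping[str, int] | pd.Series) -> PluralityResult:
    """Candidate with the most votes; flags ties and all-zero votes."""
    counts = dict(counts)
    if not counts:
        raise ValueError("need at least one candidate")
    top = max(counts.values())
    if top <= 0:
        return PluralityResult(None, (), counts)
    leaders = tuple(k for k, v in counts.items() if v == top)
    winner = leaders[0] if len(leaders) == 1 else None
    return PluralityResult(winner, leaders, counts)


def aggregate_timeframes(responses: pd.DataFrame,
                         hdi_map: Mapping[str, str]) -> pd.DataFrame:
    """Counts of recovery-timeframe votes by (HD/LD, short/long, mode).

    ``responses`` needs columns ``country``, ``bin`` (one of
    :data:`TIMEFRAME_BINS`) and ``mode`` (natural / human-assisted).  Bins
    0-10 and 10-20 years aggregate to "short", 20-30 and >30 to "long".
    Every country must appear in ``hdi_map`` (values HD or LD); unmapped
    countries raise with the offending names listed.
    """
    bad_bins = set(responses["bin"]) - set(TIMEFRAME_BINS)
    if bad_bins:
        raise ValueError(f"unknown timeframe bins: {sorted(bad_bins)}")
    unmapped = sorted(set(responses["country"]) - set(hdi_map))
    if unmapped:
        raise ValueError(f"countries missing from HDI map: {unmapped}")
    df = responses.copy()
    df["development"] = df["country"].map(dict(hdi_map))
    df["term"] = np.where(df["bin"].isin(SHORT_BINS), "short", "long")
    out = (df.groupby(["development", "term", "mode"], observed=False)
             .size().rename("count").reset_index())
    return out


def response_rate(n_returned: int, n_invited: int) -> float:
    """Percentage of invitees who responded (one decimal place)."""
    if n_invited <= 0:
        raise ValueError("n_invited must be positive")
    return round(100.0 * n_returned / n_invited, 1)


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mangal.data").joinpath(name)


def load_species_votes() -> pd.DataFrame:
    """Published per-species yes-vote percentages (columns species, pct_yes)."""
    with resources.as_file(_data_path("species_votes.csv")) as p:
        return pd.read_csv(p)


def load_hdi_countries() -> pd.DataFrame:
    """Respondent countries with HD/LD class and response counts."""
    with resources.as_file(_data_path("hdi_countries.csv")) as p:
        return pd.read_csv(p)


def hdi_mapping() -> dict[str, str]:
    """country -> HD|LD mapping from the bundled table."""
    df = load_hdi_countries()
    return dict(zip(df["country"], df["development"]))


def hdi_response_counts() -> pd.Series:
    """Number of responses per development class (HD, LD)."""
    df = load_hdi_countries()
    return df.groupby("development")["n_responses"].sum()
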