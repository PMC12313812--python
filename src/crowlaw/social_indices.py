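"""Dominance (Elo rating) and affiliation (CSI) covariates from focal data.

The Elo rating updates sequentially over agonistic interactions in date
order: the winner gains ``k * (1 - p)`` points, where ``p`` is the
logistic expected probability of that outcome given the current ratings,
and the loser loses the same amount (updates are zero-sum).  The default
steepness 400/ln(10) reproduces the classical Elo convention that a
200-point gap gives the stronger bird a ~76% expected win.

The Composite Sociality Index (CSI) averages, over the affiliative
behavior categories (allopreening and contact sitting), each dyad's
interaction rate divided by the population mean rate for that category;
the population mean of dyadic CSI values is therefore 1 by construction.
An individual's CSI is the mean over its dyads.

Both indices are corrected for unequal observation effort by regressing
the index on the per-individual number of focal observations and keeping
the residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_annotations import InteractionRecord

#: classical Elo logistic scale: 200-point gap -> p ~= 0.76
DEFAULT_STEEPNESS = 400.0 / math.log(10.0)
DEFAULT_K = 100.0
DEFAULT_INITIAL_RATING = 0.0

#: focal observations last five minutes each
FOCAL_MINUTES = 5.0


@dataclass
class EloState:
    """Sequentially updated dominance ratings."""

    ratings: dict[str, float]
    k: float = DEFAULT_K
    steepness: float = DEFAULT_STEEPNESS
    initial_rating: float = DEFAULT_INITIAL_RATING
    n_interactions: dict[str, int] = field(default_factory=dict)

    def expected_win(self, a: str, b: str) -> float:
        """Probability that ``a`` beats ``b`` under the current ratings."""
        diff = self.ratings[a] - self.ratings[b]
        return 1.0 / (1.0 + math.exp(-diff / self.steepness))


def elo_ratings(
    interactions: Iterable[InteractionRecord],
    individuals: Sequence[str],
    k: float = DEFAULT_K,
    steepness: float = DEFAULT_STEEPNESS,
    initial_rating: float = DEFAULT_INITIAL_RATING,
) -> EloState:
    """Elo ratings from agonistic interactions, in chronological order.

    Every id in ``individuals`` gets a rating; those never observed
    interacting keep ``initial_rating``.  An interaction naming an id not
    in ``individuals`` is an error.  Non-agonistic records are ignored.
    Ties in date keep input order (the update is strictly sequential).
    """
    state = EloState(
        ratings={ind: float(initial_rating) for ind in individuals},
        k=k,
        steepness=steepness,
        initial_rating=initial_rating,
        n_interactions={ind: 0 for ind in individuals},
    )
    events = sorted(
        (r for r in interactions if r.category == "agonistic"),
        key=lambda r: r.date,
    )
    for event in events:
        winner = event.winner
        loser = event.receiver if winner == event.initiator else event.initiator
        for who in (winner, loser):
            if who not in state.ratings:
                raise KeyError(
                    f"interaction involves {who!r}, absent from the metadata roster"
                )
        p = state.expected_win(winner, loser)
        delta = k * (1.0 - p)
        state.ratings[winner] += delta
        state.ratings[loser] -= delta
        state.n_interactions[winner] += 1
        state.n_interactions[loser] += 1
    return state


@dataclass
class CSITable:
    """Dyadic and per-individual composite sociality indices."""

    dyadic_csi: dict[tuple[str, str], float]
    mean_csi: dict[str, float]
    behavior_categories: tuple[str, ...]


def csi(
    interactions: Iterable[InteractionRecord],
    dyads: Sequence[tuple[str, str]],
    observation_time: Mapping[str, float] | None = None,
    categories: Sequence[str] = ("allopreen", "contact_sit"),
) -> CSITable:
    """Composite sociality index over the given dyads.

    For each dyad and behavior category the rate is events per unit of
    dyadic observation time (the smaller of the two individuals' focal
    time; all equal if ``observation_time`` is None).  The dyadic CSI is
    the mean over categories of rate / population-mean rate; a category
    with no events anywhere is dropped with a warning rather than
    dividing by zero.
    """
    dyads = [tuple(sorted(d)) for d in dyads]
    if len(set(dyads)) != len(dyads):
        raise ValueError("duplicate dyads")

    def dyad_time(d: tuple[str, str]) -> float:
        if observation_time is None:
            return 1.0
        return min(observation_time[d[0]], observation_time[d[1]])

    counts: dict[str, dict[tuple[str, str], int]] = {c: {d: 0 for d in dyads} for c in categories}
    for event in interactions:
        if event.category != "affiliative" or event.behavior not in counts:
            continue
        d = event.dyad
        if d in counts[event.behavior]:
            counts[event.behavior][d] += 1

    rates: dict[str, dict[tuple[str, str], float]] = {}
    for cat in categories:
        cat_rates = {d: counts[cat][d] / dyad_time(d) for d in dyads}
        if all(v == 0 for v in cat_rates.values()):
            warnings.warn(
                f"CSI category {cat!r} has no events in any dyad; dropping it",
                stacklevel=2,
            )
            continue
        rates[cat] = cat_rates
    if not rates:
        raise ValueError("no affiliative events in any category; CSI undefined")

    dyadic: dict[tuple[str, str], float] = {}
    for d in dyads:
        total = 0.0
        for cat, cat_rates in rates.items():
            mean_rate = sum(cat_rates.values()) / len(dyads)
            total += cat_rates[d] / mean_rate
        dyadic[d] = total / len(rates)

    individuals = sorted({i for d in dyads for i in d})
    mean_ind = {}
    for ind in individuals:
        own = [v for d, v in dyadic.items() if ind in d]
        mean_ind[ind] = float(np.mean(own)) if own else float("nan")
    return CSITable(
        dyadic_csi=dyadic,
        mean_csi=mean_ind,
        behavior_categories=tuple(rates),
    )


def effort_correct(
    index: Mapping[str, float],
    n_observations: Mapping[str, int],
) -> dict[str, float]:
    """Residuals of the index regressed on per-individual observation count.

    Removes sampling-effort bias; by OLS orthogonality the result has
    exactly zero sample correlation with the observation counts.  With
    fewer than 3 individuals, or constant effort, the regression is
    degenerate and the mean-centred index is returned with a warning.
    """
    ids = sorted(index)
    y = np.array([index[i] for i in ids], dtype=float)
    x = np.array([n_observations[i] for i in ids], dtype=float)
    if len(ids) < 3 or np.ptp(x) == 0:
        warnings.warn(
            "effort regression degenerate (constant effort or <3 individuals); "
            "returning mean-centred index",
            stacklevel=2,
        )
        resid = y - y.mean()
    else:
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    return dict(zip(ids, resid.tolist()))


def dyads_from_cohousing(meta: Mapping[str, "object"]) -> list[tuple[str, str]]:
    """All pairs of individuals whose group memberships overlap in time."""
    ids = sorted(meta)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ma, mb = meta[a], meta[b]
            if _memberships_overlap(ma.group_memberships, mb.group_memberships):
                out.append((a, b))
    return out


def _memberships_overlap(ms_a, ms_b) -> bool:
    for gid_a, start_a, end_a in ms_a:
        for gid_b, start_b, end_b in ms_b:
            if gid_a == gid_b and start_a <= end_b and start_b <= end_a:
                return True
    return False
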