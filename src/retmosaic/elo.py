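"""Elo-rating tournament for blinded pairwise grading of image phenotypes.

Raters are shown two images and pick the one that looks less fasciculated
(closer to wild type).  Each image starts at a rating of 0; after a matchup
the winner gains Δ = K·(1 − E_winner) points and the loser loses the same Δ,
where E is the chess-standard logistic expected score — so an upset (a
low-rated image beating a high-rated one) exchanges more points than an
expected result, and the total rating is conserved at every step.  Ratings
are aggregated to retinal means and compared across genotypes with Wilcoxon
rank-sum tests under Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ComparisonRecord, validate_group_table
from .stats import bh_adjust

__all__ = [
    "EloConfig",
    "EloState",
    "expected_score",
    "apply_matchup",
    "run_tournament",
    "retina_scores",
    "compare_genotypes",
]


@dataclass(frozen=True)
class EloConfig:
    """Tournament constants.

    ``initial_score`` is 0 (only rating differences enter the update, so
    the conventional 1500 offset is irrelevant); ``logistic_scale`` is the
    rating gap at which the expected score is 10/11.
    """

    initial_score: float = 0.0
    k_factor: float = 32.0
    logistic_scale: float = 400.0
    max_rounds: int = 200
    stability_window: int = 5

    def __post_init__(self) -> None:
        if self.k_factor <= 0 or self.logistic_scale <= 0:
            raise ValueError("k_factor and logistic_scale must be positive")


@dataclass
class EloState:
    ratings: dict[str, float]
    history: list[dict] = field(default_factory=list)
    converged: bool = False
    rounds_run: int = 0

    @property
    def total(self) -> float:
        return sum(self.ratings.values())


def expected_score(r_a: float, r_b: float, scale: float = 400.0) -> float:
    """Expected score of player a: 1/(1+10^((r_b−r_a)/scale))."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / scale))


def apply_matchup(state: EloState, record: ComparisonRecord, config: EloConfig) -> EloState:
    """Apply one forced-choice result in place; winner gains what loser loses."""
    for img in (record.image_a, record.image_b):
        if img not in state.ratings:
            raise KeyError(f"image {img!r} not registered in tournament")
    loser = record.image_b if record.winner == record.image_a else record.image_a
    e_winner = expected_score(
        state.ratings[record.winner], state.ratings[loser], config.logistic_scale
    )
    delta = config.k_factor * (1.0 - e_winner)
    pre = (state.ratings[record.winner], state.ratings[loser])
    state.ratings[record.winner] += delta
    state.ratings[loser] -= delta
    state.history.append(
        {
            "winner": record.winner,
            "loser": loser,
            "rater": record.rater,
            "delta": delta,
            "pre": pre,
            "post": (state.ratings[record.winner], state.ratings[loser]),
        }
    )
    return state


def _genotype_order(ratings: dict[str, float], genotype_of: dict[str, str]) -> tuple[str, ...]:
    means: dict[str, list[float]] = {}
    for img, r in ratings.items():
        means.setdefault(genotype_of[img], []).append(r)
    return tuple(sorted(means, key=lambda g: float(np.mean(means[g]))))


def run_tournament(
    images: dict[str, dict[str, str]],
    choices: Sequence[ComparisonRecord] | Callable[[str, str, np.random.Generator], str],
    config: EloConfig = EloConfig(),
    seed: int = 0,
) -> EloState:
    """Run a rating tournament to genotype-rank convergence.

    ``images`` maps image_id → ``{"retina_id": ..., "genotype": ...}``.
    ``choices`` is either a recorded comparison log (replayed in order and
    in full, deterministically) or a chooser callable ``(image_a, image_b,
    rng) → winner id`` consulted on uniformly random distinct pairs until
    convergence or ``max_rounds`` sweeps.

    Matchups are grouped into sweeps of ⌈n/2⌉ (one matchup per image on
    average); after each sweep the genotype mean-rating rank order is
    recomputed, and the tournament is converged once that order has been
    identical for ``stability_window`` consecutive sweeps.  Stops at
    ``max_rounds`` sweeps otherwise with ``converged=False``.
    """
    ids = list(images)
    if len(ids) < 2:
        raise ValueError("need at least 2 images")
    genotype_of = {i: images[i].get("genotype", "") for i in ids}
    state = EloState(ratings={i: config.initial_score for i in ids})
    rng = np.random.default_rng(seed)
    per_sweep = max(1, (len(ids) + 1) // 2)

    replay = not callable(choices)
    if replay:
        records: Iterable[ComparisonRecord] = list(choices)

    stable = 0
    last_order: tuple[str, ...] | None = None
    sweep = 0
    pos = 0
    while (pos < len(records)) if replay else (sweep < config.max_rounds):
        applied = 0
        for _ in range(per_sweep):
            if replay:
                if pos >= len(records):
                    break
                rec = records[pos]
                pos += 1
            else:
                ia, ib = rng.choice(len(ids), size=2, replace=False)
                winner = choices(ids[ia], ids[ib], rng)
                rec = ComparisonRecord(image_a=ids[ia], image_b=ids[ib], winner=winner)
            apply_matchup(state, rec, config)
            applied += 1
        sweep += 1
        state.rounds_run = sweep
        order = _genotype_order(state.ratings, genotype_of)
        stable = stable + 1 if order == last_order else 1
        last_order = order
        if stable >= config.stability_window:
            state.converged = True
            if not replay:
                break
        if replay and pos >= len(records):
            break
    return state


def retina_scores(state: EloState, images: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Average image ratings to per-retina means (the unit of statistics).

    Returns a group table with ``metric_name='elo_score'``.
    """
    rows = []
    for img, rating in state.ratings.items():
        if img not in images:
            raise KeyError(f"image {img!r} has no retina/genotype mapping")
        rows.append(
            {
                "image_id": img,
                "retina_id": images[img]["retina_id"],
                "genotype": images[img].get("genotype", ""),
                "value": rating,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["retina_id", "genotype"], as_index=False)["value"]
        .mean()
        .assign(metric_name="elo_score")
    )
    return validate_group_table(out)


def compare_genotypes(table: pd.DataFrame, exact_max_n: int = 20) -> pd.DataFrame:
    """All-pairs Wilcoxon rank-sum tests on retinal means, BH-corrected.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and there are no ties; the normal approximation
    with continuity correction otherwise.  Genotypes with fewer than 2
    retinas are excluded with a warning.
    """
    table = validate_group_table(table)
    groups = {g: sub["value"].to_numpy(float) for g, sub in table.groupby("genotype")}
    usable = {}
    for g, v in groups.items():
        if len(v) < 2:
            warnings.warn(f"genotype {g!r} has <2 retinas; excluded from comparison",
                          stacklevel=2)
        else:
            usable[g] = v
    if len(usable) < 2:
        raise ValueError("need at least 2 genotypes with >= 2 retinas each")

    rows = []
    for ga, gb in combinations(sorted(usable), 2):
        a, b = usable[ga], usable[gb]
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            stat, p = float(len(a) * len(b)) / 2.0, 1.0
        else:
            ties = len(np.unique(pooled)) < len(pooled)
            method = "exact" if (len(pooled) <= exact_max_n and not ties) else "asymptotic"
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(a),
                "n_b": len(b),
                "statistic": stat,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_list())
    return out
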