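"""Canonical headline experiments and the statistics they report.

Each function reruns one of the package's reference experiments from
scratch at its canonical scale and returns the headline numbers.  They are
used both by ``scripts/acceptance.py`` and by the acceptance test suite,
so the two always measure the same thing.

Scales (documented in docs/methods.md): the formal experiment runs 10
series of 1,000 games; meaningful/reuse 10 series of 5,000 games;
coercion 10 series of 1,000 games; erosion 5 series of 20,000 games.
"""

from __future__ import annotations

import random

import numpy as np

from .experiments import ExperimentConfig, NullStrategy, run_series
from .game import Agent, speaker_produce
from .interpretation import Interpreter, bell_number
from .lexicon import build_vocabulary
from .measures import inventory_size, usage
from .world import GenerationConfig, choose_topic, generate_ontology, generate_situation

__all__ = [
    "bell_number_check",
    "formal_dynamics",
    "meaningful_plateau",
    "reuse_advantage",
    "coercion_economy",
    "erosion_endpoint",
    "vocabulary_statistics",
    "utterance_length_statistics",
]

OPTIMAL_MARKERS = 3  # maximum topic size


def bell_number_check(n: int = 20) -> dict:
    """B(n) via the recurrence, cross-checked against full enumeration for
    small n by the caller's tests."""
    return {"value": bell_number(n), "n": n}


def formal_dynamics(seed: int, series: int = 10, games: int = 1000) -> dict:
    """Formal-strategy reference run (population turnover enabled).

    Returns the long-run efficiency E, the game index of the mean usage
    curve's peak, the convergence game (first post-peak game where the
    mean usage curve is within half a marker of the optimum and mean
    variation is at most 0.1), and the converged usage optimum (post-peak
    minimum of the mean usage curve).
    """
    config = ExperimentConfig(
        strategy="formal", games=games, series=series, seed=seed
    )
    result = run_series(config)
    agg = result.aggregate
    U = agg["U"].to_numpy()
    V = agg["V"].to_numpy()
    g = agg["game"].to_numpy()
    peak_i = int(np.argmax(U))
    convergence = None
    for i in range(peak_i, len(g)):
        if U[i] <= OPTIMAL_MARKERS + 0.5 and V[i] <= 0.1:
            convergence = int(g[i])
            break
    return {
        "efficiency": float(agg["E"].iloc[-1]),
        "peak_game": int(g[peak_i]),
        "convergence_game": convergence,
        "usage_optimum": float(U[peak_i:].min()),
        "final_usage": float(U[-1]),
        "n_games": games,
        "n_series": series,
        "result": result,
    }


def meaningful_plateau(
    seed: int, series: int = 10, games: int = 5000, tail: int = 500
) -> dict:
    """Active marker inventory of the meaningful (de novo) strategy:
    windowed usage over the final ``tail`` games, averaged over series."""
    config = ExperimentConfig(
        strategy="meaningful", games=games, series=series, seed=seed,
        turnover=0.0, measure_stride=25,
    )
    result = run_series(config)
    plateau = float(np.mean(
        [usage(s.records, games, tail) for s in result.series]
    ))
    return {
        "value": plateau, "n": games, "n_series": series, "result": result,
    }


def reuse_advantage(seed: int, series: int = 10, games: int = 5000) -> dict:
    """Percentage decrease of total invented markers when invention
    recruits existing words, at matched world seeds."""
    totals = {}
    results = {}
    for strat in ("meaningful", "reuse"):
        config = ExperimentConfig(
            strategy=strat, games=games, series=series, seed=seed,
            turnover=0.0, measure_stride=50,
        )
        res = run_series(config)
        totals[strat] = float(np.mean([
            inventory_size(s.records, games, s.initial_forms)
            for s in res.series
        ]))
        results[strat] = res
    pct = 100.0 * (totals["meaningful"] - totals["reuse"]) / totals["meaningful"]
    return {
        "value": pct,
        "invented_meaningful": totals["meaningful"],
        "invented_reuse": totals["reuse"],
        "n": games, "n_series": series, "results": results,
    }


def coercion_economy(seed: int, series: int = 10, games: int = 1000) -> dict:
    """Percentage decrease of mean per-agent marker inventory size under
    coercion relative to plain reuse, at matched world seeds."""
    sizes = {}
    for strat in ("reuse", "coerce"):
        config = ExperimentConfig(
            strategy=strat, games=games, series=series, seed=seed,
            turnover=0.0, measure_stride=25,
        )
        res = run_series(config)
        sizes[strat] = float(np.mean([
            np.mean(s.agent_inventory_sizes()) for s in res.series
        ]))
    pct = 100.0 * (sizes["reuse"] - sizes["coerce"]) / sizes["reuse"]
    return {
        "value": pct,
        "inventory_reuse": sizes["reuse"],
        "inventory_coerce": sizes["coerce"],
        "n": games, "n_series": series,
    }


def erosion_endpoint(
    seed: int, series: int = 5, games: int = 20000, window: int = 500
) -> dict:
    """Mean uttered marker length at the end of a long erosion run (the
    agreement system first stabilizes, then phonological reduction starts),
    plus the pre-erosion baseline length and success rates."""
    config = ExperimentConfig(
        strategy="reduce", games=games, series=series, seed=seed,
        turnover=0.0, window=window, measure_stride=100,
    )
    result = run_series(config)
    agg = result.aggregate
    g = agg["game"].to_numpy()
    start_i = int(np.searchsorted(g, config.reduction_start))
    return {
        "value": float(agg["marker_len"].iloc[-1]),
        "initial_length": float(agg["marker_len"].iloc[start_i]),
        "success_final": float(agg["success"].iloc[-1]),
        "success_baseline": float(agg["success"].iloc[start_i]),
        "n": games, "n_series": series,
    }


def vocabulary_statistics(seed: int, n_worlds: int = 50) -> dict:
    """Mean synonym-free vocabulary size (and share of three-attribute
    meanings) over independently generated default worlds."""
    sizes = []
    frac3 = []
    for s in range(n_worlds):
        rng = random.Random((seed * 1000003 + s) % 2**31)
        ontology = generate_ontology(GenerationConfig(), rng)
        vocab = build_vocabulary(ontology, rng)
        sizes.append(len(vocab))
        frac3.append(
            sum(1 for e in vocab.entries if len(e.meaning) == 3) / len(vocab)
        )
    return {
        "value": float(np.mean(sizes)),
        "three_attribute_share": float(np.mean(frac3)),
        "n": n_worlds,
    }


def utterance_length_statistics(
    seed: int, n_worlds: int = 10, per_world: int = 1000
) -> dict:
    """Marker-free speaker productions at default configuration: the
    percentage of utterances with exactly four words (full length
    distribution included)."""
    counts: dict[int, int] = {}
    total = 0
    strategy = NullStrategy()
    for w in range(n_worlds):
        rng = random.Random((seed * 999979 + w) % 2**31)
        ontology = generate_ontology(GenerationConfig(), rng)
        vocab = build_vocabulary(ontology, rng)
        interpreter = Interpreter(ontology)
        agent = Agent(0, vocab)
        produced = 0
        while produced < per_world:
            situation = generate_situation(ontology, 3, rng)
            topic = choose_topic(situation, rng)
            out = speaker_produce(
                agent, topic, situation, strategy, interpreter, rng,
                elaboration_rate=ExperimentConfig().elaboration_rate,
            )
            if out is None:
                continue
            n = len(out[0])
            counts[n] = counts.get(n, 0) + 1
            produced += 1
            total += 1
    distribution = {k: 100.0 * v / total for k, v in sorted(counts.items())}
    return {
        "value": distribution.get(4, 0.0),
        "distribution": distribution,
        "n": total,
    }
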