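"""Degree-preserving (iso-entropic) randomization and null-ensemble metrics.

Edge-swap randomization: repeatedly pick two existing edges ``(i, j)`` and
``(m, n)`` with four distinct endpoints and rewire them to ``(i, m)`` and
``(j, n)``, accepting only when neither new edge already exists.  Every
node's degree — hence the whole degree distribution and its Shannon
entropy — is exactly conserved, which is why the resulting ensembles are
called *iso-entropic*.  Comparing metrics that the swap does NOT conserve
(clustering, geodesic distance, efficiencies) against the ensemble mean
isolates structure beyond the degree sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .graphs import MetricSet, Network, compute_metric_set

__all__ = [
    "RewireResult",
    "NullEnsemble",
    "maslov_rewire",
    "maslov_rewire_result",
    "null_ensemble",
    "null_ensemble_metrics",
    "dump_ensemble",
    "ensemble_mean_metrics",
    "normalized_ratio",
]

#: successful swaps per member, as a multiple of the edge count
DEFAULT_SWAP_FACTOR = 10
#: proposal cap, as a multiple of the edge count (guards rigid graphs)
DEFAULT_ATTEMPT_FACTOR = 100


@dataclass(frozen=True)
class RewireResult:
    network: Network
    swaps_done: int
    attempts: int
    exhausted: bool  # True when the proposal cap hit before the swap budget


@dataclass(frozen=True)
class NullEnsemble:
    source: Network
    members: Tuple[Network, ...]
    seed: int
    swap_budget: int


def _member_rng(seed: int, index: int) -> np.random.Generator:
    # one independent stream per member so members are order-independent
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def maslov_rewire_result(
    net: Network,
    n_successful_swaps: Optional[int] = None,
    seed: int = 0,
    attempt_cap: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RewireResult:
    """Degree-preserving rewiring with explicit bookkeeping.

    ``n_successful_swaps`` defaults to ``10 * |E|`` and the proposal cap to
    ``100 * |E|``.  Candidate edge pairs are drawn uniformly over the current
    edge list; a proposal is accepted only when the four endpoints are
    distinct and both replacement edges are absent.  Deterministic given
    ``seed`` (or an explicit ``rng``).
    """
    m = net.n_edges
    if n_successful_swaps is None:
        n_successful_swaps = DEFAULT_SWAP_FACTOR * m
    if n_successful_swaps < 0:
        raise ValueError("swap budget must be nonnegative")
    if attempt_cap is None:
        attempt_cap = DEFAULT_ATTEMPT_FACTOR * max(m, 1)
    if rng is None:
        rng = np.random.default_rng(seed)
    if m < 2 or n_successful_swaps == 0:
        return RewireResult(net, 0, 0, exhausted=(n_successful_swaps > 0 and m < 2))

    edges: List[Tuple[int, int]] = sorted(net.edges)
    edge_set = set(edges)
    swaps = 0
    attempts = 0
    # draw proposals in batches: two edge indices + one orientation coin each
    batch = 1024
    while swaps < n_successful_swaps and attempts < attempt_cap:
        k = min(batch, attempt_cap - attempts)
        pair_idx = rng.integers(0, m, size=(k, 2))
        coins = rng.integers(0, 2, size=k)
        for (e1, e2), coin in zip(pair_idx, coins):
            if swaps >= n_successful_swaps:
                break
            attempts += 1
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if coin:
                c, d = d, c
            # proposed replacements: (a, c) and (b, d)
            if a == c or a == d or b == c or b == d:
                continue
            new1 = (a, c) if a < c else (c, a)
            new2 = (b, d) if b < d else (d, b)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps += 1
        if attempts >= attempt_cap:
            break

    exhausted = swaps < n_successful_swaps
    return RewireResult(
        Network(net.n_nodes, frozenset(edge_set)), swaps, attempts, exhausted
    )


def maslov_rewire(
    net: Network,
    n_successful_swaps: Optional[int] = None,
    seed: int = 0,
) -> Network:
    """Rewired copy of ``net`` with the degree multiset exactly preserved.

    Warns (and returns the best-effort graph, possibly unchanged) when the
    proposal cap is reached before the swap budget — e.g. on rigid graphs
    such as paths or complete graphs where few or no valid swaps exist.
    """
    result = maslov_rewire_result(net, n_successful_swaps, seed=seed)
    if result.exhausted:
        warnings.warn(
            f"rewiring stopped after {result.attempts} proposals with only "
            f"{result.swaps_done} successful swaps (budget not met)",
            stacklevel=2,
        )
    return result.network


def null_ensemble(
    net: Network, size: int = 30, seed: int = 0, swap_budget: Optional[int] = None
) -> NullEnsemble:
    """Ensemble of ``size`` independently rewired degree-matched networks."""
    if size < 1:
        raise ValueError("ensemble size must be at least 1")
    budget = DEFAULT_SWAP_FACTOR * net.n_edges if swap_budget is None else swap_budget
    members = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx in range(size):
            res = maslov_rewire_result(net, budget, rng=_member_rng(seed, idx))
            members.append(res.network)
    return NullEnsemble(source=net, members=tuple(members), seed=seed, swap_budget=budget)


def ensemble_mean_metrics(member_metrics: List[MetricSet]) -> Dict[str, Optional[float]]:
    """Plain arithmetic mean of each metric over members.

    Kurtosis is averaged over members where it is defined; ``None`` if it is
    defined for no member.  An infinite geodesic in any member makes the
    ensemble mean infinite.
    """
    out: Dict[str, Optional[float]] = {}
    dicts = [m.as_dict() for m in member_metrics]
    for name in dicts[0]:
        vals = [d[name] for d in dicts if d[name] is not None]
        out[name] = float(np.mean(vals)) if vals else None
    return out


def null_ensemble_metrics(
    net: Network, size: int = 30, seed: int = 0, swap_budget: Optional[int] = None
) -> Tuple[List[MetricSet], Dict[str, Optional[float]]]:
    """Per-member metric sets plus the ensemble mean of each metric.

    Member entropies all equal the source entropy: the degree distribution is
    conserved by construction.
    """
    ens = null_ensemble(net, size=size, seed=seed, swap_budget=swap_budget)
    member_metrics = [compute_metric_set(m) for m in ens.members]
    return member_metrics, ensemble_mean_metrics(member_metrics)


def dump_ensemble(ensemble: NullEnsemble, out_dir) -> list:
    """Persist ensemble members as edge-list text files in ``out_dir``.

    Members are not written by default anywhere in the pipeline; this is the
    opt-in escape hatch for inspecting or re-using null networks.
    """
    from pathlib import Path

    from .graphs import network_to_edgelist_text

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, member in enumerate(ensemble.members):
        path = out / f"member_{idx:03d}.edges"
        path.write_text(network_to_edgelist_text(member))
        paths.append(path)
    return paths


def normalized_ratio(value: float, ensemble_mean: Optional[float]) -> Optional[float]:
    """``value / ensemble_mean``; ``None`` when the mean is zero, infinite or missing."""
    if ensemble_mean is None or ensemble_mean <= 0 or not np.isfinite(ensemble_mean):
        return None
    return value / ensemble_mean
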