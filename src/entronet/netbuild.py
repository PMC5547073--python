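"""Threshold gated correlation matrices into binary networks at matched mean
degree, and find the feasible common grid of mean degrees.

Because mean degree is a step function of the correlation threshold eta,
exact density matching across conditions is implemented by *edge-rank
selection*: for a target mean degree <k> on N nodes, the L = round(<k>*N/2)
gated entries with the largest |r| become edges, and the reported eta is the
smallest retained |r|.  Ties at the cutoff are broken by lexicographic
(i, j) order so the edge count is exactly L and the construction is
deterministic.  Networks built this way are nested across grid levels.

The feasible grid for a whole study follows two criteria: at the minimum
mean degree every network must be connected and sparse (<k> > 2 ln N), and
at the maximum mean degree every network must still be small-world relative
to its degree-preserving null ensemble (lower global efficiency, greater
local efficiency than the ensemble mean).  The common grid is the
intersection of per-subject feasible intervals; subjects whose interval
cannot overlap the common one are flagged for exclusion rather than
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graphs import Network, efficiency_pair
from .nulls import null_ensemble
from .timeseries import CorrelationMatrix

__all__ = [
    "InfeasibleError",
    "DegreeGrid",
    "threshold_at_eta",
    "ranked_gated_edges",
    "match_mean_degree",
    "nested_networks",
    "sparsity_floor",
    "feasible_interval",
    "feasible_degree_grid",
]

Key = Tuple[str, str]  # (subject, condition)


class InfeasibleError(ValueError):
    """Raised when a requested density or grid cannot be realized."""


@dataclass
class DegreeGrid:
    """Common grid of integer mean-degree levels with one network per cell."""

    levels: List[int]
    networks: Dict[Tuple[str, str, int], Network]
    eta_used: Dict[Tuple[str, str, int], float]
    per_subject_intervals: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    excluded_subjects: List[str] = field(default_factory=list)


def threshold_at_eta(cm: CorrelationMatrix, eta: float) -> Network:
    """Edge (i, j) present iff the entry is gated in and |r_ij| > eta."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    ii, jj, absr = cm.gated_upper_triangle()
    keep = absr > eta
    return Network.from_edges(cm.n_regions, zip(ii[keep].tolist(), jj[keep].tolist()))


def ranked_gated_edges(cm: CorrelationMatrix) -> List[Tuple[float, int, int]]:
    """Gated upper-triangle entries sorted by descending |r|, ties by (i, j)."""
    ii, jj, absr = cm.gated_upper_triangle()
    order = np.lexsort((jj, ii, -absr))
    return [(float(absr[k]), int(ii[k]), int(jj[k])) for k in order]


def _edge_budget(k_target: int, n: int) -> int:
    return int(round(k_target * n / 2))


def match_mean_degree(cm: CorrelationMatrix, k_target: int) -> Tuple[Network, float]:
    """Top-L edge selection realizing mean degree ``k_target`` exactly.

    Returns the network and the effective threshold eta (smallest retained
    |r|).  Raises :class:`InfeasibleError` when the gate leaves fewer than
    L = round(k_target * N / 2) candidate entries.
    """
    n = cm.n_regions
    budget = _edge_budget(k_target, n)
    ranked = ranked_gated_edges(cm)
    if len(ranked) < budget:
        raise InfeasibleError(
            f"mean degree {k_target} needs {budget} edges but only "
            f"{len(ranked)} gated entries are available "
            f"(deficit {budget - len(ranked)})"
        )
    chosen = ranked[:budget]
    eta_used = chosen[-1][0] if chosen else 1.0
    net = Network.from_edges(n, ((i, j) for _, i, j in chosen))
    return net, eta_used


def nested_networks(
    cm: CorrelationMatrix, levels: Sequence[int]
) -> Dict[int, Tuple[Network, float]]:
    """Networks for every level from one shared edge ranking (hence nested)."""
    n = cm.n_regions
    ranked = ranked_gated_edges(cm)
    out: Dict[int, Tuple[Network, float]] = {}
    for k in levels:
        budget = _edge_budget(k, n)
        if len(ranked) < budget:
            raise InfeasibleError(
                f"mean degree {k} needs {budget} edges but only "
                f"{len(ranked)} gated entries are available "
                f"(deficit {budget - len(ranked)})"
            )
        chosen = ranked[:budget]
        out[k] = (
            Network.from_edges(n, ((i, j) for _, i, j in chosen)),
            chosen[-1][0] if chosen else 1.0,
        )
    return out


def sparsity_floor(n_nodes: int) -> int:
    """Smallest integer mean degree satisfying <k> > 2 ln N."""
    return int(math.floor(2.0 * math.log(n_nodes))) + 1


def _small_world_vs_null(net: Network, seed: int, null_size: int) -> bool:
    """E_g below and E_l above the degree-preserving ensemble means."""
    ens = null_ensemble(net, size=null_size, seed=seed)
    pairs = np.array([efficiency_pair(m) for m in ens.members])
    eg_rand, el_rand = pairs.mean(axis=0)
    e_g, e_l = efficiency_pair(net)
    return e_g < eg_rand and e_l > el_rand


def feasible_interval(
    cm: CorrelationMatrix,
    seed: int,
    null_size: int = 30,
    k_cap: Optional[int] = None,
) -> Optional[Tuple[int, int]]:
    """Maximal integer interval [k_min, k_max] of admissible mean degrees.

    k_max is the largest level (scanning down from the supply limit) whose
    network passes the small-world-vs-null criterion; k_min is the smallest
    level at or above the sparsity floor such that every level up to k_max
    yields a connected graph.  ``None`` when no level qualifies.
    """
    n = cm.n_regions
    k_floor = sparsity_floor(n)
    n_gated = len(ranked_gated_edges(cm))
    k_supply = int(math.floor(2 * n_gated / n))
    k_hi = min(k_supply, n - 1 if k_cap is None else min(k_cap, n - 1))
    if k_hi < k_floor:
        return None
    levels = list(range(k_floor, k_hi + 1))
    nets = nested_networks(cm, levels)

    connected = {k: nets[k][0].is_connected() for k in levels}
    candidates = [k for k in levels if connected[k]]
    if not candidates:
        return None

    cache: Dict[int, bool] = {}

    def holds(k: int) -> bool:
        if k not in cache:
            cache[k] = _small_world_vs_null(nets[k][0], seed=seed, null_size=null_size)
        return cache[k]

    # largest admissible k by bisection, treating small-worldness as monotone
    # in density (it degrades as the graph fills in)
    lo, hi, best = 0, len(candidates) - 1, -1
    while lo <= hi:
        mid = (lo + hi) // 2
        if holds(candidates[mid]):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best < 0:
        return None
    k_max = candidates[best]
    k_min = k_max
    for k in reversed(range(k_floor, k_max)):
        if not nets[k][0].is_connected():
            break
        k_min = k
    return (k_min, k_max)


def _interval_intersection(
    intervals: Dict[str, Tuple[int, int]]
) -> Optional[Tuple[int, int]]:
    lo = max(a for a, _ in intervals.values())
    hi = min(b for _, b in intervals.values())
    return (lo, hi) if lo <= hi else None


def feasible_degree_grid(
    all_cms: Dict[Key, CorrelationMatrix],
    ensemble_seed: int = 0,
    null_size: int = 30,
    grid_cap: int = 16,
    k_cap: Optional[int] = None,
) -> DegreeGrid:
    """Common degree grid across every (subject, condition) correlation matrix.

    Per-subject intervals are the intersection of that subject's two
    condition intervals.  Subjects whose interval is empty, or cannot
    overlap the intersection of the remaining subjects, are flagged for
    exclusion (never silently dropped).  When the common interval is wider
    than ``grid_cap`` levels, the topmost ``grid_cap`` levels (adjacent to
    the criterion-determined k_max) are kept.
    """
    subjects = sorted({s for s, _ in all_cms})
    if not subjects:
        raise ValueError("no correlation matrices supplied")

    per_subject: Dict[str, Optional[Tuple[int, int]]] = {}
    for idx, subj in enumerate(subjects):
        conds = sorted(c for s, c in all_cms if s == subj)
        ivals = []
        for jdx, cond in enumerate(conds):
            seed = int(
                np.random.SeedSequence(
                    entropy=ensemble_seed, spawn_key=(idx, jdx)
                ).generate_state(1)[0] % (2**31)
            )
            ivals.append(
                feasible_interval(
                    all_cms[(subj, cond)], seed=seed, null_size=null_size, k_cap=k_cap
                )
            )
        if any(iv is None for iv in ivals):
            per_subject[subj] = None
        else:
            lo = max(iv[0] for iv in ivals)  # type: ignore[index]
            hi = min(iv[1] for iv in ivals)  # type: ignore[index]
            per_subject[subj] = (lo, hi) if lo <= hi else None

    excluded = [s for s, iv in per_subject.items() if iv is None]
    retained = {s: iv for s, iv in per_subject.items() if iv is not None}
    if not retained:
        raise InfeasibleError(
            f"no subject has a feasible interval; per-subject intervals: {per_subject}"
        )

    common = _interval_intersection(retained)
    # drop, one at a time, the subject whose removal widens the intersection most
    while common is None and len(retained) > 1:
        best_subj, best_width, best_common = None, -1, None
        for s in retained:
            rest = {k: v for k, v in retained.items() if k != s}
            cand = _interval_intersection(rest)
            width = -1 if cand is None else cand[1] - cand[0]
            if width > best_width:
                best_subj, best_width, best_common = s, width, cand
        if best_common is None:
            break
        excluded.append(best_subj)  # type: ignore[arg-type]
        retained.pop(best_subj)  # type: ignore[arg-type]
        common = best_common
    if common is None:
        raise InfeasibleError(
            f"no common feasible interval across subjects; per-subject intervals: {per_subject}"
        )

    lo, hi = common
    if hi - lo + 1 > grid_cap:
        lo = hi - grid_cap + 1
    levels = list(range(lo, hi + 1))

    networks: Dict[Tuple[str, str, int], Network] = {}
    eta_used: Dict[Tuple[str, str, int], float] = {}
    for (subj, cond), cm in sorted(all_cms.items()):
        if subj not in retained:
            continue
        for k, (net, eta) in nested_networks(cm, levels).items():
            networks[(subj, cond, k)] = net
            eta_used[(subj, cond, k)] = eta

    return DegreeGrid(
        levels=levels,
        networks=networks,
        eta_used=eta_used,
        per_subject_intervals={s: iv for s, iv in per_subject.items() if iv is not None},
        excluded_subjects=sorted(set(excluded)),
    )
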