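"""Rotometry processing: net rotation rates, inclusion, allocation, recovery.

Drug-induced rotation is scored as *net full-body turns per minute*,
positive toward the lesioned side (ipsilateral) and negative away from
it (contralateral, i.e. overcompensation).  Animals enter the study only
when their baseline exceeds four net ipsilateral turns/min, and are then
dealt into treatment groups balanced on that baseline.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "net_rotation_rate",
    "apply_inclusion",
    "allocate_balanced_groups",
    "classify_recovery",
    "improvement",
    "improvement_table",
    "FULL_RECOVERY",
    "PARTIAL_RECOVERY",
]

FULL_RECOVERY = "full recovery/overcompensation"
PARTIAL_RECOVERY = "partial"


def net_rotation_rate(ipsi_turns: float, contra_turns: float, minutes: float) -> float:
    """(ipsilateral - contralateral) turns per minute of testing."""
    if minutes <= 0:
        raise ValueError("session duration must be > 0 minutes")
    if ipsi_turns < 0 or contra_turns < 0:
        raise ValueError("turn counts must be >= 0")
    return (ipsi_turns - contra_turns) / minutes


def apply_inclusion(rates: Mapping[str, float], threshold: float = 4.0) -> list[str]:
    """Animals whose baseline rate is strictly above the threshold.

    "More than four full body turns per minute" is a strict inequality:
    a rate of exactly 4.0 is excluded.
    """
    included = [a for a, r in rates.items() if r > threshold]
    if not included:
        warnings.warn("no animal passes the rotation inclusion threshold", stacklevel=2)
    return included


def _spread(sums: np.ndarray, sizes: np.ndarray) -> float:
    means = sums / sizes
    return float(means.max() - means.min())


_EXACT_ALLOCATION_LIMIT = 200_000  # max partitions to enumerate exhaustively


def _exact_assignment(ids: list[str], rates: Mapping[str, float], k: int) -> dict[str, int] | None:
    """Exhaustive minimum-spread balanced partition for small cohorts."""
    n = len(ids)
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    count = 1
    remaining = n
    for s in sizes[:-1]:
        count *= math.comb(remaining, s)
        remaining -= s
        if count > _EXACT_ALLOCATION_LIMIT:
            return None
    best: tuple[float, list[tuple[str, ...]]] | None = None

    def recurse(pool: tuple[str, ...], gi: int, acc: list[tuple[str, ...]]) -> None:
        nonlocal best
        if gi == k - 1:
            groups = acc + [pool]
            means = [np.mean([rates[a] for a in grp]) for grp in groups]
            spread = max(means) - min(means)
            if best is None or spread < best[0] - 1e-12:
                best = (spread, groups)
            return
        for combo in itertools.combinations(pool, sizes[gi]):
            rest = tuple(a for a in pool if a not in combo)
            recurse(rest, gi + 1, acc + [combo])

    recurse(tuple(ids), 0, [])
    assert best is not None
    return {a: gi for gi, grp in enumerate(best[1]) for a in grp}


def allocate_balanced_groups(
    baseline_rates: Mapping[str, float], k: int, seed: int = 0, refine: bool = True
) -> dict[str, int]:
    """Deal animals into k groups balanced on baseline rotation.

    Animals are sorted by baseline descending (ties broken by a seeded
    shuffle) and dealt in serpentine order (1..k, k..1, ...).  With
    ``refine`` (the default) the deal is then improved: small cohorts
    are re-partitioned exhaustively to the minimum possible gap between
    group mean baselines; larger cohorts get a greedy pass of
    size-preserving pairwise swaps accepting only strict improvements.
    Group sizes differ by at most one.
    """
    if k < 1:
        raise ValueError("number of groups must be >= 1")
    ids = list(baseline_rates.keys())
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} animals into {k} groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))  # seeded tie-break before the stable sort
    ids = [ids[i] for i in order]
    ids.sort(key=lambda a: baseline_rates[a], reverse=True)

    pattern = list(range(k)) + list(range(k - 1, -1, -1))
    assignment = {a: pattern[i % (2 * k)] for i, a in enumerate(ids)}

    if refine and k > 1:
        exact = _exact_assignment(ids, baseline_rates, k)
        if exact is not None:
            return exact
        rates = {a: float(baseline_rates[a]) for a in ids}
        groups: list[list[str]] = [[] for _ in range(k)]
        for a in ids:
            groups[assignment[a]].append(a)
        sums = np.array([sum(rates[a] for a in g) for g in groups])
        sizes = np.array([len(g) for g in groups], dtype=float)
        for _ in range(100):
            best = None
            current = _spread(sums, sizes)
            for ga, gb in itertools.combinations(range(k), 2):
                for a in groups[ga]:
                    for b in groups[gb]:
                        delta = rates[b] - rates[a]
                        new_sums = sums.copy()
                        new_sums[ga] += delta
                        new_sums[gb] -= delta
                        s = _spread(new_sums, sizes)
                        if s < current - 1e-12 and (best is None or s < best[0]):
                            best = (s, ga, gb, a, b)
            if best is None:
                break
            _, ga, gb, a, b = best
            groups[ga].remove(a)
            groups[gb].remove(b)
            groups[ga].append(b)
            groups[gb].append(a)
            delta = rates[b] - rates[a]
            sums[ga] += delta
            sums[gb] -= delta
        assignment = {a: gi for gi, g in enumerate(groups) for a in g}
    return assignment


def classify_recovery(week5_rate: float) -> str:
    """Full recovery/overcompensation at rate <= 0, else partial."""
    return FULL_RECOVERY if week5_rate <= 0 else PARTIAL_RECOVERY


def improvement(baseline_rate: float, week5_rate: float, relative: bool = False) -> float:
    """Behavioral improvement: baseline minus week-5 rate (turns/min).

    Larger values mean more improvement.  ``relative`` switches to
    percent of baseline (requires a nonzero baseline).
    """
    delta = baseline_rate - week5_rate
    if not relative:
        return delta
    if baseline_rate == 0:
        raise ValueError("relative improvement is undefined for a zero baseline")
    return 100.0 * delta / baseline_rate


def improvement_table(rotation: pd.DataFrame, relative: bool = False) -> pd.DataFrame:
    """Per-animal improvement from a long rotation table.

    Expects columns ``animal_id, group, timepoint, net_turns_per_min``
    with 'baseline' and 'week5' timepoints present for every animal.
    """
    wide = rotation.pivot_table(
        index=["animal_id", "group"], columns="timepoint", values="net_turns_per_min"
    )
    for tp in ("baseline", "week5"):
        if tp not in wide.columns or wide[tp].isna().any():
            raise ValueError(f"every animal needs a '{tp}' rotation measurement")
    out = wide.reset_index()
    out["improvement"] = [
        improvement(b, w5, relative=relative) for b, w5 in zip(out["baseline"], out["week5"])
    ]
    out["recovery"] = [classify_recovery(w5) for w5 in out["week5"]]
    return out
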