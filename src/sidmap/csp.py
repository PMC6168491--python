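"""Minimal chemical-shift mapping between ¹⁵N-HSQC peak lists.

When assignments are unavailable, the perturbation caused by a ligand
can still be bounded from below by matching the peaks of two spectra so
that the total weighted ¹H/¹⁵N distance is minimal, then averaging the
matched distances.  That per-comparison average is the minimal chemical
shift Δδ_min; because the matching minimises distance, Δδ_min never
overstates the true average perturbation.

Weighted distance between two amide peaks::

    Δδ = sqrt(Δδ_H² + (Δδ_N / w)²),   w = 7 by default

the common 7:1 ¹H:¹⁵N weighting.  Two matching modes are provided: the
exact assignment-problem optimum (Hungarian) and a greedy
closest-pair-first alternative; results record which produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .peaklist import PeakList

__all__ = [
    "WeightingScheme",
    "MatchResult",
    "MinShiftSummary",
    "weighted_distance",
    "match_peaks",
    "minimal_shift_summary",
    "compare_series",
]


@dataclass(frozen=True)
class WeightingScheme:
    """Divisor applied to ¹⁵N shift differences; 7 is the common choice."""

    n_weight: float = 7.0

    def __post_init__(self) -> None:
        if not self.n_weight > 0:
            raise ValueError("n_weight must be > 0")


@dataclass
class MatchResult:
    pairs: list[tuple[str, str, float]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    mode: str
    total_distance: float


@dataclass
class MinShiftSummary:
    """The average minimal shift over matched peaks of one comparison."""

    delta_min: float
    n_matched: int
    per_peak: list[tuple[str, float]] = field(default_factory=list)


def weighted_distance(dh: float, dn: float, scheme: WeightingScheme = WeightingScheme()) -> float:
    """sqrt(dh² + (dn / n_weight)²), all in ppm."""
    return float(np.hypot(dh, dn / scheme.n_weight))


def _coords(pl: PeakList, scheme: WeightingScheme) -> np.ndarray:
    xy = np.array([[p.h_ppm, p.n_ppm / scheme.n_weight] for p in pl], dtype=float)
    if xy.size and not np.isfinite(xy).all():
        raise ValueError("non-finite chemical shifts")
    return xy


def match_peaks(
    a: PeakList,
    b: PeakList,
    scheme: WeightingScheme = WeightingScheme(),
    mode: str = "optimal",
    max_distance: float | None = None,
) -> MatchResult:
    """One-to-one minimal-distance matching of two peak lists.

    ``optimal`` solves the assignment problem exactly, minimising the
    total weighted distance over all one-to-one matchings of size
    ``min(|A|, |B|)``.  ``greedy`` repeatedly pairs the globally closest
    unmatched peaks, breaking distance ties by lexicographic
    ``(id_A, id_B)``.  Pairs farther than ``max_distance`` (when given)
    are dropped after matching and their peaks reported unmatched.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot match empty peak lists")
    if mode not in ("optimal", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    xa, xb = _coords(a, scheme), _coords(b, scheme)
    cost = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    ids_a, ids_b = a.ids, b.ids

    if mode == "optimal":
        rows, cols = linear_sum_assignment(cost)
        matched = sorted(zip(rows.tolist(), cols.tolist()))
    else:
        matched = []
        order = np.argsort(cost, axis=None, kind="stable")
        # lexicographic tie-break on equal distances
        flat = [(cost.flat[k], ids_a[k // cost.shape[1]], ids_b[k % cost.shape[1]], k) for k in order]
        flat.sort(key=lambda t: (t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, _, _, k in flat:
            i, j = divmod(k, cost.shape[1])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matched.append((i, j))
            if len(matched) == min(len(a), len(b)):
                break
        matched.sort()

    pairs = []
    used_a_ids: set[str] = set()
    used_b_ids: set[str] = set()
    for i, j in matched:
        d = float(cost[i, j])
        if max_distance is not None and d > max_distance:
            continue
        pairs.append((ids_a[i], ids_b[j], d))
        used_a_ids.add(ids_a[i])
        used_b_ids.add(ids_b[j])
    return MatchResult(
        pairs=pairs,
        unmatched_a=[i for i in ids_a if i not in used_a_ids],
        unmatched_b=[i for i in ids_b if i not in used_b_ids],
        mode=mode,
        total_distance=float(sum(d for _, _, d in pairs)),
    )


def minimal_shift_summary(
    a: PeakList,
    b: PeakList,
    scheme: WeightingScheme = WeightingScheme(),
    mode: str = "optimal",
    max_distance: float | None = None,
) -> MinShiftSummary:
    """Δδ_min: summed matched distance divided by the number of matched peaks.

    Per-peak shifts are keyed by list-A ids; unmatched peaks never enter
    the average.
    """
    result = match_peaks(a, b, scheme=scheme, mode=mode, max_distance=max_distance)
    per_peak = [(ida, d) for ida, _, d in result.pairs]
    n = len(per_peak)
    delta_min = float(sum(d for _, d in per_peak) / n) if n else 0.0
    return MinShiftSummary(delta_min=delta_min, n_matched=n, per_peak=per_peak)


def compare_series(
    reference: PeakList,
    others: dict[str, PeakList] | list[tuple[str, PeakList]],
    scheme: WeightingScheme = WeightingScheme(),
    mode: str = "optimal",
) -> pd.DataFrame:
    """Δδ_min of each labelled list against a common reference.

    Supports both conventions of a mutant-series analysis: pass the apo
    spectrum as reference to size each complex's total perturbation, or
    the wild-type complex as reference so each mutant's Δδ_min measures
    how much that residue contributes to binding.

    Returns a DataFrame with columns ``label, delta_min, n_matched,
    rank, mode`` ordered by descending Δδ_min (rank 1 = largest).
    """
    items = list(others.items()) if isinstance(others, dict) else list(others)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in series")
    rows = []
    for label, pl in items:
        s = minimal_shift_summary(reference, pl, scheme=scheme, mode=mode)
        rows.append({"label": label, "delta_min": s.delta_min, "n_matched": s.n_matched, "mode": mode})
    table = pd.DataFrame(rows)
    table = table.sort_values("delta_min", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["label", "delta_min", "n_matched", "rank", "mode"]]
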