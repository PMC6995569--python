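"""Pick-to-truth matching and performance metrics.

Picks are matched to ground-truth coordinates greedily in ascending
distance order under a distance cap (a realization of the nearest-unclaimed
criterion used for the published benchmark). Reported metrics follow the
conventions of that benchmark: recall (TPR) = TP/(TP+FN), precision =
TP/(TP+FP), F1 their harmonic mean, and "FPR" = FP/(TP+FP), i.e. the false
discovery rate — the only reading under which the published FPR and
precision figures are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]
    n_tp: int
    n_fp: int
    n_fn: int
    tpr: float
    precision: float
    fpr: float
    f1: float
    mean_offset: tuple[float, float]  # (dx, dy) = pick - truth in (col, row)
    frac_within: dict[float, float] = field(default_factory=dict)
    undefined_tpr: bool = False


def match_picks(
    picks: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    max_match_dist: float = 10.0,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching with a distance cap.

    Ties in distance are broken by (pick index, truth index), making the
    matching deterministic and order-independent in its metrics.
    """
    if max_match_dist <= 0:
        raise InvalidInputError("max_match_dist must be positive")
    picks_a = np.asarray(picks, dtype=np.float64).reshape(-1, 2)
    truth_a = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    candidates = []
    for i, p in enumerate(picks_a):
        d = np.hypot(truth_a[:, 0] - p[0], truth_a[:, 1] - p[1]) if len(truth_a) else []
        for j, dist in enumerate(d):
            if dist <= max_match_dist:
                candidates.append((float(dist), i, j))
    candidates.sort()
    used_pick: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for dist, i, j in candidates:
        if i in used_pick or j in used_truth:
            continue
        used_pick.add(i)
        used_truth.add(j)
        pairs.append((i, j, dist))
    n_tp = len(pairs)
    n_fp = len(picks_a) - n_tp
    n_fn = len(truth_a) - n_tp
    undefined_tpr = (n_tp + n_fn) == 0
    tpr = 0.0 if undefined_tpr else n_tp / (n_tp + n_fn)
    precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) > 0 else 0.0
    fpr = n_fp / (n_tp + n_fp) if (n_tp + n_fp) > 0 else 0.0
    f1 = (
        2.0 * tpr * precision / (tpr + precision) if (tpr + precision) > 0 else 0.0
    )
    if pairs:
        offs = np.array(
            [
                (picks_a[i][1] - truth_a[j][1], picks_a[i][0] - truth_a[j][0])
                for i, j, _ in pairs
            ]
        )
        mean_offset = (float(offs[:, 0].mean()), float(offs[:, 1].mean()))
    else:
        mean_offset = (0.0, 0.0)
    return MatchResult(
        pairs=pairs,
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        tpr=tpr,
        precision=precision,
        fpr=fpr,
        f1=f1,
        mean_offset=mean_offset,
        undefined_tpr=undefined_tpr,
    )


def distance_fractions(
    match_result: MatchResult, thresholds: list[float]
) -> dict[float, float]:
    """Fraction of matched pairs closer than each threshold (strict <).

    The mapping is stored on the MatchResult and returned; it is
    non-decreasing in the threshold. With no matches all fractions are 0.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise InvalidInputError("thresholds must be positive and ascending")
    dists = np.array([d for _, _, d in match_result.pairs])
    out: dict[float, float] = {}
    for t in thresholds:
        out[t] = float((dists < t).mean()) if len(dists) else 0.0
    match_result.frac_within = out
    return out
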