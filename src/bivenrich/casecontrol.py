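"""Case-control comparison of two probe subsets' overlap with a track.

Typical use: hyper- vs hypo-methylated sites. The fold difference is the
ratio of the two groups' in-track proportions; significance comes from a
label-permutation test that shuffles case/control labels over the pooled
points (group sizes preserved) and compares the observed case overlap count
against the permutation distribution, one-sided greater, add-one empirical P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enrichment import empirical_p
from .intervals import IntervalTrack, PointSet, in_track_mask


@dataclass
class CaseControlResult:
    case_prop: float
    control_prop: float
    fold_difference: float
    observed_overlap: int
    p_value: float
    n_perm: int
    seed: int
    n_case: int
    n_control: int

    def to_row(self, case_name: str = "case", control_name: str = "control") -> dict:
        return {
            "case": case_name,
            "control": control_name,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "case_prop": self.case_prop,
            "control_prop": self.control_prop,
            "fold_difference": self.fold_difference,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _props(case: PointSet, control: PointSet, track: IntervalTrack) -> tuple[float, float, int, int]:
    if len(case) == 0 or len(control) == 0:
        raise ValueError("case and control sets must both be non-empty")
    k_case = int(in_track_mask(case, track).sum())
    k_ctrl = int(in_track_mask(control, track).sum())
    return k_case / len(case), k_ctrl / len(control), k_case, k_ctrl


def fold_difference(case: PointSet, control: PointSet, track: IntervalTrack) -> float:
    """(case in-track proportion) / (control in-track proportion).

    Returns +inf when only the control proportion is zero and NaN when both
    are zero (no overlap information on either side).
    """
    case_prop, ctrl_prop, _, _ = _props(case, control, track)
    if ctrl_prop == 0.0:
        return math.inf if case_prop > 0.0 else math.nan
    return case_prop / ctrl_prop


def label_permutation_test(
    case: PointSet,
    control: PointSet,
    track: IntervalTrack,
    n_perm: int = 50_000,
    seed: int = 0,
) -> CaseControlResult:
    """Permutation test of whether case points overlap the track more than
    control points.

    Case and control must be disjoint point sets (coordinates unique to one
    of the two subsets). Each permutation relabels the pooled points
    uniformly at random preserving |case|; the statistic is the case
    in-track count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(case.points) & set(control.points):
        raise ValueError("case and control point sets must be disjoint")
    case_prop, ctrl_prop, k_case, _ = _props(case, control, track)

    pooled = np.concatenate(
        [in_track_mask(case, track), in_track_mask(control, track)]
    ).astype(np.int8)
    n_case = len(case)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm_stats[i] = int(rng.permutation(pooled)[:n_case].sum())
    p = empirical_p(k_case, perm_stats)

    if ctrl_prop == 0.0:
        fold = math.inf if case_prop > 0.0 else math.nan
    else:
        fold = case_prop / ctrl_prop
    return CaseControlResult(
        case_prop=case_prop,
        control_prop=ctrl_prop,
        fold_difference=fold,
        observed_overlap=k_case,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        n_case=n_case,
        n_control=len(control),
    )


def exhaustive_permutation_p(
    case: PointSet, control: PointSet, track: IntervalTrack
) -> float:
    """Exact permutation P by enumerating every case/control label assignment.

    Feasible only for small pooled sets; serves as the reference for the
    Monte Carlo test. Uses the same one-sided-greater orientation but the
    exact proportion P = #{assignments with stat >= observed} / #assignments
    (no add-one: the observed assignment is one of those enumerated).
    """
    from itertools import combinations

    mask = np.concatenate([in_track_mask(case, track), in_track_mask(control, track)])
    n_case = len(case)
    observed = int(mask[:n_case].sum())
    total = 0
    at_least = 0
    for combo in combinations(range(mask.size), n_case):
        total += 1
        if int(mask[list(combo)].sum()) >= observed:
            at_least += 1
    return at_least / total
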