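"""Directional popularity penalty weights for categories and groups.

Each food category receives two penalty weights derived from its baseline
intake relative to the other categories of its group (a popularity proxy):

* ``w_plus``  = 2 - normalized popularity  (penalty on *increases*)
* ``w_minus`` = 1 + normalized popularity  (penalty on *decreases*)

where the normalization is within-group min-max.  Both lie in [1, 2] and sum
to 3: increasing a popular food is cheap (w_plus -> 1) but decreasing it is
expensive (w_minus -> 2), and vice versa for unpopular foods.  A new food
with zero baseline sits at the group minimum and is treated as the least
popular member of its host group: w_plus = 2, w_minus = 1.

Food groups receive a single weight ``z`` (default 2 for every group),
penalizing between-group substitution more than within-group substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .survey import DietSurvey

DEFAULT_GROUP_WEIGHT = 2.0


@dataclass
class PenaltyWeightSet:
    """Directional category weights and group weights for one survey."""

    w_plus: dict[str, float]
    w_minus: dict[str, float]
    z: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Two-column-per-category table for inspection/export."""
        return pd.DataFrame(
            {"category": list(self.w_plus),
             "w_plus": list(self.w_plus.values()),
             "w_minus": [self.w_minus[c] for c in self.w_plus]}
        )

    def without_category_weights(self) -> "PenaltyWeightSet":
        """All category weights set to 1; group weights unchanged.

        This is the "no penalty weights" sensitivity variant: only the
        category-level weights are removed, groups keep their z.
        """
        ones = {cid: 1.0 for cid in self.w_plus}
        return PenaltyWeightSet(dict(ones), dict(ones), dict(self.z))


def normalized_popularity(q_obs: float, group_values: Sequence[float],
                          tol: float = 1e-9) -> float:
    """Min-max normalized baseline intake within a group, in [0, 1].

    A degenerate group (all baselines equal) returns 0.5, which yields the
    neutral weights w_plus = w_minus = 1.5.
    """
    if not len(group_values):
        raise ValueError("group_values is empty")
    lo, hi = min(group_values), max(group_values)
    if not (lo - tol * max(1.0, abs(lo)) <= q_obs
            <= hi + tol * max(1.0, abs(hi))):
        raise ValueError(
            f"q_obs={q_obs} lies outside the group's baseline range "
            f"[{lo}, {hi}]")
    if hi - lo <= tol * max(1.0, abs(hi)):
        return 0.5
    return (q_obs - lo) / (hi - lo)


def category_weights(survey: DietSurvey) -> PenaltyWeightSet:
    """Compute directional weights for every category, group by group."""
    w_plus: dict[str, float] = {}
    w_minus: dict[str, float] = {}
    for g in survey.groups:
        members = survey.group_members(g.id)
        baselines = [c.baseline_intake for c in members]
        for c in members:
            s = normalized_popularity(c.baseline_intake, baselines)
            w_plus[c.id] = 2.0 - s
            w_minus[c.id] = 1.0 + s
    # preserve survey category order
    order = survey.category_ids
    return PenaltyWeightSet(
        {cid: w_plus[cid] for cid in order},
        {cid: w_minus[cid] for cid in order},
        group_weights(survey),
    )


def group_weights(survey: DietSurvey,
                  override: Mapping[str, float] | None = None
                  ) -> dict[str, float]:
    """Group weights: default z = 2 everywhere, optionally overridden."""
    z = {g.id: DEFAULT_GROUP_WEIGHT for g in survey.groups}
    if override:
        for gid, val in override.items():
            if gid not in z:
                raise KeyError(f"unknown group id {gid!r} in override")
            if val <= 0:
                raise ValueError(f"group weight for {gid!r} must be positive, "
                                 f"got {val}")
            z[gid] = float(val)
    return z
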