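"""Rule-based aggregation of six subregion profusion grades into a stage.

The national classification scale assigns a whole-radiograph stage from
the profusion grade (0–3) of small opacities in each of six lung
subregions plus a large-opacity flag:

* **Stage III** — large opacities present, regardless of profusion.
* **Stage II** — any subregion at grade 3, or grade ≥2 in four or more
  subregions.
* **Stage I** — grade ≥1 in two or more subregions, or grade 2 in one
  to three subregions.
* **Normal** — no opacities, or grade 1 in a single subregion.

The written scale is ambiguous at two points: grade-2 profusion "in four
subregions or less" (Stage I) versus "four subregions or more"
(Stage II) overlap at exactly four, and exactly two grade-1 subregions
fall between Normal ("one subregion") and Stage I ("more than two
subregions"). The default rule resolves both toward the more severe
stage — four grade-2 subregions are Stage II, and two grade-1 subregions
are Stage I — which keeps the rule total and errs on the side of
screening sensitivity.  ``strict_scale=True`` instead applies the
literal wording: Stage I requires more than two grade-1 subregions, and
the two-grade-1 gap case is read down to Normal.
"""

from __future__ import annotations

from enum import IntEnum
from itertools import product
from typing import Iterable

__all__ = ["StageLabel", "stage_from_profusions", "enumerate_rule_table"]


class StageLabel(IntEnum):
    """Ordinal pneumoconiosis stage."""

    NORMAL = 0
    I = 1
    II = 2
    III = 3


def stage_from_profusions(levels: Iterable[int], large_opacity: bool,
                          strict_scale: bool = False) -> StageLabel:
    """Assign a whole-image stage from six subregion profusion grades.

    Parameters
    ----------
    levels : iterable of six ints in {0,1,2,3}
        Profusion grade per subregion (upper/middle/lower × left/right).
    large_opacity : bool
        Whether a large (coalescent) opacity is present anywhere.
    strict_scale : bool
        Apply the literal wording of the scale (see module docstring).

    Returns
    -------
    StageLabel
        Exactly one stage; precedence III > II > I > Normal.
    """
    lv = list(levels)
    if len(lv) != 6:
        raise ValueError(f"expected 6 subregion levels, got {len(lv)}")
    for v in lv:
        if v not in (0, 1, 2, 3):
            raise ValueError(f"profusion level must be in {{0,1,2,3}}, got {v!r}")
    if large_opacity:
        return StageLabel.III
    n_ge1 = sum(v >= 1 for v in lv)
    n_ge2 = sum(v >= 2 for v in lv)
    if any(v == 3 for v in lv) or n_ge2 >= 4:
        return StageLabel.II
    # below here n_ge2 <= 3 and no grade 3
    stage1_threshold = 3 if strict_scale else 2
    if n_ge1 >= stage1_threshold or n_ge2 >= 1:
        return StageLabel.I
    return StageLabel.NORMAL


def enumerate_rule_table(strict_scale: bool = False) -> dict[tuple[tuple[int, ...], bool], StageLabel]:
    """Exhaustive rule table over all 4^6 × 2 = 8192 inputs.

    Used as an oracle surface: totality and monotonicity of the staging
    rule are assertable by scanning this table.
    """
    table = {}
    for lv in product(range(4), repeat=6):
        for large in (False, True):
            table[(lv, large)] = stage_from_profusions(lv, large, strict_scale=strict_scale)
    return table
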