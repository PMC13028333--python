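"""Heath-Carter anthropometric somatotype: components, categories, somatochart
coordinates and attitudinal dispersion (SAD/SAM).

Endomorphy rates relative adiposity from three height-corrected skinfolds,
mesomorphy rates musculoskeletal robustness relative to stature from bone
breadths and skinfold-corrected girths, and ectomorphy rates linearity from
the height-weight ratio HWR = stature / mass**(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phantom import PHANTOM_STATURE
from .profiles import AnthroProfile, Cohort

COMPONENT_FLOOR = 0.1
#: Differences between components below this are treated as negligible when
#: naming the somatotype.
DOMINANCE_MARGIN = 0.5


@dataclass
class Somatotype:
    endomorphy: float
    mesomorphy: float
    ectomorphy: float
    hwr: float = float("nan")
    category: str = ""
    somatopoint_x: float = field(init=False)
    somatopoint_y: float = field(init=False)

    def __post_init__(self) -> None:
        self.somatopoint_x, self.somatopoint_y = somatopoint(
            self.endomorphy, self.mesomorphy, self.ectomorphy
        )

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.endomorphy, self.mesomorphy, self.ectomorphy)

    def __str__(self) -> str:  # e.g. "3.8-7.0-0.8 (endomorphic mesomorph)"
        e, m, c = self.components
        s = f"{e:.1f}-{m:.1f}-{c:.1f}"
        return f"{s} ({self.category})" if self.category else s


@dataclass
class SamReport:
    """Somatotype attitudinal dispersion of a group around a reference."""

    position: str
    sam: float
    individual_sads: np.ndarray
    ci95: tuple[float, float]
    five_number: tuple[float, float, float, float, float]
    n: int


def endomorphy(triceps: float, subscapular: float, supraspinale: float,
               stature: float) -> float:
    """First component: relative adiposity from three height-corrected skinfolds."""
    if stature <= 0:
        raise ValueError("stature must be positive")
    if min(triceps, subscapular, supraspinale) <= 0:
        raise ValueError("skinfolds must be positive")
    x = (triceps + subscapular + supraspinale) * (PHANTOM_STATURE / stature)
    value = -0.7182 + 0.1451 * x - 0.00068 * x**2 + 0.0000014 * x**3
    return max(value, COMPONENT_FLOOR)


def mesomorphy(humerus: float, femur: float, arm_flexed: float, calf_girth: float,
               triceps_sf: float, calf_sf: float, stature: float) -> float:
    """Second component: musculoskeletal development relative to stature.

    Girths are corrected by their overlying skinfold (mm -> cm).  The formula
    is linear in all inputs, so evaluating it at group means equals the group
    mean of individual values.
    """
    corrected_arm = arm_flexed - triceps_sf / 10.0
    corrected_calf = calf_girth - calf_sf / 10.0
    value = (
        0.858 * humerus + 0.601 * femur
        + 0.188 * corrected_arm + 0.161 * corrected_calf
        - 0.131 * stature + 4.5
    )
    return max(value, COMPONENT_FLOOR)


def ectomorphy(stature: float, mass: float) -> float:
    """Third component: relative linearity from the height-weight ratio."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    hwr = stature / mass ** (1.0 / 3.0)
    if hwr >= 40.75:
        value = 0.732 * hwr - 28.58
    elif hwr > 38.25:
        value = 0.463 * hwr - 17.63
    else:
        value = COMPONENT_FLOOR
    return max(value, COMPONENT_FLOOR)


def somatopoint(endo: float, meso: float, ecto: float) -> tuple[float, float]:
    """Planar somatochart coordinates: x = ecto - endo, y = 2*meso - (endo + ecto)."""
    return (ecto - endo, 2.0 * meso - (endo + ecto))


_MAGNITUDE_BANDS = ((2.95, "low"), (5.5, "moderate"), (7.0, "high"))


def magnitude_label(value: float) -> str:
    """Component magnitude: low (0-2.9), moderate (3-5), high (5.5-7), very high (>7).

    The printed bands leave (5.0, 5.5) unassigned; values in the gap are
    labelled "moderate" (conservative reading of the band edges).
    """
    for upper, label in _MAGNITUDE_BANDS:
        if value <= upper:
            return label
    return "very high"


_ADJ = {"endomorphy": "endomorphic", "mesomorphy": "mesomorphic",
        "ectomorphy": "ectomorphic"}
_NOUN = {"endomorphy": "endomorph", "mesomorphy": "mesomorph",
         "ectomorphy": "ectomorph"}
_SHORT = {"endomorphy": "endo", "mesomorphy": "meso", "ectomorphy": "ecto"}
_ORDER = ("endomorphy", "mesomorphy", "ectomorphy")


def categorize(endo: float, meso: float, ecto: float) -> str:
    """Dominance label using the 0.5-unit negligibility rule.

    All three within 0.5 of each other -> "central"; a two-way tie for
    dominance -> a compound label such as "endo-mesomorph"; otherwise the
    dominant component names the noun and the runner-up the adjective, with
    "balanced" when the two non-dominant components are within 0.5 units.
    """
    vals = dict(zip(_ORDER, (endo, meso, ecto)))
    ranked = sorted(_ORDER, key=lambda k: vals[k], reverse=True)
    hi, mid, lo = (vals[k] for k in ranked)
    if hi - lo < DOMINANCE_MARGIN:
        return "central"
    if hi - mid < DOMINANCE_MARGIN:
        pair = [k for k in _ORDER if k in ranked[:2]]
        return f"{_SHORT[pair[0]]}-{_NOUN[pair[1]]}"
    if mid - lo < DOMINANCE_MARGIN:
        return f"balanced {_NOUN[ranked[0]]}"
    return f"{_ADJ[ranked[1]]} {_NOUN[ranked[0]]}"


def somatotype_of(profile: AnthroProfile) -> Somatotype:
    """Full somatotype of one athlete (components, HWR, category, somatopoint)."""
    endo = endomorphy(profile.triceps_sf, profile.subscapular_sf,
                      profile.supraspinale_sf, profile.stretch_stature)
    meso = mesomorphy(profile.humerus, profile.femur, profile.arm_flexed_tensed,
                      profile.calf_girth, profile.triceps_sf, profile.calf_sf,
                      profile.stretch_stature)
    ecto = ectomorphy(profile.stretch_stature, profile.body_mass)
    hwr = profile.stretch_stature / profile.body_mass ** (1.0 / 3.0)
    return Somatotype(endo, meso, ecto, hwr=hwr,
                      category=categorize(endo, meso, ecto))


def mean_somatotype(somatotypes) -> Somatotype:
    arr = np.array([s.components for s in somatotypes], float)
    if arr.size == 0:
        raise ValueError("empty group")
    e, m, c = arr.mean(axis=0)
    return Somatotype(float(e), float(m), float(c),
                      category=categorize(float(e), float(m), float(c)))


def sad(a: Somatotype, b: Somatotype) -> float:
    """Somatotype attitudinal distance: Euclidean distance in component space."""
    return math.dist(a.components, b.components)


def sam(group, reference: Somatotype, position: str = "") -> SamReport:
    """Somatotype attitudinal mean: average SAD of a group to a reference.

    The reference is conventionally the grand-sample mean somatotype.  The
    95% CI is a t-interval on the individual SADs, clipped at zero; the
    five-number summary supports box-plot style output.
    """
    group = list(group)
    if not group:
        raise ValueError("empty group")
    sads = np.array([sad(s, reference) for s in group], float)
    n = sads.size
    mean = float(sads.mean())
    if n > 1 and sads.std(ddof=1) > 0:
        lo, hi = stats.t.interval(0.95, n - 1, loc=mean,
                                  scale=sads.std(ddof=1) / math.sqrt(n))
    else:
        lo = hi = mean
    q0, q1, q2, q3, q4 = np.percentile(sads, [0, 25, 50, 75, 100])
    return SamReport(
        position=position,
        sam=mean,
        individual_sads=sads,
        ci95=(max(float(lo), 0.0), float(hi)),
        five_number=(float(q0), float(q1), float(q2), float(q3), float(q4)),
        n=n,
    )


def sam_by_position(cohort: Cohort) -> dict[str, SamReport]:
    """Per-position SAM against the grand-sample mean somatotype."""
    somas = {p.athlete_id: somatotype_of(p) for p in cohort}
    reference = mean_somatotype(somas.values())
    out: dict[str, SamReport] = {}
    for pos in sorted(set(cohort.positions)):
        group = [somas[p.athlete_id] for p in cohort if p.position == pos]
        out[pos] = sam(group, reference, position=pos)
    return out
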