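"""Phantom Z-scores and five-way tissue fractionation (adipose, muscle,
skeletal, residual, skin).

The phantom stratagem expresses a measurement as a Z-score against a unisex
reference human of stature 170.18 cm after geometric scaling::

    Z = (value * (170.18 / stature)**d - p) / s

where ``p`` and ``s`` are the phantom mean and SD for the variable and ``d``
is its dimensional exponent (1 for lengths, girths, breadths and skinfolds;
3 for masses).  The five-way fractionation estimates adipose, muscle,
skeletal, residual and skin masses from indicator Z-scores and back-transforms
each through the phantom tissue mass::

    mass_kg = (Z * s_mass + p_mass) / (170.18 / stature)**3

Indicator sets
--------------
adipose   mean phantom Z of the sum of six skinfolds (triceps, subscapular,
          supraspinale, abdominal, front thigh, medial calf)
muscle    mean phantom Z of five skinfold-corrected girths
          (corrected girth = girth - pi * skinfold_mm / 10)
skeletal  mean phantom Z of biacromial, biiliocristal, humerus and femur
          breadths and head girth
residual  mean phantom Z of transverse chest, A-P chest depth and waist girth,
          scaled by sitting height against the phantom sitting height
          (89.92 cm) instead of stretch stature
skin      body-surface-area relation: SA(cm^2) = 68.308 * h^0.725 * m^0.425,
          skin thickness 2.07 mm at phantom stature scaled linearly with
          stature, density 1.05 g/cm^3

All constants live in the versioned fixture ``data/phantom_constants.csv``;
the loader refuses to run on an incomplete table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import AnthroProfile, Cohort

PHANTOM_STATURE = 170.18
"""Phantom reference stature (cm)."""

PHANTOM_SITTING_HEIGHT = 89.92
"""Phantom reference sitting height (cm); used for the residual fraction."""

#: Skin-mass model constants: surface-area coefficient/exponents, phantom skin
#: thickness (cm) and skin density (g/cm^3).
_SA_COEF, _SA_EXP_H, _SA_EXP_M = 68.308, 0.725, 0.425
_SKIN_THICKNESS_CM, _SKIN_DENSITY = 0.207, 1.05

TISSUES = ("adipose", "muscle", "skeletal", "residual", "skin")

_REQUIRED_INDICATORS = {
    "sum6_skinfolds",
    "arm_relaxed_corrected",
    "forearm_girth",
    "chest_corrected",
    "thigh_corrected",
    "calf_corrected",
    "biacromial",
    "biiliocristal",
    "humerus",
    "femur",
    "head_girth",
    "transverse_chest",
    "ap_chest_depth",
    "waist_girth",
}
_REQUIRED_MASSES = {t + "_mass" for t in TISSUES}


class ConstantTableError(ValueError):
    """The phantom constant fixture is incomplete or malformed."""


@dataclass(frozen=True)
class PhantomConstant:
    """Phantom reference (p, s) for one variable with dimension exponent d."""

    variable: str
    p: float
    s: float
    d: int
    tissue: str

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ConstantTableError(f"{self.variable}: phantom SD must be > 0")
        if self.d not in (1, 3):
            raise ConstantTableError(f"{self.variable}: d must be 1 or 3")


@dataclass
class TissueMasses:
    """Five-way fractionation result for one athlete.

    Percentages are of scale (measured) body mass; ``error_kg`` is
    scale mass minus estimated total, so negative values mean the
    anthropometric estimate exceeds the scale.
    """

    adipose_kg: float
    muscle_kg: float
    skeletal_kg: float
    residual_kg: float
    skin_kg: float
    adipose_z: float
    muscle_z: float
    skeletal_z: float
    residual_z: float
    adipose_pct: float
    muscle_pct: float
    skeletal_pct: float
    residual_pct: float
    skin_pct: float
    estimated_total_kg: float
    error_kg: float
    error_pct: float

    def as_row(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class AgreementReport:
    """Scale-vs-estimated body-mass agreement statistics."""

    spearman_rho: float
    spearman_ci: tuple[float, float]
    r_squared: float
    r_squared_ci: tuple[float, float]
    rse_kg: float
    icc: float
    icc_ci: tuple[float, float]
    n: int


def load_phantom_constants(path: str | Path | None = None) -> dict[str, PhantomConstant]:
    """Load the phantom constant table, verifying it is complete."""
    if path is None:
        source = resources.files("kinanthro.data").joinpath("phantom_constants.csv")
        with resources.as_file(source) as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    required_cols = {"variable", "p", "s", "d", "tissue"}
    if not required_cols.issubset(df.columns):
        raise ConstantTableError(
            f"constant table must have columns {sorted(required_cols)}"
        )
    table = {
        str(r.variable): PhantomConstant(
            variable=str(r.variable), p=float(r.p), s=float(r.s),
            d=int(r.d), tissue=str(r.tissue),
        )
        for r in df.itertuples()
    }
    missing = (_REQUIRED_INDICATORS | _REQUIRED_MASSES) - set(table)
    if missing:
        raise ConstantTableError(
            "constant table incomplete; missing: " + ", ".join(sorted(missing))
        )
    return table


_DEFAULT_CONSTANTS: dict[str, PhantomConstant] | None = None


def default_constants() -> dict[str, PhantomConstant]:
    global _DEFAULT_CONSTANTS
    if _DEFAULT_CONSTANTS is None:
        _DEFAULT_CONSTANTS = load_phantom_constants()
    return _DEFAULT_CONSTANTS


def phantom_z(
    value: float,
    stature: float,
    constant: PhantomConstant,
    reference_stature: float = PHANTOM_STATURE,
) -> float:
    """Phantom Z-score of ``value`` for a subject of the given stature."""
    if stature <= 0:
        raise ValueError("stature must be positive")
    ratio = reference_stature / stature
    return (value * ratio**constant.d - constant.p) / constant.s


def _mass_from_z(z: float, stature_ratio: float, c: PhantomConstant) -> float:
    return (z * c.s + c.p) / stature_ratio**3


def body_surface_area_cm2(mass_kg: float, stature_cm: float) -> float:
    return _SA_COEF * stature_cm**_SA_EXP_H * mass_kg**_SA_EXP_M


def fractionate(
    profile: AnthroProfile,
    constants: dict[str, PhantomConstant] | None = None,
) -> TissueMasses:
    """Estimate the five tissue masses for one athlete.

    Raises :class:`ConstantTableError` if a needed constant is absent.
    """
    c = constants if constants is not None else default_constants()
    for name in _REQUIRED_INDICATORS | _REQUIRED_MASSES:
        if name not in c:
            raise ConstantTableError(f"missing phantom constant for {name!r}")

    h = profile.stretch_stature
    ratio = PHANTOM_STATURE / h

    # adipose: phantom Z of the six-skinfold sum
    sum6 = (
        profile.triceps_sf + profile.subscapular_sf + profile.supraspinale_sf
        + profile.abdominal_sf + profile.thigh_sf + profile.calf_sf
    )
    z_adip = phantom_z(sum6, h, c["sum6_skinfolds"])
    adipose = _mass_from_z(z_adip, ratio, c["adipose_mass"])

    # muscle: mean phantom Z of skinfold-corrected girths
    corrected = {
        "arm_relaxed_corrected": profile.arm_relaxed - math.pi * profile.triceps_sf / 10.0,
        "forearm_girth": profile.forearm_girth,
        "chest_corrected": profile.chest_girth - math.pi * profile.subscapular_sf / 10.0,
        "thigh_corrected": profile.thigh_girth - math.pi * profile.thigh_sf / 10.0,
        "calf_corrected": profile.calf_girth - math.pi * profile.calf_sf / 10.0,
    }
    z_musc = float(np.mean([phantom_z(v, h, c[k]) for k, v in corrected.items()]))
    muscle = _mass_from_z(z_musc, ratio, c["muscle_mass"])

    # skeletal: mean phantom Z of four breadths plus head girth
    skel_vars = ("biacromial", "biiliocristal", "humerus", "femur", "head_girth")
    z_skel = float(
        np.mean([phantom_z(getattr(profile, v), h, c[v]) for v in skel_vars])
    )
    skeletal = _mass_from_z(z_skel, ratio, c["skeletal_mass"])

    # residual: trunk indicators scaled by sitting height
    sh = profile.sitting_height
    sh_ratio = PHANTOM_SITTING_HEIGHT / sh
    res_vars = ("transverse_chest", "ap_chest_depth", "waist_girth")
    z_res = float(
        np.mean(
            [
                phantom_z(getattr(profile, v), sh, c[v],
                          reference_stature=PHANTOM_SITTING_HEIGHT)
                for v in res_vars
            ]
        )
    )
    residual = _mass_from_z(z_res, sh_ratio, c["residual_mass"])

    # skin: body-surface-area relation, thickness scaled linearly with stature
    sa = body_surface_area_cm2(profile.body_mass, h)
    thickness = _SKIN_THICKNESS_CM * (h / PHANTOM_STATURE)
    skin = sa * thickness * _SKIN_DENSITY / 1000.0

    total = adipose + muscle + skeletal + residual + skin
    scale = profile.body_mass
    error_kg = scale - total
    return TissueMasses(
        adipose_kg=adipose,
        muscle_kg=muscle,
        skeletal_kg=skeletal,
        residual_kg=residual,
        skin_kg=skin,
        adipose_z=z_adip,
        muscle_z=z_musc,
        skeletal_z=z_skel,
        residual_z=z_res,
        adipose_pct=adipose * 100.0 / scale,
        muscle_pct=muscle * 100.0 / scale,
        skeletal_pct=skeletal * 100.0 / scale,
        residual_pct=residual * 100.0 / scale,
        skin_pct=skin * 100.0 / scale,
        estimated_total_kg=total,
        error_kg=error_kg,
        error_pct=error_kg * 100.0 / scale,
    )


def fractionate_cohort(
    cohort: Cohort, constants: dict[str, PhantomConstant] | None = None
) -> pd.DataFrame:
    """Fractionation table for a whole cohort (one row per athlete)."""
    rows = []
    for p in cohort:
        row: dict[str, object] = {"athlete_id": p.athlete_id, "position": p.position,
                                  "scale_mass_kg": p.body_mass}
        row.update(fractionate(p, constants).as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def agreement(scale_kg, estimated_kg, ci: float = 0.95) -> AgreementReport:
    """Agreement between scale and anthropometrically estimated body mass.

    Spearman rho with a Bonett-Wright Fisher-z interval, R^2 and residual
    standard error from the OLS fit of estimated on scale mass (the squared
    Pearson r interval transformed), and a two-way random-effects,
    absolute-agreement, single-measure ICC.
    """
    from scipy import stats
    import pingouin as pg

    x = np.asarray(scale_kg, float)
    y = np.asarray(estimated_kg, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scale and estimated series must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")

    zcrit = stats.norm.ppf(0.5 + ci / 2.0)

    rho = float(stats.spearmanr(x, y).statistic)
    # Bonett & Wright standard error for Fisher-z of Spearman's rho
    se_rho = math.sqrt((1 + rho**2 / 2.0) / (n - 3))
    zr = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    rho_ci = (float(np.tanh(zr - zcrit * se_rho)), float(np.tanh(zr + zcrit * se_rho)))

    r = float(stats.pearsonr(x, y).statistic)
    zp = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se_r = 1.0 / math.sqrt(n - 3)
    r_lo, r_hi = np.tanh(zp - zcrit * se_r), np.tanh(zp + zcrit * se_r)
    r2_ci = (float(min(r_lo**2, r_hi**2)), float(max(r_lo**2, r_hi**2)))

    # OLS of estimated on scale: R^2 and residual standard error
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rse = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    r_squared = r**2

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["scale", "estimated"], n),
            "value": np.concatenate([x, y]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        icc_tab = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
    # ICC(A,1): two-way random effects, absolute agreement, single measures
    icc_row = icc_tab.loc["ICC(A,1)"] if "ICC(A,1)" in icc_tab.index else icc_tab.loc["ICC2"]
    icc = float(icc_row["ICC"])
    ci_col = "CI95" if "CI95" in icc_tab.columns else "CI95%"
    icc_ci = (float(icc_row[ci_col][0]), float(icc_row[ci_col][1]))

    return AgreementReport(
        spearman_rho=rho,
        spearman_ci=rho_ci,
        r_squared=r_squared,
        r_squared_ci=r2_ci,
        rse_kg=rse,
        icc=icc,
        icc_ci=icc_ci,
        n=n,
    )


def tem(pairs) -> tuple[float, float]:
    """Technical error of measurement over duplicate pairs.

    TEM = sqrt(sum(d_i^2) / (2 n)) over pair differences; %TEM normalizes by
    the grand mean of all readings.  Returns ``(tem, pct_tem)``.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 duplicate (first, second) pairs")
    d = arr[:, 0] - arr[:, 1]
    t = float(np.sqrt(np.sum(d**2) / (2 * arr.shape[0])))
    grand = float(np.mean(arr))
    return t, t * 100.0 / grand
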