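"""Derived anthropometric indices: BMI, skinfold sums, proportionality ratios
and tissue-mass ratios.

Ratio conventions follow the source study: the proportionality ratios (arm
span to stature, cormic, relative breadths, shoulder-hip, Manouvrier) are
reported per 100; the Manouvrier index uses stature as the denominator,
(stature - sitting height) / stature * 100, i.e. the relative lower-limb
length (~47), not the classical sitting-height-denominator form (~90).  With
this convention Manouvrier + cormic = 100 exactly.
"""

from __future__ import annotations

import pandas as pd

from .phantom import PhantomConstant, TissueMasses, fractionate
from .profiles import AnthroProfile, Cohort


def bmi(mass: float, stature: float) -> float:
    """Body mass index, kg/m^2 (stature in cm)."""
    if stature <= 0:
        raise ValueError("stature must be positive")
    return mass / (stature / 100.0) ** 2


def sum6sf(triceps: float, subscapular: float, supraspinale: float,
           abdominal: float, thigh: float, calf: float) -> float:
    """Sum of six skinfolds (mm): triceps, subscapular, supraspinale,
    abdominal, front thigh, medial calf."""
    return triceps + subscapular + supraspinale + abdominal + thigh + calf


def sum8sf(triceps: float, subscapular: float, biceps: float, iliac_crest: float,
           supraspinale: float, abdominal: float, thigh: float, calf: float) -> float:
    """Sum of eight skinfolds (mm)."""
    return (triceps + subscapular + biceps + iliac_crest + supraspinale
            + abdominal + thigh + calf)


def _per100(numerator: float, denominator: float, name: str) -> float:
    if denominator == 0:
        raise ZeroDivisionError(f"zero denominator in index {name!r}")
    return numerator / denominator * 100.0


def ape_index(arm_span: float, stature: float) -> float:
    """Arm span as a percentage of stretch stature."""
    return _per100(arm_span, stature, "ape_index")


def cormic_index(sitting_height: float, stature: float) -> float:
    """Sitting height as a percentage of stretch stature (relative trunk length)."""
    return _per100(sitting_height, stature, "cormic")


def relative_biacromial(biacromial: float, stature: float) -> float:
    return _per100(biacromial, stature, "rel_biacromial")


def relative_biiliocristal(biiliocristal: float, stature: float) -> float:
    return _per100(biiliocristal, stature, "rel_biiliocristal")


def shoulder_hip_index(biacromial: float, biiliocristal: float,
                       inverted: bool = False) -> float:
    """Shoulder-hip index, per 100.

    The primary definition is biacromial / biiliocristal; ``inverted=True``
    gives the biiliocristal / biacromial compatibility variant (some published
    tables are only consistent with the inverted form).
    """
    if inverted:
        return _per100(biiliocristal, biacromial, "shoulder_hip")
    return _per100(biacromial, biiliocristal, "shoulder_hip")


def manouvrier_index(stature: float, sitting_height: float) -> float:
    """Relative lower-limb length: (stature - sitting height)/stature * 100."""
    return _per100(stature - sitting_height, stature, "manouvrier")


def muscle_to_bone(muscle_kg: float, skeletal_kg: float) -> float:
    if skeletal_kg == 0:
        raise ZeroDivisionError("zero denominator in index 'muscle_to_bone'")
    return muscle_kg / skeletal_kg


def locomotive_index(adipose_kg: float, residual_kg: float,
                     muscle_kg: float, skeletal_kg: float) -> float:
    """Load on the locomotor system: (adipose + residual)/(muscle + bone)."""
    denom = muscle_kg + skeletal_kg
    if denom == 0:
        raise ZeroDivisionError("zero denominator in index 'locomotive'")
    return (adipose_kg + residual_kg) / denom


INDEX_NAMES = (
    "bmi", "sum6sf", "sum8sf", "ape_index", "cormic", "rel_biacromial",
    "rel_biiliocristal", "shoulder_hip", "manouvrier", "muscle_to_bone",
    "locomotive",
)


def index_row(
    profile: AnthroProfile,
    masses: TissueMasses | None = None,
    inverted_shoulder_hip: bool = False,
) -> dict[str, float]:
    """All indices for one athlete.

    ``muscle_to_bone`` and ``locomotive`` need tissue masses; if ``masses`` is
    None they are computed on the fly via the five-way fractionation.
    """
    if masses is None:
        masses = fractionate(profile)
    return {
        "bmi": bmi(profile.body_mass, profile.stretch_stature),
        "sum6sf": sum6sf(profile.triceps_sf, profile.subscapular_sf,
                         profile.supraspinale_sf, profile.abdominal_sf,
                         profile.thigh_sf, profile.calf_sf),
        "sum8sf": sum8sf(profile.triceps_sf, profile.subscapular_sf,
                         profile.biceps_sf, profile.iliac_crest_sf,
                         profile.supraspinale_sf, profile.abdominal_sf,
                         profile.thigh_sf, profile.calf_sf),
        "ape_index": ape_index(profile.arm_span, profile.stretch_stature),
        "cormic": cormic_index(profile.sitting_height, profile.stretch_stature),
        "rel_biacromial": relative_biacromial(profile.biacromial,
                                              profile.stretch_stature),
        "rel_biiliocristal": relative_biiliocristal(profile.biiliocristal,
                                                    profile.stretch_stature),
        "shoulder_hip": shoulder_hip_index(profile.biacromial,
                                           profile.biiliocristal,
                                           inverted=inverted_shoulder_hip),
        "manouvrier": manouvrier_index(profile.stretch_stature,
                                       profile.sitting_height),
        "muscle_to_bone": muscle_to_bone(masses.muscle_kg, masses.skeletal_kg),
        "locomotive": locomotive_index(masses.adipose_kg, masses.residual_kg,
                                       masses.muscle_kg, masses.skeletal_kg),
    }


def index_table(
    cohort: Cohort,
    constants: dict[str, PhantomConstant] | None = None,
    inverted_shoulder_hip: bool = False,
) -> pd.DataFrame:
    """Index table for a cohort, one row per athlete."""
    rows = []
    for p in cohort:
        row: dict[str, object] = {"athlete_id": p.athlete_id, "position": p.position}
        masses = fractionate(p, constants)
        row.update(index_row(p, masses, inverted_shoulder_hip=inverted_shoulder_hip))
        rows.append(row)
    return pd.DataFrame(rows)
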