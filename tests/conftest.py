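"""Shared fixtures: phantom-valued profile, printed group means, synthetic cohorts."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import kinanthro as ka

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return ka.load_phantom_constants()


@pytest.fixture(scope="session")
def table1():
    """Printed per-position means/SDs, indexed by (position, variable)."""
    return ka.load_table1_parameters().set_index(["position", "variable"])


@pytest.fixture(scope="session")
def cohort189():
    """Default synthetic study cohort at a fixed seed."""
    return ka.generate(ka.default_spec(seed=1))


def profile_from_means(table1: pd.DataFrame, position: str,
                       athlete_id: str = "X") -> ka.AnthroProfile:
    """An athlete sitting exactly at a position's printed mean vector."""
    sub = table1.xs(position)["mean"]
    return ka.AnthroProfile(athlete_id=athlete_id, position=position,
                            **{v: float(sub[v]) for v in sub.index})


@pytest.fixture(scope="session")
def mean_profiles(table1) -> dict[str, ka.AnthroProfile]:
    return {pos: profile_from_means(table1, pos, athlete_id=pos)
            for pos in ka.POSITIONS}


@pytest.fixture()
def phantom_profile(constants) -> ka.AnthroProfile:
    """A profile whose every fractionation indicator sits at its phantom value.

    Skinfolds are set so the six-skinfold sum equals the phantom constant
    exactly (the published per-site phantom values round to a sum of 116.40,
    the sum constant is 116.41).
    """
    c = constants
    tri, sub, sup, abd, thi, cal = 15.4, 17.2, 15.4, 25.41, 27.0, 16.0
    assert math.isclose(tri + sub + sup + abd + thi + cal, c["sum6_skinfolds"].p)
    return ka.AnthroProfile(
        athlete_id="phantom", position="QB", age=30.0,
        body_mass=64.58,
        stretch_stature=ka.PHANTOM_STATURE,
        sitting_height=ka.PHANTOM_SITTING_HEIGHT,
        arm_span=172.35,
        biacromial=c["biacromial"].p,
        transverse_chest=c["transverse_chest"].p,
        ap_chest_depth=c["ap_chest_depth"].p,
        biiliocristal=c["biiliocristal"].p,
        humerus=c["humerus"].p,
        femur=c["femur"].p,
        head_girth=c["head_girth"].p,
        arm_relaxed=c["arm_relaxed_corrected"].p + math.pi * tri / 10.0,
        arm_flexed_tensed=c["arm_relaxed_corrected"].p + math.pi * tri / 10.0 + 2.5,
        forearm_girth=c["forearm_girth"].p,
        chest_girth=c["chest_corrected"].p + math.pi * sub / 10.0,
        waist_girth=c["waist_girth"].p,
        thigh_girth=c["thigh_corrected"].p + math.pi * thi / 10.0,
        calf_girth=c["calf_corrected"].p + math.pi * cal / 10.0,
        triceps_sf=tri, subscapular_sf=sub, biceps_sf=8.0, iliac_crest_sf=12.0,
        supraspinale_sf=sup, abdominal_sf=abd, thigh_sf=thi, calf_sf=cal,
    )


def scaled_profile(profile: ka.AnthroProfile, k: float) -> ka.AnthroProfile:
    """Geometrically similar profile: linear measures scaled by k, mass by k^3."""
    row = profile.as_row()
    row["athlete_id"] = f"{profile.athlete_id}*{k}"
    row["body_mass"] = profile.body_mass * k**3
    for v in ka.MEASUREMENTS:
        if v != "body_mass":
            row[v] = row[v] * k
    return ka.AnthroProfile(**row)
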