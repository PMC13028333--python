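"""Synthetic cohort generation with the statistical structure the analysis
assumes.

Each playing position is drawn from a correlated multivariate model whose
marginal means and SDs come from a printed per-position parameter table
(shipped as ``data/table1_parameters.csv``).  Real anthropometric variables
are strongly positively inter-correlated, so the default model is a factor
model with

* a global *size* factor loading on mass, lengths, breadths and girths,
* an *adiposity* factor loading on skinfolds, girths and mass,
* one residual block factor per measurement family, calibrated so the
  within-family correlation equals the configured block correlation
  (girths 0.70, skinfolds 0.60, lengths 0.70, breadths 0.70 by default).

Rows violating physiological plausibility (any value beyond the truncation
band or outside the profile invariants) are redrawn, which leaves the
marginal moments essentially untouched at the default +/-4 SD band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import AnthroProfile, Cohort, MEASUREMENTS, POSITIONS, SKINFOLDS

#: Per-position sample sizes of the study cohort (design constants).
POSITION_COUNTS: dict[str, int] = {
    "DB": 30, "DL": 33, "LB": 33, "OL": 27, "QB": 18, "RB": 16, "WR": 31,
}

VARIABLES: tuple[str, ...] = ("age",) + MEASUREMENTS

_LENGTHS = ("stretch_stature", "sitting_height", "arm_span")
_BREADTHS = ("biacromial", "transverse_chest", "ap_chest_depth",
             "biiliocristal", "humerus", "femur")
_GIRTHS = ("head_girth", "arm_relaxed", "arm_flexed_tensed", "forearm_girth",
           "chest_girth", "waist_girth", "thigh_girth", "calf_girth")

#: Baseline variance shares on the global size and adiposity factors; the
#: remainder of each block correlation is carried by the block factor.
_SIZE_SHARE = {"lengths": 0.35, "breadths": 0.35, "girths": 0.45,
               "skinfolds": 0.05, "body_mass": 0.65}
_ADIP_SHARE = {"lengths": 0.0, "breadths": 0.0, "girths": 0.10,
               "skinfolds": 0.55, "body_mass": 0.25}


class SpecError(ValueError):
    """The cohort specification is internally inconsistent."""


@dataclass
class PositionSpec:
    n: int
    means: dict[str, float]
    sds: dict[str, float]


@dataclass
class CohortSpec:
    """Everything needed to draw a synthetic cohort deterministically."""

    per_position: dict[str, PositionSpec]
    correlation_model: str = "block"  # "block" | "independent"
    rho_girths: float = 0.70
    rho_skinfolds: float = 0.60
    rho_lengths: float = 0.70
    rho_breadths: float = 0.70
    truncation_sd: float = 4.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    lognormal_skinfolds: bool = False
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.correlation_model not in ("block", "independent"):
            raise SpecError(f"unknown correlation model {self.correlation_model!r}")
        for rho in (self.rho_girths, self.rho_skinfolds, self.rho_lengths,
                    self.rho_breadths):
            if not 0.0 <= rho <= 0.95:
                raise SpecError(f"block correlation {rho} outside [0, 0.95]")
        for pos, ps in self.per_position.items():
            if ps.n < 1:
                raise SpecError(f"{pos}: n must be >= 1")
            for v in VARIABLES:
                if v not in ps.means or v not in ps.sds:
                    raise SpecError(f"{pos}: missing parameters for {v!r}")
                if ps.sds[v] < 0:
                    raise SpecError(f"{pos}: negative SD for {v!r}")
        for v, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise SpecError(f"infeasible bounds for {v!r}: {lo} > {hi}")
        return self


def load_table1_parameters(path: str | Path | None = None) -> pd.DataFrame:
    """The per-position mean/SD parameter fixture (long format)."""
    if path is None:
        source = resources.files("kinanthro.data").joinpath("table1_parameters.csv")
        with resources.as_file(source) as f:
            return pd.read_csv(f)
    return pd.read_csv(path)


def default_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-cohort spec: printed per-position parameters and counts."""
    tab = load_table1_parameters()
    per_position: dict[str, PositionSpec] = {}
    for pos in POSITIONS:
        sub = tab[tab["position"] == pos].set_index("variable")
        per_position[pos] = PositionSpec(
            n=POSITION_COUNTS[pos],
            means=sub["mean"].to_dict(),
            sds=sub["sd"].to_dict(),
        )
    return CohortSpec(per_position=per_position, seed=seed, **overrides).validate()


def _block_of(variable: str) -> str | None:
    if variable in _LENGTHS:
        return "lengths"
    if variable in _BREADTHS:
        return "breadths"
    if variable in _GIRTHS:
        return "girths"
    if variable in SKINFOLDS:
        return "skinfolds"
    if variable == "body_mass":
        return "body_mass"
    return None  # age: independent


def _loadings(spec: CohortSpec) -> dict[str, tuple[float, float, float]]:
    """Per-variable variance shares (size, adiposity, block factor)."""
    rho = {"lengths": spec.rho_lengths, "breadths": spec.rho_breadths,
           "girths": spec.rho_girths, "skinfolds": spec.rho_skinfolds}
    out: dict[str, tuple[float, float, float]] = {}
    for v in VARIABLES:
        blk = _block_of(v)
        if blk is None or spec.correlation_model == "independent":
            out[v] = (0.0, 0.0, 0.0)
            continue
        g, a = _SIZE_SHARE[blk], _ADIP_SHARE[blk]
        if blk == "body_mass":
            out[v] = (g, a, 0.0)
            continue
        base = g + a
        target = rho[blk]
        if target >= base:
            out[v] = (g, a, target - base)
        else:  # shrink the shared factors to honour a small block correlation
            scale = target / base if base > 0 else 0.0
            out[v] = (g * scale, a * scale, 0.0)
    return out


def _draw_standard(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """n rows of correlated standard-normal deviates.

    Returns the deviates, the shared (factor) component of each column and
    the idiosyncratic variance share, so that individual cells can be
    redrawn without touching the factor structure.
    """
    loads = _loadings(spec)
    f_size = rng.standard_normal(n)
    f_adip = rng.standard_normal(n)
    f_block = {b: rng.standard_normal(n) for b in
               ("lengths", "breadths", "girths", "skinfolds")}
    cols = {}
    shared_cols = {}
    e_share = {}
    for v in VARIABLES:
        g, a, b = loads[v]
        e = max(1.0 - g - a - b, 0.0)
        shared = np.sqrt(g) * f_size + np.sqrt(a) * f_adip
        blk = _block_of(v)
        if b > 0 and blk in f_block:
            shared = shared + np.sqrt(b) * f_block[blk]
        cols[v] = shared + np.sqrt(e) * rng.standard_normal(n)
        shared_cols[v] = shared
        e_share[v] = e
    return pd.DataFrame(cols), pd.DataFrame(shared_cols), e_share


def _to_marginal(z: np.ndarray, mean: float, sd: float, lognormal: bool) -> np.ndarray:
    if lognormal and mean > 0 and sd > 0:
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return np.exp(mu + np.sqrt(sigma2) * z)
    return mean + sd * z


def _row_valid(df: pd.DataFrame, ps: PositionSpec, spec: CohortSpec) -> np.ndarray:
    ok = np.ones(len(df), bool)
    for v in VARIABLES:
        x = df[v].to_numpy()
        # symmetric band: mean +/- trunc_sd*SD, shrunk to the positivity floor
        # symmetrically so that redraws do not bias the mean
        half = min(spec.truncation_sd * ps.sds[v], ps.means[v])
        lo, hi = ps.means[v] - half, ps.means[v] + half
        if spec.lognormal_skinfolds and v in SKINFOLDS:
            lo, hi = 0.0, np.inf  # lognormal marginals have their own tail
        if v in spec.bounds:
            lo, hi = max(lo, spec.bounds[v][0]), min(hi, spec.bounds[v][1])
        ok &= (x >= lo) & (x <= hi) & (x > 0)
    ok &= df["sitting_height"].to_numpy() < df["stretch_stature"].to_numpy()
    ok &= df["humerus"].to_numpy() < df["femur"].to_numpy() + 5.0
    ok &= (df["age"].to_numpy() >= 15.0) & (df["age"].to_numpy() <= 60.0)
    return ok


def _enforce_arm_consistency(z: pd.DataFrame, shared: pd.DataFrame,
                             e_share: dict[str, float], ps: PositionSpec,
                             rng: np.random.Generator) -> None:
    """Redraw the idiosyncratic part of the relaxed/flexed arm-girth pair
    until flexed >= relaxed - 2 cm.

    Only the pair's own noise is resampled, so the factor structure and the
    marginals of every other variable are untouched.
    """
    for _ in range(1000):
        relaxed = ps.means["arm_relaxed"] + ps.sds["arm_relaxed"] * z["arm_relaxed"]
        flexed = (ps.means["arm_flexed_tensed"]
                  + ps.sds["arm_flexed_tensed"] * z["arm_flexed_tensed"])
        bad = np.flatnonzero(flexed.to_numpy() < relaxed.to_numpy() - 2.0)
        if bad.size == 0:
            return
        for v in ("arm_relaxed", "arm_flexed_tensed"):
            z.iloc[bad, z.columns.get_loc(v)] = (
                shared[v].to_numpy()[bad]
                + np.sqrt(e_share[v]) * rng.standard_normal(bad.size)
            )
    raise SpecError("could not enforce arm-girth consistency")


def _draw_position(pos: str, ps: PositionSpec, spec: CohortSpec,
                   rng: np.random.Generator) -> list[AnthroProfile]:
    rows: pd.DataFrame | None = None
    need = ps.n
    for _ in range(1000):
        z, shared, e_share = _draw_standard(spec, need, rng)
        _enforce_arm_consistency(z, shared, e_share, ps, rng)
        vals = pd.DataFrame(
            {
                v: _to_marginal(
                    z[v].to_numpy(), ps.means[v], ps.sds[v],
                    spec.lognormal_skinfolds and v in SKINFOLDS,
                )
                for v in VARIABLES
            }
        )
        keep = vals[_row_valid(vals, ps, spec)]
        rows = keep if rows is None else pd.concat([rows, keep], ignore_index=True)
        need = ps.n - len(rows)
        if need <= 0:
            break
    else:
        raise SpecError(f"{pos}: could not draw valid rows; bounds too tight?")
    rows = rows.iloc[: ps.n].reset_index(drop=True)
    profiles = []
    for i, rec in rows.iterrows():
        profiles.append(
            AnthroProfile(
                athlete_id=f"{pos}{i + 1:03d}", position=pos,
                **{v: float(rec[v]) for v in VARIABLES},
            )
        )
    return profiles


def generate(spec: CohortSpec | None = None, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic given the spec and seed.

    ``seed`` overrides ``spec.seed`` when given.
    """
    if spec is None:
        spec = default_spec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    profiles: list[AnthroProfile] = []
    for pos in sorted(spec.per_position):
        profiles.extend(_draw_position(pos, spec.per_position[pos], spec, rng))
    return Cohort(profiles=profiles, provenance=f"synthetic(seed={spec.seed if seed is None else seed})")


def generate_agreement_pairs(
    n: int = 189,
    noise_sd_kg: float = 3.2,
    bias: float = 1.05,
    mean_kg: float = 97.1,
    sd_kg: float = 19.3,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(scale, estimated) body-mass pairs for exercising agreement statistics.

    Scale masses are normal with the cohort's mean and SD; the estimate is a
    multiplicative bias of the scale mass plus independent gaussian noise.
    """
    rng = np.random.default_rng(seed)
    scale = rng.normal(mean_kg, sd_kg, n)
    estimated = scale * bias + rng.normal(0.0, noise_sd_kg, n)
    return scale, estimated
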