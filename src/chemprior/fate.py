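"""Steady-state multimedia fate model (air / water / soil).

A three-compartment box model with first-order degradation in every
compartment and one-way interfacial transfer fluxes whose rate
constants are interfacial transfer velocities scaled by the relevant
partition coefficients: air-water exchange through the dimensionless
Henry-law constant Kaw, soil retention through the organic-carbon
normalised sorption coefficient Koc = c * Kow.

Three metrics are derived from the steady-state solution under unit
emission:

* overall persistence Pov (days) — the residence time of the chemical
  in the closed model system, sum(m_i) / sum(k_deg_i * m_i);
* characteristic travel distance CTD (km) — the distance over which
  the concentration from a point source decays to 1/e, computed as the
  mobile-phase velocity times Pov times the mobile mass fraction, for
  air (wind) and water (current), reporting the larger;
* transfer efficiency TE (%) — the percentage of the emission that
  reaches surface media (water, soil) of a remote region after
  transport, computed on two identical linked regions coupled by
  advection in air and water.

Classification: a chemical is placed in region A (very persistent,
POP-like) when Pov exceeds its boundary AND either CTD or TE exceeds
theirs, region B with only Pov high, region C with only long-range
transport high, region D with both low.

All internal rates are per day; half-lives are days; transfer
velocities are configured in m/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import FateParameters, ThresholdConfig
from .substances import PropertySet, SubstanceRecord

__all__ = [
    "COMPARTMENTS",
    "HalfLifeSet",
    "FateResult",
    "FateInputError",
    "DegenerateSystemError",
    "derive_halflives",
    "build_steady_state_system",
    "build_two_region_system",
    "solve_steady_state",
    "compute_pov",
    "compute_ctd",
    "compute_te",
    "classify_region",
    "run_fate",
]

COMPARTMENTS = ("air", "water", "soil")


class FateInputError(ValueError):
    """A record lacks the inputs needed to run the fate model."""


class DegenerateSystemError(ValueError):
    """The steady-state system is singular (a compartment has no loss)."""


@dataclass
class HalfLifeSet:
    """Resolved degradation half-lives (days) with per-value provenance.

    Provenance tags: ``experimental``, ``mapped_from_biowin3``,
    ``doubled_from_water``, ``copied_from_water``, ``floor_default``.
    """

    water: float = 0.0
    sediment: float = 0.0
    soil: float = 0.0
    air: float = 0.0
    provenance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class FateResult:
    pov_days: float
    ctd_km: float
    te_percent: float
    mass_fractions: dict[str, float]
    emission_scenario: str
    region: str = ""
    mobile_phase: str = ""      # compartment that sets the CTD

    @property
    def f_water(self) -> float:
        return self.mass_fractions["water"]


def derive_halflives(props: PropertySet,
                     thresholds: ThresholdConfig | None = None) -> HalfLifeSet:
    """Resolve the four compartment half-lives for one substance.

    Measured values take precedence.  A missing water half-life is
    mapped from the ultimate-biodegradation survey score through a
    documented monotone step table; a missing sediment half-life is
    twice the water value; a missing soil half-life defaults to the
    water value.  The air half-life (an atmospheric-oxidation
    estimate) must be supplied — if absent the configured floor value
    is used and a warning is recorded.  With no route to a water
    half-life the substance cannot be fate-modelled.
    """
    t = thresholds or ThresholdConfig()
    hl = HalfLifeSet()

    if props.t_half_water is not None:
        hl.water = props.t_half_water
        hl.provenance["water"] = "experimental"
    elif props.biowin3 is not None:
        for lower, value in t.biowin3_halflife_map:
            if props.biowin3 >= lower:
                hl.water = value
                break
        hl.provenance["water"] = "mapped_from_biowin3"
    else:
        raise FateInputError(
            "no route to a water half-life (neither a measured value nor a "
            "biodegradation survey score)")

    if props.t_half_sediment is not None:
        hl.sediment = props.t_half_sediment
        hl.provenance["sediment"] = "experimental"
    else:
        hl.sediment = t.sediment_water_halflife_ratio * hl.water
        hl.provenance["sediment"] = "doubled_from_water"

    if props.t_half_soil is not None:
        hl.soil = props.t_half_soil
        hl.provenance["soil"] = "experimental"
    else:
        hl.soil = hl.water
        hl.provenance["soil"] = "copied_from_water"

    if props.t_half_air is not None:
        hl.air = props.t_half_air
        hl.provenance["air"] = "experimental"
    else:
        hl.air = t.t_half_air_floor_days
        hl.provenance["air"] = "floor_default"
        hl.warnings.append("air half-life missing; floor value assigned")

    ceiling = t.t_half_ceiling_days
    for comp in ("water", "sediment", "soil", "air"):
        v = getattr(hl, comp)
        if v > ceiling:
            setattr(hl, comp, ceiling)
            hl.warnings.append(f"{comp} half-life clamped to ceiling {ceiling} d")
    return hl


def _rates(props: PropertySet, half_lives: HalfLifeSet, params: FateParameters,
           thresholds: ThresholdConfig | None = None) -> dict[str, float]:
    """First-order rate constants (per day) of the single-region model."""
    t = thresholds or ThresholdConfig()
    if props.log_kow is None or props.log_kaw is None:
        raise FateInputError("log Kow and log Kaw are required for fate modelling")
    log_kaw = min(max(props.log_kaw, t.log_kaw_min), t.log_kaw_max)
    kaw = 10.0 ** log_kaw
    kow = 10.0 ** props.log_kow
    if not (math.isfinite(kaw) and math.isfinite(kow)):
        raise FateInputError("non-finite partition coefficient")

    p = params
    v_air = p.area_m2 * p.air_height_m
    a_water = p.area_m2 * p.water_area_fraction
    v_water = a_water * p.water_depth_m
    a_soil = p.area_m2 * p.soil_area_fraction
    v_soil = a_soil * p.soil_depth_m

    koc = p.koc_coefficient * kow                       # L/kg
    ksw = p.foc * koc * p.soil_bulk_density_kg_L        # dimensionless
    f_diss_soil = 1.0 / (1.0 + ksw)

    h = 24.0  # m/h -> m/day
    return {
        "k_deg_air": math.log(2.0) / half_lives.air,
        "k_deg_water": math.log(2.0) / half_lives.water,
        "k_deg_soil": math.log(2.0) / half_lives.soil,
        "k_aw": p.u_air_water * h * a_water / v_air,
        "k_as": p.u_air_soil * h * a_soil / v_air,
        "k_wa": p.u_water_air * h * kaw * a_water / v_water,
        "k_sw": p.u_soil_water * h * f_diss_soil * a_soil / v_soil,
        "k_sa": p.u_soil_air * h * kaw * f_diss_soil * a_soil / v_soil,
    }


def build_steady_state_system(props: PropertySet, half_lives: HalfLifeSet,
                              params: FateParameters,
                              emission_compartment: str = "water",
                              thresholds: ThresholdConfig | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble ``dm/dt = K m + e`` for the closed three-box system.

    Compartment order is (air, water, soil).  Off-diagonal gains equal
    the corresponding donors' transfer losses, so each column of K sums
    to minus that compartment's degradation rate — mass is conserved by
    construction.  The source vector is a unit emission rate into the
    chosen compartment.
    """
    if emission_compartment not in COMPARTMENTS:
        raise ValueError(f"unknown emission compartment {emission_compartment!r}")
    r = _rates(props, half_lives, params, thresholds)
    K = np.array([
        [-(r["k_deg_air"] + r["k_aw"] + r["k_as"]), r["k_wa"], r["k_sa"]],
        [r["k_aw"], -(r["k_deg_water"] + r["k_wa"]), r["k_sw"]],
        [r["k_as"], 0.0, -(r["k_deg_soil"] + r["k_sw"] + r["k_sa"])],
    ])
    e = np.zeros(3)
    e[COMPARTMENTS.index(emission_compartment)] = 1.0
    return K, e


def solve_steady_state(K: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Solve ``K m + e = 0`` for the steady-state masses.

    Raises :class:`DegenerateSystemError` when a compartment has no
    loss process at all (singular system), naming the compartment.
    """
    n = K.shape[0]
    for i in range(n):
        if K[i, i] == 0.0:
            name = COMPARTMENTS[i] if i < len(COMPARTMENTS) else str(i)
            raise DegenerateSystemError(
                f"compartment {name!r} has zero total loss; steady state undefined")
    try:
        m = np.linalg.solve(K, -e)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSystemError(f"singular steady-state system: {exc}") from exc
    residual = np.linalg.norm(K @ m + e) / max(np.linalg.norm(e), 1e-300)
    if residual > 1e-10:
        raise DegenerateSystemError(
            f"ill-conditioned steady-state system (relative residual {residual:.2e})")
    # round tiny negative values caused by floating point to zero
    m = np.where(np.abs(m) < 1e-15 * np.max(np.abs(m)), np.maximum(m, 0.0), m)
    if np.any(m < 0):
        raise DegenerateSystemError("negative steady-state mass")
    return m


def compute_pov(masses: np.ndarray, degradation_rates: np.ndarray) -> float:
    """Overall persistence: mass-weighted residence time, in days."""
    total_loss = float(np.dot(degradation_rates, masses))
    if total_loss <= 0:
        raise DegenerateSystemError("zero total degradation; Pov undefined")
    return float(np.sum(masses)) / total_loss


def compute_ctd(masses: np.ndarray, pov_days: float,
                params: FateParameters) -> tuple[float, str]:
    """Characteristic travel distance (km) and the mobile phase that sets it.

    CTD in each mobile phase is the phase velocity times the overall
    persistence times that phase's mass fraction; the reported value is
    the larger of air and water.
    """
    total = float(np.sum(masses))
    if total <= 0:
        return 0.0, "none"
    day_m = 86400.0 / 1000.0  # (m/s -> km/day)
    ctd_air = params.wind_speed_m_s * day_m * pov_days * float(masses[0]) / total
    ctd_water = params.water_current_m_s * day_m * pov_days * float(masses[1]) / total
    if ctd_air >= ctd_water:
        return ctd_air, "air"
    return ctd_water, "water"


def build_two_region_system(props: PropertySet, half_lives: HalfLifeSet,
                            params: FateParameters,
                            emission_compartment: str = "water",
                            thresholds: ThresholdConfig | None = None
                            ) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Assemble the linked source/remote transport construct.

    Two identical regions are coupled by advection: source air and
    water export into the remote region at rate (phase velocity) /
    (box length); the remote region advects out of the system at the
    same rates.  Compartment order is (air, water, soil) for the
    source region then the remote region.  Returns the 6x6 rate
    matrix, the unit source vector and the rate constants used.
    """
    r = _rates(props, half_lives, params, thresholds)
    K1, _ = build_steady_state_system(props, half_lives, params,
                                      emission_compartment, thresholds)
    day = 86400.0
    r["k_adv_air"] = params.wind_speed_m_s * day / params.box_length_m     # per day
    r["k_adv_water"] = params.water_current_m_s * day / params.box_length_m

    K = np.zeros((6, 6))
    K[:3, :3] = K1
    K[3:, 3:] = K1
    # advective export from both regions (air, water diagonals)
    for block in (0, 3):
        K[block, block] -= r["k_adv_air"]
        K[block + 1, block + 1] -= r["k_adv_water"]
    # source-region exports feed the remote region
    K[3, 0] += r["k_adv_air"]
    K[4, 1] += r["k_adv_water"]
    e = np.zeros(6)
    e[COMPARTMENTS.index(emission_compartment)] = 1.0
    return K, e, r


def compute_te(props: PropertySet, half_lives: HalfLifeSet, params: FateParameters,
               emission_compartment: str = "water",
               thresholds: ThresholdConfig | None = None) -> float:
    """Transfer efficiency (%): emission reaching remote surface media.

    TE is the steady-state flux into the remote region's surface media
    (deposition from remote air to remote water and soil, plus the
    advective water inflow) relative to the unit emission rate, on the
    linked two-region construct.
    """
    K, e, r = build_two_region_system(props, half_lives, params,
                                      emission_compartment, thresholds)
    m = solve_steady_state(K, e)
    deposition_remote = (r["k_aw"] + r["k_as"]) * m[3]
    water_inflow_remote = r["k_adv_water"] * m[1]
    te = 100.0 * (deposition_remote + water_inflow_remote)
    return float(min(max(te, 0.0), 100.0))


def classify_region(pov_days: float, ctd_km: float, te_percent: float,
                    thresholds: ThresholdConfig | None = None) -> str:
    """Place a chemical in the persistence/long-range-transport plane.

    ``A``: Pov and LRTP both above their boundaries (very persistent,
    POP-like); ``B``: only Pov high; ``C``: only LRTP high; ``D``:
    both low (non-persistent).
    """
    t = thresholds or ThresholdConfig()
    pov_high = pov_days > t.pov_cut_days
    lrtp_high = ctd_km > t.ctd_cut_km or te_percent > t.te_cut_percent
    if pov_high and lrtp_high:
        return "A"
    if pov_high:
        return "B"
    if lrtp_high:
        return "C"
    return "D"


def _scenario_result(props: PropertySet, half_lives: HalfLifeSet,
                     params: FateParameters, scenario: str,
                     thresholds: ThresholdConfig | None) -> FateResult:
    K, e = build_steady_state_system(props, half_lives, params, scenario, thresholds)
    m = solve_steady_state(K, e)
    k_deg = np.array([math.log(2.0) / half_lives.air,
                      math.log(2.0) / half_lives.water,
                      math.log(2.0) / half_lives.soil])
    pov = compute_pov(m, k_deg)
    ctd, mobile = compute_ctd(m, pov, params)
    te = compute_te(props, half_lives, params, scenario, thresholds)
    total = float(np.sum(m))
    fractions = {c: float(m[i]) / total for i, c in enumerate(COMPARTMENTS)}
    return FateResult(
        pov_days=pov, ctd_km=ctd, te_percent=te,
        mass_fractions=fractions, emission_scenario=scenario,
        region=classify_region(pov, ctd, te, thresholds), mobile_phase=mobile)


def run_fate(record: SubstanceRecord, params: FateParameters | None = None,
             thresholds: ThresholdConfig | None = None
             ) -> tuple[dict[str, FateResult], FateResult]:
    """Run all three emission scenarios for one substance.

    Returns the per-scenario results and a conservative summary whose
    Pov, CTD and TE are the maxima across scenarios (classification is
    applied to those maxima).  The summary's mass fractions — used for
    the water-distribution term of the surface-water concentration
    estimate — come from the scenario named in the configuration
    (default: emission to water).
    """
    params = params or FateParameters()
    t = thresholds or ThresholdConfig()
    try:
        half_lives = derive_halflives(record.props, t)
        scenarios = {s: _scenario_result(record.props, half_lives, params, s, t)
                     for s in COMPARTMENTS}
    except (FateInputError, DegenerateSystemError) as exc:
        raise FateInputError(f"substance {record.cas}: {exc}") from exc
    pov = max(r.pov_days for r in scenarios.values())
    ctd = max(r.ctd_km for r in scenarios.values())
    te = max(r.te_percent for r in scenarios.values())
    reference = scenarios[t.pec_emission_scenario]
    summary = FateResult(
        pov_days=pov, ctd_km=ctd, te_percent=te,
        mass_fractions=dict(reference.mass_fractions),
        emission_scenario="summary",
        region=classify_region(pov, ctd, te, t),
        mobile_phase=reference.mobile_phase)
    return scenarios, summary
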