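"""Caspase-dependent apoptosis execution model.

Simulates the post-MOMP execution phase of apoptosis for a single tumour
sample from five measured protein concentrations (Apaf-1, procaspase-3,
procaspase-9, SMAC and XIAP, all in μM).  The network is a mass-action ODE
system covering apoptosome assembly, apoptosome-catalysed caspase-3
activation, XIAP sequestration of caspase-3 and of the apoptosome,
XIAP-mediated caspase-3 degradation, SMAC (and SMAC-mimetic) neutralisation
of XIAP, and cleavage of a normalised caspase-3 substrate pool.

The primary readout is substrate cleavage (SC), the percentage of the
substrate pool cleaved, evaluated at 15 minutes of simulated time; samples
with SC ≤ 80% at 15 min are classed apoptosis-resistant, samples above the
threshold apoptosis-sensitive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "KineticParameters",
    "SimulationSettings",
    "ClassificationRule",
    "ReactionNetwork",
    "SimulationResult",
    "SimulationError",
    "ProteinProfile",
    "build_reference_network",
    "simulate",
    "substrate_cleavage_at",
    "classify",
    "classify_cohort",
    "rk4_reference_trajectory",
    "SENSITIVE",
    "RESISTANT",
    "NOMINAL_SENSITIVE_PROFILE",
    "NOMINAL_RESISTANT_PROFILE",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"

#: Model species, all in μM.  APOP is the assembled Apaf-1/caspase-9
#: apoptosome, C3 free active caspase-3, XC3 / XAPOP the XIAP-bound forms,
#: SX / MX the SMAC- and mimetic-bound XIAP complexes, SUB / CSUB the
#: intact and cleaved substrate pool (dimensionless, normalised to sub0).
SPECIES = (
    "APAF", "PC9", "APOP", "PC3", "C3", "XIAP", "XC3",
    "XAPOP", "SMAC", "SX", "MIM", "MX", "SUB", "CSUB",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or inputs are invalid."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the execution network.

    Second-order constants are in μM⁻¹·min⁻¹, first-order constants in
    min⁻¹.  ``sub0`` is the normalised substrate pool (dimensionless).
    The defaults are package fallbacks calibrated so that a nominal
    high-SMAC/low-XIAP profile executes apoptosis well before 15 min while
    a high-XIAP/low-SMAC profile does not (see docs/methods.md).
    """

    k_apop: float = 10.0    # apoptosome assembly, APAF + PC9 -> APOP
    k_cat9: float = 10.0    # apoptosome-catalysed PC3 -> C3
    k_x3_on: float = 10.0   # XIAP + C3 binding
    k_x3_off: float = 0.01
    k_deg3: float = 0.1     # degradation of caspase-3 within XC3 (XIAP recycled)
    k_xa_on: float = 10.0   # XIAP + apoptosome binding
    k_xa_off: float = 0.01
    k_sx_on: float = 10.0   # SMAC + XIAP binding
    k_sx_off: float = 0.01
    k_mx_on: float = 10.0   # mimetic + XIAP binding (defaults mirror SMAC)
    k_mx_off: float = 0.01
    k_sub: float = 10.0     # substrate cleavage by free caspase-3
    k_turn3: float = 0.01   # first-order turnover of free caspase-3
    sub0: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"kinetic parameter {f.name}={v!r} must be finite and >= 0")
        if self.sub0 <= 0:
            raise ValueError("sub0 must be > 0")

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, readout time, tolerances and output grid (min)."""

    t_end: float = 60.0
    readout_time: float = 15.0
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.readout_time <= self.t_end):
            raise ValueError("require 0 < readout_time <= t_end")
        if self.grid_dt <= 0:
            raise ValueError("grid_dt must be > 0")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.grid_dt))
        return np.linspace(0.0, n * self.grid_dt, n + 1)


@dataclass(frozen=True)
class ClassificationRule:
    """Resistant iff substrate cleavage at the readout time is <= threshold.

    The boundary itself (SC exactly at the threshold) is assigned to the
    resistant class.
    """

    threshold: float = 80.0
    readout_time: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 100):
            raise ValueError("threshold must lie in (0, 100)")


@dataclass(frozen=True)
class ProteinProfile:
    """Per-sample absolute concentrations (μM) driving one simulation."""

    sample_id: str
    apaf1: float
    pc3: float
    pc9: float
    smac: float
    xiap: float
    history: str = "newly_diagnosed"

    def __post_init__(self) -> None:
        for name in ("apaf1", "pc3", "pc9", "smac", "xiap"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name}={v!r} must be finite and >= 0"
                )

    @classmethod
    def from_row(cls, row: Mapping) -> "ProteinProfile":
        return cls(
            sample_id=str(row["sample_id"]),
            apaf1=float(row["apaf1_uM"]),
            pc3=float(row["pc3_uM"]),
            pc9=float(row["pc9_uM"]),
            smac=float(row["smac_uM"]),
            xiap=float(row["xiap_uM"]),
            history=str(row.get("history", "newly_diagnosed")),
        )


# Nominal fixture profiles used for the fallback-parameter calibration check.
# Concentration ordering follows the cohort structure (procaspase-3 highest,
# procaspase-9 lowest); the resistant fixture inverts the XIAP/SMAC balance.
NOMINAL_SENSITIVE_PROFILE = ProteinProfile("nominal_sensitive", apaf1=1.0, pc3=2.0,
                                           pc9=0.1, smac=1.0, xiap=0.3)
NOMINAL_RESISTANT_PROFILE = ProteinProfile("nominal_resistant", apaf1=1.0, pc3=2.0,
                                           pc9=0.1, smac=0.1, xiap=2.0)


def _stoichiometry() -> tuple[np.ndarray, list[str]]:
    """Stoichiometry matrix (species x elementary fluxes).

    Reversible bindings contribute two flux columns each; the network has
    nine distinct reactions (R1-R9).
    """
    fluxes = [
        # (name, {species: delta})
        ("apoptosome_assembly", {"APAF": -1, "PC9": -1, "APOP": +1}),
        ("pc3_activation", {"PC3": -1, "C3": +1}),
        ("xiap_c3_bind", {"XIAP": -1, "C3": -1, "XC3": +1}),
        ("xiap_c3_unbind", {"XIAP": +1, "C3": +1, "XC3": -1}),
        ("c3_degradation_in_complex", {"XC3": -1, "XIAP": +1}),
        ("xiap_apop_bind", {"XIAP": -1, "APOP": -1, "XAPOP": +1}),
        ("xiap_apop_unbind", {"XIAP": +1, "APOP": +1, "XAPOP": -1}),
        ("smac_xiap_bind", {"SMAC": -1, "XIAP": -1, "SX": +1}),
        ("smac_xiap_unbind", {"SMAC": +1, "XIAP": +1, "SX": -1}),
        ("mimetic_xiap_bind", {"MIM": -1, "XIAP": -1, "MX": +1}),
        ("mimetic_xiap_unbind", {"MIM": +1, "XIAP": +1, "MX": -1}),
        ("substrate_cleavage", {"SUB": -1, "CSUB": +1}),
        ("c3_turnover", {"C3": -1}),
    ]
    S = np.zeros((len(SPECIES), len(fluxes)))
    for j, (_, deltas) in enumerate(fluxes):
        for sp, d in deltas.items():
            S[_IDX[sp], j] = d
    return S, [name for name, _ in fluxes]


@dataclass(frozen=True)
class ReactionNetwork:
    """Mass-action network binding the stoichiometry to rate constants."""

    params: KineticParameters
    stoichiometry: np.ndarray = field(repr=False)
    flux_names: tuple[str, ...] = field(repr=False)

    n_species: int = len(SPECIES)
    n_reactions: int = 9  # reversible pairs counted once

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Elementary reaction fluxes; vectorised over leading axes of ``y``.

        ``y`` has species along the last axis.
        """
        p = self.params
        APAF, PC9, APOP, PC3, C3, XIAP, XC3, XAPOP, SMAC, SX, MIM, MX, SUB, _ = (
            y[..., i] for i in range(len(SPECIES))
        )
        return np.stack(
            [
                p.k_apop * APAF * PC9,
                p.k_cat9 * APOP * PC3,
                p.k_x3_on * XIAP * C3,
                p.k_x3_off * XC3,
                p.k_deg3 * XC3,
                p.k_xa_on * XIAP * APOP,
                p.k_xa_off * XAPOP,
                p.k_sx_on * SMAC * XIAP,
                p.k_sx_off * SX,
                p.k_mx_on * MIM * XIAP,
                p.k_mx_off * MX,
                p.k_sub * C3 * SUB,
                p.k_turn3 * C3,
            ],
            axis=-1,
        )

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.fluxes(y) @ self.stoichiometry.T

    def conservation_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Left null-vectors of the stoichiometry: conserved pools.

        Rows are (substrate, SMAC, mimetic, Apaf-1, caspase-9, XIAP) totals.
        """
        pools = {
            "substrate": ["SUB", "CSUB"],
            "smac": ["SMAC", "SX"],
            "mimetic": ["MIM", "MX"],
            "apaf1": ["APAF", "APOP", "XAPOP"],
            "caspase9": ["PC9", "APOP", "XAPOP"],
            "xiap": ["XIAP", "XC3", "XAPOP", "SX", "MX"],
        }
        L = np.zeros((len(pools), len(SPECIES)))
        for i, members in enumerate(pools.values()):
            for sp in members:
                L[i, _IDX[sp]] = 1.0
        return L, list(pools)


def build_reference_network(params: KineticParameters | None = None) -> ReactionNetwork:
    """Assemble the canonical execution network for the given rate constants."""
    params = params or KineticParameters()
    S, names = _stoichiometry()
    return ReactionNetwork(params=params, stoichiometry=S, flux_names=tuple(names))


def initial_state(profile: ProteinProfile, mimetic_dose: float, sub0: float) -> np.ndarray:
    """State at full mitochondrial permeabilisation: SMAC cytosolic, no complexes."""
    if mimetic_dose < 0 or not np.isfinite(mimetic_dose):
        raise ValueError("mimetic_dose must be finite and >= 0")
    y0 = np.zeros(len(SPECIES))
    y0[_IDX["APAF"]] = profile.apaf1
    y0[_IDX["PC9"]] = profile.pc9
    y0[_IDX["PC3"]] = profile.pc3
    y0[_IDX["XIAP"]] = profile.xiap
    y0[_IDX["SMAC"]] = profile.smac
    y0[_IDX["MIM"]] = mimetic_dose
    y0[_IDX["SUB"]] = sub0
    return y0


@dataclass
class SimulationResult:
    """Trajectories on a uniform grid plus the SC readout and class."""

    sample_id: str
    time: np.ndarray
    trajectories: pd.DataFrame  # columns = SPECIES, index aligned with time
    sc_percent: np.ndarray
    sc_at_readout: float
    apoptosis_class: str
    mimetic_dose: float = 0.0

    def conservation_errors(self, profile: ProteinProfile,
                            network: ReactionNetwork) -> dict[str, float]:
        """Max relative drift of each conserved pool along the trajectory."""
        L, names = network.conservation_matrix()
        totals = self.trajectories[list(SPECIES)].to_numpy() @ L.T
        y0 = initial_state(profile, self.mimetic_dose, network.params.sub0)
        ref = L @ y0
        out = {}
        for i, name in enumerate(names):
            if ref[i] == 0.0:
                out[name] = float(np.max(np.abs(totals[:, i])))
            else:
                out[name] = float(np.max(np.abs(totals[:, i] - ref[i]) / ref[i]))
        return out


def simulate(profile: ProteinProfile,
             mimetic_dose: float = 0.0,
             params: KineticParameters | None = None,
             settings: SimulationSettings | None = None,
             rule: ClassificationRule | None = None) -> SimulationResult:
    """Integrate the execution network for one sample.

    The clock starts at mitochondrial permeabilisation with SMAC fully
    cytosolic.  Trajectories are reported on a uniform grid; tiny negative
    excursions from the solver are clamped to zero for reporting only.
    """
    params = params or KineticParameters()
    settings = settings or SimulationSettings()
    rule = rule or ClassificationRule(readout_time=settings.readout_time)
    network = build_reference_network(params)
    y0 = initial_state(profile, mimetic_dose, params.sub0)
    t_grid = settings.time_grid

    sol = solve_ivp(
        network.rhs, (0.0, settings.t_end), y0,
        method="LSODA", t_eval=t_grid,
        rtol=settings.rtol, atol=settings.atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed for sample {profile.sample_id!r}: {sol.message}"
        )

    y = sol.y.T
    if np.min(y) < -10.0 * settings.atol * max(1.0, float(np.max(np.abs(y0)))):
        raise SimulationError(
            f"solver produced significantly negative concentrations for "
            f"sample {profile.sample_id!r} (min={np.min(y):.3e})"
        )
    y = np.clip(y, 0.0, None)

    traj = pd.DataFrame(y, columns=list(SPECIES))
    sc = 100.0 * np.clip(y[:, _IDX["CSUB"]] / params.sub0, 0.0, 1.0)
    sc_readout = float(np.interp(rule.readout_time, t_grid, sc))
    return SimulationResult(
        sample_id=profile.sample_id,
        time=t_grid,
        trajectories=traj,
        sc_percent=sc,
        sc_at_readout=sc_readout,
        apoptosis_class=classify(sc_readout, rule),
        mimetic_dose=mimetic_dose,
    )


def substrate_cleavage_at(result: SimulationResult, t: float = 15.0) -> float:
    """SC (%) at time ``t`` by linear interpolation on the output grid."""
    if not (result.time[0] <= t <= result.time[-1]):
        raise ValueError(f"t={t} outside the simulated range "
                         f"[{result.time[0]}, {result.time[-1]}]")
    return float(np.interp(t, result.time, result.sc_percent))


def classify(sc_at_readout: float, rule: ClassificationRule | None = None) -> str:
    """Apoptosis class from the SC readout; the threshold itself is resistant."""
    rule = rule or ClassificationRule()
    if not (0.0 <= sc_at_readout <= 100.0) or not np.isfinite(sc_at_readout):
        raise ValueError(f"substrate cleavage {sc_at_readout!r} outside [0, 100]")
    return RESISTANT if sc_at_readout <= rule.threshold else SENSITIVE


def classify_cohort(profiles: pd.DataFrame,
                    params: KineticParameters | None = None,
                    settings: SimulationSettings | None = None,
                    rule: ClassificationRule | None = None) -> pd.DataFrame:
    """Simulate every sample and attach the SC readout and apoptosis class.

    ``profiles`` follows the profiles.csv schema (sample_id, history,
    apaf1_uM, pc3_uM, pc9_uM, smac_uM, xiap_uM).  Returns one row per
    sample: sample_id, history, sc_at_15min_percent, apoptosis_class.
    """
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    rows = []
    for _, row in profiles.iterrows():
        prof = ProteinProfile.from_row(row)
        res = simulate(prof, params=params, settings=settings, rule=rule)
        rows.append({
            "sample_id": prof.sample_id,
            "history": prof.history,
            "sc_at_15min_percent": res.sc_at_readout,
            "apoptosis_class": res.apoptosis_class,
        })
    return pd.DataFrame(rows)


def contingency_by_history(classified: pd.DataFrame) -> pd.DataFrame:
    """2x2 apoptosis-class by tumour-history table with preserved marginals."""
    tab = pd.crosstab(classified["apoptosis_class"], classified["history"])
    return tab.reindex(index=[SENSITIVE, RESISTANT], fill_value=0)


def rk4_reference_trajectory(profile: ProteinProfile,
                             mimetic_dose: float = 0.0,
                             params: KineticParameters | None = None,
                             t_end: float = 15.0,
                             dt: float = 1e-3,
                             record_every: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical Runge-Kutta integration, used as a solver oracle.

    Returns (times, states) with states recorded every ``record_every``
    steps.  Deliberately independent of :func:`simulate`'s adaptive path.
    """
    params = params or KineticParameters()
    network = build_reference_network(params)
    y = initial_state(profile, mimetic_dose, params.sub0)
    n_steps = int(round(t_end / dt))
    times = [0.0]
    states = [y.copy()]
    f = lambda yv: network.fluxes(yv) @ network.stoichiometry.T
    for step in range(1, n_steps + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % record_every == 0:
            times.append(step * dt)
            states.append(y.copy())
    return np.asarray(times), np.asarray(states)


def calibrate_fallback_rates(params: KineticParameters | None = None,
                             settings: SimulationSettings | None = None,
                             rule: ClassificationRule | None = None,
                             max_iter: int = 40) -> KineticParameters:
    """Ensure the fallback constants separate the nominal fixture profiles.

    Requires the nominal sensitive profile to cross the SC threshold before
    the readout time and the nominal resistant profile to stay at or below
    it.  If the supplied constants fail, ``k_cat9`` and ``k_sub`` are scaled
    by a common factor found by bisection on log2(scale).
    """
    params = params or KineticParameters()
    settings = settings or SimulationSettings()
    rule = rule or ClassificationRule()

    def separates(p: KineticParameters) -> bool:
        sens = simulate(NOMINAL_SENSITIVE_PROFILE, params=p, settings=settings, rule=rule)
        res = simulate(NOMINAL_RESISTANT_PROFILE, params=p, settings=settings, rule=rule)
        return (sens.apoptosis_class == SENSITIVE) and (res.apoptosis_class == RESISTANT)

    if separates(params):
        return params

    def scaled(log2s: float) -> KineticParameters:
        s = 2.0 ** log2s
        return params.replace(k_cat9=params.k_cat9 * s, k_sub=params.k_sub * s)

    lo, hi = -8.0, 8.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = scaled(mid)
        sens = simulate(NOMINAL_SENSITIVE_PROFILE, params=p, settings=settings, rule=rule)
        res = simulate(NOMINAL_RESISTANT_PROFILE, params=p, settings=settings, rule=rule)
        if sens.apoptosis_class == SENSITIVE and res.apoptosis_class == RESISTANT:
            return p
        if sens.apoptosis_class == RESISTANT:
            lo = mid  # too slow: speed up catalysis
        else:
            hi = mid  # resistant fixture cleaving too fast: slow down
    raise SimulationError("fallback calibration failed: no common scale separates "
                          "the nominal sensitive and resistant fixtures")
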