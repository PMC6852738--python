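"""Synthetic cohort generation.

Generates fully synthetic glioblastoma-like cohorts — protein profiles,
raw densitometry tables with calibration standards, and linked
progression-free-survival outcomes — carrying the statistical structure
the pipeline assumes: right-skewed positive concentrations with
procaspase-3 highest and procaspase-9 lowest, systematically lower levels
in recurrent than newly-diagnosed tumours, per-batch multiplicative scale
distortions, and exponential proportional-hazards PFS whose hazard depends
on apoptosis class with a configurable hazard ratio and administrative
censoring.

All randomness in every operation flows through a single
``numpy.random.Generator`` seeded per call, so outputs are byte-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    ClassificationRule,
    KineticParameters,
    RESISTANT,
    SimulationSettings,
    classify_cohort,
)
from .quantify import (
    CalibrationCurve,
    NEWLY_DIAGNOSED,
    PROTEINS,
    PROTEIN_COLUMNS,
    RECURRENT,
)

__all__ = [
    "CohortSpec",
    "OutcomeSpec",
    "default_calibration_curves",
    "generate_profiles",
    "generate_densitometry",
    "generate_outcomes",
    "make_fixture_cohort",
]

#: Median concentrations (μM) of the log-normal concentration model for
#: newly-diagnosed tumours.  Ordered so procaspase-3 is highest and
#: procaspase-9 lowest; the XIAP/SMAC balance yields a mixed cohort with a
#: minority of apoptosis-resistant samples under the default kinetics.
DEFAULT_MEDIANS_UM = {"APAF1": 0.8, "PC3": 2.0, "PC9": 0.1, "SMAC": 1.0, "XIAP": 0.9}
#: Log-scale standard deviation of the log-normal concentration model.
DEFAULT_SIGMA = 0.6


@dataclass(frozen=True)
class CohortSpec:
    """Concentration model for one synthetic cohort."""

    n_total: int = 46
    fraction_recurrent: float = 15 / 46
    medians_uM: dict = field(default_factory=lambda: dict(DEFAULT_MEDIANS_UM))
    sigma_log: float = DEFAULT_SIGMA
    group_effect: float = 0.7   # multiplicative reduction for recurrent samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not (0.0 <= self.fraction_recurrent <= 1.0):
            raise ValueError("fraction_recurrent must lie in [0, 1]")
        if self.sigma_log <= 0 or self.group_effect <= 0:
            raise ValueError("sigma_log and group_effect must be > 0")
        if set(self.medians_uM) != set(PROTEINS):
            raise ValueError(f"medians_uM must cover exactly {PROTEINS}")


@dataclass(frozen=True)
class OutcomeSpec:
    """Exponential proportional-hazards outcome model."""

    hazard_ratio: float = 5.0        # resistant vs sensitive
    baseline_rate: float = 0.063     # events / month for the sensitive class
    censor_window_months: float = 36.0  # administrative censoring ~ U(0, window)
    # optional log-hazard covariate effects (all default to no effect)
    effect_recurrent: float = 0.0
    effect_age_per_year: float = 0.0
    effect_mgmt_unmethylated: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0 or self.baseline_rate <= 0:
            raise ValueError("hazard_ratio and baseline_rate must be > 0")
        if self.censor_window_months < 0:
            raise ValueError("censor_window_months must be >= 0")


def default_calibration_curves(seed: int = 0) -> dict[str, CalibrationCurve]:
    """Synthetic per-protein calibration lines (documented fixture).

    Slopes map a typical normalised band intensity of ~1 onto each
    protein's typical concentration; intercepts are zero so batch scale
    distortions stay purely multiplicative through calibration.
    """
    return {
        p: CalibrationCurve(protein=p, slope=DEFAULT_MEDIANS_UM[p], intercept=0.0,
                            r_squared=1.0)
        for p in PROTEINS
    }


def generate_profiles(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of protein profiles (profiles.csv layout + history).

    Concentrations are independent log-normals per protein; recurrent
    samples are scaled down by ``group_effect`` for every protein, so the
    recurrent/newly median ratio converges to the group effect.
    """
    rng = np.random.default_rng(spec.seed)
    n_rec = int(round(spec.n_total * spec.fraction_recurrent))
    n_new = spec.n_total - n_rec
    history = np.array([NEWLY_DIAGNOSED] * n_new + [RECURRENT] * n_rec)
    out = {
        "sample_id": [f"S{i + 1:03d}" for i in range(spec.n_total)],
        "history": history,
    }
    scale = np.where(history == RECURRENT, spec.group_effect, 1.0)
    for protein in PROTEINS:
        draws = rng.lognormal(mean=np.log(spec.medians_uM[protein]),
                              sigma=spec.sigma_log, size=spec.n_total)
        out[PROTEIN_COLUMNS[protein]] = draws * scale
    return pd.DataFrame(out)


def generate_densitometry(profiles: pd.DataFrame,
                          curves: dict[str, CalibrationCurve] | None = None,
                          noise_sd: float = 0.0,
                          batch_factors: dict[str, dict[str, float]] | None = None,
                          seed: int = 0,
                          standards_points: int = 5,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the quantification stage: profiles -> raw band intensities.

    ``batch_factors`` maps batch_id -> protein -> multiplicative intensity
    distortion; samples are assigned to batches via a ``batch_id`` column
    on ``profiles`` (default: single batch "batch0" with unit factors).
    ``noise_sd`` is the log-normal measurement noise on band intensities.
    Returns (densitometry, standards) in the CSV schemas; the standards are
    noise-free titration points of each calibration line.
    """
    curves = curves or default_calibration_curves()
    for p, c in curves.items():
        if c.slope == 0:
            raise ValueError(f"{p}: zero calibration slope is not invertible")
    rng = np.random.default_rng(seed)
    batch_ids = profiles["batch_id"] if "batch_id" in profiles else \
        pd.Series("batch0", index=profiles.index)
    batch_factors = batch_factors or {}

    rows = []
    for (_, prof), batch in zip(profiles.iterrows(), batch_ids):
        per_batch = batch_factors.get(str(batch), {})
        for protein in PROTEINS:
            conc = float(prof[PROTEIN_COLUMNS[protein]])
            x = (conc - curves[protein].intercept) / curves[protein].slope
            actin = float(rng.uniform(800.0, 1200.0))
            noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            band = x * actin * per_batch.get(protein, 1.0) * noise
            rows.append({
                "sample_id": prof["sample_id"],
                "batch_id": str(batch),
                "protein": protein,
                "band_intensity": max(band, 0.0),
                "actin_intensity": actin,
            })

    std_rows = []
    for protein in PROTEINS:
        c = curves[protein]
        # titration spanning the physiological range around the typical intensity
        for x in np.geomspace(0.25, 4.0, standards_points):
            std_rows.append({
                "protein": protein,
                "normalized_intensity": float(x),
                "known_concentration_uM": float(c.slope * x + c.intercept),
            })
    return pd.DataFrame(rows), pd.DataFrame(std_rows)


def generate_outcomes(classified: pd.DataFrame,
                      spec: OutcomeSpec,
                      covariate_mode: bool = True) -> pd.DataFrame:
    """Exponential PFS linked to apoptosis class (clinical.csv layout).

    ``classified`` needs sample_id, history and apoptosis_class columns
    (either simulated or planted).  Event times are exponential with rate
    ``baseline_rate * hazard_ratio**[resistant]``; censoring times are
    uniform on (0, censor_window_months].  A zero window censors everyone
    immediately, the degenerate no-event case downstream code must reject.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(classified)
    resistant = (classified["apoptosis_class"] == RESISTANT).to_numpy()
    recurrent = (classified["history"] == RECURRENT).to_numpy()

    covariates = None
    log_hr = np.log(spec.hazard_ratio) * resistant \
        + spec.effect_recurrent * recurrent
    if covariate_mode:
        treated = rng.random(n) < 0.6
        age = np.clip(rng.normal(55.0, 13.0, size=n), 16, 80).round(0)
        mgmt = rng.choice(["methylated", "unmethylated", "missing"],
                          size=n, p=[0.37, 0.48, 0.15])
        covariates = {
            "age_years": age,
            "sex": rng.choice(["M", "F"], size=n),
            "location": rng.choice(["left", "right", "other", "missing"],
                                   size=n, p=[0.30, 0.55, 0.10, 0.05]),
            "history3": np.where(
                recurrent,
                np.where(treated, "recurrent_treated", "recurrent_no_treatment"),
                "newly_no_treatment"),
            "mgmt": mgmt,
        }
        log_hr = log_hr + spec.effect_age_per_year * (age - 55.0) \
            + spec.effect_mgmt_unmethylated * (mgmt == "unmethylated")

    rate = spec.baseline_rate * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)
    if spec.censor_window_months > 0:
        t_censor = rng.uniform(0.0, spec.censor_window_months, size=n)
    else:
        t_censor = np.full(n, 1e-9)
    pfs = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    out = pd.DataFrame({
        "sample_id": classified["sample_id"].to_numpy(),
        "pfs_months": np.maximum(pfs, 1e-9),
        "event": event,
    })
    if covariates is not None:
        for k, v in covariates.items():
            out[k] = v
    return out


def make_fixture_cohort(seed: int = 0,
                        cohort_spec: CohortSpec | None = None,
                        outcome_spec: OutcomeSpec | None = None,
                        params: KineticParameters | None = None,
                        settings: SimulationSettings | None = None,
                        ) -> dict:
    """Complete study-sized bundle: densitometry, standards and clinical CSVs.

    Defaults to n = 46 with 31 newly-diagnosed / 15 recurrent samples split
    across two blotting batches (batch1 carries planted intensity
    distortions).  Apoptosis classes feeding the outcome generator are
    produced by actually running the simulator on the true profiles.
    Returns a dict of DataFrames plus a ``truth`` record of every planted
    parameter.
    """
    cohort_spec = cohort_spec or CohortSpec(seed=seed)
    if cohort_spec.seed != seed:
        cohort_spec = replace(cohort_spec, seed=seed)
    profiles = generate_profiles(cohort_spec)

    # even/odd sample split across two batches; batch1 intensities distorted
    batch_ids = np.where(np.arange(len(profiles)) % 2 == 0, "batch0", "batch1")
    profiles = profiles.assign(batch_id=batch_ids)
    planted_factors = {p: f for p, f in zip(PROTEINS, (1.3, 0.8, 1.5, 0.7, 1.2))}
    densitometry, standards = generate_densitometry(
        profiles, noise_sd=0.05, batch_factors={"batch1": planted_factors},
        seed=seed + 1,
    )

    classes = classify_cohort(profiles, params=params, settings=settings)
    outcome_spec = outcome_spec or OutcomeSpec(seed=seed + 2)
    if outcome_spec.seed != seed + 2:
        outcome_spec = replace(outcome_spec, seed=seed + 2)
    clinical = generate_outcomes(classes, outcome_spec)

    truth = {
        "seed": seed,
        "group_effect": cohort_spec.group_effect,
        "hazard_ratio": outcome_spec.hazard_ratio,
        "baseline_rate": outcome_spec.baseline_rate,
        "batch_factors": {"batch1": planted_factors},
        "medians_uM": dict(cohort_spec.medians_uM),
        "n_total": cohort_spec.n_total,
        "n_recurrent": int((profiles["history"] == RECURRENT).sum()),
    }
    return {
        "profiles": profiles,
        "densitometry": densitometry,
        "standards": standards,
        "classes": classes,
        "clinical": clinical,
        "truth": truth,
    }
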