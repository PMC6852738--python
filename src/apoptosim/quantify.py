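"""Western-blot densitometry to absolute protein concentrations.

Band intensities are normalised to the β-actin loading control, mapped to
μM via per-protein linear calibration curves fitted against reference
standards (titrated recombinant protein in cell extract), and harmonised
across blotting batches by aligning per-protein medians of the
newly-diagnosed samples.  Expression differences between newly-diagnosed
and recurrent tumours are assessed with two-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROTEINS",
    "PROTEIN_COLUMNS",
    "NEWLY_DIAGNOSED",
    "RECURRENT",
    "DensitometryRecord",
    "CalibrationCurve",
    "BatchScaleFactors",
    "InvalidRecordError",
    "DegenerateFitError",
    "normalize_band",
    "fit_calibration",
    "apply_calibration",
    "quantify_cohort",
    "batch_align",
    "align_batches_within",
    "compare_expression",
]

#: Canonical protein codes (densitometry ``protein`` column) and the
#: matching concentration columns of profiles.csv.
PROTEINS = ("APAF1", "PC3", "PC9", "SMAC", "XIAP")
PROTEIN_COLUMNS = {
    "APAF1": "apaf1_uM",
    "PC3": "pc3_uM",
    "PC9": "pc9_uM",
    "SMAC": "smac_uM",
    "XIAP": "xiap_uM",
}
NEWLY_DIAGNOSED = "newly_diagnosed"
RECURRENT = "recurrent"


class InvalidRecordError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class DensitometryRecord:
    sample_id: str
    protein: str
    band_intensity: float
    actin_intensity: float
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        if self.protein not in PROTEINS:
            raise InvalidRecordError(
                f"sample {self.sample_id!r}: unknown protein {self.protein!r} "
                f"(expected one of {PROTEINS})"
            )
        if self.band_intensity < 0:
            raise InvalidRecordError(
                f"sample {self.sample_id!r}: negative band intensity")


@dataclass(frozen=True)
class CalibrationCurve:
    """μM = slope * (band/actin) + intercept for one protein."""

    protein: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise DegenerateFitError(f"{self.protein}: non-finite slope")


@dataclass(frozen=True)
class BatchScaleFactors:
    """Per-protein multiplicative correction applied to a target batch."""

    factors: Mapping[str, float]
    alignment_subset: str

    def __post_init__(self) -> None:
        for p, f in self.factors.items():
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"batch factor for {p} must be finite and > 0, got {f!r}")


def normalize_band(record: DensitometryRecord) -> float:
    """Band intensity relative to the β-actin loading control."""
    if not record.actin_intensity > 0:
        raise InvalidRecordError(
            f"sample {record.sample_id!r}, protein {record.protein}: "
            f"loading-control intensity must be > 0 (got {record.actin_intensity!r})"
        )
    return record.band_intensity / record.actin_intensity


def fit_calibration(standards: pd.DataFrame, protein: str) -> CalibrationCurve:
    """Ordinary least-squares line of known μM on normalised intensity.

    ``standards`` needs columns protein, normalized_intensity,
    known_concentration_uM.
    """
    sub = standards[standards["protein"] == protein]
    x = sub["normalized_intensity"].to_numpy(dtype=float)
    y = sub["known_concentration_uM"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateFitError(
            f"{protein}: need >= 2 distinct normalised intensities to fit "
            f"a calibration line (got {len(np.unique(x))})"
        )
    res = stats.linregress(x, y)
    return CalibrationCurve(protein=protein, slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))


def apply_calibration(normalized_intensity: float, curve: CalibrationCurve) -> float:
    """Map a normalised intensity to μM, flooring negatives at zero."""
    if not np.isfinite(normalized_intensity):
        raise InvalidRecordError(f"non-finite normalised intensity for {curve.protein}")
    conc = curve.slope * normalized_intensity + curve.intercept
    if conc < 0:
        warnings.warn(
            f"{curve.protein}: calibrated concentration {conc:.4g} uM < 0 floored to 0",
            stacklevel=2,
        )
        conc = 0.0
    return float(conc)


def quantify_cohort(densitometry: pd.DataFrame,
                    standards: pd.DataFrame,
                    history: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Full quantification: normalise, calibrate, pivot to one row per sample.

    ``densitometry`` follows densitometry.csv (sample_id, batch_id, protein,
    band_intensity, actin_intensity); ``history`` optionally maps sample_id
    to newly_diagnosed / recurrent.  Returns the profiles.csv schema.
    """
    curves = {p: fit_calibration(standards, p) for p in PROTEINS}
    rows: dict[str, dict] = {}
    for _, r in densitometry.iterrows():
        rec = DensitometryRecord(
            sample_id=str(r["sample_id"]), protein=str(r["protein"]),
            band_intensity=float(r["band_intensity"]),
            actin_intensity=float(r["actin_intensity"]),
            batch_id=str(r.get("batch_id", "batch0")),
        )
        conc = apply_calibration(normalize_band(rec), curves[rec.protein])
        row = rows.setdefault(rec.sample_id, {"sample_id": rec.sample_id,
                                              "batch_id": rec.batch_id})
        row[PROTEIN_COLUMNS[rec.protein]] = conc
    profiles = pd.DataFrame(list(rows.values()))
    missing = [c for c in PROTEIN_COLUMNS.values() if c not in profiles.columns
               or profiles[c].isna().any()]
    if missing:
        raise InvalidRecordError(f"incomplete densitometry: missing measurements for {missing}")
    if history is not None:
        profiles["history"] = profiles["sample_id"].map(dict(history))
        if profiles["history"].isna().any():
            lost = profiles.loc[profiles["history"].isna(), "sample_id"].tolist()
            raise InvalidRecordError(f"no history label for samples {lost}")
    cols = ["sample_id"] + (["history"] if history is not None else []) \
        + ["batch_id"] + list(PROTEIN_COLUMNS.values())
    return profiles[cols]


def batch_align(target_profiles: pd.DataFrame,
                reference_profiles: pd.DataFrame,
                alignment_subset: str = NEWLY_DIAGNOSED,
                ) -> tuple[pd.DataFrame, BatchScaleFactors]:
    """Multiplicatively align a target batch to a reference batch.

    For each protein the scale factor is the ratio of reference to target
    medians computed over the alignment subset (newly-diagnosed samples by
    default); the factor is applied to every target sample, newly-diagnosed
    and recurrent alike, so within-batch concentration ratios are preserved
    and the alignment-subset medians agree exactly after correction.
    """
    cols = list(PROTEIN_COLUMNS.values())
    t_sub = target_profiles[target_profiles["history"] == alignment_subset]
    r_sub = reference_profiles[reference_profiles["history"] == alignment_subset]
    if len(t_sub) == 0 or len(r_sub) == 0:
        raise ValueError(
            f"alignment subset {alignment_subset!r} empty in "
            f"{'target' if len(t_sub) == 0 else 'reference'} batch"
        )
    factors = {}
    for protein, col in PROTEIN_COLUMNS.items():
        med_t = float(t_sub[col].median())
        med_r = float(r_sub[col].median())
        if med_t <= 0:
            raise ValueError(f"{protein}: non-positive target median ({med_t}); "
                             "cannot scale")
        factors[protein] = med_r / med_t
    corrected = target_profiles.copy()
    for protein, col in PROTEIN_COLUMNS.items():
        corrected[col] = corrected[col] * factors[protein]
    return corrected, BatchScaleFactors(
        factors=factors,
        alignment_subset=f"{alignment_subset} samples "
                         f"(n={len(t_sub)} target, n={len(r_sub)} reference)",
    )


def align_batches_within(profiles: pd.DataFrame,
                         reference_batch: str | None = None,
                         alignment_subset: str = NEWLY_DIAGNOSED,
                         ) -> tuple[pd.DataFrame, dict[str, BatchScaleFactors]]:
    """Align every blotting batch in one table to a reference batch.

    ``profiles`` must carry a ``batch_id`` column; each non-reference batch
    is median-aligned (via :func:`batch_align`) to the reference batch
    (default: the first batch_id in sorted order).  Returns the corrected
    table and the per-batch scale factors.
    """
    if "batch_id" not in profiles.columns:
        raise ValueError("profiles need a batch_id column for within-table alignment")
    batches = sorted(profiles["batch_id"].astype(str).unique())
    reference_batch = reference_batch or batches[0]
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} not present")
    ref = profiles[profiles["batch_id"].astype(str) == reference_batch]
    pieces, factors = [ref], {}
    for b in batches:
        if b == reference_batch:
            continue
        target = profiles[profiles["batch_id"].astype(str) == b]
        corrected, f = batch_align(target, ref, alignment_subset=alignment_subset)
        pieces.append(corrected)
        factors[b] = f
    out = pd.concat(pieces).loc[profiles.index]
    return out, factors


def compare_expression(profiles: pd.DataFrame,
                       group_col: str = "history",
                       groups: tuple[str, str] = (NEWLY_DIAGNOSED, RECURRENT),
                       exact_max_n: int = 20) -> pd.Series:
    """Two-sided Mann-Whitney U p-value per protein between two groups.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and there are no ties, the tie-corrected normal
    approximation otherwise.
    """
    a = profiles[profiles[group_col] == groups[0]]
    b = profiles[profiles[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"both groups must be non-empty (got {len(a)} vs {len(b)})")
    pvals = {}
    for protein, col in PROTEIN_COLUMNS.items():
        x, y = a[col].to_numpy(float), b[col].to_numpy(float)
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= exact_max_n and no_ties) else "asymptotic"
        pvals[protein] = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                                  method=method).pvalue)
    return pd.Series(pvals, name="mannwhitney_p")
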