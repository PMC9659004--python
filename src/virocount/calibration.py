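"""Copy-number calibration and motor-count arithmetic.

A set of protein-nanocage standards with known fluorophore copy numbers
(24-, 60-, 120- and 180-mer) defines a through-origin intensity standard
curve; virion intensities are divided by its slope to yield fluorophore
(molecule) counts, halved to motor complexes (two tagged heavy chains per
kinesin-1), and rescaled by an antibody-derived expression-correction
factor when the tagged line under-expresses the motor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError

__all__ = [
    "CalibrationCurve",
    "MotorCountResult",
    "fit_calibration",
    "intensity_to_molecules",
    "molecules_to_complexes",
    "expression_correction_factor",
    "corrected_mean_complexes",
]


@dataclass
class CalibrationCurve:
    """Copy-number → intensity standard.

    ``species`` has one row per standard (copy_number, n_spots,
    mean_intensity, sd); ``slope`` is the through-origin least-squares
    slope in counts per fluorophore and ``r_squared`` the uncentred R² of
    the through-origin fit on the fitted points.
    """

    species: pd.DataFrame
    slope: float
    r_squared: float
    per_spot: bool = False


@dataclass
class MotorCountResult:
    """Cohort-level motor-count summary for one virion type."""

    molecules: np.ndarray           # per-virion fluorophore counts
    complexes: np.ndarray           # molecules / 2
    mean_molecules: float
    sem_molecules: float
    mean_complexes: float
    sem_complexes: float
    correction_factor: float
    corrected_mean_complexes: int
    n_negative: int                 # virions with negative corrected intensity


def _as_standards(standards) -> list[tuple[float, np.ndarray]]:
    if isinstance(standards, pd.DataFrame):
        return [(float(cn), g["intensity"].to_numpy(dtype=float))
                for cn, g in standards.groupby("copy_number")]
    return [(float(cn), np.asarray(vals, dtype=float))
            for cn, vals in standards]


def fit_calibration(standards, per_spot: bool = False) -> CalibrationCurve:
    """Fit the through-origin calibration line to nanocage standards.

    Parameters
    ----------
    standards:
        Either a list of ``(copy_number, intensities)`` pairs or a
        DataFrame with columns ``copy_number, intensity``.
    per_spot:
        Fit pooled per-spot values instead of per-species means. The
        default fits the species means, matching how the standard curve is
        plotted.

    Returns
    -------
    CalibrationCurve with slope s minimising Σ(y − s·x)²:
    s = Σ x·y / Σ x².
    """
    groups = _as_standards(standards)
    if len({cn for cn, _ in groups}) < 2:
        raise CalibrationError(
            "calibration needs >= 2 distinct copy numbers (rank-deficient)")
    rows = []
    for cn, vals in groups:
        if cn <= 0:
            raise CalibrationError("copy numbers must be positive")
        if len(vals) == 0:
            raise CalibrationError(f"standard {cn} has no intensities")
        rows.append(dict(copy_number=cn, n_spots=len(vals),
                         mean_intensity=float(np.mean(vals)),
                         sd=float(np.std(vals, ddof=1)) if len(vals) > 1
                         else 0.0))
    species = pd.DataFrame(rows).sort_values("copy_number",
                                             ignore_index=True)
    if per_spot:
        x = np.concatenate([np.full(len(v), cn) for cn, v in groups])
        y = np.concatenate([v for _, v in groups])
    else:
        x = species["copy_number"].to_numpy()
        y = species["mean_intensity"].to_numpy()
    slope = float(np.sum(x * y) / np.sum(x * x))
    if slope <= 0:
        raise CalibrationError("fitted slope is non-positive; the standards "
                               "carry no signal")
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationCurve(species=species, slope=slope, r_squared=r2,
                            per_spot=per_spot)


def intensity_to_molecules(corrected_intensity, curve: CalibrationCurve):
    """Convert corrected intensities to fluorophore counts (intensity/slope).

    Negative intensities map to negative molecule counts — they are kept,
    not clipped, so that cohort means stay unbiased.
    """
    if curve.slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return np.asarray(corrected_intensity, dtype=float) / curve.slope \
        if np.ndim(corrected_intensity) else float(corrected_intensity) / curve.slope


def molecules_to_complexes(molecules):
    """Fluorophore-tagged heavy chains → motor complexes (exactly half)."""
    return np.asarray(molecules, dtype=float) / 2.0 \
        if np.ndim(molecules) else float(molecules) / 2.0


def expression_correction_factor(reference_intensities,
                                 tagged_line_intensities) -> float:
    """Fold-difference of cohort mean intensities, reference / tagged line.

    Compensates for reduced expression of the tagged motor: antibody
    staining of the untagged parental line is the reference.
    """
    ref = np.asarray(reference_intensities, dtype=float)
    tag = np.asarray(tagged_line_intensities, dtype=float)
    if ref.size == 0 or tag.size == 0:
        raise ValidationError("both cohorts must be non-empty")
    m = float(np.mean(tag))
    if m <= 0:
        raise ValidationError("tagged-line mean intensity must be > 0")
    return float(np.mean(ref)) / m


def corrected_mean_complexes(mean_complexes: float, fold: float) -> int:
    """Expression-corrected cohort mean, rounded to the nearest integer."""
    if fold <= 0:
        raise ValidationError("correction factor must be > 0")
    return int(round(mean_complexes * fold))


def summarize_motor_counts(
    corrected_intensities,
    curve: CalibrationCurve,
    correction_factor: float = 1.0,
    use_rounded_mean: bool = True,
) -> MotorCountResult:
    """Full cohort summary: molecules, complexes, corrected mean.

    ``use_rounded_mean`` applies the correction factor to the cohort mean
    complexes rounded to the nearest integer first (matching how such
    results are usually reported); set False to correct the unrounded mean.
    """
    intens = np.asarray(corrected_intensities, dtype=float)
    intens = intens[~np.isnan(intens)]
    mol = intensity_to_molecules(intens, curve)
    cpx = molecules_to_complexes(mol)
    n = len(mol)
    if n == 0:
        raise ValidationError("cohort is empty")
    sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    mean_cpx = float(np.mean(cpx))
    base = round(mean_cpx) if use_rounded_mean else mean_cpx
    return MotorCountResult(
        molecules=mol, complexes=cpx,
        mean_molecules=float(np.mean(mol)), sem_molecules=sem(mol),
        mean_complexes=mean_cpx, sem_complexes=sem(cpx),
        correction_factor=float(correction_factor),
        corrected_mean_complexes=corrected_mean_complexes(
            base, correction_factor),
        n_negative=int(np.sum(intens < 0)),
    )
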