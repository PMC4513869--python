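"""Nucleoside quantification and rRNA-contamination-corrected m6A/A ratios.

Bacterial mRNA preparations retain a residue of rRNA, and bacterial rRNA
itself carries two m6A residues, so a raw LC-MS/MS m6A/A ratio
overestimates the mRNA methylation level. rRNA also carries
N6,N6-dimethyladenosine (m62A, installed by KsgA) which is absent from
mRNA, so the measured m62A quantity traces the rRNA residue. Given the
rRNA-intrinsic ratio R = m62A/m6A (1.30 in wild-type E. coli; 2.04 in
rlmF or rlmJ mutants, each of which lacks one of the two rRNA m6A
sites), the rRNA-derived m6A equals m62A / R and the corrected mRNA
methylation level is

    m6A/A = (m6A_measured - m62A_measured / R) / A_measured

Negative corrected values (over-correction within noise) are clamped to
zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleosideMeasurement",
    "StandardCurve",
    "ReferenceRatio",
    "CorrectedRatio",
    "UndetectableM62AError",
    "WILD_TYPE_R",
    "SINGLE_MUTANT_R",
    "fit_standard_curve",
    "quantify",
    "reference_ratio",
    "corrected_ratio",
    "summarize_condition",
]

#: rRNA-intrinsic m62A/m6A ratio of the wild-type strain.
WILD_TYPE_R = 1.30
#: rRNA-intrinsic ratio when one of the two rRNA m6A writers (RlmF or
#: RlmJ) is deleted: half the m6A, same m62A.
SINGLE_MUTANT_R = 2.04


class UndetectableM62AError(ValueError):
    """Raised when m62A is zero (ksgA-like sample): R is undefined and the
    internal-reference correction cannot be anchored on this sample."""


@dataclass
class NucleosideMeasurement:
    """Per-replicate nucleoside quantities from one LC-MS/MS run.

    Quantities share one unit (e.g. fmol); the unit cancels in every
    ratio computed downstream.
    """

    sample_id: str
    replicate: int
    quantity_A: float
    quantity_m6A: float
    quantity_m62A: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.quantity_A <= 0:
            raise ValueError("quantity_A must be positive")
        if self.quantity_m6A < 0 or self.quantity_m62A < 0:
            raise ValueError("nucleoside quantities must be non-negative")


@dataclass
class StandardCurve:
    """Linear calibration signal = slope * amount + intercept."""

    nucleoside: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard curve slope must be positive")


@dataclass
class ReferenceRatio:
    """rRNA-intrinsic m62A/m6A ratio used as internal reference."""

    R: float
    source: str = "user"

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("reference ratio R must be positive")


@dataclass
class CorrectedRatio:
    """Contamination-corrected m6A/A level."""

    value: float
    sd: float = 0.0
    n_reps: int = 1
    clamped: bool = False


def fit_standard_curve(
    points: Sequence[tuple[float, float]], nucleoside: str = ""
) -> StandardCurve:
    """Ordinary-least-squares calibration line through (amount, signal) pairs.

    The intercept is retained (the line is not forced through the
    origin). Raises if fewer than two distinct amounts are given or the
    fitted slope is not positive.
    """
    if len(points) < 2:
        raise ValueError("standard curve needs at least 2 points")
    amounts = np.array([p[0] for p in points], dtype=float)
    signals = np.array([p[1] for p in points], dtype=float)
    if np.ptp(amounts) == 0:
        raise ValueError("standard curve needs at least 2 distinct amounts")
    slope, intercept = np.polyfit(amounts, signals, 1)
    return StandardCurve(nucleoside=nucleoside, slope=slope, intercept=intercept)


def quantify(signal: float, curve: StandardCurve) -> tuple[float, bool]:
    """Invert the calibration line: amount = (signal - intercept) / slope.

    Returns ``(amount, clamped)``; negative amounts are clamped to 0.
    """
    amount = (signal - curve.intercept) / curve.slope
    if amount < 0:
        return 0.0, True
    return amount, False


def reference_ratio(rrna_measurement: NucleosideMeasurement) -> ReferenceRatio:
    """m62A/m6A ratio of a purified-rRNA measurement.

    A zero m62A quantity (as in a ksgA deletion, which lacks the
    dimethyltransferase) leaves R undefined and raises
    :class:`UndetectableM62AError`.
    """
    if rrna_measurement.quantity_m6A <= 0:
        raise ValueError("rRNA m6A quantity must be positive to form R")
    if rrna_measurement.quantity_m62A == 0:
        raise UndetectableM62AError(
            "m62A undetectable in this sample; cannot serve as internal reference"
        )
    return ReferenceRatio(
        R=rrna_measurement.quantity_m62A / rrna_measurement.quantity_m6A,
        source=rrna_measurement.sample_id or "user",
    )


def corrected_ratio(
    meas: NucleosideMeasurement, ref: ReferenceRatio
) -> CorrectedRatio:
    """rRNA-corrected m6A/A level of one measurement.

    value = (m6A - m62A / R) / A, clamped at zero with a flag when the
    m62A-attributed m6A exceeds the measured m6A.
    """
    if meas.quantity_A <= 0:
        raise ValueError("quantity_A must be positive")
    value = (meas.quantity_m6A - meas.quantity_m62A / ref.R) / meas.quantity_A
    # at value <= 0 the entire m6A signal is attributable to the rRNA
    # residue: no mRNA methylation remains, which the flag records
    clamped = value <= 0 and meas.quantity_m62A > 0
    return CorrectedRatio(value=max(value, 0.0), clamped=clamped)


def summarize_condition(
    measurements: Iterable[NucleosideMeasurement], ref: ReferenceRatio
) -> pd.DataFrame:
    """Per-condition mean and sample SD (ddof=1) of corrected ratios.

    Returns a DataFrame with columns condition, mean, sd, n, ordered by
    condition label. SD is 0 for single-replicate conditions.
    """
    rows = []
    for m in measurements:
        rows.append(
            {"condition": m.condition, "value": corrected_ratio(m, ref).value}
        )
    if not rows:
        raise ValueError("no measurements to summarize")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("condition")["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
        .sort_values("condition", kind="stable")
        .reset_index(drop=True)
    )
    return out
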