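"""Cell-level quantifications: glycoform scoring, growth-curve doubling
time, immunoblot expression ratios, copies-per-cell calibration, nuclear
enrichment and group summaries.

The Glycoscore condenses a reporter glycoprotein's glycoform ladder (bands
carrying 4, 3, 2, 1 or 0 N-glycans) into a single 0-100 score: band
intensities are weighted by their glycan count, summed, and expressed as a
percentage of the fully glycosylated maximum,

    score = 100 * sum_n(n * I_n) / (4 * sum_n(I_n)).

Doubling time uses a fixed early-exponential absorbance window: the first
reading at or above A600 = 0.35 and the last reading at or below 0.5, with
Td = (t2 - t1) * log 2 / (log C2 - log C1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import Avogadro

from .errors import (
    CalibrationError,
    DomainError,
    InputError,
    NonGrowthError,
    WindowError,
)

#: Glycan counts of the ladder bands, in input column order glycans_4..glycans_0.
GLYCOFORM_WEIGHTS = (4, 3, 2, 1, 0)

GLYCOFORM_COLUMNS = ["glycans_4", "glycans_3", "glycans_2", "glycans_1", "glycans_0"]

DOUBLING_WINDOW = (0.35, 0.5)


@dataclass(frozen=True)
class GroupStats:
    """Descriptive statistics for one group: mean, sample SD (None when
    n < 2) and n."""

    mean: float
    sd: float | None
    n: int


@dataclass
class BandTable:
    """Lane-wise band intensities for a glycoform ladder.

    Wraps a DataFrame with columns ``sample, glycans_4..glycans_0`` and an
    optional ``loading_control`` column.  Band identity is declared by the
    column header, never inferred from gel position.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ["sample", *GLYCOFORM_COLUMNS] if c not in self.df.columns]
        if missing:
            raise InputError(f"band table is missing columns: {missing}")
        intensities = self.df[GLYCOFORM_COLUMNS].to_numpy(dtype=float)
        if np.any(intensities < 0):
            raise InputError("band intensities must be >= 0")
        if np.any(intensities.sum(axis=1) == 0):
            raise InputError("every lane needs at least one nonzero band")

    @classmethod
    def from_records(
        cls,
        lanes: Sequence[tuple[str, Sequence[float]]],
        loading_control: Sequence[float] | None = None,
    ) -> "BandTable":
        rows = [
            {"sample": label, **dict(zip(GLYCOFORM_COLUMNS, vals))}
            for label, vals in lanes
        ]
        df = pd.DataFrame(rows)
        if loading_control is not None:
            df["loading_control"] = list(loading_control)
        return cls(df)

    def scores(self) -> pd.Series:
        """Glycoscore per lane, indexed by sample label."""
        vals = self.df[GLYCOFORM_COLUMNS].apply(lambda row: glycoscore(row), axis=1)
        return pd.Series(vals.to_numpy(), index=self.df["sample"], name="glycoscore")


def glycoscore(intensities: Sequence[float]) -> float:
    """Glycoscore of one lane from intensities ordered (I4, I3, I2, I1, I0).

    Invariant under rescaling of the lane; 100 for a fully glycosylated
    lane, 0 for a fully deglycosylated one.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.shape != (5,):
        raise InputError("expected 5 intensities (glycans 4..0)")
    if np.any(arr < 0):
        raise InputError("intensities must be >= 0")
    total = arr.sum()
    if total == 0:
        raise InputError("all-zero lane")
    weighted = float(np.dot(GLYCOFORM_WEIGHTS, arr))
    return 100.0 * weighted / (4.0 * total)


def glycoscore_summary(lanes: Sequence[Sequence[float]]) -> GroupStats:
    """Mean +/- sample SD of Glycoscores over replicate lanes."""
    if len(lanes) < 1:
        raise InputError("at least one lane is required")
    scores = [glycoscore(lane) for lane in lanes]
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else None
    return GroupStats(mean=float(np.mean(scores)), sd=sd, n=len(scores))


@dataclass
class GrowthCurve:
    """Optical-density growth record, nominally sampled every 15 min."""

    time_min: np.ndarray
    a600: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a600 = np.asarray(self.a600, dtype=float)
        if self.time_min.shape != self.a600.shape or self.time_min.ndim != 1:
            raise InputError("time and A600 must be 1-D arrays of equal length")
        if self.time_min.size and not np.all(np.diff(self.time_min) > 0):
            raise InputError("time must be strictly increasing")


def doubling_time(
    curve: GrowthCurve, window: tuple[float, float] = DOUBLING_WINDOW
) -> float:
    """Culture doubling time in minutes from the early-exponential window.

    ``t1`` is the first reading with A600 >= window[0] and ``t2`` the last
    reading with A600 <= window[1] after ``t1``; then
    ``Td = (t2 - t1) * log 2 / (log C2 - log C1)``.  The absolute window
    bounds deliberately tie the rule to the instrument's A600 scale, so a
    rescaled curve fails with a window error instead of silently shifting
    the measured phase.
    """
    lo, hi = window
    t, a = curve.time_min, curve.a600
    above = np.nonzero(a >= lo)[0]
    if above.size == 0:
        raise WindowError(
            f"no reading reaches A600 >= {lo}; curve {curve.label!r} has no window"
        )
    i1 = above[0]
    candidates = np.nonzero((a <= hi) & (t > t[i1]))[0]
    if candidates.size == 0:
        raise WindowError(
            f"no reading with A600 <= {hi} after t = {t[i1]:g} min in {curve.label!r}"
        )
    i2 = candidates[-1]
    c1, c2 = a[i1], a[i2]
    if c2 <= c1:
        raise NonGrowthError(
            f"culture {curve.label!r} did not grow across the window "
            f"(C1 = {c1:g}, C2 = {c2:g})"
        )
    return float((t[i2] - t[i1]) * np.log(2.0) / (np.log(c2) - np.log(c1)))


def expression_level(
    sample_band: float,
    control_band: float,
    reference_band: float,
    reference_control: float,
) -> float:
    """Loading-control-normalized expression relative to a reference lane:
    ``(sample/control) / (reference/reference_control)``."""
    if control_band <= 0 or reference_control <= 0:
        raise InputError("loading-control intensities must be > 0")
    if reference_band <= 0:
        raise InputError("reference band intensity must be > 0")
    if sample_band < 0:
        raise InputError("sample band intensity must be >= 0")
    return (sample_band / control_band) / (reference_band / reference_control)


@dataclass
class CalibrationSeries:
    """Standard series for quantitative immunoblotting: known protein
    amounts (ng) versus band intensities, plus the cell count loaded in the
    sample lane and the protein's molar mass (g/mol)."""

    standard_amounts_ng: np.ndarray
    intensities: np.ndarray
    lane_cells: float
    protein_molar_mass_g_mol: float

    def __post_init__(self) -> None:
        self.standard_amounts_ng = np.asarray(self.standard_amounts_ng, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.standard_amounts_ng.shape != self.intensities.shape:
            raise InputError("amounts and intensities must have equal length")
        if self.standard_amounts_ng.size < 3:
            raise InputError("need at least 3 calibration standards")
        if np.any(self.standard_amounts_ng <= 0):
            raise InputError("standard amounts must be > 0")
        if self.lane_cells <= 0 or self.protein_molar_mass_g_mol <= 0:
            raise InputError("lane_cells and protein molar mass must be > 0")


@dataclass(frozen=True)
class CalibrationResult:
    """Copies-per-cell estimate with the fitted standard line and an
    extrapolation flag."""

    copies_per_cell: float
    amount_ng: float
    slope: float
    intercept: float
    extrapolated: bool


def copies_from_calibration(
    calib: CalibrationSeries, lane_intensity: float
) -> CalibrationResult:
    """Copies per cell of a tagged protein from a standard curve.

    Fits an ordinary least-squares line with intercept (blot background)
    through (amount, intensity), inverts it for the sample lane, and
    converts mass to copies via the protein molar mass, Avogadro's number
    and the number of cells loaded.  Lane intensities outside [0.5x, 2x]
    of the standard intensity range are flagged as extrapolated.
    """
    res = stats.linregress(calib.standard_amounts_ng, calib.intensities)
    if res.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope ({res.slope:.3g})")
    lo, hi = calib.intensities.min(), calib.intensities.max()
    extrapolated = not (0.5 * lo <= lane_intensity <= 2.0 * hi)
    if extrapolated:
        warnings.warn(
            f"lane intensity {lane_intensity:.3g} outside [0.5x, 2x] of the "
            "standard range; extrapolating",
            stacklevel=2,
        )
    amount_ng = (lane_intensity - res.intercept) / res.slope
    if amount_ng < 0:
        warnings.warn(
            "fitted amount is negative (intensity below blot background); "
            "clamping to 0",
            stacklevel=2,
        )
        amount_ng = 0.0
    copies = (
        amount_ng * 1e-9 / calib.protein_molar_mass_g_mol * Avogadro / calib.lane_cells
    )
    return CalibrationResult(
        copies_per_cell=copies,
        amount_ng=amount_ng,
        slope=float(res.slope),
        intercept=float(res.intercept),
        extrapolated=extrapolated,
    )


def nuclear_enrichment_ratio(
    f_nuc: float, f_total: float, noise_tolerance: float = 0.05
) -> float:
    """Fraction of a cell's background-corrected fluorescence found in the
    nucleus, F_nuc / F_total, clamped to [0, 1].

    Background correction pushes sums slightly out of range in noisy
    images; violations within ``noise_tolerance`` (relative to F_total) are
    clamped with a warning, larger ones raise.
    """
    if f_total <= 0:
        raise InputError("f_total must be > 0")
    ratio = f_nuc / f_total
    if ratio < 0 or ratio > 1:
        if -noise_tolerance <= ratio <= 1 + noise_tolerance:
            clamped = min(max(ratio, 0.0), 1.0)
            warnings.warn(
                f"F_nuc/F_total = {ratio:.3g} outside [0, 1]; clamped "
                "(background-correction noise)",
                stacklevel=2,
            )
            return clamped
        raise DomainError(f"F_nuc/F_total = {ratio:.3g} is out of range beyond noise")
    return ratio


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics per group plus one-way ANOVA results."""

    stats: dict[str, GroupStats]
    anova_p: float | None
    p_vs_reference: dict[str, float] = field(default_factory=dict)
    reference: str | None = None


def summarize_groups(
    values_by_group: Mapping[str, Sequence[float]],
    reference: str | None = None,
) -> GroupSummary:
    """Per-group mean, sample SD and n, with one-way ANOVA.

    The overall ANOVA spans all groups with >= 2 values.  When a
    ``reference`` group is named, each other group is additionally compared
    with it by pairwise one-way ANOVA (only where both have >= 2 values).
    Tests are skipped, not failed, when sample sizes do not permit them.
    """
    if len(values_by_group) < 1:
        raise InputError("at least one group is required")
    per_group: dict[str, GroupStats] = {}
    for name, vals in values_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 1:
            raise InputError(f"group {name!r} is empty")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else None
        per_group[name] = GroupStats(mean=float(v.mean()), sd=sd, n=int(v.size))

    testable = {k: list(v) for k, v in values_by_group.items() if len(list(v)) >= 2}
    anova_p: float | None = None
    if len(testable) >= 2:
        f = stats.f_oneway(*testable.values())
        anova_p = float(f.pvalue) if np.isfinite(f.pvalue) else None

    p_vs_ref: dict[str, float] = {}
    if reference is not None:
        if reference not in values_by_group:
            raise InputError(f"reference group {reference!r} not present")
        ref_vals = list(values_by_group[reference])
        if len(ref_vals) >= 2:
            for name, vals in testable.items():
                if name == reference:
                    continue
                f = stats.f_oneway(ref_vals, vals)
                if np.isfinite(f.pvalue):
                    p_vs_ref[name] = float(f.pvalue)
    return GroupSummary(
        stats=per_group, anova_p=anova_p, p_vs_reference=p_vs_ref, reference=reference
    )
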