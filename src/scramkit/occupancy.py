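"""Vesicle occupancy and scramblase abundance mathematics.

Reconstituting a detergent extract of ER membrane proteins into large
unilamellar vesicles distributes protein copies over vesicles essentially at
random, so the number of scramblases per vesicle is modelled as Poisson with
mean ``m``.  A vesicle with at least one scramblase equilibrates reporter
lipid between leaflets and is fully exposed to an outer-leaflet-only probe
(dithionite bleaching of NBD-PC, or Con A capture of a glycolipid); a vesicle
with none behaves like the protein-free control.  The population readout is
therefore a two-component mixture, and the scramblase-positive fraction ``f``
follows from the measured proteoliposome signal and the protein-free
baseline:

    f = (S_PL - S_L) / (1 - S_L)

where ``S`` is the bleached (or captured) fraction.  The Poisson link
``f = 1 - exp(-m)`` then converts between the positive fraction and the mean
copy number, and simple geometry plus the protein/phospholipid ratio of the
reconstitution converts the copy number into a weight fraction of total
membrane protein and into copies per cell.

The protein-free control is used as the *empirical* baseline: ideal symmetric
vesicles would bleach exactly 50%, but real preparations typically bleach
somewhat more, and the mixture formula takes the measured control rather than
the ideal value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import (
    DegenerateBaselineError,
    DomainError,
    InconsistentInputsError,
    InfiniteOccupancyError,
)

#: Cross-sectional area of a phospholipid in a fluid bilayer (nm^2).
AREA_PER_LIPID_NM2 = 0.71

#: Mean molar mass of egg phosphatidylcholine (g/mol).
EGG_PC_MOLAR_MASS_G_MOL = 770.0

#: Average molar mass assumed for an ER membrane protein (Da).
AVG_PROTEIN_MASS_DA = 50_000.0

#: Approximate number of ER membrane protein molecules in a haploid yeast cell.
TOTAL_ER_MEMBRANE_PROTEINS = 2.0e6

#: Typical diameter of extruder-free, detergent-removal LUVs (nm), as
#: measured by dynamic light scattering for egg-PC reconstitutions.
DEFAULT_VESICLE_DIAMETER_NM = 175.0


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be a fraction in [0, 1], got {value!r}")
    return value


def _clamp_fraction(value: float, context: str) -> float:
    if value < 0.0 or value > 1.0:
        clamped = min(max(value, 0.0), 1.0)
        warnings.warn(
            f"{context}: fraction {value:.4g} outside [0, 1]; clamped to "
            f"{clamped:.4g} (attributed to measurement noise)",
            stacklevel=3,
        )
        return clamped
    return value


@dataclass(frozen=True)
class VesiclePrep:
    """Description of a one-pot reconstitution, sufficient to compute the
    protein/phospholipid ratio and vesicle geometry.

    Volumes are in ml, masses in mg, the lipid molar mass in g/mol, the
    vesicle diameter in nm and the lipid cross-section in nm^2.  The lipid
    mix is prepared at ``lipid_mass_total_mg`` in ``lipid_mix_volume_ml`` and
    distributed into aliquots of ``aliquot_volume_ml``, each of which
    receives ``protein_volume_ml`` of extract at ``protein_conc_mg_ml``.
    """

    protein_volume_ml: float
    protein_conc_mg_ml: float
    lipid_mass_total_mg: float
    lipid_mix_volume_ml: float
    aliquot_volume_ml: float
    lipid_molar_mass_g_mol: float = EGG_PC_MOLAR_MASS_G_MOL
    vesicle_diameter_nm: float = DEFAULT_VESICLE_DIAMETER_NM
    area_per_lipid_nm2: float = AREA_PER_LIPID_NM2

    def __post_init__(self) -> None:
        if self.protein_volume_ml < 0:
            raise DomainError("protein_volume_ml must be >= 0")
        if self.protein_conc_mg_ml < 0:
            raise DomainError("protein_conc_mg_ml must be >= 0")
        for name in (
            "lipid_mass_total_mg",
            "lipid_mix_volume_ml",
            "aliquot_volume_ml",
            "lipid_molar_mass_g_mol",
            "vesicle_diameter_nm",
            "area_per_lipid_nm2",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.aliquot_volume_ml > self.lipid_mix_volume_ml:
            raise DomainError("aliquot_volume_ml cannot exceed lipid_mix_volume_ml")


@dataclass(frozen=True)
class OccupancyEstimate:
    """Scramblase-positive vesicle fraction and the matching Poisson mean.

    ``f_positive`` and ``m_mean`` are linked by ``f = 1 - exp(-m)``;
    construction enforces the link.  ``baseline_source`` records which
    protein-free control defined the baseline.
    """

    f_positive: float
    m_mean: float
    baseline_source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_positive < 1.0:
            raise DomainError("f_positive must lie in [0, 1)")
        if self.m_mean < 0:
            raise DomainError("m_mean must be >= 0")
        if abs(self.f_positive - fraction_from_poisson_mean(self.m_mean)) > 1e-9:
            raise InconsistentInputsError(
                "f_positive and m_mean violate f = 1 - exp(-m)"
            )

    @classmethod
    def from_fraction(cls, f: float, baseline_source: str = "") -> "OccupancyEstimate":
        return cls(f, poisson_mean_from_fraction(f), baseline_source)

    @classmethod
    def from_mean(cls, m: float, baseline_source: str = "") -> "OccupancyEstimate":
        return cls(fraction_from_poisson_mean(m), m, baseline_source)


@dataclass(frozen=True)
class AbundanceEstimate:
    """Scramblase abundance derived from occupancy plus prep geometry:
    weight fraction of total membrane protein and inferred copies per cell."""

    lipids_per_vesicle: float
    ppr_mg_per_mmol: float
    weight_fraction: float
    copies_per_cell: float
    assumed_scramblase_mass_da: float
    assumed_total_proteins: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_fraction <= 1.0:
            raise DomainError("weight_fraction must lie in [0, 1]")


def scramblase_positive_fraction(delta_f_proteo: float, delta_f_lipo: float) -> float:
    """Fraction of vesicles containing at least one scramblase, from
    dithionite bleach fractions.

    Scramblase-positive vesicles lose all probe fluorescence while negative
    vesicles bleach like the protein-free control, so

        f = (dF_PL - dF_L) / (1 - dF_L).

    Noise-driven negative excess bleaching is clamped to 0 with a warning.

    Parameters
    ----------
    delta_f_proteo : bleached fraction of the proteoliposome sample.
    delta_f_lipo : bleached fraction of the protein-free control.
    """
    dfp = _check_fraction("delta_f_proteo", delta_f_proteo)
    dfl = _check_fraction("delta_f_lipo", delta_f_lipo)
    if dfl == 1.0:
        raise DegenerateBaselineError(
            "protein-free control bleaches 100%; positive fraction undefined"
        )
    f = (dfp - dfl) / (1.0 - dfl)
    return _clamp_fraction(f, "scramblase_positive_fraction")


def capture_positive_fraction(capture_proteo: float, capture_lipo: float = 0.5) -> float:
    """Fraction of vesicles with glycolipid scramblase activity, from lectin
    capture fractions.

    Identical mixture logic to :func:`scramblase_positive_fraction`: positive
    vesicles expose their entire glycolipid pool to the lectin, negative ones
    behave like the protein-free control (ideally 50% captured, outer leaflet
    only).
    """
    cp = _check_fraction("capture_proteo", capture_proteo)
    cl = _check_fraction("capture_lipo", capture_lipo)
    if cl == 1.0:
        raise DegenerateBaselineError(
            "protein-free control captures 100%; positive fraction undefined"
        )
    f = (cp - cl) / (1.0 - cl)
    return _clamp_fraction(f, "capture_positive_fraction")


def predicted_capture_fraction(f: float, baseline: float = 0.5) -> float:
    """Forward model for the capture assay: expected captured fraction of a
    population in which a fraction ``f`` of vesicles is scramblase-positive.

    With a symmetric transbilayer glycolipid distribution and only the outer
    leaflet accessible, the protein-free prediction is ``baseline`` = 0.5;
    positive vesicles are fully captured, so the mixture captures
    ``baseline + (1 - baseline) * f``.
    """
    f = _check_fraction("f", f)
    b = _check_fraction("baseline", baseline)
    return b + (1.0 - b) * f


def poisson_mean_from_fraction(f: float) -> float:
    """Mean scramblase copies per vesicle implied by a positive fraction:
    ``m = -ln(1 - f)``."""
    f = float(f)
    if f < 0 or not math.isfinite(f):
        raise DomainError(f"f must lie in [0, 1), got {f!r}")
    if f >= 1.0:
        raise InfiniteOccupancyError(
            "a positive fraction of 1 implies infinite mean occupancy"
        )
    return -math.log1p(-f)


def fraction_from_poisson_mean(m: float) -> float:
    """Fraction of vesicles with >= 1 copy under Poisson occupancy:
    ``f = 1 - exp(-m)`` (strictly below 1 for finite ``m``)."""
    m = float(m)
    if m < 0 or not math.isfinite(m):
        raise DomainError(f"m must be a finite non-negative mean, got {m!r}")
    return -math.expm1(-m)


def lipids_per_vesicle(
    diameter_nm: float = DEFAULT_VESICLE_DIAMETER_NM,
    area_per_lipid_nm2: float = AREA_PER_LIPID_NM2,
) -> float:
    """Phospholipid molecules per unilamellar vesicle from its diameter.

    Both leaflets are approximated at the outer radius (thin-shell
    approximation, adequate at back-of-envelope precision):
    ``N = 2 * 4 pi (d/2)^2 / a``.
    """
    d = float(diameter_nm)
    a = float(area_per_lipid_nm2)
    if d <= 0 or a <= 0:
        raise DomainError("diameter and area per lipid must be > 0")
    return 8.0 * math.pi * (d / 2.0) ** 2 / a


def ppr_from_prep(prep: VesiclePrep) -> float:
    """Protein/phospholipid ratio of a reconstitution in mg protein per mmol
    lipid (numerically equal to g protein per mol lipid).

    Protein mass is ``protein_volume * protein_conc``; the lipid amount in
    one aliquot is the aliquot's share of the total lipid divided by the
    lipid molar mass.
    """
    protein_mg = prep.protein_volume_ml * prep.protein_conc_mg_ml
    lipid_mg = prep.lipid_mass_total_mg * prep.aliquot_volume_ml / prep.lipid_mix_volume_ml
    lipid_mmol = lipid_mg / prep.lipid_molar_mass_g_mol
    return protein_mg / lipid_mmol


def scramblase_weight_fraction(
    m_mean: float,
    lipids_per_vesicle_count: float,
    ppr_mg_per_mmol: float,
    scramblase_mass_da: float = AVG_PROTEIN_MASS_DA,
) -> float:
    """Weight fraction of total membrane protein contributed by the
    scramblase.

    Per vesicle there are ``m_mean`` scramblases of mass ``scramblase_mass``
    among ``lipids_per_vesicle * PPR`` (g protein per mol lipid times mol
    lipid) of total protein:

        w = m * M_scr / (N_lipid * PPR)

    with PPR read as g/mol so the ratio is dimensionless.
    """
    if m_mean < 0:
        raise DomainError("m_mean must be >= 0")
    if lipids_per_vesicle_count <= 0 or ppr_mg_per_mmol <= 0 or scramblase_mass_da <= 0:
        raise DomainError("lipids per vesicle, PPR and scramblase mass must be > 0")
    w = m_mean * scramblase_mass_da / (lipids_per_vesicle_count * ppr_mg_per_mmol)
    if w > 1.0:
        raise InconsistentInputsError(
            f"weight fraction {w:.3g} exceeds 1; inputs are inconsistent"
        )
    return w


def copies_per_cell(
    weight_fraction: float,
    total_membrane_proteins: float = TOTAL_ER_MEMBRANE_PROTEINS,
    mass_ratio: float = 1.0,
) -> float:
    """Scramblase copies per cell from its weight fraction of membrane
    protein.

    ``mass_ratio`` is the scramblase mass divided by the average membrane
    protein mass; a heavier scramblase means fewer copies at the same weight
    fraction: ``copies = w * N_total / mass_ratio``.
    """
    w = _check_fraction("weight_fraction", weight_fraction)
    if total_membrane_proteins <= 0:
        raise DomainError("total_membrane_proteins must be > 0")
    if mass_ratio <= 0:
        raise DomainError("mass_ratio must be > 0")
    return w * total_membrane_proteins / mass_ratio


def estimate_abundance(
    m_mean: float,
    prep: VesiclePrep | None = None,
    *,
    ppr_mg_per_mmol: float | None = None,
    diameter_nm: float | None = None,
    area_per_lipid_nm2: float | None = None,
    scramblase_mass_da: float = AVG_PROTEIN_MASS_DA,
    total_membrane_proteins: float = TOTAL_ER_MEMBRANE_PROTEINS,
    mass_ratio: float = 1.0,
) -> AbundanceEstimate:
    """Convenience chain from mean occupancy to an :class:`AbundanceEstimate`.

    Geometry and PPR come from ``prep`` unless overridden explicitly.
    """
    if prep is not None:
        ppr = ppr_from_prep(prep) if ppr_mg_per_mmol is None else ppr_mg_per_mmol
        d = prep.vesicle_diameter_nm if diameter_nm is None else diameter_nm
        a = prep.area_per_lipid_nm2 if area_per_lipid_nm2 is None else area_per_lipid_nm2
    else:
        if ppr_mg_per_mmol is None:
            raise DomainError("either prep or ppr_mg_per_mmol is required")
        ppr = ppr_mg_per_mmol
        d = DEFAULT_VESICLE_DIAMETER_NM if diameter_nm is None else diameter_nm
        a = AREA_PER_LIPID_NM2 if area_per_lipid_nm2 is None else area_per_lipid_nm2
    n_lipids = lipids_per_vesicle(d, a)
    w = scramblase_weight_fraction(m_mean, n_lipids, ppr, scramblase_mass_da)
    copies = copies_per_cell(w, total_membrane_proteins, mass_ratio)
    return AbundanceEstimate(
        lipids_per_vesicle=n_lipids,
        ppr_mg_per_mmol=ppr,
        weight_fraction=w,
        copies_per_cell=copies,
        assumed_scramblase_mass_da=scramblase_mass_da,
        assumed_total_proteins=total_membrane_proteins,
    )
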