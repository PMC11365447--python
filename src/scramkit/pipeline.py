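"""End-to-end occupancy analysis chain and the consolidated report.

The chain mirrors the full reconstitution workflow: fit (or accept) bleach
fractions for the protein-free control and the proteoliposome sample,
convert the excess bleaching into a scramblase-positive vesicle fraction,
apply the Poisson link to get mean copies per vesicle, combine with vesicle
geometry and the protein/phospholipid ratio of the prep to get the
scramblase's weight fraction of total membrane protein, and scale by the
cellular membrane-protein count to get copies per cell.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Any, Sequence

from . import occupancy
from .errors import ConfigurationError
from .io import _jsonable
from .traces import CaptureAssayData, FluorescenceTrace, capture_fraction, fit_dithionite_trace

SCHEMA_VERSION = 1

try:
    _PKG_VERSION = version("scramkit")
except PackageNotFoundError:  # pragma: no cover - not installed
    _PKG_VERSION = "unknown"


@dataclass
class AnalysisReport:
    """Consolidated, serializable result record.

    ``results`` maps a result name to a record carrying ``value``,
    ``units`` and the ``operation`` that produced it, so every number in
    the report is traceable.
    """

    results: dict[str, dict[str, Any]] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION
    package_version: str = _PKG_VERSION

    def add(self, name: str, value: Any, units: str, operation: str) -> None:
        self.results[name] = {"value": value, "units": units, "operation": operation}

    def value(self, name: str) -> Any:
        return self.results[name]["value"]

    def to_dict(self) -> dict[str, Any]:
        return _jsonable(
            {
                "schema_version": self.schema_version,
                "package_version": self.package_version,
                "seed": self.seed,
                "config": self.config,
                "warnings": self.warnings,
                "results": self.results,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        payload = json.loads(text)
        return cls(
            results=payload["results"],
            config=payload.get("config", {}),
            warnings=payload.get("warnings", []),
            seed=payload.get("seed"),
            schema_version=payload.get("schema_version", SCHEMA_VERSION),
            package_version=payload.get("package_version", "unknown"),
        )


def run_occupancy_chain(
    *,
    delta_f_proteo: float | None = None,
    delta_f_lipo: float | None = None,
    proteo_trace: FluorescenceTrace | None = None,
    lipo_trace: FluorescenceTrace | None = None,
    capture_proteo: float | None = None,
    capture_lipo: float = 0.5,
    capture_data: Sequence[CaptureAssayData] | None = None,
    prep: occupancy.VesiclePrep | None = None,
    ppr_mg_per_mmol: float | None = None,
    vesicle_diameter_nm: float = occupancy.DEFAULT_VESICLE_DIAMETER_NM,
    area_per_lipid_nm2: float = occupancy.AREA_PER_LIPID_NM2,
    scramblase_mass_da: float = occupancy.AVG_PROTEIN_MASS_DA,
    weight_fraction: float | None = None,
    total_membrane_proteins: float = occupancy.TOTAL_ER_MEMBRANE_PROTEINS,
    mass_ratio: float = 1.0,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full occupancy/abundance chain and return an
    :class:`AnalysisReport`.

    Bleach fractions may be given directly (``delta_f_*``) or as traces to
    fit.  A protein-free baseline (``delta_f_lipo`` or ``lipo_trace``) is
    mandatory.  The capture branch is optional.  ``weight_fraction``, when
    given, overrides the geometric computation (used when occupancy and
    PPR come from a different experiment than the prep at hand); otherwise
    the weight fraction is computed from the mean occupancy (capture-based
    when available, else bleach-based), vesicle geometry and PPR.
    """
    report = AnalysisReport(seed=seed)
    report.config = {
        "capture_lipo": capture_lipo,
        "vesicle_diameter_nm": vesicle_diameter_nm,
        "area_per_lipid_nm2": area_per_lipid_nm2,
        "scramblase_mass_da": scramblase_mass_da,
        "total_membrane_proteins": total_membrane_proteins,
        "mass_ratio": mass_ratio,
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if lipo_trace is not None:
            fit = fit_dithionite_trace(lipo_trace)
            delta_f_lipo = fit.delta_f
            report.add(
                "delta_f_lipo", delta_f_lipo, "fraction of F_max", "fit_dithionite_trace"
            )
        elif delta_f_lipo is not None:
            report.add("delta_f_lipo", delta_f_lipo, "fraction of F_max", "input")
        else:
            raise ConfigurationError(
                "a protein-free baseline (delta_f_lipo or lipo_trace) is required"
            )

        if proteo_trace is not None:
            fit = fit_dithionite_trace(proteo_trace)
            delta_f_proteo = fit.delta_f
            report.add(
                "delta_f_proteo", delta_f_proteo, "fraction of F_max", "fit_dithionite_trace"
            )
        elif delta_f_proteo is not None:
            report.add("delta_f_proteo", delta_f_proteo, "fraction of F_max", "input")
        else:
            warnings.warn("no proteoliposome input; reporting zero scramblase occupancy")
            delta_f_proteo = delta_f_lipo

        f_nbd = occupancy.scramblase_positive_fraction(delta_f_proteo, delta_f_lipo)
        m_nbd = occupancy.poisson_mean_from_fraction(f_nbd) if f_nbd < 1 else None
        report.add("f_nbd", f_nbd, "fraction of vesicles", "scramblase_positive_fraction")
        if m_nbd is not None:
            report.add("m_nbd", m_nbd, "copies per vesicle", "poisson_mean_from_fraction")

        f_capture = m_capture = None
        if capture_data is not None:
            summary = capture_fraction(capture_data)
            capture_proteo = summary.mean
            report.add(
                "capture_proteo", capture_proteo, "fraction captured", "capture_fraction"
            )
        elif capture_proteo is not None:
            report.add("capture_proteo", capture_proteo, "fraction captured", "input")
        if capture_proteo is not None:
            f_capture = occupancy.capture_positive_fraction(capture_proteo, capture_lipo)
            report.add(
                "f_capture", f_capture, "fraction of vesicles", "capture_positive_fraction"
            )
            if f_capture < 1:
                m_capture = occupancy.poisson_mean_from_fraction(f_capture)
                report.add(
                    "m_capture", m_capture, "copies per vesicle", "poisson_mean_from_fraction"
                )

        ppr = None
        if prep is not None:
            ppr = occupancy.ppr_from_prep(prep)
            vesicle_diameter_nm = prep.vesicle_diameter_nm
            area_per_lipid_nm2 = prep.area_per_lipid_nm2
        elif ppr_mg_per_mmol is not None:
            ppr = ppr_mg_per_mmol
        if ppr is not None:
            report.add("ppr", ppr, "mg protein / mmol lipid", "ppr_from_prep")

        n_lipids = occupancy.lipids_per_vesicle(vesicle_diameter_nm, area_per_lipid_nm2)
        report.add("lipids_per_vesicle", n_lipids, "lipids", "lipids_per_vesicle")

        w = weight_fraction
        w_source = "input"
        if w is None and ppr is not None:
            m_for_w = m_capture if m_capture is not None else m_nbd
            if m_for_w is not None:
                w = occupancy.scramblase_weight_fraction(
                    m_for_w, n_lipids, ppr, scramblase_mass_da
                )
                w_source = "scramblase_weight_fraction"
        if w is not None:
            report.add("weight_fraction", w, "fraction by weight", w_source)
            copies = occupancy.copies_per_cell(w, total_membrane_proteins, mass_ratio)
            report.add("copies_per_cell", copies, "copies", "copies_per_cell")

        report.warnings = [str(w.message) for w in caught]
    return report
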