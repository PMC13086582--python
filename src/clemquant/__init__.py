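"""Quantification of membrane-compartment fluorescence densities from
correlated fluorescence / electron-microscopy contour models.

The pipeline goes: classified 3D membrane contour models -> projected
class outlines -> blurred class masks -> overlap-aware intensity
assignment -> per-compartment densities and relative enrichments.
Validation utilities (line-profile FWHM, serial-section Pearson) and a
synthetic scene generator make every stage testable without real data.
"""

from clemquant.model_geometry import (
    CompartmentClass,
    ContourModel,
    ContourObject,
    DomainMeasure,
    compute_domain_measure,
    project_outlines,
    read_contour_model,
    write_contour_model,
)
from clemquant.mask_builder import ClassMaskPartition, MaskConfig, build_class_masks, partition_masks
from clemquant.intensity_assignment import (
    AssignConfig,
    ChannelImage,
    IntensityTable,
    assign_intensities,
    estimate_background,
    fit_value_pdf,
)
from clemquant.density_metrics import (
    ConditionComparison,
    DensityResult,
    compare_conditions,
    compute_densities,
    max_fold_enrichment,
)
from clemquant.validation_metrics import (
    FwhmResult,
    LineProfile,
    estimate_fwhm,
    extract_line_profile,
    serial_section_pearson,
)
from clemquant.io_cli import RegistrationTransform, fit_landmark_affine, correlation_error_map

__version__ = "0.1.0"

__all__ = [
    "CompartmentClass",
    "ContourModel",
    "ContourObject",
    "DomainMeasure",
    "compute_domain_measure",
    "project_outlines",
    "read_contour_model",
    "write_contour_model",
    "ClassMaskPartition",
    "MaskConfig",
    "build_class_masks",
    "partition_masks",
    "AssignConfig",
    "ChannelImage",
    "IntensityTable",
    "assign_intensities",
    "estimate_background",
    "fit_value_pdf",
    "ConditionComparison",
    "DensityResult",
    "compare_conditions",
    "compute_densities",
    "max_fold_enrichment",
    "FwhmResult",
    "LineProfile",
    "estimate_fwhm",
    "extract_line_profile",
    "serial_section_pearson",
    "RegistrationTransform",
    "fit_landmark_affine",
    "correlation_error_map",
]
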