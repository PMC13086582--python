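"""Densities, relative densities, enrichment bounds and cross-condition
statistics.

For each compartment class ``d`` and channel ``k``::

    density        D_dk = I_dk / A_d
    relative       R_dk = D_dk / (I_k_total / A_total)
    max fold bound M_d  = A_total / A_d

where ``I`` are assigned intensities and ``A`` the per-class membrane
measures (surface area in ``area3d`` mode, outline length in
``length2d``).  ``R`` is bounded above by ``M`` and its area-weighted
mean over classes is exactly one per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clemquant.errors import AnalysisError, ValidationError
from clemquant.intensity_assignment import IntensityTable
from clemquant.model_geometry import CompartmentClass, DomainMeasure

_BOUND_ATOL = 1e-9
_WEIGHTED_MEAN_RTOL = 1e-6


@dataclass
class DensityResult:
    """Per-compartment densities and enrichments for one endosome."""

    endosome_id: str
    mode: str
    areas: dict[CompartmentClass, float]
    densities: dict[tuple[CompartmentClass, str], float]
    relative_densities: dict[tuple[CompartmentClass, str], float]
    max_fold: dict[CompartmentClass, float]

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def channels(self) -> list[str]:
        return sorted({k[1] for k in self.densities})

    @property
    def classes(self) -> list[CompartmentClass]:
        return sorted(self.areas, key=lambda c: c.value)

    def relative_density(self, label: CompartmentClass, channel: str) -> float:
        return self.relative_densities[(label, channel)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "endosome_id": self.endosome_id,
                "mode": self.mode,
                "class": label.value,
                "channel": channel,
                "area": self.areas[label],
                "density": self.densities[(label, channel)],
                "relative_density": value,
                "max_fold_enrichment": self.max_fold[label],
            }
            for (label, channel), value in sorted(
                self.relative_densities.items(), key=lambda kv: (kv[0][1], kv[0][0].value)
            )
        ]
        return pd.DataFrame(rows)


def max_fold_enrichment(measures: DomainMeasure) -> dict[CompartmentClass, float]:
    """Upper bound on relative density per class: total measure over the
    class measure.  Equals 1 only for a single-class model."""
    total = measures.total
    out = {}
    for label, area in measures.per_class.items():
        if area <= 0:
            raise AnalysisError(f"zero measure for class {label.value}")
        out[label] = total / area
    return out


def compute_densities(
    intensities: IntensityTable,
    measures: DomainMeasure,
    endosome_id: str | None = None,
) -> DensityResult:
    """Combine assigned intensities with domain measures into densities,
    relative densities and enrichment bounds; all invariants are asserted
    before returning."""
    classes = set(measures.per_class)
    if classes != set(intensities.classes):
        raise ValidationError(
            f"class mismatch: measures have {sorted(c.value for c in classes)}, "
            f"intensities have {sorted(c.value for c in intensities.classes)}"
        )
    bounds = max_fold_enrichment(measures)
    total_area = measures.total

    densities: dict[tuple[CompartmentClass, str], float] = {}
    relative: dict[tuple[CompartmentClass, str], float] = {}
    for channel in intensities.channels:
        i_total = sum(intensities.intensity(c, channel) for c in classes)
        mean_density = i_total / total_area
        for label in classes:
            d = intensities.intensity(label, channel) / measures.per_class[label]
            densities[(label, channel)] = d
            if mean_density > 0:
                r = d / mean_density
            else:
                warnings.warn(
                    f"channel {channel}: zero total intensity; "
                    "relative densities undefined",
                    stacklevel=2,
                )
                r = float("nan")
            relative[(label, channel)] = r

        values = [relative[(c, channel)] for c in classes]
        if np.all(np.isfinite(values)):
            for label in classes:
                if relative[(label, channel)] > bounds[label] + _BOUND_ATOL:
                    raise AnalysisError(
                        f"relative density {relative[(label, channel)]} exceeds the "
                        f"bound {bounds[label]} for {label.value}/{channel}"
                    )
            weighted = sum(
                measures.per_class[c] / total_area * relative[(c, channel)]
                for c in classes
            )
            if abs(weighted - 1.0) > _WEIGHTED_MEAN_RTOL:
                raise AnalysisError(
                    f"channel {channel}: area-weighted mean relative density "
                    f"{weighted} != 1"
                )

    return DensityResult(
        endosome_id=endosome_id or intensities.endosome_id,
        mode=measures.mode,
        areas=dict(measures.per_class),
        densities=densities,
        relative_densities=relative,
        max_fold=bounds,
    )


@dataclass
class ConditionComparison:
    """Two-condition comparison of per-endosome relative densities."""

    label: CompartmentClass
    channel: str
    mean_a: float
    mean_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def _mean_ci_sem(values: np.ndarray) -> tuple[float, tuple[float, float], float]:
    n = values.size
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return mean, (mean - half, mean + half), sem


def compare_conditions(
    results_a: list[DensityResult],
    results_b: list[DensityResult],
    label: CompartmentClass,
    channel: str,
    welch: bool = False,
) -> ConditionComparison:
    """Compare one (class, channel) relative density between two
    conditions with a two-sided two-sample t test (pooled-variance
    Student by default, Welch with ``welch=True``)."""
    label = CompartmentClass.coerce(label)
    a = np.array([r.relative_density(label, channel) for r in results_a], dtype=float)
    b = np.array([r.relative_density(label, channel) for r in results_b], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"need >= 2 endosomes per condition, got {a.size} and {b.size}"
        )
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=not welch)
    mean_a, ci_a, sem_a = _mean_ci_sem(a)
    mean_b, ci_b, sem_b = _mean_ci_sem(b)
    return ConditionComparison(
        label=label,
        channel=channel,
        mean_a=mean_a,
        mean_b=mean_b,
        ci95_a=ci_a,
        ci95_b=ci_b,
        sem_a=sem_a,
        sem_b=sem_b,
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=float(t_stat),
        p_value=float(p_value),
    )
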