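"""Formulation-replacement analysis.

A formula is a proportion-weighted blend of raw material spectra (linear
mixing — a model of absorbance blending, standing in for physically blended
samples).  Replacing one material with a substitute at exactly the same
proportion yields a second formula; the similarity of the two formulas,
under a chosen preprocessing pipeline and metric, measures how detectable
the swap is.  The default method is the grid's preferred scheme,
``snv+d1_sg+mms`` with the SS/CS metric.

The comparison batch defaults to the four spectra {original material,
substitute material, formula before, formula after}; because batch min-max
normalization pins the batch extremes to 0 and 1, a broader normalization
context (e.g. the whole materials dataset) can be supplied to place the
similarities on a less degenerate scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .preprocess import PipelineSpec, apply_pipeline
from .simmetrics import pairwise_matrix
from .spectra import SpectralDataset, Spectrum

__all__ = [
    "FormulationSpec",
    "ReplacementScenario",
    "ReplacementRecord",
    "mix_spectra",
    "replacement_experiment",
    "replacement_table",
    "write_replacement_table",
]

PROPORTION_TOL = 1e-9

#: the preferred scheme for replacement similarity scoring
DEFAULT_PIPELINE_ID = "snv+d1_sg+mms"
DEFAULT_METRIC_ID = "ss_cs"


@dataclass(frozen=True)
class FormulationSpec:
    """Component proportions of a blend; positive and summing to 1."""

    components: Mapping[str, float]

    def __post_init__(self) -> None:
        comp = dict(self.components)
        if not comp:
            raise InputError("formulation has no components")
        for sid, prop in comp.items():
            if not prop > 0.0:
                raise InputError(f"component {sid!r} has non-positive proportion {prop}")
        total = sum(comp.values())
        if abs(total - 1.0) > PROPORTION_TOL:
            raise InputError(f"proportions sum to {total}, expected 1")
        object.__setattr__(self, "components", comp)


@dataclass(frozen=True)
class ReplacementScenario:
    """One replacement case: which component of the base formula is swapped
    for which substitute material."""

    scenario_id: str
    base: FormulationSpec
    replaced_id: str
    substitute_id: str


@dataclass
class ReplacementRecord:
    """Result of one replacement experiment: material-vs-material
    similarity, the swapped proportion, and formula-vs-formula similarity
    (all similarities normalized to [0, 1] over the comparison batch)."""

    scenario_id: str
    material_similarity: float
    proportion: float
    formula_similarity: float
    pipeline_id: str
    metric_id: str

    def __post_init__(self) -> None:
        if not (0.0 < self.proportion < 1.0):
            raise InputError(f"proportion must be in (0,1), got {self.proportion}")


def mix_spectra(
    materials: SpectralDataset,
    formula: FormulationSpec,
    sample_id: str = "formula",
) -> Spectrum:
    """Proportion-weighted sum of the component spectra on the shared axis."""
    vals = np.zeros(len(materials.axis))
    for sid, prop in formula.components.items():
        vals += prop * materials.get(sid).values
    return Spectrum(sample_id, vals)


def replacement_experiment(
    materials: SpectralDataset,
    base: FormulationSpec,
    replaced_id: str,
    substitute_id: str,
    pipeline: PipelineSpec | None = None,
    metric_id: str = DEFAULT_METRIC_ID,
    context: SpectralDataset | None = None,
    scenario_id: str = "",
) -> ReplacementRecord:
    """Swap one component for a substitute at the same proportion and score
    both the material pair and the formula pair.

    Builds formula_a (the base blend) and formula_b (the blend with
    ``replaced_id`` -> ``substitute_id``), preprocesses the comparison batch
    with ``pipeline``, computes normalized metric values over all pairs of
    that batch, and reports the material-material and formula-formula
    similarities.  ``context`` adds reference spectra to the batch (they
    take part in preprocessing and normalization only)."""
    if pipeline is None:
        pipeline = PipelineSpec.from_id(DEFAULT_PIPELINE_ID)
    if replaced_id not in base.components:
        raise InputError(f"replaced component {replaced_id!r} not in base formula")
    if substitute_id in base.components:
        raise InputError(f"substitute {substitute_id!r} already in base formula")
    proportion = base.components[replaced_id]

    new_components = dict(base.components)
    new_components[substitute_id] = new_components.pop(replaced_id)
    formula_a = mix_spectra(materials, base, "formula_a")
    formula_b = mix_spectra(materials, FormulationSpec(new_components), "formula_b")

    batch: list[Spectrum] = []
    seen: set[str] = set()
    if context is not None:
        if context.axis != materials.axis:
            raise InputError("context axis differs from materials axis")
        for s in context.spectra:
            batch.append(s)
            seen.add(s.sample_id)
    for sid in (replaced_id, substitute_id):
        if sid not in seen:
            batch.append(materials.get(sid))
            seen.add(sid)
    for s in (formula_a, formula_b):
        if s.sample_id in seen:
            raise InputError(f"context already contains id {s.sample_id!r}")
        batch.append(s)

    processed = apply_pipeline(SpectralDataset(materials.axis, batch), pipeline)
    pairs = {
        (p.id_a, p.id_b): p.normalized for p in pairwise_matrix(processed, metric_id)
    }

    def lookup(a: str, b: str) -> float:
        return pairs[tuple(sorted((a, b)))]

    return ReplacementRecord(
        scenario_id=scenario_id,
        material_similarity=lookup(replaced_id, substitute_id),
        proportion=proportion,
        formula_similarity=lookup("formula_a", "formula_b"),
        pipeline_id=pipeline.id,
        metric_id=metric_id,
    )


def replacement_table(
    materials: SpectralDataset,
    scenarios: Sequence[ReplacementScenario],
    pipeline: PipelineSpec | None = None,
    metric_id: str = DEFAULT_METRIC_ID,
    context: SpectralDataset | None = None,
) -> list[ReplacementRecord]:
    """One :class:`ReplacementRecord` per scenario, in input order."""
    return [
        replacement_experiment(
            materials,
            sc.base,
            sc.replaced_id,
            sc.substitute_id,
            pipeline=pipeline,
            metric_id=metric_id,
            context=context,
            scenario_id=sc.scenario_id,
        )
        for sc in scenarios
    ]


def write_replacement_table(
    records: Iterable[ReplacementRecord], path: str | Path
) -> None:
    """CSV with the three similarity columns plus scenario and method ids.

    The first line is a ``#`` comment recording the scoring method."""
    records = list(records)
    methods = sorted({f"{r.pipeline_id} + {r.metric_id}" for r in records})
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# method: {'; '.join(methods)}\n")
        writer = csv.writer(fh)
        writer.writerow(
            [
                "scenario_id",
                "material_similarity",
                "proportion",
                "formula_similarity",
                "pipeline_id",
                "metric_id",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.scenario_id,
                    repr(r.material_similarity),
                    repr(r.proportion),
                    repr(r.formula_similarity),
                    r.pipeline_id,
                    r.metric_id,
                ]
            )
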