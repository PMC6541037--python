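"""Default ontology build: class rules, biophysics models and category terms.

Ties the pieces together the way the full database is meant to be built:
enumerate all species from the shipped class rules and the 37-entry
fatty-acid alphabet, fit the three biophysical property models on the
bundled (synthetic) training tables, calibrate the five category bins per
property on a reference lipidome, and annotate every predictable species
with its category terms.
"""

from __future__ import annotations

import numpy as np

from .biophysics import (
    CategoryLimits,
    PropertyRegressionResults,
    assign_biophysics_terms,
    derive_limits,
    fit_property_model,
)
from .ontology import (
    Ontology,
    attach_property_assignments,
    build_ontology,
    default_class_rules,
)
from .simulate import (
    SYNTHETIC_MODEL_TRUTH,
    synthetic_reference_lipidome,
    synthetic_training_records,
)

__all__ = ["build_default_ontology", "default_property_models"]

PROPERTIES = tuple(SYNTHETIC_MODEL_TRUTH)


def default_property_models(
    seed: int = 1234,
) -> dict[str, PropertyRegressionResults]:
    """Fit the three property models on the bundled synthetic training data."""
    return {
        prop: fit_property_model(
            synthetic_training_records(prop, seed=seed),
            property_name=prop,
            units=SYNTHETIC_MODEL_TRUTH[prop]["units"],
        )
        for prop in PROPERTIES
    }


def derive_default_limits(
    ontology: Ontology,
    models: dict[str, PropertyRegressionResults],
    reference_species: list[str] | None = None,
) -> dict[str, CategoryLimits]:
    """Category limits from model predictions over a reference lipidome."""
    if reference_species is None:
        reference_species = synthetic_reference_lipidome(ontology)
    limits: dict[str, CategoryLimits] = {}
    species = [ontology.species[name] for name in reference_species]
    classes = [sp.lipid_class for sp in species]
    length = [sp.total_carbons for sp in species]
    unsat = [sp.total_double_bonds for sp in species]
    for prop, model in models.items():
        values = model.predict_values(classes, length, unsat)
        values = values[~np.isnan(values)]
        limits[prop] = derive_limits(values, property_name=prop)
    return limits


def build_default_ontology(
    include_biophysics: bool = True,
    seed: int = 1234,
) -> Ontology:
    """Build the full default ontology (all shipped classes, 37-FA alphabet).

    With ``include_biophysics`` the three property models are fitted, the
    category limits calibrated on the synthetic reference lipidome, and every
    predictable species annotated with one category term per property.
    """
    ontology = build_ontology(default_class_rules())
    if include_biophysics:
        models = default_property_models(seed=seed)
        limits = derive_default_limits(ontology, models)
        assignments = assign_biophysics_terms(ontology, models, limits)
        attach_property_assignments(ontology, assignments)
    return ontology
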