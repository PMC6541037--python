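"""Synthetic fixtures: toy ontologies, training tables and planted datasets.

Everything needed to exercise the package without external downloads is
generated here, seed-deterministically.  The abundance generator uses a
log-normal intensity model (sigma of the natural-log scale = 1) — a generic
lipidomics-like intensity distribution, not a claim about any particular
instrument — and plants a multiplicative abundance shift on the lipids
annotated to a chosen term in one condition, so that enrichment analyses
have a known ground truth to recover.

The synthetic property training tables double as the package's bundled
default training data for the biophysical models: coefficient signs follow
the literature (transition temperature rises with chain length and falls
with unsaturation; lateral diffusion does the opposite), but the values are
synthetic stand-ins, not measured data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .biophysics import PropertyTrainingRecord
from .nomenclature import MOLECULAR_SPECIES
from .ontology import (
    DEFAULT_SPHINGOID_BASES,
    Ontology,
    build_ontology,
    default_class_rules,
)

__all__ = [
    "PlantedTruth",
    "make_toy_ontology",
    "make_property_training",
    "make_abundance_matrix",
    "synthetic_training_records",
    "synthetic_reference_lipidome",
    "SYNTHETIC_MODEL_TRUTH",
]

#: Small fatty-acid alphabet used by the toy ontology (common mammalian chains).
TOY_FATTY_ACIDS: tuple[tuple[int, int], ...] = (
    (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (20, 4),
)
#: Class order used when a toy ontology asks for the first n classes.
TOY_CLASS_ORDER = ("PC", "PE", "PS", "TG", "SM", "PG", "DG", "PA", "Cer", "CE")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a synthetic abundance matrix."""

    planted_term: str
    effect_size: float
    affected_condition: str
    seed: int

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def make_toy_ontology(
    n_classes: int = 4,
    fatty_acid_subset: tuple[tuple[int, int], ...] = TOY_FATTY_ACIDS,
) -> Ontology:
    """A small but structurally complete ontology: all four branches, CAT
    roots, molecular and sum-composition layers."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rules = {r.class_id: r for r in default_class_rules()}
    chosen = [rules[c] for c in TOY_CLASS_ORDER[:n_classes]]
    return build_ontology(chosen, fatty_acids=fatty_acid_subset,
                          sphingoid_bases=DEFAULT_SPHINGOID_BASES)


def make_property_training(
    classes: dict[str, float],
    beta_length: float,
    beta_unsaturation: float,
    noise_sd: float,
    n: int,
    seed: int,
    intercept: float = 0.0,
) -> list[PropertyTrainingRecord]:
    """Training records drawn from a known linear model.

    ``classes`` maps class id -> true class offset.  Chain lengths are even
    totals in 28..44, unsaturations 0..6; the value is
    ``intercept + offset + beta_length * L + beta_unsaturation * U + noise``.
    """
    if n < 10:
        raise ValueError("need n >= 10 training records")
    rng = np.random.default_rng(seed)
    names = sorted(classes)
    out = []
    for _ in range(n):
        cls = names[rng.integers(len(names))]
        length = int(rng.integers(14, 23) * 2)  # 28..44 even
        unsat = int(rng.integers(0, 7))
        value = (intercept + classes[cls] + beta_length * length
                 + beta_unsaturation * unsat + rng.normal(0.0, noise_sd))
        out.append(PropertyTrainingRecord(cls, length, unsat, float(value)))
    return out


def make_abundance_matrix(
    ontology: Ontology,
    n_samples_per_condition: int,
    conditions: tuple[str, ...],
    planted: PlantedTruth,
    missing_rate: float = 0.0,
    replicate_noise_sd: float = 0.4,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Synthetic lipid x sample abundance matrix with one planted enrichment.

    Rows are the molecular species of the ontology.  Baseline abundances
    across lipids are log-normal with a natural-log sigma of 1 (lipid
    abundances in real datasets span orders of magnitude); replicate scatter
    around each lipid's baseline is log-normal with
    ``replicate_noise_sd`` (default 0.4, i.e. roughly 40% CV, at the upper
    end of typical biological replicate variation).  Species annotated
    (closure included) to ``planted.planted_term`` are multiplied by
    ``planted.effect_size`` in the affected condition.  Missing values are
    masked completely at random at ``missing_rate``.

    Returns ``(matrix, sample_conditions, planted)``.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if planted.affected_condition not in conditions:
        raise ValueError("affected_condition must be one of conditions")
    term_id = ontology.resolve_term(planted.planted_term)
    lipids = sorted(
        name for name, sp in ontology.species.items()
        if sp.level == MOLECULAR_SPECIES
    )
    annotated = ontology.species_of_term(term_id) & set(lipids)
    if len(annotated) < 5:
        raise ValueError(
            f"planted term annotates only {len(annotated)} species (< 5)"
        )
    rng = np.random.default_rng(planted.seed)
    n_lip = len(lipids)
    samples = [f"{cond}_{i+1}" for cond in conditions
               for i in range(n_samples_per_condition)]
    labels = pd.Series(
        [cond for cond in conditions for _ in range(n_samples_per_condition)],
        index=samples,
    )
    base_mu = rng.normal(10.0, 1.0, size=n_lip)
    log_values = rng.normal(
        base_mu[:, None], replicate_noise_sd, size=(n_lip, len(samples))
    )
    matrix = pd.DataFrame(np.exp(log_values), index=lipids, columns=samples)
    affected_cols = labels.index[labels == planted.affected_condition]
    hit_rows = [name for name in lipids if name in annotated]
    matrix.loc[hit_rows, affected_cols] *= planted.effect_size
    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        matrix = matrix.mask(mask)
    return matrix, labels, planted


# -- bundled synthetic defaults for the biophysical layer --------------------

#: True coefficients behind the bundled synthetic training tables; signs
#: follow the literature (longer saturated chains melt higher and diffuse
#: slower), values are synthetic.
SYNTHETIC_MODEL_TRUTH: dict[str, dict] = {
    "transition_temperature": {
        "classes": {"PC": 0.0, "PE": 20.0, "PG": -5.0, "PA": 10.0,
                    "PS": 15.0, "SM": 10.0},
        "intercept": -60.0,
        "beta_length": 3.0,
        "beta_unsaturation": -20.0,
        "noise_sd": 4.0,
        "units": "degC",
    },
    "bilayer_thickness": {
        "classes": {"PC": 0.0, "PS": 0.1, "PG": -0.05, "PA": -0.1, "PE": 0.05},
        "intercept": 2.0,
        "beta_length": 0.055,
        "beta_unsaturation": -0.10,
        "noise_sd": 0.08,
        "units": "nm",
    },
    "lateral_diffusion": {
        "classes": {"PC": 0.0, "PS": -0.2, "PG": 0.1, "PA": 0.2, "PE": -0.1},
        "intercept": 9.0,
        "beta_length": -0.12,
        "beta_unsaturation": 0.35,
        "noise_sd": 0.3,
        "units": "um^2/s",
    },
}


def synthetic_training_records(
    property_name: str,
    n: int = 80,
    seed: int = 1234,
) -> list[PropertyTrainingRecord]:
    """The bundled synthetic training table for one property (seeded)."""
    truth = SYNTHETIC_MODEL_TRUTH[property_name]
    return make_property_training(
        classes=truth["classes"],
        beta_length=truth["beta_length"],
        beta_unsaturation=truth["beta_unsaturation"],
        noise_sd=truth["noise_sd"],
        n=n,
        seed=seed,
        intercept=truth["intercept"],
    )


def synthetic_reference_lipidome(
    ontology: Ontology,
    size: int = 500,
    seed: int = 2024,
) -> list[str]:
    """A synthetic mammalian-like reference lipidome: a seeded sample of
    membrane-lipid species used to calibrate the category limits."""
    preferred = {"PC", "PE", "PS", "PG", "PA", "SM", "PC O-", "PE O-",
                 "PC P-", "PE P-"}
    pool = sorted(
        name for name, sp in ontology.species.items()
        if sp.lipid_class in preferred
    )
    if not pool:
        raise ValueError("ontology holds no membrane-lipid species")
    rng = np.random.default_rng(seed)
    size = min(size, len(pool))
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]
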