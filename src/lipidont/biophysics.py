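"""Biophysical property models: regression, LOOCV and quintile categorization.

Three membrane properties are modelled — chain-melting transition temperature
(degrees C, from experimental compilations), bilayer thickness and lateral
diffusion (from coarse-grained simulation datasets).  Each property is fitted
by ordinary least squares with lipid class (categorical), total fatty-acid
chain length and total unsaturation as predictors, which allows extrapolation
to every enumerated species of a trained class.  Models are validated by
leave-one-out cross-validation.

Because an ontology holds categorical terms, predicted values are discretized
into five named bins ("very low", "low", "average", "high", "very high").
The bin limits are the empirical 20/40/60/80th percentiles of predictions
over a *reference lipidome* — a species list standing in for typical
mammalian membrane composition — so the bins carry physiological meaning
rather than being quantiles of the enumeration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .nomenclature import LipidSpecies
from .ontology import CATEGORY_NAMES, PROPERTY_LABELS, Ontology

__all__ = [
    "PropertyTrainingRecord",
    "PropertyRegression",
    "PropertyRegressionResults",
    "LoocvReport",
    "CategoryLimits",
    "DEFAULT_CLASS_PROXIES",
    "fit_property_model",
    "predict_property",
    "loocv",
    "derive_limits",
    "categorize",
    "assign_biophysics_terms",
]

#: Classes absent from the training sources mapped onto a trained stand-in.
#: Ether and plasmalogen species borrow the coefficients of their diacyl
#: parent class; everything else without training data is left unpredictable.
DEFAULT_CLASS_PROXIES: dict[str, str] = {
    "PC O-": "PC",
    "PC P-": "PC",
    "PE O-": "PE",
    "PE P-": "PE",
}


@dataclass(frozen=True)
class PropertyTrainingRecord:
    """One training observation: class, summed length/unsaturation, value."""

    lipid_class: str
    chain_length: int
    unsaturation: int
    value: float

    def __post_init__(self) -> None:
        if self.chain_length <= 0:
            raise ValueError("chain_length must be positive")
        if self.unsaturation < 0:
            raise ValueError("unsaturation must be >= 0")


def _records_frame(records: Sequence[PropertyTrainingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lipid_class": [r.lipid_class for r in records],
            "chain_length": [r.chain_length for r in records],
            "unsaturation": [r.unsaturation for r in records],
            "value": [r.value for r in records],
        }
    )


class PropertyRegression:
    """OLS model of one biophysical property.

    ``value ~ 1 + C(lipid_class) + chain_length + unsaturation``, with the
    lexicographically first class as the reference level.
    """

    def __init__(
        self,
        records: Sequence[PropertyTrainingRecord],
        property_name: str = "property",
        units: str | None = None,
    ) -> None:
        if not records:
            raise ValueError("no training records")
        self.records = list(records)
        self.property_name = property_name
        self.units = units
        df = _records_frame(self.records)
        self.classes = sorted(df["lipid_class"].unique())
        self.reference_class = self.classes[0]
        self.exog = self._design(df)
        self.endog = df["value"].to_numpy(float)
        n, p = self.exog.shape
        if n < p:
            raise ValueError(
                f"{n} records cannot identify {p} free parameters"
            )
        self._check_rank(self.exog)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        property_name: str = "property",
        units: str | None = None,
    ) -> "PropertyRegression":
        records = [
            PropertyTrainingRecord(
                str(r.lipid_class), int(r.chain_length), int(r.unsaturation),
                float(r.value),
            )
            for r in df.itertuples()
        ]
        return cls(records, property_name=property_name, units=units)

    def _design(self, df: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
        for cls_name in self.classes[1:]:
            X[f"class[{cls_name}]"] = (df["lipid_class"] == cls_name).astype(float)
        X["chain_length"] = df["chain_length"].astype(float)
        X["unsaturation"] = df["unsaturation"].astype(float)
        return X

    @staticmethod
    def _check_rank(X: pd.DataFrame) -> None:
        arr = X.to_numpy(float)
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            # Name a column lying in the span of the others; prefer blaming a
            # predictor over the intercept (a constant predictor is the usual
            # culprit, e.g. all records sharing one chain length).
            order = sorted(range(arr.shape[1]), key=lambda j: X.columns[j] == "const")
            for j in order:
                reduced = np.delete(arr, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    raise ValueError(
                        f"rank-deficient design: column {X.columns[j]!r} is collinear"
                    )
            raise ValueError("rank-deficient design")  # pragma: no cover

    def fit(self) -> "PropertyRegressionResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return PropertyRegressionResults(self, res)


class PropertyRegressionResults:
    """Fitted coefficients, uncertainties and diagnostics of a property model."""

    def __init__(self, model: PropertyRegression, sm_results) -> None:
        self.model = model
        self._res = sm_results
        params = sm_results.params
        self.intercept = float(params["const"])
        self.class_offsets = {model.reference_class: 0.0}
        for cls_name in model.classes[1:]:
            self.class_offsets[cls_name] = float(params[f"class[{cls_name}]"])
        self.beta_length = float(params["chain_length"])
        self.beta_unsaturation = float(params["unsaturation"])

    @property
    def property_name(self) -> str:
        return self.model.property_name

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._res.resid)

    def summary(self):
        return self._res.summary(title=f"OLS model of {self.model.property_name}")

    def predict_values(
        self,
        lipid_class: np.ndarray | Sequence[str],
        chain_length: np.ndarray | Sequence[float],
        unsaturation: np.ndarray | Sequence[float],
        proxies: Mapping[str, str] | None = None,
    ) -> np.ndarray:
        """Vectorized prediction; NaN for classes without coefficients/proxy."""
        if proxies is None:
            proxies = DEFAULT_CLASS_PROXIES
        offsets = np.array(
            [
                self.class_offsets.get(
                    c, self.class_offsets.get(proxies.get(c, ""), np.nan)
                )
                for c in lipid_class
            ],
            dtype=float,
        )
        length = np.asarray(chain_length, dtype=float)
        unsat = np.asarray(unsaturation, dtype=float)
        return (
            self.intercept
            + offsets
            + self.beta_length * length
            + self.beta_unsaturation * unsat
        )

    def predict_species(
        self,
        species: LipidSpecies,
        proxies: Mapping[str, str] | None = None,
    ) -> float | None:
        """Prediction for one species; None when the class is not predictable."""
        v = self.predict_values(
            [species.lipid_class],
            [species.total_carbons],
            [species.total_double_bonds],
            proxies=proxies,
        )[0]
        return None if np.isnan(v) else float(v)

    def coefficients_frame(self) -> pd.DataFrame:
        """Coefficient export: property, class, coefficient name, value."""
        rows = [
            {"property": self.property_name, "coefficient": "intercept",
             "value": self.intercept},
            {"property": self.property_name, "coefficient": "chain_length",
             "value": self.beta_length},
            {"property": self.property_name, "coefficient": "unsaturation",
             "value": self.beta_unsaturation},
        ]
        for cls_name, off in self.class_offsets.items():
            rows.append(
                {"property": self.property_name,
                 "coefficient": f"class_offset[{cls_name}]", "value": off}
            )
        return pd.DataFrame(rows)


@dataclass
class LoocvReport:
    """Held-out predictions from leave-one-out cross-validation."""

    property_name: str
    predicted: np.ndarray  # NaN where a refit was rank-deficient
    observed: np.ndarray
    flagged: list[int] = field(default_factory=list)

    @property
    def rmse(self) -> float:
        ok = ~np.isnan(self.predicted)
        return float(np.sqrt(np.mean((self.predicted[ok] - self.observed[ok]) ** 2)))

    @property
    def r_squared(self) -> float:
        ok = ~np.isnan(self.predicted)
        obs, pred = self.observed[ok], self.predicted[ok]
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot


def fit_property_model(
    records: Sequence[PropertyTrainingRecord],
    property_name: str = "property",
    units: str | None = None,
) -> PropertyRegressionResults:
    """Fit the per-property OLS model (class + length + unsaturation)."""
    return PropertyRegression(records, property_name=property_name, units=units).fit()


def predict_property(
    model: PropertyRegressionResults,
    species: LipidSpecies,
    proxies: Mapping[str, str] | None = None,
) -> float | None:
    """Linear prediction for a species; None when its class is untrained."""
    return model.predict_species(species, proxies=proxies)


def loocv(
    records: Sequence[PropertyTrainingRecord],
    property_name: str = "property",
) -> LoocvReport:
    """Leave-one-out cross-validation: refit on n-1 records, predict the rest.

    Records whose refit design is rank-deficient are flagged and excluded
    from the aggregate error statistics.
    """
    n = len(records)
    full = PropertyRegression(records, property_name=property_name)
    if n < full.exog.shape[1] + 1:
        raise ValueError("need at least one more record than free parameters")
    observed = np.array([r.value for r in records], dtype=float)
    predicted = np.full(n, np.nan)
    flagged: list[int] = []
    for i in range(n):
        subset = records[:i] + records[i + 1:] if isinstance(records, list) else \
            [r for j, r in enumerate(records) if j != i]
        try:
            res = PropertyRegression(subset, property_name=property_name).fit()
        except ValueError:
            flagged.append(i)
            continue
        r = records[i]
        # Held-out class unseen in the training subset: flag as well.
        if r.lipid_class not in res.class_offsets:
            flagged.append(i)
            continue
        predicted[i] = res.predict_values(
            [r.lipid_class], [r.chain_length], [r.unsaturation], proxies={}
        )[0]
    return LoocvReport(property_name, predicted, observed, flagged)


@dataclass(frozen=True)
class CategoryLimits:
    """Four quantile cut points defining the five named bins of a property."""

    property_name: str
    limits: tuple[float, float, float, float]
    category_names: tuple[str, ...] = CATEGORY_NAMES

    def __post_init__(self) -> None:
        if len(self.limits) != 4:
            raise ValueError("exactly four limits required")
        if any(b < a for a, b in zip(self.limits, self.limits[1:])):
            raise ValueError("limits must be nondecreasing")
        if len(self.category_names) != 5:
            raise ValueError("exactly five categories required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"property": self.property_name,
             "quantile": [0.2, 0.4, 0.6, 0.8],
             "limit": list(self.limits)}
        )


def derive_limits(
    reference_values: Sequence[float],
    property_name: str = "property",
) -> CategoryLimits:
    """Empirical 20/40/60/80th percentiles of a reference distribution.

    Quantile convention: inclusive linear interpolation (numpy's default
    ``linear`` method).  At least five distinct values are required for the
    quintiles to be meaningful.
    """
    values = np.asarray(list(reference_values), dtype=float)
    values = values[~np.isnan(values)]
    if np.unique(values).size < 5:
        raise ValueError("need at least 5 distinct reference values")
    q = np.quantile(values, [0.2, 0.4, 0.6, 0.8], method="linear")
    return CategoryLimits(property_name, tuple(float(x) for x in q))


def categorize(value: float, limits: CategoryLimits) -> str:
    """Map a value to its bin: (-inf, q20) "very low", [q20, q40) "low",
    [q40, q60) "average", [q60, q80) "high", [q80, inf) "very high"."""
    if np.isnan(value):
        raise ValueError("cannot categorize NaN")
    idx = int(np.searchsorted(np.asarray(limits.limits), value, side="right"))
    return limits.category_names[idx]


def assign_biophysics_terms(
    ontology: Ontology,
    models: Mapping[str, PropertyRegressionResults],
    limits_per_property: Mapping[str, CategoryLimits],
    proxies: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Category term names for every predictable species of an ontology.

    Returns a mapping canonical species name -> list of term names such as
    ``"very low transition temperature"``; species of untrained classes get
    no terms for that property.  The result plugs into
    :func:`lipidont.ontology.attach_property_assignments` or
    :func:`lipidont.ontology.build_ontology`.
    """
    names = list(ontology.species)
    classes = [ontology.species[n].lipid_class for n in names]
    length = np.array([ontology.species[n].total_carbons for n in names], float)
    unsat = np.array([ontology.species[n].total_double_bonds for n in names], float)

    assignments: dict[str, list[str]] = {}
    for prop, model in models.items():
        label = PROPERTY_LABELS.get(prop, prop)
        limits = limits_per_property[prop]
        values = model.predict_values(classes, length, unsat, proxies=proxies)
        ok = ~np.isnan(values)
        bins = np.searchsorted(np.asarray(limits.limits), values[ok], side="right")
        for name, b in zip(np.array(names, dtype=object)[ok], bins):
            assignments.setdefault(name, []).append(
                f"{limits.category_names[b]} {label}"
            )
    return assignments
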