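"""Rule-based fuzzy crop suitability from climate attribute summaries.

Each rule maps one mean-annual climate attribute (seasonal degree-day sum,
frost-day count, heat-day count, annual rainfall, ...) through a
trapezoidal membership function onto [0, 1]; a combiner (minimum by
default — the limiting-factor convention of land evaluation — or product,
or a weighted geometric mean) collapses the memberships into a single
suitability score, 0 = poor to 1 = good.  Scores can be discretised into
four classes at 0.25 / 0.5 / 0.75 (a declared convention).

The shipped apple and kiwifruit rule sets are illustrative defaults for
exercising the framework; they are not calibrated against any published
suitability surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .climate import DailyClimateSeries
from .errors import AlignmentError, ConfigurationError, InputError
from .hazards import HazardSpec, count_hazard_days
from .phenology import CropPhenologyParams, thermal_time_from_tmean

CLASS_NAMES = ("unsuited", "marginal", "suited", "well_suited")
CLASS_BOUNDS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid a <= b <= c <= d: zero outside [a, d], one on [b, c],
    linear in between.  Degenerate edges (a == b) give a hard shoulder."""

    attribute_name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"membership for {self.attribute_name!r} needs a <= b <= c <= d"
            )

    def __call__(self, x: float) -> float:
        x = float(x)
        if x < self.a or x > self.d:
            return 0.0
        if self.b <= x <= self.c:
            return 1.0
        if x < self.b:  # rising edge; a < b here since a <= x < b
            return (x - self.a) / (self.b - self.a)
        return (self.d - x) / (self.d - self.c)


@dataclass(frozen=True)
class SuitabilityRuleSet:
    """All membership functions for one crop plus the combiner."""

    crop_name: str
    functions: tuple[MembershipFunction, ...]
    combiner: Literal["min", "product", "weighted_geometric"] = "min"
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.functions:
            raise ConfigurationError("rule set needs at least one attribute")
        names = [f.attribute_name for f in self.functions]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate attribute in rule set")
        if self.combiner == "weighted_geometric":
            if self.weights is None or len(self.weights) != len(self.functions):
                raise ConfigurationError("weighted_geometric needs one weight "
                                         "per attribute")
            w = np.asarray(self.weights, float)
            if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
                raise ConfigurationError("weights must be positive and sum to 1")
        elif self.combiner not in ("min", "product"):
            raise ConfigurationError(f"unknown combiner {self.combiner!r}")

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(f.attribute_name for f in self.functions)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = dict(
            crop_name=self.crop_name,
            combiner=self.combiner,
            weights=list(self.weights) if self.weights else None,
            functions=[
                dict(attribute_name=f.attribute_name, a=f.a, b=f.b, c=f.c, d=f.d)
                for f in self.functions
            ],
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SuitabilityRuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            crop_name=doc["crop_name"],
            functions=tuple(MembershipFunction(**f) for f in doc["functions"]),
            combiner=doc.get("combiner", "min"),
            weights=tuple(doc["weights"]) if doc.get("weights") else None,
        )


def apple_ruleset() -> SuitabilityRuleSet:
    """Illustrative temperate pipfruit rule set (synthetic, not calibrated)."""
    return SuitabilityRuleSet(
        crop_name="apple",
        functions=(
            MembershipFunction("gdd", 800.0, 1100.0, 1900.0, 2400.0),
            MembershipFunction("frost_days", -1.0, 0.0, 15.0, 40.0),
            MembershipFunction("heat_days", -1.0, 0.0, 10.0, 30.0),
            MembershipFunction("annual_rainfall", 350.0, 550.0, 1500.0, 2500.0),
        ),
    )


def kiwifruit_ruleset() -> SuitabilityRuleSet:
    """Illustrative warm-temperate vine rule set (synthetic, not calibrated)."""
    return SuitabilityRuleSet(
        crop_name="kiwifruit",
        functions=(
            MembershipFunction("gdd", 1200.0, 1600.0, 2600.0, 3200.0),
            MembershipFunction("frost_days", -1.0, 0.0, 5.0, 20.0),
            MembershipFunction("annual_rainfall", 500.0, 800.0, 1800.0, 3000.0),
        ),
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AttributeConfig:
    """How the standard climate attributes are summarised."""

    gdd_base: float = 10.0
    frost_threshold: float = 0.0  # tmin strictly below
    heat_threshold: float = 30.0  # tmax strictly above


def attribute_summaries(
    series: DailyClimateSeries,
    slice_years: tuple[int, int],
    config: AttributeConfig = AttributeConfig(),
) -> dict[str, float]:
    """Mean-annual attribute vector for one cell over a year slice.

    ``gdd`` (degC day above the base), ``frost_days`` and ``heat_days``
    (strict threshold counts, consistent with the hazard counter) and
    ``annual_rainfall`` (mm), each averaged over the calendar years of the
    slice.
    """
    sub = series.subset_years(*slice_years)
    years = sub.data.index.year
    n_years = len(set(years))
    params = CropPhenologyParams(crop_name="_gdd", base_temp=config.gdd_base,
                                 stage_thresholds=(1.0,), stage_kc=(1.0,))
    gdd = thermal_time_from_tmean(sub.tmean.to_numpy(), params)
    return {
        "gdd": float(gdd.sum() / n_years),
        "frost_days": float(
            (sub.data["tmin"].to_numpy() < config.frost_threshold).sum() / n_years
        ),
        "heat_days": float(
            (sub.data["tmax"].to_numpy() > config.heat_threshold).sum() / n_years
        ),
        "annual_rainfall": float(sub.data["precip"].to_numpy().sum() / n_years),
    }


def score(attributes: Mapping[str, float], rules: SuitabilityRuleSet) -> float:
    """Combine attribute memberships into one suitability score in [0, 1]."""
    memberships = []
    for fn in rules.functions:
        if fn.attribute_name not in attributes:
            raise InputError(f"missing attribute {fn.attribute_name!r}")
        memberships.append(fn(attributes[fn.attribute_name]))
    m = np.asarray(memberships, float)
    if rules.combiner == "min":
        return float(m.min())
    if rules.combiner == "product":
        return float(m.prod())
    w = np.asarray(rules.weights, float)
    if np.any(m == 0.0):  # geometric mean with a zero factor is zero
        return 0.0
    return float(np.exp(np.sum(w * np.log(m))))


def classify(value: float) -> str:
    """Discretise a continuous score; class bounds are left-closed
    (a score of exactly 0.25 is 'marginal')."""
    if not 0.0 <= value <= 1.0:
        raise InputError("score must be in [0, 1]")
    idx = int(np.searchsorted(CLASS_BOUNDS, value, side="right"))
    return CLASS_NAMES[idx]


def suitability_change(
    baseline: Mapping[str, float] | pd.Series,
    future: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Per-cell score delta plus class transitions between two climates.

    Inputs map cell_id -> score.  Returns a frame indexed by cell with
    columns ``baseline``, ``future``, ``delta``, ``class_baseline``,
    ``class_future``; the frame's ``attrs['transitions']`` tallies
    (class_baseline, class_future) pairs.
    """
    b = pd.Series(baseline, dtype=float)
    f = pd.Series(future, dtype=float)
    if set(b.index) != set(f.index):
        diff = sorted(set(b.index).symmetric_difference(f.index))
        raise AlignmentError(f"cells differ between baseline and future: {diff}")
    f = f.reindex(b.index)
    out = pd.DataFrame(
        {
            "baseline": b,
            "future": f,
            "delta": f - b,
            "class_baseline": [classify(v) for v in b],
            "class_future": [classify(v) for v in f],
        }
    ).sort_index()
    out.attrs["transitions"] = (
        out.groupby(["class_baseline", "class_future"]).size().to_dict()
    )
    return out
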