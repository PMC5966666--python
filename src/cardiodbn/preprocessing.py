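"""Encoding of UCI-heart-style clinical attributes into unit-interval features.

The 13 standard heart-disease attributes mix continuous measurements
(age, resting blood pressure, serum cholesterol, maximum heart rate,
ST depression) with coded categorical factors (sex, chest-pain type,
fasting blood sugar, resting ECG, exercise angina, ST slope, vessel
count, thallium result).  All features are mapped into [0, 1] so they
can feed the visible layer of an RBM:

* ``range`` attributes are rescaled by *robust* min-max scaling, where
  the scaling extremes are the averages of the ``k`` largest and ``k``
  smallest observed values rather than the raw extremes, making the
  transform insensitive to isolated outliers;
* ``direct-map`` and ``hierarchical-map`` attributes are mapped through
  an ordered code table and divided by the largest code.

Ranges and imputation statistics are fitted on the training partition
only and reused on held-out data; out-of-range values are clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

#: Attribute order of the canonical 13-column heart-disease table.
ATTRIBUTES: tuple[str, ...] = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
)

#: Name of the diagnosis column (0 = absence, 1-4 = graded presence).
LABEL = "num"

#: Token used by the public heart-disease files for a missing value.
MISSING_TOKEN = "?"

VALID_KINDS = ("direct-map", "hierarchical-map", "range")


class EncodingError(ValueError):
    """Raised when a record cannot be encoded under the active schema."""


def canonical_token(token: str) -> str:
    """Normalize a raw categorical token: strip whitespace and collapse
    integral floats ("3.0" -> "3") so the Statlog and Cleveland spellings
    of the same code compare equal."""
    token = token.strip()
    try:
        value = float(token)
    except ValueError:
        return token
    if math.isfinite(value) and value == int(value):
        return str(int(value))
    return token


@dataclass(frozen=True)
class RobustRange:
    """Fitted scaling interval of one continuous attribute.

    ``robust_min``/``robust_max`` are the tail averages of the ``tail_count``
    smallest/largest training values.
    """

    robust_min: float
    robust_max: float
    tail_count: int

    def __post_init__(self) -> None:
        if self.tail_count < 1:
            raise ValueError("tail_count must be a positive integer")
        if not self.robust_max > self.robust_min:
            raise ValueError(
                f"degenerate range [{self.robust_min}, {self.robust_max}]"
            )

    @property
    def width(self) -> float:
        return self.robust_max - self.robust_min


@dataclass
class FeatureSchema:
    """Encoding rule for a single attribute.

    Parameters
    ----------
    name:
        Attribute identifier (one of :data:`ATTRIBUTES`).
    kind:
        ``"direct-map"`` or ``"hierarchical-map"`` for coded categorical
        attributes, ``"range"`` for continuous attributes.
    category_codes:
        Ordered raw-token -> integer-code mapping (categorical kinds only).
        Distinct tokens may share no code; aliases for the same clinical
        category (e.g. the Cleveland thallium spellings) map extra tokens
        onto an existing code.
    tail_count:
        Number of extreme values averaged by robust min-max fitting
        (range kind only).  ``None`` selects ceil(2% of the training
        sample) at fit time; ``1`` reduces to plain min-max.
    """

    name: str
    kind: str
    category_codes: dict[str, int] | None = None
    tail_count: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"{self.name}: unknown schema kind {self.kind!r}")
        if self.kind == "range":
            if self.tail_count is not None and self.tail_count < 1:
                raise ValueError(f"{self.name}: tail_count must be >= 1")
        else:
            if not self.category_codes:
                raise ValueError(f"{self.name}: categorical kind needs codes")
            self.category_codes = {
                canonical_token(k): int(v) for k, v in self.category_codes.items()
            }

    @property
    def max_code(self) -> int:
        assert self.category_codes is not None
        return max(self.category_codes.values())

    def code_for(self, token: str) -> int:
        assert self.category_codes is not None
        key = canonical_token(token)
        if key not in self.category_codes:
            raise EncodingError(
                f"attribute {self.name!r}: unknown category token {token!r}"
            )
        return self.category_codes[key]


def fit_improved_minmax(
    values: Sequence[float] | np.ndarray,
    tail_count: int,
    name: str = "feature",
) -> RobustRange:
    """Fit the robust min-max interval of one attribute.

    The maximum is the mean of the ``tail_count`` largest values and the
    minimum the mean of the ``tail_count`` smallest, which damps the
    influence of single recording outliers in clinical columns such as
    cholesterol.  ``tail_count=1`` is exactly ordinary min-max.
    """
    arr = np.asarray(values, dtype=float)
    if tail_count < 1:
        raise ValueError(f"{name}: tail_count must be >= 1, got {tail_count}")
    if arr.size < tail_count:
        raise ValueError(
            f"{name}: need at least tail_count={tail_count} values, "
            f"got {arr.size}"
        )
    ordered = np.sort(arr)
    lo = float(ordered[:tail_count].mean())
    hi = float(ordered[-tail_count:].mean())
    if not hi > lo:
        raise ValueError(f"{name}: degenerate range (all values identical?)")
    return RobustRange(robust_min=lo, robust_max=hi, tail_count=tail_count)


def apply_minmax(value: float, rng: RobustRange) -> float:
    """Rescale ``value`` into [0, 1] by the fitted robust interval.

    Values outside the interval (possible on held-out data, since the
    robust extremes are interior to the raw range) are clamped so the
    output always satisfies the unit-interval contract of RBM visible
    units.
    """
    scaled = (value - rng.robust_min) / rng.width
    return float(min(1.0, max(0.0, scaled)))


def binarize_label(num: int) -> int:
    """Collapse the graded diagnosis 0-4 to disease absence/presence."""
    num = int(num)
    if num not in (0, 1, 2, 3, 4):
        raise ValueError(f"diagnosis label out of range 0-4: {num}")
    return 0 if num == 0 else 1


def default_tail_count(n_samples: int) -> int:
    """Default robust-tail size: ~2% of the fitting sample, at least 1."""
    return max(1, math.ceil(0.02 * n_samples))


def heart_schema() -> list[FeatureSchema]:
    """The canonical 13-attribute schema.

    Continuous attributes use robust min-max except age, which uses the
    plain variant (tail_count=1).  Categorical code tables include the
    alias spellings used by the public Cleveland/Statlog files (chest
    pain 1-4, slope 1-3, thallium 3/6/7) mapped onto the canonical
    0-based codes.
    """
    return [
        FeatureSchema("age", "range", tail_count=1),
        FeatureSchema("sex", "direct-map", {"0": 0, "female": 0, "1": 1, "male": 1}),
        FeatureSchema("cp", "direct-map", {"0": 0, "1": 1, "2": 2, "3": 3, "4": 3}),
        FeatureSchema("trestbps", "range"),
        FeatureSchema("chol", "range"),
        FeatureSchema("fbs", "hierarchical-map", {"0": 0, "1": 1}),
        FeatureSchema("restecg", "direct-map", {"0": 0, "1": 1, "2": 2}),
        FeatureSchema("thalach", "range"),
        FeatureSchema("exang", "direct-map", {"0": 0, "no": 0, "1": 1, "yes": 1}),
        FeatureSchema("oldpeak", "range"),
        FeatureSchema("slope", "direct-map", {"0": 0, "1": 1, "2": 2, "3": 2}),
        FeatureSchema("ca", "direct-map", {"0": 0, "1": 1, "2": 2, "3": 3}),
        FeatureSchema("thal", "direct-map",
                      {"0": 0, "1": 1, "2": 2, "3": 0, "6": 1, "7": 2}),
    ]


def statlog_schema() -> list[FeatureSchema]:
    """Schema variant for the Statlog (Heart) spelling.

    Statlog codes chest pain 1-4 and slope 1-3 with no 0 category; the
    shifted tokens are remapped so the encoded feature still spans the
    canonical code range.
    """
    schema = heart_schema()
    by_name = {s.name: s for s in schema}
    by_name["cp"].category_codes = {"1": 0, "2": 1, "3": 2, "4": 3}
    by_name["slope"].category_codes = {"1": 0, "2": 1, "3": 2}
    return schema


def schema_to_yaml(schema: Sequence[FeatureSchema], path: str) -> None:
    """Serialize a schema to a YAML config file (one entry per attribute)."""
    doc = []
    for s in schema:
        entry: dict = {"name": s.name, "kind": s.kind}
        if s.category_codes is not None:
            entry["category_codes"] = dict(s.category_codes)
        if s.tail_count is not None:
            entry["tail_count"] = s.tail_count
        doc.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def schema_from_yaml(path: str) -> list[FeatureSchema]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        FeatureSchema(
            name=entry["name"],
            kind=entry["kind"],
            category_codes=entry.get("category_codes"),
            tail_count=entry.get("tail_count"),
        )
        for entry in doc
    ]


def encode_record(
    raw_record: Mapping[str, str],
    schema: Sequence[FeatureSchema],
    fitted_ranges: Mapping[str, RobustRange],
) -> np.ndarray:
    """Encode one raw record into a 13-vector of unit-interval features.

    Feature order follows :data:`ATTRIBUTES`.  Categorical codes are
    divided by the attribute's maximum code; range attributes go through
    :func:`apply_minmax` with the fitted robust interval.  Missing values
    must already have been imputed (see :class:`Preprocessor`).
    """
    features = np.empty(len(schema), dtype=float)
    for i, s in enumerate(schema):
        if s.name not in raw_record:
            raise EncodingError(f"record is missing attribute {s.name!r}")
        token = raw_record[s.name]
        if token == MISSING_TOKEN:
            raise EncodingError(
                f"attribute {s.name!r}: missing value must be imputed "
                "before encoding"
            )
        if s.kind == "range":
            try:
                value = float(token)
            except ValueError as exc:
                raise EncodingError(
                    f"attribute {s.name!r}: non-numeric token {token!r}"
                ) from exc
            features[i] = apply_minmax(value, fitted_ranges[s.name])
        else:
            code = s.code_for(token)
            features[i] = code / s.max_code if s.max_code > 0 else 0.0
    return features


class Preprocessor:
    """Fit-on-train / apply-anywhere encoder for raw heart records.

    ``fit`` learns, from the training partition only, the robust scaling
    intervals of range attributes and the imputation statistics for the
    ``?`` missing-value token (training mode for categorical attributes,
    training median for continuous ones).  ``transform`` then maps any
    record list to an ``(X, y)`` pair with ``X`` in [0, 1] and ``y``
    binarized.
    """

    def __init__(self, schema: Sequence[FeatureSchema] | None = None):
        self.schema = list(schema) if schema is not None else heart_schema()
        self.ranges: dict[str, RobustRange] = {}
        self.fill_values: dict[str, str] = {}
        self._fitted = False

    def fit(self, records: Iterable) -> "Preprocessor":
        records = list(records)
        if not records:
            raise ValueError("cannot fit preprocessor on an empty record list")
        n = len(records)
        for s in self.schema:
            tokens = [rec.values[s.name] for rec in records]
            present = [t for t in tokens if t != MISSING_TOKEN]
            if not present:
                raise EncodingError(f"attribute {s.name!r}: all values missing")
            if s.kind == "range":
                values = np.array([float(t) for t in present])
                k = s.tail_count if s.tail_count is not None else default_tail_count(n)
                self.ranges[s.name] = fit_improved_minmax(values, k, name=s.name)
                self.fill_values[s.name] = repr(float(np.median(values)))
            else:
                canon = [canonical_token(t) for t in present]
                codes, counts = np.unique(canon, return_counts=True)
                self.fill_values[s.name] = str(codes[np.argmax(counts)])
        self._fitted = True
        return self

    def _impute(self, rec) -> dict[str, str]:
        out = dict(rec.values)
        for name, token in out.items():
            if token == MISSING_TOKEN:
                out[name] = self.fill_values[name]
        return out

    def transform(self, records: Iterable) -> tuple[np.ndarray, np.ndarray]:
        if not self._fitted:
            raise RuntimeError("Preprocessor.transform called before fit")
        records = list(records)
        X = np.vstack([
            encode_record(self._impute(rec), self.schema, self.ranges)
            for rec in records
        ])
        y = np.array([binarize_label(int(float(rec.label))) for rec in records])
        return X, y

    def fit_transform(self, records: Iterable) -> tuple[np.ndarray, np.ndarray]:
        return self.fit(records).transform(records)
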