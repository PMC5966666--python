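"""Reading UCI-heart-style flat files, splitting, and synthetic records.

Two public file dialects are supported:

* ``statlog-heart`` — whitespace-delimited, 13 attributes plus a label
  coded 1 (absence) / 2 (presence), no missing values;
* ``heart-disease`` — comma-delimited Cleveland-style rows with the
  graded diagnosis ``num`` in 0..4 and ``?`` for missing values.

The synthetic generator emulates the same 13-attribute schema from a
latent binary hierarchy of controllable depth: a disease bit at the
root, levels of binary factors each copying its parent with a small
flip probability while branching geometrically, and the observable
attributes emitted from the deepest factor level (factor-shifted
Gaussians for continuous attributes, factor-tilted multinomials over
the canonical code sets for categorical ones).  Deeper hierarchies
yield multi-scale correlation among the attributes; the generator is
the ground-truth instrument for the depth-selection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .preprocessing import ATTRIBUTES, MISSING_TOKEN, binarize_label, canonical_token

DIALECTS = ("comma", "whitespace", "statlog-heart", "heart-disease")


@dataclass(frozen=True)
class RawRecord:
    """One tokenized record: 13 attribute tokens plus the label token."""

    values: dict[str, str]
    label: str

    def __post_init__(self) -> None:
        if set(self.values) != set(ATTRIBUTES):
            raise ValueError("record must carry exactly the 13 attributes")

    def to_line(self, dialect: str = "heart-disease") -> str:
        sep = " " if dialect in ("whitespace", "statlog-heart") else ","
        return sep.join([self.values[a] for a in ATTRIBUTES] + [self.label])


class ParseError(ValueError):
    """Raised for malformed flat-file lines, with the line number."""


def sniff_dialect(line: str) -> str:
    """Guess the field separator of a record line: comma or whitespace."""
    return "comma" if "," in line else "whitespace"


def read_uci_heart(path: str | Path, dialect: str = "auto") -> list[RawRecord]:
    """Read a flat heart-disease file into raw records.

    One record per non-empty line, 14 fields; ``?`` is preserved as the
    missing-value token.  ``dialect`` selects the separator (``comma`` /
    ``whitespace``), or a named convention: ``statlog-heart``
    (whitespace, labels 1/2 remapped to 0/1) or ``heart-disease``
    (comma, num 0..4 kept as is).  ``auto`` sniffs the separator from
    the first non-empty line and applies no label remapping.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    non_empty = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not non_empty:
        return []
    if dialect == "auto":
        dialect = sniff_dialect(non_empty[0][1])
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = None if dialect in ("whitespace", "statlog-heart") else ","
    remap_statlog = dialect == "statlog-heart"

    records = []
    for lineno, line in non_empty:
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != len(ATTRIBUTES) + 1:
            raise ParseError(
                f"{path.name}:{lineno}: expected {len(ATTRIBUTES) + 1} "
                f"fields, got {len(fields)}"
            )
        label = fields[-1]
        if remap_statlog:
            label = {"1": "0", "2": "1"}[canonical_token(label)]
        records.append(
            RawRecord(values=dict(zip(ATTRIBUTES, fields[:-1])), label=label)
        )
    return records


def write_uci_heart(
    records: list[RawRecord], path: str | Path, dialect: str = "heart-disease"
) -> None:
    """Write records back to a flat file in the given dialect's separator."""
    Path(path).write_text(
        "".join(rec.to_line(dialect) + "\n" for rec in records)
    )


def split_train_test(
    records: list[RawRecord],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[RawRecord], list[RawRecord]]:
    """Stratified, mutually exclusive and jointly exhaustive 70/30 split.

    Stratification is by the binarized label so the class mix of the
    two partitions matches the full data as closely as rounding allows.
    Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = [binarize_label(int(float(r.label))) for r in records]
    for cls in (0, 1):
        if labels.count(cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 records")
    idx_train, idx_test = train_test_split(
        np.arange(len(records)),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed % (2 ** 32),
        shuffle=True,
    )
    return ([records[i] for i in sorted(idx_train)],
            [records[i] for i in sorted(idx_test)])


@dataclass
class SyntheticConfig:
    """Parameters of the hierarchical generator.

    n_samples:
        Number of records.
    latent_depth:
        Number of latent factor levels between the disease bit and the
        observables; 1 means the attributes load directly on (a noisy
        copy of) the label.
    factors_per_level:
        Width of the first factor level; each deeper level doubles,
        capped at the 13 observables.
    noise_sd:
        Unitless noise multiplier.  Scales the attribute-specific
        Gaussian jitter of the continuous columns, the confusion of the
        categorical columns, and the per-edge factor flip probability
        (0.1 * noise_sd, capped at 0.45).  0 makes every observable a
        deterministic function of the label.
    label_flip_prob:
        Probability that the emitted label contradicts the latent
        disease bit (irreducible Bayes error).
    """

    n_samples: int = 300
    latent_depth: int = 2
    factors_per_level: int = 2
    noise_sd: float = 1.0
    label_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.latent_depth < 1 or self.factors_per_level < 1:
            raise ValueError("n_samples, latent_depth, factors_per_level must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.label_flip_prob < 0.5:
            raise ValueError("label_flip_prob must be in [0, 0.5)")


# Per-attribute emission parameters: healthy mean, diseased mean, and the
# baseline Gaussian SD (multiplied by noise_sd).  Values sit in the
# clinically typical ranges of the respective measurements.
_CONTINUOUS_EMISSION = {
    "age": (48.0, 58.0, 8.0, 0),       # years; 0 decimals
    "trestbps": (125.0, 142.0, 12.0, 0),  # mmHg
    "chol": (225.0, 268.0, 35.0, 0),   # mg/dl
    "thalach": (158.0, 131.0, 15.0, 0),  # bpm; disease lowers peak rate
    "oldpeak": (0.4, 1.9, 0.7, 1),     # ST depression, mm
}

# Categorical attributes: code count and the tilt strength with which
# the latent factor shifts probability mass toward the high codes
# (negative = diseased favours the low codes).
_CATEGORICAL_EMISSION = {
    "sex": (2, 0.8),
    "cp": (4, 1.2),
    "fbs": (2, 0.9),
    "restecg": (3, 1.0),
    "exang": (2, 1.3),
    "slope": (3, 1.1),
    "ca": (4, 1.2),
    "thal": (3, 1.2),
}


def _level_sizes(cfg: SyntheticConfig) -> list[int]:
    sizes = []
    width = cfg.factors_per_level
    for _ in range(cfg.latent_depth):
        sizes.append(min(width, len(ATTRIBUTES)))
        width *= 2
    return sizes


def _format(value: float, decimals: int) -> str:
    if decimals == 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def generate_synthetic(config: SyntheticConfig) -> list[RawRecord]:
    """Sample records from the latent hierarchy.

    Per sample: a disease bit y ~ Bernoulli(0.5); factor levels sampled
    top-down, each factor copying its parent (grouped contiguously in
    the level above) with flip probability 0.1 * noise_sd; the 13
    attributes emitted from contiguous blocks of the deepest level.
    The emitted label equals y flipped with ``label_flip_prob``.
    Byte-identical output for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    flip_p = min(0.45, 0.1 * config.noise_sd)
    sizes = _level_sizes(config)
    n_attr = len(ATTRIBUTES)

    records = []
    for _ in range(config.n_samples):
        y = int(rng.random() < 0.5)
        level = np.full(sizes[0], y, dtype=int)
        level ^= rng.random(sizes[0]) < flip_p
        for width in sizes[1:]:
            prev = level
            parent_idx = (np.arange(width) * len(prev)) // width
            level = prev[parent_idx] ^ (rng.random(width) < flip_p)
        leaf_idx = (np.arange(n_attr) * len(level)) // n_attr
        factors = level[leaf_idx]

        values: dict[str, str] = {}
        for i, name in enumerate(ATTRIBUTES):
            f = int(factors[i])
            if name in _CONTINUOUS_EMISSION:
                mu0, mu1, sd, decimals = _CONTINUOUS_EMISSION[name]
                mu = mu1 if f else mu0
                value = mu + rng.normal(0.0, sd) * config.noise_sd
                if name == "oldpeak":
                    value = max(0.0, value)
                values[name] = _format(value, decimals)
            else:
                n_codes, tilt = _CATEGORICAL_EMISSION[name]
                if config.noise_sd == 0:
                    code = n_codes - 1 if f else 0
                else:
                    centered = np.arange(n_codes) - (n_codes - 1) / 2
                    logits = tilt * (2 * f - 1) * centered / config.noise_sd
                    p = np.exp(logits - logits.max())
                    p /= p.sum()
                    code = int(rng.choice(n_codes, p=p))
                values[name] = str(code)
        label = y
        if config.label_flip_prob > 0 and rng.random() < config.label_flip_prob:
            label = 1 - label
        records.append(RawRecord(values=values, label=str(label)))
    return records
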