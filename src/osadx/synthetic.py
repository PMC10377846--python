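"""Synthetic clinical-style tables with planted class signal.

Generates labeled tables shaped like a sleep-clinic feature export:
31 mixed numeric/nominal columns (race, sex, age, questionnaire scores,
polysomnography summaries), an imbalanced binary outcome, optional
missing cells, and a configurable set of informative ("planted")
features whose class separation can be modulated per demographic
subgroup.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .masks import mask_from_indices
from .table import NOMINAL, NUMERIC, LabeledTable

__all__ = [
    "SchemaSpec",
    "GeneratorConfig",
    "default_schema",
    "generate_dataset",
    "inject_missing",
    "planted_feature_mask",
]

ROLES = ("race", "sex", "age")

# Default clinical schema: 31 features, mixed types, with explicit
# race / sex / age roles.  Yes/no style flags are nominal.
_DEFAULT_FEATURES = [
    ("Race", NOMINAL, ["Caucasian", "Hispanic"]),
    ("Age", NUMERIC, None),
    ("Sex", NOMINAL, ["F", "M"]),
    ("BMI", NOMINAL, ["normal", "overweight", "obese", "severely_obese"]),
    ("Epworth", NUMERIC, None),
    ("Waist", NUMERIC, None),
    ("Hip", NUMERIC, None),
    ("RDI", NUMERIC, None),
    ("Neck", NUMERIC, None),
    ("TonguePosition", NUMERIC, None),
    ("Comorbid", NOMINAL, ["no", "yes"]),
    ("Snoring", NOMINAL, ["no", "yes"]),
    ("DaytimeSleepiness", NOMINAL, ["no", "yes"]),
    ("DM", NOMINAL, ["no", "yes"]),
    ("HTN", NOMINAL, ["no", "yes"]),
    ("CAD", NOMINAL, ["no", "yes"]),
    ("CVA", NOMINAL, ["no", "yes"]),
    ("TST", NUMERIC, None),
    ("SleepEfficiency", NUMERIC, None),
    ("REM_AHI", NUMERIC, None),
    ("NREM_AHI", NUMERIC, None),
    ("Supine_AHI", NUMERIC, None),
    ("ApneaIndex", NUMERIC, None),
    ("HypopneaIndex", NUMERIC, None),
    ("BerlinQ", NOMINAL, ["low", "high"]),
    ("ArousalIndex", NUMERIC, None),
    ("AwakeningIndex", NUMERIC, None),
    ("PLMIndex", NUMERIC, None),
    ("MinsSaO2", NUMERIC, None),
    ("MinsSaO2Desats", NUMERIC, None),
    ("LowestSaO2", NUMERIC, None),
]


@dataclass
class SchemaSpec:
    """Column layout of a generated table.

    ``demographic_roles`` maps each of the roles ``race``, ``sex`` and
    ``age`` to exactly one column name.
    """

    feature_names: list
    feature_types: list
    nominal_levels: dict
    demographic_roles: dict

    def __post_init__(self):
        if len(self.feature_names) != len(self.feature_types):
            raise ValueError("feature_types length must equal feature_names length")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if set(self.demographic_roles) != set(ROLES):
            raise ValueError(f"demographic_roles must map exactly {ROLES}")
        for role, col in self.demographic_roles.items():
            if col not in self.feature_names:
                raise ValueError(f"role {role!r} column {col!r} not in schema")
        for name, typ in zip(self.feature_names, self.feature_types):
            if typ not in (NUMERIC, NOMINAL):
                raise ValueError(f"bad type {typ!r} for {name!r}")
            if typ == NOMINAL:
                levels = self.nominal_levels.get(name)
                if not levels or len(levels) < 2:
                    raise ValueError(f"nominal feature {name!r} needs >= 2 levels")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def index_of(self, name: str) -> int:
        return self.feature_names.index(name)

    def role_index(self, role: str) -> int:
        return self.index_of(self.demographic_roles[role])


def default_schema() -> SchemaSpec:
    """The 31-column clinical schema used throughout the package."""
    names = [f[0] for f in _DEFAULT_FEATURES]
    types = [f[1] for f in _DEFAULT_FEATURES]
    levels = {f[0]: list(f[2]) for f in _DEFAULT_FEATURES if f[2] is not None}
    return SchemaSpec(
        feature_names=names,
        feature_types=types,
        nominal_levels=levels,
        demographic_roles={"race": "Race", "sex": "Sex", "age": "Age"},
    )


@dataclass
class GeneratorConfig:
    """Knobs of the generator.

    ``group_modulation`` maps a role to a per-level multiplier on the
    planted effect sizes, e.g. ``{"sex": {"M": 2.0, "F": 0.0}}``
    concentrates the class signal in male rows.  For the ``age`` role
    the two level keys are ``"le50"`` and ``"gt50"``.
    """

    n_samples: int = 274
    positive_fraction: float = 125 / 274
    race_fraction: float = 151 / 274      # proportion of first race level
    female_fraction: float = 118 / 274
    age_mean: float = 50.0
    age_sd: float = 15.0
    age_bounds: tuple = (19.0, 96.0)
    planted_features: tuple = ()
    effect_sizes: tuple = ()
    group_modulation: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.planted_features = tuple(self.planted_features)
        self.effect_sizes = tuple(self.effect_sizes)
        for name, p in [
            ("positive_fraction", self.positive_fraction),
            ("race_fraction", self.race_fraction),
            ("female_fraction", self.female_fraction),
        ]:
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if len(self.effect_sizes) != len(self.planted_features):
            raise ValueError("effect_sizes must align with planted_features")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not self.age_bounds[0] < self.age_bounds[1]:
            raise ValueError("age_bounds must be increasing")

    def validate_against(self, schema: SchemaSpec) -> None:
        n = schema.n_features
        for idx in self.planted_features:
            if not 0 <= idx < n:
                raise ValueError(f"planted feature index {idx} out of range 0..{n - 1}")
        role_cols = {schema.role_index(r) for r in ROLES}
        bad = role_cols & set(self.planted_features)
        if bad:
            raise ValueError(f"demographic columns cannot be planted: {sorted(bad)}")
        for role in self.group_modulation:
            if role not in ROLES:
                raise ValueError(f"unknown modulation role {role!r}")


def planted_feature_mask(schema: SchemaSpec, config: GeneratorConfig) -> np.ndarray:
    """Ground-truth informative-feature mask (1 at each planted index)."""
    return mask_from_indices(config.planted_features, schema.n_features)


def _row_modulation(config, schema, race_code, sex_code, age) -> np.ndarray:
    """Per-row multiplier on planted effects, product over modulated roles."""
    n = len(age)
    mod = np.ones(n)
    for role, table in config.group_modulation.items():
        if role == "age":
            labels = np.where(age <= 50.0, "le50", "gt50")
        elif role == "race":
            levels = schema.nominal_levels[schema.demographic_roles["race"]]
            labels = np.asarray(levels)[race_code]
        else:
            levels = schema.nominal_levels[schema.demographic_roles["sex"]]
            labels = np.asarray(levels)[sex_code]
        mod *= np.array([float(table.get(lab, 1.0)) for lab in labels])
    return mod


def _latent_to_codes(z: np.ndarray, n_levels: int) -> np.ndarray:
    # threshold a latent Gaussian at equal-frequency cut points
    cuts = stats.norm.ppf(np.arange(1, n_levels) / n_levels)
    return np.searchsorted(cuts, z).astype(float)


def generate_dataset(schema: SchemaSpec, config: GeneratorConfig) -> LabeledTable:
    """Draw a labeled table from the configured generative model.

    Labels are Bernoulli(``positive_fraction``); planted numeric
    features are unit-variance Gaussians whose class-mean gap equals
    the feature's effect size times the row's group modulation;
    planted nominal features threshold the same latent construction
    into level codes; all other features are class-independent noise.
    """
    config.validate_against(schema)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    y = (rng.random(n) < config.positive_fraction).astype(int)
    race_code = (rng.random(n) >= config.race_fraction).astype(int)
    sex_code = (rng.random(n) >= config.female_fraction).astype(int)
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    mod = _row_modulation(config, schema, race_code, sex_code, age)
    effects = dict(zip(config.planted_features, config.effect_sizes))
    role_idx = {schema.role_index(r): r for r in ROLES}

    columns = {}
    for j, (name, typ) in enumerate(zip(schema.feature_names, schema.feature_types)):
        if j in role_idx:
            role = role_idx[j]
            if role == "race":
                columns[name] = race_code.astype(float)
            elif role == "sex":
                columns[name] = sex_code.astype(float)
            else:
                columns[name] = age
            continue
        shift = effects.get(j, 0.0) * mod if j in effects else 0.0
        z = rng.standard_normal(n) + y * shift
        if typ == NUMERIC:
            columns[name] = z
        else:
            n_levels = len(schema.nominal_levels[name])
            columns[name] = _latent_to_codes(z, n_levels)

    X = pd.DataFrame(columns, columns=schema.feature_names)
    table = LabeledTable(X, y, tuple(schema.feature_types), dict(schema.nominal_levels))
    if config.missing_rate > 0.0:
        miss_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missing(table, config.missing_rate, miss_seed)
    return table


def inject_missing(table: LabeledTable, rate: float, seed: int) -> LabeledTable:
    """Mask each feature cell independently with probability ``rate`` (MCAR).

    Labels are never masked.  ``rate`` must lie in [0, 1).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.X.shape) < rate
    values = out.X.to_numpy(dtype=float)
    values[mask] = np.nan
    out.X = pd.DataFrame(values, columns=out.X.columns)
    return out
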