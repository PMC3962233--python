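"""Synthetic formulary generator with known ground truth.

Formulas are independent draws: each gets one efficacy class, uses each of
its class's "main" plants with probability ``p_main`` and every other plant
with a low baseline ``p_support``.  Activity annotations link each class's
main plants to a small set of class-specific activities, link main plants of
every class to a shared pool of general activities, and add sparse Bernoulli
noise elsewhere.  Recovery tests check that the downstream models find this
planted structure back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigError
from .formulary import ActivityMatrix, EfficacyLabels, PlantUsageMatrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "simulate_formulary",
    "JAMU_CLASS_NAMES",
    "JAMU_CLASS_COUNTS",
]

# Registered efficacy categories of the motivating formulary and the number
# of formulas in each (3,138 in total over 465 plants and 46 activities).
JAMU_CLASS_NAMES = ("URI", "DOA", "DMB", "GST", "FML", "MSC", "PIN", "RSP", "WND")
JAMU_CLASS_COUNTS = (72, 249, 22, 980, 398, 840, 311, 107, 159)


@dataclass(frozen=True)
class GeneratorConfig:
    I: int
    J: int
    K: int
    L: int
    class_proportions: tuple[float, ...]
    n_main_per_class: int = 5
    p_main: float = 0.6
    p_support: float = 0.02
    n_specific_activities_per_class: int = 2
    n_general_activities: int = 4
    p_activity_noise: float = 0.01
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K, self.L) < 1:
            raise ConfigError("I, J, K, L must all be positive")
        props = tuple(float(p) for p in self.class_proportions)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != self.L:
            raise ConfigError(f"need {self.L} class proportions, got {len(props)}")
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-12:
            raise ConfigError("class proportions must be non-negative and sum to 1")
        for name in ("p_main", "p_support", "p_activity_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.n_main_per_class * self.L > self.J:
            raise ConfigError(
                f"n_main_per_class*L = {self.n_main_per_class * self.L} exceeds J = {self.J}"
            )
        n_structured = self.n_specific_activities_per_class * self.L + self.n_general_activities
        if n_structured > self.K:
            raise ConfigError(
                f"{n_structured} structured activities exceed K = {self.K}"
            )
        if self.class_names is not None:
            names = tuple(str(c) for c in self.class_names)
            if len(names) != self.L:
                raise ConfigError(f"need {self.L} class names, got {len(names)}")
            object.__setattr__(self, "class_names", names)

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        if self.L == len(JAMU_CLASS_NAMES):
            return JAMU_CLASS_NAMES
        return tuple(f"C{l + 1}" for l in range(self.L))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        for key in ("class_proportions", "class_names"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated formulary."""

    main_plants: dict[str, tuple[str, ...]]
    specific_activities: dict[str, tuple[str, ...]]
    general_activities: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "main_plants": {c: list(v) for c, v in self.main_plants.items()},
                "specific_activities": {c: list(v) for c, v in self.specific_activities.items()},
                "general_activities": list(self.general_activities),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            main_plants={c: tuple(v) for c, v in raw["main_plants"].items()},
            specific_activities={c: tuple(v) for c, v in raw["specific_activities"].items()},
            general_activities=tuple(raw["general_activities"]),
        )


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Configuration mirroring the motivating formulary's marginals.

    3,138 formulas over 465 plants, 46 activities and 9 efficacy classes with
    the registered per-class formula counts as class proportions.
    """
    total = sum(JAMU_CLASS_COUNTS)
    params = dict(
        I=total,
        J=465,
        K=46,
        L=9,
        class_proportions=tuple(c / total for c in JAMU_CLASS_COUNTS),
        n_main_per_class=10,
        p_main=0.6,
        p_support=0.02,
        n_specific_activities_per_class=3,
        n_general_activities=8,
        p_activity_noise=0.01,
        seed=seed,
        class_names=JAMU_CLASS_NAMES,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def simulate_formulary(
    cfg: GeneratorConfig,
) -> tuple[PlantUsageMatrix, EfficacyLabels, ActivityMatrix, GroundTruth]:
    """Draw one synthetic formulary; bitwise reproducible for a given seed.

    Three independent child streams (labels, usage, activities) are spawned
    from the master seed so that extra draws in one block never perturb the
    others.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_labels, rng_usage, rng_activity = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    class_names = cfg.resolved_class_names()
    formula_ids = tuple(f"F{i + 1:05d}" for i in range(cfg.I))
    plant_ids = tuple(f"P{j + 1:04d}" for j in range(cfg.J))
    activity_ids = tuple(f"A{k + 1:03d}" for k in range(cfg.K))

    classes = rng_labels.choice(cfg.L, size=cfg.I, p=np.asarray(cfg.class_proportions))
    labels = EfficacyLabels(formula_ids, [class_names[c] for c in classes])

    # Disjoint blocks of main plants per class.
    main_idx = {
        c: np.arange(c * cfg.n_main_per_class, (c + 1) * cfg.n_main_per_class)
        for c in range(cfg.L)
    }
    P = np.full((cfg.I, cfg.J), cfg.p_support)
    for c in range(cfg.L):
        rows = classes == c
        P[np.ix_(rows, main_idx[c])] = cfg.p_main
    X = (rng_usage.random((cfg.I, cfg.J)) < P).astype(np.int8)
    usage = PlantUsageMatrix(formula_ids, plant_ids, X)

    n_spec = cfg.n_specific_activities_per_class
    spec_idx = {c: np.arange(c * n_spec, (c + 1) * n_spec) for c in range(cfg.L)}
    general_idx = np.arange(n_spec * cfg.L, n_spec * cfg.L + cfg.n_general_activities)

    A = np.zeros((cfg.J, cfg.K), dtype=np.int8)
    all_main = np.concatenate([main_idx[c] for c in range(cfg.L)]) if cfg.n_main_per_class else []
    for c in range(cfg.L):
        A[np.ix_(main_idx[c], spec_idx[c])] = 1
    if cfg.n_general_activities and len(all_main):
        A[np.ix_(all_main, general_idx)] = 1
    noise = rng_activity.random((cfg.J, cfg.K)) < cfg.p_activity_noise
    A = np.where((A == 0) & noise, 1, A).astype(np.int8)
    activities = ActivityMatrix(plant_ids, activity_ids, A)

    truth = GroundTruth(
        main_plants={
            class_names[c]: tuple(plant_ids[j] for j in main_idx[c]) for c in range(cfg.L)
        },
        specific_activities={
            class_names[c]: tuple(activity_ids[k] for k in spec_idx[c]) for c in range(cfg.L)
        },
        general_activities=tuple(activity_ids[k] for k in general_idx),
    )
    return usage, labels, activities, truth
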