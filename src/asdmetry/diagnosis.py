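"""Naive-Bayes diagnosis with genetic-algorithm feature selection.

Operates on tables of discretised (categorical) patient features plus a
class label. The classifier is the standard naive-Bayes rule

    C(Y) = argmax_j P(C_j) * prod_k P(Y_k | C_j)

with additive (Laplace) smoothing of the count estimates; posteriors are
the normalised class scores. The genetic algorithm searches binary feature
masks: fitness is the cross-validated accuracy of the classifier restricted
to the masked features, passed through a sigmoid, and selection copies
individuals in proportion to fitness via rounded expected counts
(largest-remainder rounding keeps the population size exact), followed by
one-point crossover, bit-flip mutation and single-elite preservation.

The sigmoid is available in two orientations: the decreasing form
``1 / (1 + e^a)`` and the conventional increasing form ``1 / (1 + e^-a)``.
Selection must reward accuracy, so the GA uses the increasing orientation
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "RecordTable",
    "NBModel",
    "Chromosome",
    "GAConfig",
    "fitness_sigmoid",
    "expected_copies",
    "ga_select_features",
    "nb_fit",
    "nb_predict",
    "bayes_posterior",
    "joint_probability",
    "cross_val_accuracy",
    "synthetic_records",
    "discretize",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class RecordTable:
    """Discretised patient records: categorical feature columns + a label."""

    frame: pd.DataFrame
    label_column: str

    def __post_init__(self) -> None:
        if self.label_column not in self.frame.columns:
            raise ConfigError(f"label column {self.label_column!r} not in table")
        if self.frame[self.label_column].isna().any():
            raise ConfigError("records with missing labels are not allowed")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.label_column]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def labels(self) -> pd.Series:
        return self.frame[self.label_column]

    def arity(self) -> dict[str, int]:
        return {c: int(self.frame[c].nunique()) for c in self.feature_columns}

    def subset(self, mask) -> "RecordTable":
        cols = [c for c, keep in zip(self.feature_columns, mask) if keep]
        return RecordTable(self.frame[cols + [self.label_column]], self.label_column)


def discretize(frame: pd.DataFrame, columns: list[str], bins: int = 4) -> pd.DataFrame:
    """Equal-frequency binning of continuous columns into categorical codes."""
    out = frame.copy()
    for c in columns:
        out[c] = pd.qcut(frame[c], q=bins, labels=False, duplicates="drop")
    return out


# ---------------------------------------------------------------------------
# probability primitives
# ---------------------------------------------------------------------------


def joint_probability(p_n_given_m: float, p_m: float) -> float:
    """P(M and N) = P(N | M) P(M)."""
    return float(p_n_given_m) * float(p_m)


def bayes_posterior(likelihoods, priors) -> np.ndarray:
    """Posteriors P(N_j | M) from likelihoods P(M | N_j) and priors P(N_j),
    normalised by the total probability of M."""
    lik = np.asarray(likelihoods, dtype=float)
    pri = np.asarray(priors, dtype=float)
    if lik.shape != pri.shape:
        raise ValueError("likelihoods and priors must have equal length")
    joint = lik * pri
    total = joint.sum()
    if total <= 0:
        raise ValueError("total probability of the evidence is zero")
    return joint / total


def fitness_sigmoid(a: float, orientation: str = "printed") -> float:
    """Sigmoid fitness map.

    ``orientation="printed"`` gives the decreasing form ``1 / (1 + e^a)``;
    ``"conventional"`` the increasing ``1 / (1 + e^-a)``.
    """
    a = float(a)
    if orientation == "printed":
        return float(1.0 / (1.0 + np.exp(a)))
    if orientation == "conventional":
        return float(1.0 / (1.0 + np.exp(-a)))
    raise ConfigError(f"unknown sigmoid orientation {orientation!r}")


def expected_copies(fitness_values, population_size: int) -> np.ndarray:
    """Integer copy counts proportional to fitness.

    ``count_x = N * f_x / sum(f)`` rounded so the counts sum exactly to N
    (floor + largest-remainder distribution of the residual).
    """
    f = np.asarray(fitness_values, dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("fitness values must be non-negative with positive sum")
    raw = population_size * f / f.sum()
    counts = np.floor(raw).astype(int)
    residual = population_size - counts.sum()
    if residual > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:residual]] += 1
    return counts


# ---------------------------------------------------------------------------
# naive Bayes
# ---------------------------------------------------------------------------


@dataclass
class NBModel:
    """Smoothed class priors and per-feature conditional tables."""

    classes: list
    priors: dict
    conditionals: dict  # feature -> {class -> {value -> prob}}
    feature_values: dict  # feature -> list of known values
    smoothing: float = 1.0

    def posterior(self, record) -> dict:
        logs = {}
        for cls in self.classes:
            lp = np.log(self.priors[cls])
            for feat, table in self.conditionals.items():
                val = record[feat]
                probs = table[cls]
                if val in probs:
                    p = probs[val]
                else:
                    arity = len(self.feature_values[feat])
                    denom_extra = self.smoothing * arity
                    if self.smoothing == 0:
                        import warnings

                        warnings.warn(
                            f"unseen value {val!r} for feature {feat!r} with zero "
                            "smoothing gives zero probability",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        p = 0.0
                    else:
                        p = self.smoothing / (self._class_count[cls] + denom_extra)
                lp += np.log(p) if p > 0 else -np.inf
            logs[cls] = lp
        mx = max(logs.values())
        if not np.isfinite(mx):
            # every class got probability zero: fall back to the priors
            return dict(self.priors)
        expd = {c: np.exp(v - mx) for c, v in logs.items()}
        total = sum(expd.values())
        return {c: v / total for c, v in expd.items()}

    _class_count: dict = field(default_factory=dict)


def nb_fit(table: RecordTable, smoothing: float = 1.0) -> NBModel:
    """Estimate priors and conditionals by additively smoothed counts.

    ``P(v | c) = (count(v, c) + s) / (count(c) + s * arity)`` where
    ``arity`` is the number of distinct values of the feature.
    """
    if smoothing < 0:
        raise ConfigError("smoothing must be non-negative")
    labels = table.labels
    classes = sorted(labels.unique().tolist())
    n = len(labels)
    class_count = {c: int((labels == c).sum()) for c in classes}
    k = len(classes)
    priors = {c: (class_count[c] + smoothing) / (n + smoothing * k) for c in classes}

    conditionals: dict = {}
    feature_values: dict = {}
    for feat in table.feature_columns:
        col = table.frame[feat]
        values = sorted(col.unique().tolist())
        feature_values[feat] = values
        arity = len(values)
        per_class = {}
        for c in classes:
            sub = col[labels == c]
            counts = sub.value_counts()
            denom = class_count[c] + smoothing * arity
            per_class[c] = {
                v: (int(counts.get(v, 0)) + smoothing) / denom for v in values
            }
        conditionals[feat] = per_class

    model = NBModel(
        classes=classes,
        priors=priors,
        conditionals=conditionals,
        feature_values=feature_values,
        smoothing=smoothing,
    )
    model._class_count = class_count
    return model


def nb_predict(model: NBModel, record) -> tuple[object, dict]:
    """Arg-max class and normalised posteriors for one record.

    ``record`` is a mapping (or Series) from feature name to value.
    """
    post = model.posterior(record)
    best = max(model.classes, key=lambda c: (post[c], model.priors[c]))
    return best, post


def cross_val_accuracy(table: RecordTable, k: int = 3, smoothing: float = 1.0, seed: int = 0) -> float:
    """k-fold cross-validated naive-Bayes accuracy on a table."""
    n = len(table.frame)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    correct = 0
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        train = RecordTable(table.frame.iloc[train_idx].reset_index(drop=True), table.label_column)
        model = nb_fit(train, smoothing=smoothing)
        test = table.frame.iloc[test_idx]
        for _, row in test.iterrows():
            pred, _ = nb_predict(model, row)
            correct += pred == row[table.label_column]
    return correct / n


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class Chromosome:
    """Binary feature-selection mask with its fitness."""

    mask: np.ndarray
    fitness: float = 0.0
    accuracy: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("chromosome must select at least one feature")


@dataclass
class GAConfig:
    population: int = 30
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    elitism: int = 1
    cv_folds: int = 3
    smoothing: float = 1.0
    orientation: str = "conventional"


def ga_select_features(
    table: RecordTable, ga_cfg: GAConfig | None = None, seed: int = 0
) -> tuple[Chromosome, np.ndarray]:
    """Search feature masks maximising cross-validated NB accuracy.

    Returns the best chromosome and the best-fitness trace per generation
    (monotone non-decreasing thanks to elitism). Fully deterministic given
    ``seed``.
    """
    cfg = ga_cfg or GAConfig()
    rng = np.random.default_rng(seed)
    n_feat = len(table.feature_columns)
    if n_feat == 0:
        raise ConfigError("no feature columns to select from")

    cache: dict[tuple, tuple[float, float]] = {}

    def evaluate(mask: np.ndarray) -> tuple[float, float]:
        key = tuple(mask.tolist())
        if key not in cache:
            acc = cross_val_accuracy(
                table.subset(mask), k=cfg.cv_folds, smoothing=cfg.smoothing, seed=seed
            )
            cache[key] = (fitness_sigmoid(acc, cfg.orientation), acc)
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(n_feat)] = True
        return mask

    pop = [repair(rng.random(n_feat) < 0.5) for _ in range(cfg.population)]
    fits = np.array([evaluate(m)[0] for m in pop])
    trace = []
    best_idx = int(np.argmax(fits))
    best = Chromosome(pop[best_idx].copy(), fits[best_idx], evaluate(pop[best_idx])[1])

    for _ in range(cfg.generations):
        counts = expected_copies(fits, cfg.population)
        mating = [pop[i].copy() for i, c in enumerate(counts) for _ in range(c)]
        rng.shuffle(mating)

        children = []
        for i in range(0, len(mating) - 1, 2):
            a, b = mating[i], mating[i + 1]
            if rng.random() < cfg.crossover_prob and n_feat > 1:
                cut = int(rng.integers(1, n_feat))
                a, b = (
                    np.concatenate([a[:cut], b[cut:]]),
                    np.concatenate([b[:cut], a[cut:]]),
                )
            children.extend([a, b])
        if len(mating) % 2:
            children.append(mating[-1])

        for child in children:
            flips = rng.random(n_feat) < cfg.mutation_prob
            child ^= flips
            repair(child)

        # elitism: the best-so-far mask survives unconditionally
        children[: cfg.elitism] = [best.mask.copy() for _ in range(cfg.elitism)]
        pop = children[: cfg.population]
        fits = np.array([evaluate(m)[0] for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = Chromosome(pop[gen_best].copy(), fits[gen_best], evaluate(pop[gen_best])[1])
        trace.append(best.fitness)

    return best, np.array(trace)


# ---------------------------------------------------------------------------
# synthetic tabular generator
# ---------------------------------------------------------------------------


def synthetic_records(
    n: int = 2000,
    n_informative: int = 1,
    n_noise: int = 3,
    seed: int = 0,
    informative_strength: float = 0.85,
) -> tuple[RecordTable, dict]:
    """Draw records from a known naive-Bayes model.

    Two equiprobable classes; each informative binary feature takes value 1
    with probability ``informative_strength`` under class 1 and
    ``1 - informative_strength`` under class 0; noise features are uniform
    over {0, 1, 2} independent of the class. Returns the table and the true
    generating parameters (for parameter-recovery checks).
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    data = {}
    truth: dict = {"prior": {0: 0.5, 1: 0.5}, "conditionals": {}}
    for j in range(n_informative):
        p = np.where(y == 1, informative_strength, 1.0 - informative_strength)
        col = f"inf_{j}"
        data[col] = (rng.random(n) < p).astype(int)
        truth["conditionals"][col] = {
            0: {0: informative_strength, 1: 1.0 - informative_strength},
            1: {0: 1.0 - informative_strength, 1: informative_strength},
        }
    for j in range(n_noise):
        col = f"noise_{j}"
        data[col] = rng.integers(0, 3, size=n)
        truth["conditionals"][col] = {
            c: {v: 1.0 / 3.0 for v in range(3)} for c in (0, 1)
        }
    data["disease"] = y
    return RecordTable(pd.DataFrame(data), "disease"), truth
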