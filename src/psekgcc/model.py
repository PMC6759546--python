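"""Random-forest base predictors, the ten-member weighted ensemble, the
genetic-algorithm weight optimiser, and OOB permutation importance.

The base classifier is scikit-learn's RandomForestClassifier with 600 trees,
sqrt feature subsampling, min_samples_leaf=1, min_samples_split=2 and gini
impurity. A predicted probability is the mean of per-tree class-probability
estimates (sklearn's convention), not a hard-vote fraction.

The ensemble fuses exactly ten base predictors, each built from a different
encoder parameter set, through the score ss = sum_i q_i * P_i with weights
q on the probability simplex (q_i >= 0, sum q_i = 1). A sequence is called a
replication origin iff ss > 0.5 (strictly). The weights are fitted by a
small real-valued genetic algorithm on out-of-fold member probabilities,
with the AUC of the fused scores as fitness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .features import PsekgccParams, encode_matrix
from .seqio import DnaRecord

logger = logging.getLogger(__name__)

N_MEMBERS = 10
BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters; defaults follow the published setting."""

    n_trees: int = 600
    max_features: str = "sqrt"
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    criterion: str = "gini"
    seed: int = 0

    def make_estimator(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            criterion=self.criterion,
            random_state=self.seed,
            bootstrap=True,
            n_jobs=1,
        )


@dataclass
class BasicPredictor:
    """One trained forest plus the encoder parameters it was trained on."""

    forest: RandomForestClassifier
    config: ForestConfig
    params: PsekgccParams | None = None
    cv_score: float | None = None

    @property
    def n_features(self) -> int:
        return self.forest.n_features_in_


def train_forest(
    features: np.ndarray, labels: np.ndarray, config: ForestConfig
) -> BasicPredictor:
    """Fit one forest; deterministic given ``config.seed``.

    Both classes must be present and features must be finite.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ValueError(
            f"{features.shape[0]} feature rows but {labels.shape[0]} labels"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain NaN or infinite values")
    forest = config.make_estimator()
    forest.fit(features, labels)
    return BasicPredictor(forest=forest, config=config)


def predict_proba(model: BasicPredictor, features: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row (mean of per-tree estimates)."""
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {features.shape[1]}"
        )
    pos_col = int(np.where(model.forest.classes_ == 1)[0][0])
    return model.forest.predict_proba(features)[:, pos_col]


def fuse_scores(probabilities: np.ndarray, weights: np.ndarray) -> np.ndarray | float:
    """Fusion score ss = sum_i q_i P_i over exactly ten member probabilities.

    ``probabilities`` is a length-10 vector (one sample) or an (n, 10) matrix;
    weights must lie on the 10-simplex.
    """
    P = np.asarray(probabilities, dtype=float)
    q = np.asarray(weights, dtype=float)
    if q.shape != (N_MEMBERS,):
        raise ValueError(f"weights must have length {N_MEMBERS}, got {q.shape}")
    if P.shape[-1] != N_MEMBERS:
        raise ValueError(
            f"probabilities must have {N_MEMBERS} columns, got {P.shape[-1]}"
        )
    if np.any(q < -1e-12) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    out = P @ q
    return float(out) if P.ndim == 1 else out


def classify(score: np.ndarray | float, threshold: float = 0.5) -> np.ndarray | int:
    """Label origin (1) iff score > threshold, strictly; score == threshold is 0."""
    arr = np.asarray(score, dtype=float)
    labels = (arr > threshold).astype(int)
    return int(labels) if np.isscalar(score) or arr.ndim == 0 else labels


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings for the weight search."""

    population: int = 50
    generations: int = 100
    tournament: int = 3
    blend_alpha: float = 0.5
    mutation_sigma: float = 0.05
    crossover_prob: float = 0.7
    mutation_prob: float = 0.3
    seed: int = 0


def optimize_weights_ga(
    member_probs: np.ndarray, labels: np.ndarray, ga_config: GaConfig | None = None
) -> tuple[np.ndarray, float]:
    """Search the 10-simplex for weights maximising the AUC of the fused
    out-of-fold scores.

    Chromosomes are real-valued and projected back to the simplex after blend
    crossover and Gaussian mutation; selection is tournament (size 3). The
    uniform vector and all ten one-hot vectors are injected into generation 0,
    so the result is never worse than any single member or the plain mean.
    Deterministic given ``ga_config.seed``. Returns (weights, achieved AUC).
    """
    cfg = ga_config or GaConfig()
    P = np.asarray(member_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if P.ndim != 2 or P.shape[1] < N_MEMBERS:
        raise ValueError(
            f"need an (n, {N_MEMBERS}) out-of-fold probability matrix, got {P.shape}"
        )
    if P.shape[1] != N_MEMBERS:
        raise ValueError(f"expected exactly {N_MEMBERS} members, got {P.shape[1]}")
    rng = np.random.default_rng(cfg.seed)

    def fitness(q: np.ndarray) -> float:
        return roc_auc_score(y, P @ q)

    pop = [project_to_simplex(rng.random(N_MEMBERS)) for _ in range(cfg.population)]
    pop[0] = np.full(N_MEMBERS, 1.0 / N_MEMBERS)
    for i in range(N_MEMBERS):
        onehot = np.zeros(N_MEMBERS)
        onehot[i] = 1.0
        pop[1 + i] = onehot
    fits = np.array([fitness(q) for q in pop])

    for _ in range(cfg.generations):
        new_pop: list[np.ndarray] = []
        while len(new_pop) < cfg.population:
            idx = rng.integers(0, cfg.population, cfg.tournament)
            parent1 = pop[idx[np.argmax(fits[idx])]]
            idx = rng.integers(0, cfg.population, cfg.tournament)
            parent2 = pop[idx[np.argmax(fits[idx])]]
            if rng.random() < cfg.crossover_prob:
                gamma = (1 + 2 * cfg.blend_alpha) * rng.random(N_MEMBERS) - cfg.blend_alpha
                child = (1 - gamma) * parent1 + gamma * parent2
            else:
                child = parent1.copy()
            if rng.random() < cfg.mutation_prob:
                child = child + rng.normal(0.0, cfg.mutation_sigma, N_MEMBERS)
            new_pop.append(project_to_simplex(child))
        new_fits = np.array([fitness(q) for q in new_pop])
        # elitism: keep the best individual seen so far
        best = int(np.argmax(fits))
        worst = int(np.argmin(new_fits))
        if fits[best] > new_fits[worst]:
            new_pop[worst] = pop[best]
            new_fits[worst] = fits[best]
        pop, fits = new_pop, new_fits

    best = int(np.argmax(fits))
    return pop[best], float(fits[best])


def _tree_oob_indices(tree_seed: int, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices for one tree, reconstructed from its seed.

    Reproduces the bootstrap draw scikit-learn uses (a RandomState seeded per
    tree drawing n_samples indices with replacement); falls back to the local
    reconstruction if sklearn's internal helper is unavailable.
    """
    try:
        from sklearn.ensemble._forest import _generate_unsampled_indices

        return _generate_unsampled_indices(tree_seed, n_samples, n_samples)
    except Exception:  # pragma: no cover - exercised only on other versions
        rs = np.random.RandomState(tree_seed)
        sampled = rs.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.nonzero(mask)[0]


def mda_importance(
    model: BasicPredictor,
    features: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean Decrease Accuracy per feature, in percentage points.

    For each tree: the accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature's values among those same OOB
    samples; the drop is averaged over trees and over ``n_repeats``
    independent permutations. ``features``/``labels`` must be the data the
    forest was trained on.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(d)
    n_terms = 0
    for tree in model.forest.estimators_:
        oob = _tree_oob_indices(tree.random_state, n)
        if oob.size == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        for v in range(d):
            for _ in range(n_repeats):
                X_perm = X_oob.copy()
                X_perm[:, v] = X_perm[rng.permutation(oob.size), v]
                perm_acc = float(np.mean(tree.predict(X_perm) == y_oob))
                drops[v] += (base_acc - perm_acc) / n_repeats
        n_terms += 1
    if n_terms == 0:
        raise ValueError("no tree had out-of-bag samples")
    return 100.0 * drops / n_terms


@dataclass
class EnsembleModel:
    """Ten base predictors (ordered best CV score first) with fusion weights."""

    members: list[BasicPredictor]
    weights: np.ndarray
    threshold: float = 0.5
    ga_fitness: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValueError(f"ensemble needs exactly {N_MEMBERS} members")
        q = np.asarray(self.weights, dtype=float)
        if q.shape != (N_MEMBERS,) or np.any(q < -1e-12) or abs(q.sum() - 1) > 1e-9:
            raise ValueError("weights must be a length-10 simplex vector")
        self.weights = q

    def member_probabilities(self, records: Sequence[DnaRecord]) -> np.ndarray:
        """(n, 10) matrix of member probabilities, encoding per member params."""
        cols = []
        for m in self.members:
            if m.params is None:
                raise ValueError("ensemble member lacks encoder parameters")
            X = encode_matrix(records, m.params).to_numpy()
            cols.append(predict_proba(m, X))
        return np.column_stack(cols)

    def predict_scores(self, records: Sequence[DnaRecord]) -> np.ndarray:
        return fuse_scores(self.member_probabilities(records), self.weights)

    def predict(self, records: Sequence[DnaRecord]) -> np.ndarray:
        return classify(self.predict_scores(records), self.threshold)

    def save(self, bundle_dir: str | Path) -> None:
        """Persist as a bundle directory: JSON manifest + joblib forests."""
        bundle = Path(bundle_dir)
        bundle.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "threshold": self.threshold,
            "weights": self.weights.tolist(),
            "ga_fitness": self.ga_fitness,
            "metadata": self.metadata,
            "members": [
                {
                    "file": f"member_{i:02d}.joblib",
                    "params": {
                        "epsilon": m.params.epsilon,
                        "delta": m.params.delta,
                        "k": m.params.k,
                        "lam": m.params.lam,
                        "w": m.params.w,
                    },
                    "cv_score": m.cv_score,
                    "forest_seed": m.config.seed,
                    "n_trees": m.config.n_trees,
                }
                for i, m in enumerate(self.members)
            ],
        }
        (bundle / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for i, m in enumerate(self.members):
            joblib.dump(m.forest, bundle / f"member_{i:02d}.joblib")

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "EnsembleModel":
        bundle = Path(bundle_dir)
        manifest = json.loads((bundle / "manifest.json").read_text())
        if manifest["format_version"] != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported bundle format {manifest['format_version']}"
            )
        members = []
        for entry in manifest["members"]:
            forest = joblib.load(bundle / entry["file"])
            members.append(
                BasicPredictor(
                    forest=forest,
                    config=ForestConfig(
                        n_trees=entry["n_trees"], seed=entry["forest_seed"]
                    ),
                    params=PsekgccParams(**entry["params"]),
                    cv_score=entry["cv_score"],
                )
            )
        return cls(
            members=members,
            weights=np.array(manifest["weights"]),
            threshold=manifest["threshold"],
            ga_fitness=manifest.get("ga_fitness"),
            metadata=manifest.get("metadata", {}),
        )


def train_ensemble(
    records: Sequence[DnaRecord],
    labels: np.ndarray,
    member_params: Sequence[PsekgccParams],
    forest_config: ForestConfig | None = None,
    ga_config: GaConfig | None = None,
    cv_seed: int = 0,
    n_folds: int = 5,
) -> EnsembleModel:
    """Build the full ensemble from ten encoder parameter sets.

    Each member is scored by stratified ``n_folds``-fold out-of-fold AUC;
    members are ordered best first; the GA then fits fusion weights on the
    out-of-fold probability matrix, and final forests are trained on all data.
    """
    from sklearn.model_selection import StratifiedKFold

    if len(member_params) != N_MEMBERS:
        raise ValueError(f"need exactly {N_MEMBERS} member parameter sets")
    fc = forest_config or ForestConfig()
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)

    oof = np.zeros((len(records), N_MEMBERS))
    aucs = []
    matrices = []
    for i, params in enumerate(member_params):
        X = encode_matrix(records, params).to_numpy()
        matrices.append(X)
        for tr, te in skf.split(X, y):
            member = train_forest(X[tr], y[tr], fc)
            oof[te, i] = predict_proba(member, X[te])
        aucs.append(roc_auc_score(y, oof[:, i]))

    order = np.argsort(-np.asarray(aucs), kind="stable")
    oof = oof[:, order]
    weights, fitness = optimize_weights_ga(oof, y, ga_config)

    members = []
    for rank, idx in enumerate(order):
        member = train_forest(matrices[idx], y, fc)
        member.params = member_params[idx]
        member.cv_score = float(aucs[idx])
        members.append(member)
    logger.info("ensemble trained: member AUCs %s, GA fitness %.4f",
                [f"{a:.3f}" for a in sorted(aucs, reverse=True)], fitness)
    return EnsembleModel(members=members, weights=weights, ga_fitness=fitness)
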