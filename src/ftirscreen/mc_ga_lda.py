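"""Monte Carlo genetic-algorithm LDA ensemble (MC-GA-LDA).

The classifier at the heart of the pipeline.  For each of ``n_models``
Monte Carlo iterations the labelled training patients are re-split into a
stratified calibration/validation pair; a genetic algorithm searches
binary wavenumber masks, scoring each candidate by the validation
misclassification rate of a two-class linear discriminant fitted on the
calibration subset (plus a small parsimony penalty per selected
variable); the best mask's discriminant, refitted on that iteration's
calibration subset, becomes one ensemble member.  One hundred such
models, each on its own wavenumber subset, vote at prediction time.

The per-wavenumber count of models selecting each variable — the
selection-frequency profile — is the ensemble's interpretability output:
with class differences planted at known bands it should concentrate
there.

LDA details: pooled within-class covariance (unbiased, n-2 denominator)
with a diagonal shrinkage safeguard so the discriminant stays well-posed
when selected variables approach or exceed the calibration sample count;
weights w = S^-1 (mu1 - mu0) and equal-priors bias placing the decision
boundary at the midpoint of the projected class means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import PreprocConfig, dataset_matrix, preprocess_dataset
from .spectra_io import SpectralDataset

#: condition-number ceiling for the (shrunk) pooled covariance
MAX_CONDITION = 1e8

ENSEMBLE_FORMAT_VERSION = 1


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Stratified 70/30 split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split(patients, cfg: SplitConfig):
    """Split labelled patients into (train_ids, test_ids).

    Per class, round-half-up(train_fraction * n_class) patients go to the
    train side; the split is disjoint, exhaustive and deterministic for a
    fixed seed.  A 50/50 cohort of 100 at 0.70 therefore yields 35+35
    train and 15+15 test.
    """
    by_class: dict[str, list] = {}
    for p in patients:
        label = p.label if hasattr(p, "label") else p[1]
        pid = p.patient_id if hasattr(p, "patient_id") else p[0]
        if label not in ("positive", "negative"):
            raise ValueError(f"patient {pid} is unlabelled")
        by_class.setdefault(label, []).append(pid)
    if cfg.stratified and len(by_class) < 2:
        raise ValueError("stratified split needs both classes present")

    rng = np.random.default_rng(cfg.seed)
    train, test = [], []
    if cfg.stratified:
        groups = [ids for _, ids in sorted(by_class.items())]
    else:
        groups = [sorted(pid for ids in by_class.values() for pid in ids)]
    for ids in groups:
        ids = sorted(ids)
        n_train = _round_half_up(cfg.train_fraction * len(ids))
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# Two-class LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """A fitted two-class linear discriminant on a wavenumber subset.

    ``score(x) = w . x[variable_indices] + b``; positive score calls the
    positive class.  The boundary sits at the midpoint of the projected
    class means (equal priors).
    """

    variable_indices: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    pooled_cov: np.ndarray
    w: np.ndarray
    b: float
    gamma: float = 0.0
    sub_seed: int | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores for rows of X on the full variable grid."""
        X = np.atleast_2d(X)
        return X[:, self.variable_indices] @ self.w + self.b

    def to_dict(self) -> dict:
        return {
            "variable_indices": self.variable_indices.tolist(),
            "mu0": self.mu0.tolist(),
            "mu1": self.mu1.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "gamma": self.gamma,
            "sub_seed": self.sub_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LdaModel":
        return cls(
            variable_indices=np.asarray(d["variable_indices"], dtype=int),
            mu0=np.asarray(d["mu0"], dtype=float),
            mu1=np.asarray(d["mu1"], dtype=float),
            pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            gamma=float(d.get("gamma", 0.0)),
            sub_seed=d.get("sub_seed"),
        )


def _shrink_gamma(n_samples: int, k: int) -> float:
    """Fixed shrinkage rule: no shrinkage while calibration samples
    comfortably exceed dimensionality, otherwise 0.1 toward the
    diagonal (further loading is added only if conditioning demands)."""
    return 0.0 if n_samples > 3 * k else 0.1


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    variable_indices: np.ndarray | None = None,
    gamma: float | None = None,
) -> LdaModel:
    """Fit the two-class discriminant on X (samples x selected variables).

    ``variable_indices`` records which columns of the *full* grid the
    columns of X correspond to (identity if omitted).  Shrinkage gamma
    follows the fixed rule unless given explicitly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_lda requires exactly two classes in y")
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 samples")
    n, k = X.shape
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n - 2)

    g = _shrink_gamma(n, k) if gamma is None else float(gamma)
    Ssh = (1.0 - g) * S + g * np.diag(np.diag(S))

    # escalate diagonal loading until the covariance is invertible and
    # acceptably conditioned
    loading = 0.0
    scale = float(np.mean(np.diag(Ssh))) or 1.0
    while True:
        M = Ssh + loading * scale * np.eye(k)
        try:
            cond = np.linalg.cond(M)
            if np.isfinite(cond) and cond <= MAX_CONDITION:
                break
        except np.linalg.LinAlgError:
            pass
        loading = 1e-8 if loading == 0.0 else loading * 10.0
        if loading > 1.0:
            M = Ssh + scale * np.eye(k)
            break

    w = np.linalg.solve(M, mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    idx = (
        np.arange(k, dtype=int)
        if variable_indices is None
        else np.asarray(sorted(variable_indices), dtype=int)
    )
    return LdaModel(idx, mu0, mu1, M, w, b, gamma=g)


# ---------------------------------------------------------------------------
# Genetic-algorithm variable selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 40
    k_min: int = 5
    k_max: int = 30
    crossover_rate: float = 0.6
    mutation_rate: float = 0.01
    elitism: int = 2
    parsimony_weight: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_min > self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0 or self.elitism < 0:
            raise ValueError("generations and elitism must be >= 0")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "generations": self.generations,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "crossover_rate": self.crossover_rate,
            "mutation_rate": self.mutation_rate,
            "elitism": self.elitism,
            "parsimony_weight": self.parsimony_weight,
            "seed": self.seed,
        }


def _repair_mask(mask: np.ndarray, k_min: int, k_max: int, rng) -> np.ndarray:
    """Force the selected-variable count into [k_min, k_max] by random
    add/drop."""
    k = int(mask.sum())
    if k < k_min:
        off = np.flatnonzero(~mask)
        mask[rng.choice(off, size=k_min - k, replace=False)] = True
    elif k > k_max:
        on = np.flatnonzero(mask)
        mask[rng.choice(on, size=k - k_max, replace=False)] = False
    return mask


def ga_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: GAConfig,
) -> np.ndarray:
    """Search binary wavenumber masks with a genetic algorithm.

    Fitness (minimized) = validation misclassification rate of the LDA
    fitted on the calibration subset + parsimony_weight * k.  Tournament
    selection of size 2, one-point crossover, per-bit mutation, repair to
    [k_min, k_max], elitism.  Returns the best mask's sorted variable
    indices; deterministic under the config seed.
    """
    n_vars = X_cal.shape[1]
    if cfg.k_max > n_vars:
        raise ValueError(f"k_max={cfg.k_max} exceeds available variables ({n_vars})")
    rng = np.random.default_rng(cfg.seed)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key in cache:
            return cache[key]
        idx = np.flatnonzero(mask)
        model = fit_lda(X_cal[:, idx], y_cal)
        pred = (X_val[:, idx] @ model.w + model.b) > 0
        err = float(np.mean(pred.astype(int) != y_val))
        f = err + cfg.parsimony_weight * idx.size
        cache[key] = f
        return f

    # initial population: mask sizes uniform in [k_min, k_max]
    pop = np.zeros((cfg.population_size, n_vars), dtype=bool)
    for i in range(cfg.population_size):
        k = int(rng.integers(cfg.k_min, cfg.k_max + 1))
        pop[i, rng.choice(n_vars, size=k, replace=False)] = True

    fits = np.array([fitness(m) for m in pop])
    best_idx = int(np.argmin(fits))
    best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])

    for _ in range(cfg.generations):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            # tournament selection, size 2 (ties -> lower index)
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, cfg.population_size, size=2)
                parents.append(pop[a if fits[a] <= fits[b] else b].copy())
            c1, c2 = parents
            if rng.random() < cfg.crossover_rate and n_vars > 1:
                cut = int(rng.integers(1, n_vars))
                c1[cut:], c2[cut:] = c2[cut:].copy(), c1[cut:].copy()
            for child in (c1, c2):
                flip = rng.random(n_vars) < cfg.mutation_rate
                child ^= flip
                _repair_mask(child, cfg.k_min, cfg.k_max, rng)
                if not child.any():
                    child[rng.choice(n_vars, size=cfg.k_min, replace=False)] = True
                new_pop.append(child)
        pop = np.vstack(new_pop[: cfg.population_size])
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit, best_mask = float(fits[gen_best]), pop[gen_best].copy()

    return np.flatnonzero(best_mask)


# ---------------------------------------------------------------------------
# Monte Carlo ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McConfig:
    n_models: int = 100
    calibration_fraction: float = 0.8
    seed: int = 0
    refit_on_full_train: bool = False

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "calibration_fraction": self.calibration_fraction,
            "seed": self.seed,
            "refit_on_full_train": self.refit_on_full_train,
        }


@dataclass
class Ensemble:
    """100 (by default) GA-selected LDA models plus their
    selection-frequency profile and full provenance."""

    models: list
    wavenumbers: np.ndarray  # preprocessed (truncated) grid, descending
    preproc: PreprocConfig
    ga: GAConfig
    mc: McConfig
    sub_seeds: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def selection_frequency(self) -> np.ndarray:
        freq = np.zeros(self.wavenumbers.size, dtype=int)
        for m in self.models:
            freq[m.variable_indices] += 1
        return freq

    def scores(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_models) discriminant scores."""
        X = np.atleast_2d(X)
        return np.column_stack([m.score(X) for m in self.models])

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Per sample: fraction of models scoring positive."""
        return (self.scores(X) > 0).mean(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "format_version": ENSEMBLE_FORMAT_VERSION,
            "wavenumbers": self.wavenumbers.tolist(),
            "preproc": self.preproc.to_dict(),
            "ga": self.ga.to_dict(),
            "mc": self.mc.to_dict(),
            "sub_seeds": list(self.sub_seeds),
            "models": [m.to_dict() for m in self.models],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Ensemble":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format_version") != ENSEMBLE_FORMAT_VERSION:
            raise ValueError(f"unsupported ensemble format: {d.get('format_version')}")
        return cls(
            models=[LdaModel.from_dict(m) for m in d["models"]],
            wavenumbers=np.asarray(d["wavenumbers"], dtype=float),
            preproc=PreprocConfig.from_dict(d["preproc"]),
            ga=GAConfig(**d["ga"]),
            mc=McConfig(**d["mc"]),
            sub_seeds=list(d["sub_seeds"]),
        )


def _stratified_subsample(y: np.ndarray, fraction: float, rng):
    """Indices of a stratified without-replacement subsample; the
    complement serves as the validation fold."""
    take = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_take = max(2, _round_half_up(fraction * idx.size))
        n_take = min(n_take, idx.size - 1)  # leave at least one for validation
        take.append(rng.choice(idx, size=n_take, replace=False))
    cal = np.sort(np.concatenate(take))
    val = np.setdiff1d(np.arange(y.size), cal)
    return cal, val


def train_ensemble(
    train_patients: SpectralDataset | list,
    preproc_cfg: PreprocConfig,
    ga_cfg: GAConfig,
    mc_cfg: McConfig,
    quarantined_ids=None,
) -> Ensemble:
    """Train the MC-GA-LDA ensemble on labelled *training* patients only.

    ``quarantined_ids`` (the held-out test ids) are asserted absent from
    the input — the test set stays isolated until training is over.
    Each Monte Carlo iteration draws a fresh stratified calibration/
    validation re-split of the (patient-mean preprocessed) training
    matrix under its own recorded sub-seed, runs the GA on it, and fits
    the final member model on that iteration's calibration subset.
    """
    if isinstance(train_patients, SpectralDataset):
        dataset = train_patients
    else:
        grid = train_patients[0].grid
        dataset = SpectralDataset(list(train_patients), grid)

    ids = [p.patient_id for p in dataset.patients]
    if quarantined_ids:
        leaked = sorted(set(ids) & set(quarantined_ids))
        if leaked:
            raise ValueError(f"test patients leaked into training: {leaked}")

    processed = preprocess_dataset(dataset, preproc_cfg, mode="patient_mean")
    X, y, _ = dataset_matrix(processed)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")

    master = np.random.default_rng(mc_cfg.seed)
    sub_seeds = [int(s) for s in master.integers(0, 2**31, size=mc_cfg.n_models)]

    models = []
    for s in sub_seeds:
        rng = np.random.default_rng(s)
        cal, val = _stratified_subsample(y, mc_cfg.calibration_fraction, rng)
        iter_ga = replace(ga_cfg, seed=int(rng.integers(0, 2**31)))
        idx = ga_select(X[cal], y[cal], X[val], y[val], iter_ga)
        if mc_cfg.refit_on_full_train:
            model = fit_lda(X[:, idx], y, variable_indices=idx)
        else:
            model = fit_lda(X[cal][:, idx], y[cal], variable_indices=idx)
        model.variable_indices = np.asarray(idx, dtype=int)
        model.sub_seed = s
        models.append(model)

    return Ensemble(
        models=models,
        wavenumbers=processed.grid.values.copy(),
        preproc=preproc_cfg,
        ga=ga_cfg,
        mc=mc_cfg,
        sub_seeds=sub_seeds,
    )
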