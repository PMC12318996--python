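"""Characteristic-wavelength selection: SPA, GA, PSO and BOSS.

All four selectors wrap the same cheap, deterministic fitness — stratified
cross-validated PLS-DA accuracy on the candidate band subset, minus a size
penalty ``lam * |subset| / B`` for the population methods — and return a
:class:`WavelengthSubset` carrying the chosen band indices, their nm
values, the per-iteration best-fitness trace and the seed, so a selection
is fully reproducible from its metadata.

* SPA (successive projections algorithm) grows chains of maximally
  orthogonal columns from every candidate start and picks the chain/length
  with the best cross-validated accuracy — it favours few, decorrelated
  bands.
* GA evolves binary band masks with tournament selection, uniform
  crossover, bit-flip mutation and elitism.
* PSO moves a swarm of binary masks with a sigmoid-derived flip-probability
  velocity transfer (zero velocity leaves a particle frozen).
* BOSS (bootstrapping soft shrinkage) accumulates normalised absolute PLS
  coefficients over bootstrap sub-models and re-samples bands with soft-
  shrunk inclusion weights, keeping the round with the best accuracy.

The selector hyperparameter defaults are conventional values, recorded in
each result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemometrics import PLSDA, _fit_raw, plsda_predict
from .ingest import LabeledSpectra
from .selstm import EvalReport, SELSTMConfig, SplitSpec, evaluate, stratified_split, train_selstm

__all__ = [
    "WavelengthSubset",
    "spa_chain",
    "spa_select",
    "ga_select",
    "pso_select",
    "boss_select",
    "fit_simplified_model",
    "SimplifiedModelReport",
]


@dataclass
class WavelengthSubset:
    """A selected band subset with provenance (method, seed, fitness trace)."""

    method: str
    indices: np.ndarray
    wavelengths_nm: np.ndarray
    fitness_trace: list[float]
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size and (np.unique(idx).size != idx.size or np.any(np.diff(np.sort(idx)) == 0)):
            raise ValueError("indices must be unique")
        self.indices = np.sort(idx)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)

    def __len__(self) -> int:
        return self.indices.size

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "indices": self.indices.tolist(),
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "fitness_trace": list(map(float, self.fitness_trace)),
            **{k: v for k, v in self.extras.items() if np.isscalar(v) or isinstance(v, str)},
        }


# ---------------------------------------------------------------------------
# shared fitness: cross-validated PLS-DA accuracy on a band subset
# ---------------------------------------------------------------------------


def _make_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified fold assignment, fixed once per selector run."""
    y = np.asarray(y)
    assign = np.empty(y.size, dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        assign[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(assign == f) for f in range(n_folds)]


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    band_idx: np.ndarray,
    folds: list[np.ndarray],
    n_components: int,
) -> float:
    """Fraction correct of PLS-DA restricted to ``band_idx`` under fixed folds."""
    band_idx = np.asarray(band_idx)
    if band_idx.size == 0:
        return 0.0
    classes = np.unique(y)
    k = int(min(n_components, band_idx.size, X.shape[0] - 1))
    correct = 0
    for f, te in enumerate(folds):
        tr = np.concatenate([folds[g] for g in range(len(folds)) if g != f])
        model = _fit_raw(X[np.ix_(tr, band_idx)], y[tr], classes, k)
        correct += int(np.sum(plsda_predict(model, X[np.ix_(te, band_idx)]) == y[te]))
    return correct / X.shape[0]


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


def spa_chain(X: np.ndarray, start: int, k: int, tol: float = 1e-12) -> np.ndarray:
    """Greedy projection chain: from ``start``, repeatedly add the column with
    the largest residual after projection onto the span of the chain.

    Columns whose residual norm is below ``tol`` (e.g. duplicates of an
    already-chosen column) are never added; the chain stops early at the
    rank of X.
    """
    X = np.asarray(X, dtype=np.float64)
    n, B = X.shape
    chain = [int(start)]
    q = X[:, start].astype(np.float64)
    nq = np.linalg.norm(q)
    if nq < tol:
        raise ValueError(f"start column {start} is numerically zero")
    Q = (q / nq)[:, None]
    R = X - Q @ (Q.T @ X)  # residuals of all columns
    while len(chain) < k:
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= tol:
            break
        chain.append(j)
        q = R[:, j] / norms[j]
        Q = np.hstack([Q, q[:, None]])
        R = R - q[:, None] * (q @ R)[None, :]
    return np.array(chain, dtype=np.int64)


def spa_select(
    X: np.ndarray,
    labels: np.ndarray,
    k_min: int = 3,
    k_max: int | None = None,
    wavelengths: np.ndarray | None = None,
    n_components: int = 5,
    cv_folds: int = 3,
    seed: int = 0,
    max_starts: int | None = None,
) -> WavelengthSubset:
    """Successive projections algorithm with CV-chosen chain length.

    Chains are grown from each candidate start column (all columns, or a
    seeded sample of ``max_starts``); every prefix length in
    [k_min, k_max] is scored by cross-validated PLS-DA accuracy and the
    best (accuracy, then fewer bands, then lower start index) wins.
    X with rank below ``k_min`` cannot supply a valid chain and is
    rejected.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    n, B = X.shape
    if k_max is None:
        k_max = min(25, B)
    if k_max > B:
        raise ValueError(f"k_max {k_max} exceeds band count {B}")
    if k_min < 1 or k_min > k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got {k_min}..{k_max}")
    Xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, cv_folds, rng)
    starts = np.arange(B)
    if max_starts is not None and max_starts < B:
        starts = np.sort(rng.choice(B, size=max_starts, replace=False))
    best = None  # (negacc, k, start, chain_prefix, trace)
    for start in starts:
        if np.linalg.norm(Xc[:, start]) < 1e-12:
            continue
        chain = spa_chain(Xc, start, k_max)
        if chain.size < k_min:
            continue
        trace = []
        for k in range(k_min, chain.size + 1):
            acc = _cv_accuracy(X, y, chain[:k], folds, n_components)
            trace.append(acc)
            cand = (-acc, k, int(start), chain[:k], trace.copy())
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        raise ValueError(f"X is rank-deficient below k_min={k_min}; no valid SPA chain")
    _, k, start, chain, trace = best
    wl = np.asarray(wavelengths) if wavelengths is not None else np.arange(B, dtype=float)
    return WavelengthSubset(
        method="SPA",
        indices=chain,
        wavelengths_nm=wl[np.sort(chain)],
        fitness_trace=trace,
        seed=seed,
        extras={"start": start, "k": int(k)},
    )


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_select(
    X: np.ndarray,
    labels: np.ndarray,
    population: int = 50,
    generations: int = 100,
    crossover: float = 0.8,
    mutation: float = 0.02,
    lam: float = 0.2,
    wavelengths: np.ndarray | None = None,
    n_components: int = 5,
    cv_folds: int = 3,
    seed: int = 0,
    init_population: np.ndarray | None = None,
) -> WavelengthSubset:
    """Genetic algorithm over binary band masks.

    Fitness = CV PLS-DA accuracy − lam * |subset| / B.  Tournament
    selection (size 3), uniform crossover, bit-flip mutation, one elite
    carried unchanged per generation — so the best-fitness trace is
    non-decreasing.  Zero-band offspring are repaired to one random band.
    """
    if population < 2:
        raise ValueError(f"population must be >= 2, got {population}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    B = X.shape[1]
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, cv_folds, rng)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            idx = np.flatnonzero(mask)
            cache[key] = _cv_accuracy(X, y, idx, folds, n_components) - lam * idx.size / B
        return cache[key]

    if init_population is not None:
        pop = np.asarray(init_population, dtype=bool).copy()
        if pop.shape != (population, B):
            raise ValueError(f"init_population must be ({population}, {B})")
    else:
        pop = rng.random((population, B)) < 0.3
    pop = np.array([_repair(m, rng) for m in pop])
    fits = np.array([fitness(m) for m in pop])
    trace = [float(fits.max())]
    for _ in range(generations):
        elite = pop[int(np.argmax(fits))].copy()
        children = [elite]
        while len(children) < population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(population, size=3)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents
            if rng.random() < crossover:
                swap = rng.random(B) < 0.5
                child = np.where(swap, a, b)
            else:
                child = a.copy()
            flip = rng.random(B) < mutation
            child = np.logical_xor(child, flip)
            children.append(_repair(child, rng))
        pop = np.array(children[:population])
        fits = np.array([fitness(m) for m in pop])
        trace.append(float(fits.max()))
    best = pop[int(np.argmax(fits))]
    idx = np.flatnonzero(best)
    wl = np.asarray(wavelengths) if wavelengths is not None else np.arange(B, dtype=float)
    return WavelengthSubset(
        method="GA", indices=idx, wavelengths_nm=wl[idx], fitness_trace=trace, seed=seed,
        extras={"lam": lam, "population": population, "generations": generations},
    )


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------


def pso_select(
    X: np.ndarray,
    labels: np.ndarray,
    swarm: int = 30,
    iterations: int = 100,
    inertia: tuple[float, float] = (0.9, 0.4),
    cognitive: float = 2.0,
    social: float = 2.0,
    lam: float = 0.2,
    vmax: float = 4.0,
    wavelengths: np.ndarray | None = None,
    n_components: int = 5,
    cv_folds: int = 3,
    seed: int = 0,
    init_positions: np.ndarray | None = None,
) -> WavelengthSubset:
    """Binary particle swarm over band masks, same fitness as the GA.

    Velocities follow the standard update with linearly decaying inertia;
    the bit-flip probability is the sigmoid-derived transfer
    ``|2 sigmoid(v) − 1|``, so zero velocity (e.g. all weights zero)
    leaves a particle exactly where it is.  The global-best trace is
    non-decreasing by construction.
    """
    if swarm < 2:
        raise ValueError(f"swarm must be >= 2, got {swarm}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    B = X.shape[1]
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, cv_folds, rng)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            idx = np.flatnonzero(mask)
            cache[key] = _cv_accuracy(X, y, idx, folds, n_components) - lam * idx.size / B
        return cache[key]

    if init_positions is not None:
        pos = np.asarray(init_positions, dtype=bool).copy()
        if pos.shape != (swarm, B):
            raise ValueError(f"init_positions must be ({swarm}, {B})")
    else:
        pos = rng.random((swarm, B)) < 0.3
    pos = np.array([_repair(m, rng) for m in pos])
    vel = np.zeros((swarm, B))
    fits = np.array([fitness(m) for m in pos])
    pbest, pbest_fit = pos.copy(), fits.copy()
    g = int(np.argmax(fits))
    gbest, gbest_fit = pos[g].copy(), float(fits[g])
    trace = [gbest_fit]
    w_hi, w_lo = inertia
    for it in range(iterations):
        w = w_hi + (w_lo - w_hi) * (it / max(iterations - 1, 1))
        r1 = rng.random((swarm, B))
        r2 = rng.random((swarm, B))
        vel = (
            w * vel
            + cognitive * r1 * (pbest.astype(float) - pos.astype(float))
            + social * r2 * (gbest.astype(float)[None, :] - pos.astype(float))
        )
        np.clip(vel, -vmax, vmax, out=vel)
        flip_prob = np.abs(2.0 / (1.0 + np.exp(-vel)) - 1.0)
        flips = rng.random((swarm, B)) < flip_prob
        pos = np.logical_xor(pos, flips)
        pos = np.array([_repair(m, rng) for m in pos])
        fits = np.array([fitness(m) for m in pos])
        improved = fits > pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fits[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)
    idx = np.flatnonzero(gbest)
    wl = np.asarray(wavelengths) if wavelengths is not None else np.arange(B, dtype=float)
    return WavelengthSubset(
        method="PSO", indices=idx, wavelengths_nm=wl[idx], fitness_trace=trace, seed=seed,
        extras={"lam": lam, "swarm": swarm, "iterations": iterations},
    )


# ---------------------------------------------------------------------------
# BOSS
# ---------------------------------------------------------------------------


def boss_select(
    X: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 500,
    n_rounds: int = 30,
    wavelengths: np.ndarray | None = None,
    n_components: int = 5,
    cv_folds: int = 3,
    seed: int = 0,
) -> WavelengthSubset:
    """Bootstrapping soft shrinkage.

    Each round fits ``n_bootstrap`` PLS-DA sub-models on bootstrap sample
    draws and weighted band draws, accumulates the normalised absolute
    regression coefficients into band weights (the weights sum to 1 after
    every round), and soft-shrinks the candidate set to the top-weighted
    bands on an exponentially decaying size schedule.  The round whose
    candidate subset scores the best cross-validated accuracy wins.
    Constant (zero-variance) bands are removed before weighting and
    reported in the result metadata.
    """
    if n_bootstrap < 2:
        raise ValueError(f"n_bootstrap must be >= 2, got {n_bootstrap}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    n, B = X.shape
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, cv_folds, rng)

    variances = X.var(axis=0)
    alive = np.flatnonzero(variances > 0)
    degenerate = np.flatnonzero(variances == 0)

    weights = np.zeros(B)
    weights[alive] = 1.0 / alive.size
    # size schedule: from all live bands down to n_components over the rounds
    ratio = (max(n_components, 2) / alive.size) ** (1.0 / max(n_rounds - 1, 1))
    current = alive.copy()
    best = None  # (acc, -round, subset)
    trace: list[float] = []
    weight_sums: list[float] = []
    for r in range(n_rounds):
        acc_w = np.zeros(B)
        for _ in range(n_bootstrap):
            rows = rng.integers(n, size=n)
            if np.unique(y[rows]).size < 2:
                continue
            p = weights[current]
            p = p / p.sum()
            draw = np.unique(rng.choice(current, size=current.size, p=p))
            if draw.size < 2:
                continue
            k = int(min(n_components, draw.size, n - 1))
            Xb = X[np.ix_(rows, draw)]
            model = _fit_raw(Xb, y[rows], classes, k)
            coef = np.abs(np.asarray(model.coef_))  # (n_targets, n_draw)
            coef = coef.sum(axis=0)
            # standardised magnitude: coefficient x band spread, so bands are
            # comparable regardless of their raw variance
            coef = coef * Xb.std(axis=0)
            s = coef.sum()
            if s > 0:
                acc_w[draw] += coef / s
        total = acc_w.sum()
        if total == 0:
            break
        weights = acc_w / total  # normalises to 1 every round
        weight_sums.append(float(weights.sum()))
        n_keep = max(int(round(alive.size * ratio ** (r + 1))), max(n_components, 2))
        n_keep = min(n_keep, int(np.count_nonzero(weights)))
        current = np.sort(np.argsort(weights)[::-1][:n_keep])
        acc = _cv_accuracy(X, y, current, folds, n_components)
        trace.append(acc)
        if best is None or acc > best[0]:
            best = (acc, r, current.copy())
    if best is None:
        raise ValueError("BOSS found no usable sub-models (degenerate data?)")
    idx = best[2]
    wl = np.asarray(wavelengths) if wavelengths is not None else np.arange(B, dtype=float)
    return WavelengthSubset(
        method="BOSS", indices=idx, wavelengths_nm=wl[np.sort(idx)],
        fitness_trace=trace, seed=seed,
        extras={
            "n_bootstrap": n_bootstrap,
            "n_rounds": n_rounds,
            "best_round": int(best[1]),
            "degenerate_bands": degenerate.tolist(),
            "weight_sums": weight_sums,
            "final_weights": weights,
        },
    )


# ---------------------------------------------------------------------------
# simplified models on the selected bands
# ---------------------------------------------------------------------------


@dataclass
class SimplifiedModelReport:
    """Simplified-model accuracies: calibration, cross-validation, prediction."""

    subset: WavelengthSubset
    model_kind: str
    report: EvalReport
    accuracy_cv: float

    def summary(self) -> str:
        return (
            f"{self.subset.method} subset ({len(self.subset)} bands), "
            f"{self.model_kind}:\n{self.report.summary()}\n"
            f"cross-validation accuracy: {self.accuracy_cv:.2f}%"
        )


def fit_simplified_model(
    data: LabeledSpectra,
    subset: WavelengthSubset | np.ndarray,
    model_kind: str = "plsda",
    config: SELSTMConfig | None = None,
    split: SplitSpec = SplitSpec(),
    n_components: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
) -> SimplifiedModelReport:
    """Retrain a classifier on the selected bands only.

    Reports calibration, k-fold cross-validation and prediction accuracy.
    With the subset equal to all bands this reproduces the full-wavelength
    model bit for bit (same seed).  An empty subset is an error.
    """
    idx = subset.indices if isinstance(subset, WavelengthSubset) else np.asarray(subset)
    if idx.size == 0:
        raise ValueError("empty wavelength subset")
    sub = data.subset(bands=idx)
    y = sub.class_codes()
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, cv_folds, rng)

    if model_kind == "plsda":
        cal, pred = stratified_split(y, split)
        k = int(min(n_components, idx.size, cal.size - 1))
        model = _fit_raw(sub.X[cal], y[cal], np.unique(y), k)
        report = evaluate(
            _PLSDAProba(model), (sub.X[cal], y[cal]), (sub.X[pred], y[pred])
        )
        acc_cv = 100.0 * _cv_accuracy(sub.X, y, np.arange(idx.size), folds, n_components)
    elif model_kind == "selstm":
        cfg = config or SELSTMConfig()
        cfg = _adapt_config(cfg, idx.size)
        model, report, _ = train_selstm(cfg, sub, split)
        accs = []
        for f, te in enumerate(folds):
            tr = np.concatenate([folds[g] for g in range(cv_folds) if g != f])
            m_f, _, _ = train_selstm(cfg, (sub.X[tr], y[tr]), SplitSpec(0.9, split.seed))
            accs.append(float(np.mean(m_f.predict(sub.X[te]) == y[te])))
        acc_cv = 100.0 * float(np.mean(accs))
    else:
        raise ValueError(f"unknown model kind {model_kind!r} (plsda|selstm)")
    ws = subset if isinstance(subset, WavelengthSubset) else WavelengthSubset(
        method="manual", indices=idx, wavelengths_nm=data.wavelengths[idx],
        fitness_trace=[], seed=seed,
    )
    return SimplifiedModelReport(subset=ws, model_kind=model_kind, report=report,
                                 accuracy_cv=acc_cv)


def _adapt_config(cfg: SELSTMConfig, n_bands: int) -> SELSTMConfig:
    from dataclasses import replace

    r = cfg.reduction_ratio
    while r > 1 and n_bands % r != 0:
        r -= 1
    return replace(cfg, n_bands=n_bands, reduction_ratio=max(r, 1))


class _PLSDAProba:
    """Adapter: PLS-DA responses as softmax-free pseudo-probabilities for evaluate()."""

    def __init__(self, model: PLSDA):
        self.model = model

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        scores = self.model.pls.predict(np.asarray(X, dtype=np.float64))
        # shift/normalise responses onto the simplex for the CE metric
        scores = scores - scores.min(axis=1, keepdims=True) + 1e-9
        return scores / scores.sum(axis=1, keepdims=True)
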