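"""Shapley-value attribution of wavelength contributions.

The attribution follows the interventional (marginal) game: the value of a
coalition S of bands for a sample x is the expected model output when the
bands in S keep x's values and every other band is replaced by a background
sample,

    v(S) = E_b [ f(x_S, b_{not S}) ],

and a band's Shapley value is the coalition-weighted average of its
marginal contributions

    phi_j = sum_{S not containing j} |S|! (d-|S|-1)! / d!  (v(S+j) - v(S)).

Exact mode enumerates all 2^d coalitions (feasible for d <= 15 single
bands, or for contiguous band *groups* on a full 256-band spectrum);
sampling mode estimates the same quantity by seeded permutation sampling
with a reported Monte-Carlo error.  Both satisfy local accuracy
(sum_j phi_j = f(x) - E_b f(b)), symmetry and the dummy axiom, which the
test suite checks against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributionResult",
    "shapley_attribute",
    "make_band_groups",
    "global_importance",
    "per_class_summary",
]


@dataclass
class AttributionResult:
    """Per-sample, per-band, per-class Shapley values plus base values."""

    shap_values: np.ndarray  # samples x bands x classes
    base_values: np.ndarray  # classes
    X: np.ndarray  # the attributed samples
    predictions: np.ndarray  # samples x classes, f(X)
    mode: str
    background_spec: str
    seed: int | None
    class_levels: tuple = (0, 10, 100)  # mg/L encoding of the class axis
    mc_error: np.ndarray | None = None  # sampling mode: s.e. per band/class
    extras: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.shap_values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.shap_values.shape[1]

    def local_accuracy_error(self) -> np.ndarray:
        """|sum_j phi_j - (f(x) - base)| per sample and class."""
        return np.abs(self.shap_values.sum(axis=1) - (self.predictions - self.base_values))


def _as_matrix_fn(f: Callable) -> Callable:
    def g(Z: np.ndarray) -> np.ndarray:
        out = np.asarray(f(np.atleast_2d(Z)), dtype=np.float64)
        return out[:, None] if out.ndim == 1 else out

    return g


def make_band_groups(n_bands: int, n_groups: int = 16) -> list[np.ndarray]:
    """Split band indices into contiguous, nearly equal groups."""
    return [np.asarray(g) for g in np.array_split(np.arange(n_bands), n_groups)]


def _shapley_weights(d: int) -> np.ndarray:
    """w[s] = s! (d-s-1)! / d! for coalition size s."""
    return np.array(
        [math.factorial(s) * math.factorial(d - s - 1) / math.factorial(d) for s in range(d)]
    )


def _exact_one(
    fm: Callable, x: np.ndarray, background: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    d = len(groups)
    n_bg, D = background.shape
    n_masks = 1 << d
    # composite inputs for every (coalition, background) pair
    Z = np.repeat(background[None, :, :], n_masks, axis=0)  # (masks, bg, D)
    for j, g in enumerate(groups):
        present = (np.arange(n_masks) >> j) & 1 == 1
        Z[np.ix_(present, np.arange(n_bg), g)] = x[g]
    vals = fm(Z.reshape(n_masks * n_bg, D)).reshape(n_masks, n_bg, -1).mean(axis=1)
    K = vals.shape[1]
    w = _shapley_weights(d)
    sizes = np.array([bin(m).count("1") for m in range(n_masks)])
    phi_groups = np.zeros((d, K))
    for j in range(d):
        without = np.flatnonzero((np.arange(n_masks) >> j) & 1 == 0)
        with_j = without | (1 << j)
        contrib = vals[with_j] - vals[without]  # (n_masks/2, K)
        phi_groups[j] = (w[sizes[without]][:, None] * contrib).sum(axis=0)
    # distribute each group's value equally over its member bands (sums preserved)
    phi = np.zeros((D, K))
    for j, g in enumerate(groups):
        phi[g] = phi_groups[j] / g.size
    return phi


def _sampling_one(
    fm: Callable,
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    D = x.size
    K = fm(x[None, :]).shape[1]
    total = np.zeros((D, K))
    chunk_means = []
    done = 0
    while done < n_samples:
        P = min(chunk, n_samples - done)
        perms = np.argsort(rng.random((P, D)), axis=1)
        bg = background[rng.integers(background.shape[0], size=P)]
        Z = bg.copy()
        prev = fm(Z)
        phi_chunk = np.zeros((D, K))
        for t in range(D):
            j = perms[:, t]
            Z[np.arange(P), j] = x[j]
            cur = fm(Z)
            np.add.at(phi_chunk, j, cur - prev)
            prev = cur
        total += phi_chunk
        chunk_means.append(phi_chunk / P)
        done += P
    phi = total / n_samples
    if len(chunk_means) > 1:
        se = np.std(np.stack(chunk_means), axis=0, ddof=1) / math.sqrt(len(chunk_means))
    else:
        se = np.full((D, K), np.nan)
    return phi, se


def shapley_attribute(
    f: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    mode: str = "exact",
    n_samples: int = 2000,
    seed: int | None = 0,
    groups: Sequence[np.ndarray] | int | None = None,
    class_levels: tuple = (0, 10, 100),
) -> AttributionResult:
    """Shapley attributions of ``f`` over bands (or contiguous band groups).

    ``f`` maps a (n, bands) matrix to per-class scores (1-D outputs are
    treated as a single class).  ``background`` supplies the replacement
    values for absent bands.  Exact mode enumerates coalitions and is
    limited to 15 features — pass ``groups`` (a count or explicit index
    lists) to attribute a long spectrum over contiguous band groups, whose
    value is spread equally over member bands.  Sampling mode draws
    ``n_samples`` seeded permutations per sample and reports the
    Monte-Carlo standard error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.shape[0] == 0:
        raise ValueError("empty background set")
    if background.shape[1] != X.shape[1]:
        raise ValueError(
            f"background has {background.shape[1]} bands, samples have {X.shape[1]}"
        )
    fm = _as_matrix_fn(f)
    D = X.shape[1]
    if isinstance(groups, int):
        groups = make_band_groups(D, groups)
    elif groups is not None:
        groups = [np.asarray(g) for g in groups]

    preds = fm(X)
    base = fm(background).mean(axis=0)
    K = preds.shape[1]
    phi = np.zeros((X.shape[0], D, K))
    mc = None
    if mode == "exact":
        gs = groups if groups is not None else [np.array([j]) for j in range(D)]
        if len(gs) > 15:
            raise ValueError(
                f"exact mode supports <= 15 features; got {len(gs)} "
                "(use groups= or mode='sampling')"
            )
        for i in range(X.shape[0]):
            phi[i] = _exact_one(fm, X[i], background, gs)
        bg_note = f"{background.shape[0]} background rows, {len(gs)} features"
    elif mode == "sampling":
        if groups is not None:
            raise ValueError("groups are an exact-mode device; sampling works per band")
        rng = np.random.default_rng(seed)
        mc = np.zeros((X.shape[0], D, K))
        for i in range(X.shape[0]):
            phi[i], mc[i] = _sampling_one(fm, X[i], background, n_samples, rng)
        bg_note = f"{background.shape[0]} background rows, {n_samples} permutations"
    else:
        raise ValueError(f"unknown mode {mode!r} (exact|sampling)")
    return AttributionResult(
        shap_values=phi,
        base_values=base,
        X=X,
        predictions=preds,
        mode=mode,
        background_spec=bg_note,
        seed=seed,
        class_levels=class_levels[:K] if K > 1 else (class_levels[0],),
        mc_error=mc,
    )


def global_importance(
    result: AttributionResult, wavelengths: np.ndarray | None = None, top_k: int | None = None
) -> pd.DataFrame:
    """Mean |contribution| per band over samples at their predicted class, ranked.

    This is the ranking behind the global-importance bar chart: bands that
    move the winning class score the most, regardless of direction.
    """
    if result.n_samples == 0:
        raise ValueError("empty attribution result")
    pred_class = np.argmax(result.predictions, axis=1)
    vals = result.shap_values[np.arange(result.n_samples), :, pred_class]  # samples x bands
    imp = np.abs(vals).mean(axis=0)
    df = pd.DataFrame({"band": np.arange(result.n_bands), "importance": imp})
    if wavelengths is not None:
        df["wavelength_nm"] = np.asarray(wavelengths)
    df = df.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.head(top_k) if top_k else df


def per_class_summary(
    result: AttributionResult, class_mg_per_L: int, wavelengths: np.ndarray | None = None
) -> pd.DataFrame:
    """Long-format beeswarm table for one concentration class.

    One row per (sample, band): the band's reflectance (colour channel in
    the plot) and its signed attribution (positive = pushes the model
    toward this class, negative = inhibits it).
    """
    levels = tuple(result.class_levels)
    if class_mg_per_L not in levels:
        raise ValueError(f"unknown class {class_mg_per_L} mg/L; expected one of {levels}")
    k = levels.index(class_mg_per_L)
    n, B = result.n_samples, result.n_bands
    sample_idx = np.repeat(np.arange(n), B)
    band_idx = np.tile(np.arange(B), n)
    df = pd.DataFrame(
        {
            "sample": sample_idx,
            "band": band_idx,
            "feature_value": result.X[sample_idx, band_idx],
            "shap_value": result.shap_values[sample_idx, band_idx, k],
        }
    )
    if wavelengths is not None:
        df["wavelength_nm"] = np.asarray(wavelengths)[band_idx]
    return df
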