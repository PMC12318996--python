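"""SR-FTIR preprocessing and two-dimensional correlation spectroscopy (2DCOS).

A perturbation-ordered series of mid-infrared spectra (here: microplastic
exposure levels) is converted to absorbance, baseline-corrected, split into
the functional-group (4000-2800 cm^-1) and fingerprint (1800-800 cm^-1)
regions, and expanded into synchronous / asynchronous correlation maps:

    Phi = Ytilde^T Ytilde / (m - 1)
    Psi = Ytilde^T N Ytilde / (m - 1),   N_jk = 0 if j = k else 1/(pi (k - j))

with ``Ytilde`` the dynamic spectra (reference-subtracted) over m
perturbation levels and N the Hilbert-Noda transform matrix.  The signs of
synchronous and asynchronous cross peaks then sequence the band responses
(Noda's rules): for a pair (nu1, nu2), Phi > 0 and Psi(nu1, nu2) > 0 means
nu1 responds before nu2; a negative Phi inverts the conclusion; a vanishing
Psi means the bands respond simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "FTIRSeries",
    "TwoDCOSResult",
    "SequenceOrder",
    "transmission_to_absorbance",
    "baseline_correct",
    "split_regions",
    "dynamic_spectra",
    "synchronous_map",
    "asynchronous_map",
    "hilbert_noda_matrix",
    "find_auto_peaks",
    "noda_ordering",
    "compute_2dcos",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FTIRSeries:
    """Perturbation-ordered spectra: one row per level, one column per wavenumber."""

    wavenumbers: np.ndarray
    spectra: np.ndarray
    mode: str = "transmission"  # or "absorbance"
    levels: list = field(default_factory=list)
    tissue: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        if self.spectra.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} points but "
                f"{self.wavenumbers.size} wavenumbers"
            )
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if not self.levels:
            self.levels = list(range(self.spectra.shape[0]))

    @property
    def n_levels(self) -> int:
        return self.spectra.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.spectra.T, columns=[str(l) for l in self.levels])
        df.insert(0, "wavenumber_cm-1", self.wavenumbers)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str = "transmission") -> "FTIRSeries":
        df = pd.read_csv(path)
        wn = df.iloc[:, 0].to_numpy(dtype=np.float64)
        return cls(
            wavenumbers=wn,
            spectra=df.iloc[:, 1:].to_numpy(dtype=np.float64).T,
            mode=mode,
            levels=list(df.columns[1:]),
        )


@dataclass
class TwoDCOSResult:
    """Synchronous/asynchronous maps with the peak tables derived from them."""

    wavenumbers: np.ndarray
    sync: np.ndarray
    async_: np.ndarray
    reference: np.ndarray
    auto_peaks: pd.DataFrame
    cross_peaks: pd.DataFrame
    n_levels: int
    notes: dict = field(default_factory=dict)


@dataclass
class SequenceOrder:
    """Band response order inferred from cross-peak signs.

    ``groups`` lists bands earliest-first; bands inside one tuple respond
    simultaneously.  ``pair_rules`` records, per unordered band pair, which
    sign combination fired.  ``consistent`` is False when the pairwise
    conclusions contain a cycle (reported, never silently linearised).
    """

    groups: list[tuple[float, ...]]
    pair_rules: dict[tuple[float, float], str]
    consistent: bool

    def arrow_notation(self) -> str:
        """Render like '3356 -> 2910 -> 2863' (simultaneous bands joined by '/')."""
        def fmt(v: float) -> str:
            return f"{v:g}"

        if not self.consistent:
            return "inconsistent"
        return " → ".join("/".join(fmt(b) for b in g) for g in self.groups)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def transmission_to_absorbance(series: FTIRSeries) -> FTIRSeries:
    """Lambert-Beer conversion A = -log10(T), per spectral point.

    Transmittance must be positive; values above 1 (possible after
    background ratioing) are clipped to 1 and the clip count reported in
    ``notes['n_clipped']``.
    """
    if series.mode == "absorbance":
        return series
    T = series.spectra
    if np.any(T <= 0):
        lev, pos = np.unravel_index(int(np.argmin(T)), T.shape)
        raise ValueError(
            f"non-positive transmittance at level {lev}, "
            f"{series.wavenumbers[pos]:g} cm^-1 (T = {T[lev, pos]:g})"
        )
    n_clipped = int(np.count_nonzero(T > 1.0))
    A = -np.log10(np.minimum(T, 1.0))
    notes = dict(series.notes)
    notes["n_clipped"] = n_clipped
    notes["conversion"] = "A = -log10(T) (Lambert-Beer)"
    return replace(series, spectra=A, mode="absorbance", notes=notes)


def _rubberband_one(x_asc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull baseline on an ascending grid."""
    n = x_asc.size
    # Andrew's monotone chain, lower hull only
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x_asc[i2] - x_asc[i1]) * (y[i] - y[i1]) - (x_asc[i] - x_asc[i1]) * (
                y[i2] - y[i1]
            )
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x_asc, x_asc[hull], y[hull])


def _als_one(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Asymmetric least squares baseline (Eilers-Boelens)."""
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    DTD = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + DTD).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(
    series: FTIRSeries,
    method: str = "rubberband",
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
) -> FTIRSeries:
    """Remove baseline drift per spectrum.

    ``rubberband`` subtracts the lower convex hull (corrected minimum is
    >= -1e-9 by construction, and the correction is idempotent to
    numerical precision); ``als`` subtracts an asymmetric least-squares
    baseline with smoothness ``lam`` and asymmetry ``p``, which on an
    already-corrected spectrum leaves only a small residual of the order
    of the asymmetry-weighted noise floor.
    """
    if series.spectra.shape[1] < 8:
        raise ValueError("baseline correction needs >= 8 points per spectrum")
    ascending = series.wavenumbers[0] < series.wavenumbers[-1]
    order = slice(None) if ascending else slice(None, None, -1)
    x_asc = series.wavenumbers[order]
    corrected = np.empty_like(series.spectra)
    for i, row in enumerate(series.spectra):
        y = row[order]
        if method == "rubberband":
            base = _rubberband_one(x_asc, y)
        elif method == "als":
            base = _als_one(y, lam, p, n_iter)
        else:
            raise ValueError(f"unknown baseline method {method!r} (rubberband|als)")
        corrected[i] = (y - base)[order]
    notes = dict(series.notes)
    notes["baseline"] = method
    return replace(series, spectra=corrected, notes=notes)


DEFAULT_REGIONS = {
    "functional_group": (2800.0, 4000.0),
    "fingerprint": (800.0, 1800.0),
}


def split_regions(
    series: FTIRSeries,
    regions: dict[str, tuple[float, float]] | None = None,
) -> dict[str, FTIRSeries]:
    """Restrict the series to named closed wavenumber windows.

    Defaults to the functional-group region (4000-2800 cm^-1) and the
    fingerprint region (1800-800 cm^-1); boundary points belong to the
    region (closed intervals).
    """
    regions = DEFAULT_REGIONS if regions is None else regions
    out: dict[str, FTIRSeries] = {}
    for name, (lo, hi) in regions.items():
        if lo >= hi:
            raise ValueError(f"region {name!r}: invalid window [{lo}, {hi}]")
        keep = (series.wavenumbers >= lo) & (series.wavenumbers <= hi)
        if not keep.any():
            raise ValueError(
                f"region {name!r}: no points in [{lo}, {hi}] cm^-1 "
                f"(series spans [{series.wavenumbers.min():g}, "
                f"{series.wavenumbers.max():g}])"
            )
        out[name] = replace(
            series, wavenumbers=series.wavenumbers[keep], spectra=series.spectra[:, keep]
        )
    return out


# ---------------------------------------------------------------------------
# 2DCOS
# ---------------------------------------------------------------------------


def dynamic_spectra(series: FTIRSeries, reference: str | np.ndarray = "mean") -> np.ndarray:
    """Dynamic spectra: each level minus a reference spectrum.

    ``reference`` is ``'mean'`` (perturbation-mean, the usual convention),
    ``'first'`` (the lowest perturbation level), or an explicit spectrum.
    """
    if series.n_levels < 2:
        raise ValueError("dynamic spectra need >= 2 perturbation levels")
    if isinstance(reference, str):
        if reference == "mean":
            ref = series.spectra.mean(axis=0)
        elif reference == "first":
            ref = series.spectra[0]
        else:
            raise ValueError(f"unknown reference {reference!r} (mean|first|array)")
    else:
        ref = np.asarray(reference, dtype=np.float64)
        if ref.shape != (series.wavenumbers.size,):
            raise ValueError(
                f"custom reference has length {ref.size}, expected {series.wavenumbers.size}"
            )
    return series.spectra - ref[None, :]


def synchronous_map(dyn: np.ndarray) -> np.ndarray:
    """Synchronous correlation Phi = Ytilde^T Ytilde / (m - 1); symmetric, PSD."""
    dyn = np.atleast_2d(dyn)
    m = dyn.shape[0]
    if m < 2:
        raise ValueError(f"need >= 2 levels, got {m}")
    return dyn.T @ dyn / (m - 1)


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """m x m Hilbert-Noda transform matrix: N_jk = 0 if j = k else 1/(pi (k - j))."""
    j = np.arange(m)
    diff = j[None, :] - j[:, None]  # k - j
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * diff)
    np.fill_diagonal(N, 0.0)
    return N


def asynchronous_map(dyn: np.ndarray) -> np.ndarray:
    """Asynchronous correlation Psi = Ytilde^T N Ytilde / (m - 1); antisymmetric."""
    dyn = np.atleast_2d(dyn)
    m = dyn.shape[0]
    if m < 2:
        raise ValueError(f"need >= 2 levels, got {m}")
    N = hilbert_noda_matrix(m)
    psi = dyn.T @ (N @ dyn) / (m - 1)
    # enforce exact antisymmetry (removes ~1e-17 roundoff on the diagonal)
    return 0.5 * (psi - psi.T)


def find_auto_peaks(
    sync: np.ndarray,
    wavenumbers: np.ndarray,
    prominence: float = 0.0,
) -> pd.DataFrame:
    """Local maxima of the synchronous diagonal (autopeaks = response hot spots).

    With ``prominence=0`` a relative floor of 1e-3 of the strongest
    autopeak is applied, so numerical ripple on an otherwise flat diagonal
    is not reported as a peak.
    """
    if prominence < 0:
        raise ValueError("prominence must be >= 0")
    diag = np.diag(sync)
    if prominence == 0 and diag.size and diag.max() > 0:
        prominence = 1e-3 * float(diag.max())
    idx, props = signal.find_peaks(diag, prominence=prominence if prominence > 0 else None)
    df = pd.DataFrame(
        {
            "wavenumber_cm-1": np.asarray(wavenumbers)[idx],
            "intensity": diag[idx],
            "index": idx,
        }
    )
    return df.sort_values("intensity", ascending=False).reset_index(drop=True)


def cross_peak_table(
    sync: np.ndarray,
    async_: np.ndarray,
    wavenumbers: np.ndarray,
    bands: Sequence[float],
) -> pd.DataFrame:
    """(nu1, nu2, Phi, Psi, signs) for every unordered pair of listed bands, nu1 < nu2."""
    wn = np.asarray(wavenumbers)
    idx = {b: int(np.argmin(np.abs(wn - b))) for b in bands}
    rows = []
    ordered = sorted(bands)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            nu1, nu2 = ordered[a], ordered[b]
            i, j = idx[nu1], idx[nu2]
            rows.append(
                {
                    "nu1_cm-1": nu1,
                    "nu2_cm-1": nu2,
                    "phi": sync[i, j],
                    "psi": async_[i, j],
                    "sign_phi": int(np.sign(sync[i, j])),
                    "sign_psi": int(np.sign(async_[i, j])),
                }
            )
    return pd.DataFrame(rows)


def noda_ordering(
    sync: np.ndarray,
    async_: np.ndarray,
    wavenumbers: np.ndarray,
    bands: Sequence[float],
    tol: float | None = None,
) -> SequenceOrder:
    """Sequence band responses from cross-peak signs (Noda's rules).

    For each unordered pair (nu1, nu2), nu1 < nu2, with Phi = sync and
    Psi = async at that coordinate:

    * Phi > 0, Psi > 0  ->  nu1 responds before nu2
    * Phi > 0, Psi < 0  ->  nu2 responds before nu1
    * Phi < 0           ->  the conclusion above is inverted
    * |Psi| <= tol      ->  simultaneous

    ``tol`` defaults to 1e-6 of the largest |Psi| among the listed pairs.
    The pairwise conclusions are aggregated into a partial order
    (simultaneous bands merged into one group); cyclic conclusions are
    reported as inconsistent rather than silently linearised.
    """
    wn = np.asarray(wavenumbers)
    bands = list(bands)
    if len(bands) < 2:
        raise ValueError("need at least two bands to order")
    for b in bands:
        if np.min(np.abs(wn - b)) > np.max(np.abs(np.diff(wn))):
            raise ValueError(f"band {b} cm^-1 not on the wavenumber grid")
    idx = {b: int(np.argmin(np.abs(wn - b))) for b in bands}

    # simultaneity threshold tied to the synchronous intensity scale: an
    # asynchronous peak far below the autopeak level is numerical noise
    auto_scale = max(abs(sync[idx[b], idx[b]]) for b in bands)
    if tol is None:
        tol = 1e-8 * auto_scale
    phi_tol = 1e-8 * auto_scale

    before: dict[tuple[float, float], bool] = {}  # (a, b): a responds before b
    simultaneous: list[tuple[float, float]] = []
    pair_rules: dict[tuple[float, float], str] = {}
    ordered = sorted(bands)
    for a_i in range(len(ordered)):
        for b_i in range(a_i + 1, len(ordered)):
            nu1, nu2 = ordered[a_i], ordered[b_i]
            phi = sync[idx[nu1], idx[nu2]]
            psi = async_[idx[nu1], idx[nu2]]
            if abs(psi) <= tol:
                simultaneous.append((nu1, nu2))
                pair_rules[(nu1, nu2)] = f"|psi| <= tol -> simultaneous (phi={phi:.3g})"
                continue
            if abs(phi) <= phi_tol:
                pair_rules[(nu1, nu2)] = (
                    f"phi ~ 0 (phi={phi:.3g}, psi={psi:.3g}) -> undetermined"
                )
                continue
            first_first = (psi > 0) == (phi > 0)  # nu1 before nu2?
            rule = (
                f"phi {'>' if phi > 0 else '<'} 0, psi {'>' if psi > 0 else '<'} 0 -> "
                f"{nu1 if first_first else nu2:g} before {nu2 if first_first else nu1:g}"
            )
            pair_rules[(nu1, nu2)] = rule
            before[(nu1, nu2) if first_first else (nu2, nu1)] = True

    # merge simultaneous bands into groups (union-find)
    parent = {b: b for b in bands}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in simultaneous:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups_map: dict[float, list[float]] = {}
    for b in bands:
        groups_map.setdefault(find(b), []).append(b)
    members = {root: tuple(sorted(g)) for root, g in groups_map.items()}

    # precedence between groups; Kahn's algorithm for a topological grouping
    edges: set[tuple[float, float]] = set()
    for (a, b) in before:
        ra, rb = find(a), find(b)
        if ra == rb:
            # a pair both "simultaneous-linked" and directed: contradiction
            return SequenceOrder(groups=[], pair_rules=pair_rules, consistent=False)
        edges.add((ra, rb))
    indeg = {r: 0 for r in members}
    for _, rb in edges:
        indeg[rb] += 1
    ready = sorted([r for r, d in indeg.items() if d == 0])
    out_groups: list[tuple[float, ...]] = []
    edges_left = set(edges)
    while ready:
        layer = ready
        ready = []
        # groups tied in one layer have no mutual precedence: emit in wavenumber order
        for r in sorted(layer, key=lambda r: members[r]):
            out_groups.append(members[r])
        for r in layer:
            for e in [e for e in edges_left if e[0] == r]:
                edges_left.discard(e)
                indeg[e[1]] -= 1
                if indeg[e[1]] == 0:
                    ready.append(e[1])
    if edges_left:
        return SequenceOrder(groups=[], pair_rules=pair_rules, consistent=False)
    return SequenceOrder(groups=out_groups, pair_rules=pair_rules, consistent=True)


def compute_2dcos(
    series: FTIRSeries,
    reference: str | np.ndarray = "mean",
    bands: Sequence[float] | None = None,
    prominence: float = 0.0,
) -> TwoDCOSResult:
    """Full 2DCOS analysis of an absorbance series.

    Computes dynamic spectra against ``reference``, the synchronous and
    asynchronous maps, autopeaks on the synchronous diagonal, and — when
    ``bands`` are given — the cross-peak sign table.  With only three
    perturbation levels the asynchronous map is rank-limited; a note is
    attached so downstream sequencing is read with care.
    """
    if series.mode != "absorbance":
        raise ValueError("2DCOS expects an absorbance series; convert first")
    dyn = dynamic_spectra(series, reference)
    sync = synchronous_map(dyn)
    async_ = asynchronous_map(dyn)
    ref = series.spectra.mean(axis=0) if isinstance(reference, str) and reference == "mean" \
        else (series.spectra[0] if isinstance(reference, str) else np.asarray(reference))
    auto = find_auto_peaks(sync, series.wavenumbers, prominence)
    cross = (
        cross_peak_table(sync, async_, series.wavenumbers, bands)
        if bands is not None
        else pd.DataFrame()
    )
    notes = dict(series.notes)
    if series.n_levels < 4:
        notes["async_rank"] = f"low-rank (m={series.n_levels})"
    return TwoDCOSResult(
        wavenumbers=series.wavenumbers,
        sync=sync,
        async_=async_,
        reference=ref,
        auto_peaks=auto,
        cross_peaks=cross,
        n_levels=series.n_levels,
        notes=notes,
    )
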