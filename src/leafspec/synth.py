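"""Seeded synthetic data with known ground truth for every pipeline stage.

The study system this emulates: rice seedlings grown under microplastic
(PET / PS / PVC) suspensions at 0, 10 and 100 mg/L, imaged as detached
leaves on a bright Teflon board with a VNIR line scanner, plus SR-FTIR
transmission spectra of leaf sections at the three exposure levels.  No
real cubes are shipped; everything downstream is validated against the
planted ground truth produced here.

Leaf reflectance model
----------------------
A mean reflectance curve per (polymer, concentration class) is composed of
a flat base plus the canonical vegetation features:

* a green reflectance peak near 540 nm (chlorophyll window),
* absorption troughs in the blue (~480 nm, pigments) and red (~660 nm,
  chlorophyll a),
* the red edge — a logistic reflectance rise between ~660 and 770 nm up to
  the NIR plateau,
* a water absorption trough near 940 nm.

Microplastic stress is encoded as pigment degradation: absorption troughs
become monotonically shallower with concentration class and the red edge
shifts toward the blue by a few nm, scaled per polymer.  Leaf-level
spectra are the class mean plus i.i.d. Gaussian band noise (a correlated
low-rank variability option exists but is off by default so that sample
means converge to the class means at the CLT rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ingest import LabeledSpectra, LeafMask, SpectralCube

__all__ = [
    "GaussianFeature",
    "RedEdge",
    "ProfileConfig",
    "ClassProfileSet",
    "CubeLayout",
    "default_wavelength_grid",
    "make_class_profiles",
    "simulate_spectra",
    "simulate_cube",
    "simulate_informative_bands",
    "simulate_ftir_series",
]

N_BANDS_DEFAULT = 256
VNIR_RANGE_NM = (425.0, 965.0)

POLYMERS_DEFAULT = ("PET", "PS", "PVC")
CONCENTRATIONS_DEFAULT = (0, 10, 100)


def default_wavelength_grid() -> np.ndarray:
    """256 equally spaced band centers spanning the retained 425-965 nm window."""
    return np.linspace(*VNIR_RANGE_NM, N_BANDS_DEFAULT)


# ---------------------------------------------------------------------------
# class profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian reflectance feature; negative amplitude = absorption trough."""

    center_nm: float
    width_nm: float
    amplitude: float
    name: str = ""

    def curve(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.width_nm) ** 2)


@dataclass(frozen=True)
class RedEdge:
    """Logistic reflectance rise from the red trough to the NIR plateau."""

    center_nm: float = 715.0
    width_nm: float = 18.0
    amplitude: float = 0.42

    def curve(self, wl: np.ndarray, shift_nm: float = 0.0) -> np.ndarray:
        return self.amplitude / (1.0 + np.exp(-(wl - (self.center_nm - shift_nm)) / self.width_nm))


def _default_features() -> tuple[GaussianFeature, ...]:
    return (
        GaussianFeature(480.0, 22.0, -0.040, "blue pigment trough"),
        GaussianFeature(540.0, 28.0, +0.080, "green peak"),
        GaussianFeature(660.0, 16.0, -0.050, "chlorophyll-a trough"),
        GaussianFeature(940.0, 26.0, -0.080, "NIR water trough"),
    )


@dataclass(frozen=True)
class ProfileConfig:
    """Generator settings for the per-class mean reflectance curves.

    ``trough_depth_scale`` is the per-concentration-step fractional
    shallowing of absorption troughs (pigment degradation) and
    ``red_edge_shift_nm`` the per-step blue shift of the red edge; both are
    multiplied by a per-polymer susceptibility factor and by the global
    ``effect_scale`` separability knob.
    """

    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)
    polymers: tuple[str, ...] = POLYMERS_DEFAULT
    concentrations: tuple[int, ...] = CONCENTRATIONS_DEFAULT
    base_level: float = 0.10
    features: tuple[GaussianFeature, ...] = field(default_factory=_default_features)
    red_edge: RedEdge = field(default_factory=RedEdge)
    trough_depth_scale: float = 0.22
    red_edge_shift_nm: float = 2.0
    polymer_factors: dict[str, float] = field(
        default_factory=lambda: {"PET": 1.0, "PS": 0.85, "PVC": 1.15}
    )
    effect_scale: float = 1.0
    noise_sd: float = 0.001
    seed: int = 0


@dataclass
class ClassProfileSet:
    """Mean reflectance curve per (polymer, concentration class) plus noise level."""

    wavelengths: np.ndarray
    mean_curves: dict[tuple[str, int], np.ndarray]
    config: ProfileConfig
    noise_sd: float
    seed: int

    @property
    def class_keys(self) -> list[tuple[str, int]]:
        return list(self.mean_curves.keys())

    def restrict(self, polymer: str) -> "ClassProfileSet":
        """Profiles of a single polymer (the classifiers are trained per polymer)."""
        curves = {k: v for k, v in self.mean_curves.items() if k[0] == polymer}
        if not curves:
            raise ValueError(f"no profiles for polymer {polymer!r}")
        return ClassProfileSet(self.wavelengths, curves, self.config, self.noise_sd, self.seed)


def _check_finite(value: float, fieldname: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"non-finite feature parameter: {fieldname} = {value}")


def make_class_profiles(config: ProfileConfig | None = None) -> ClassProfileSet:
    """Build the per-(polymer, class) mean reflectance curves.

    The concentration effect is a monotone scaling of the absorption-trough
    depths plus a small blue shift of the red edge; both are linear in the
    concentration class index, so class separability grows monotonically
    with ``effect_scale``.  Identical configs (including seed) produce
    bitwise-identical profiles.
    """
    config = config or ProfileConfig()
    wl = np.asarray(config.wavelengths, dtype=np.float64)
    if wl.size < 1 or (wl.size > 1 and not np.all(np.diff(wl) > 0)):
        raise ValueError("wavelength grid must be non-empty and strictly increasing")
    if config.noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {config.noise_sd}")
    _check_finite(config.base_level, "base_level")
    _check_finite(config.trough_depth_scale, "trough_depth_scale")
    _check_finite(config.red_edge_shift_nm, "red_edge_shift_nm")
    _check_finite(config.effect_scale, "effect_scale")
    for f in config.features:
        for attr in ("center_nm", "width_nm", "amplitude"):
            _check_finite(getattr(f, attr), f"features[{f.name or f.center_nm}].{attr}")
    for attr in ("center_nm", "width_nm", "amplitude"):
        _check_finite(getattr(config.red_edge, attr), f"red_edge.{attr}")

    curves: dict[tuple[str, int], np.ndarray] = {}
    for polymer in config.polymers:
        pf = config.polymer_factors.get(polymer, 1.0)
        for idx, conc in enumerate(config.concentrations):
            stress = idx * pf * config.effect_scale
            depth_factor = 1.0 - config.trough_depth_scale * stress
            shift = config.red_edge_shift_nm * stress
            curve = np.full_like(wl, config.base_level)
            curve = curve + config.red_edge.curve(wl, shift_nm=shift)
            for feat in config.features:
                amp = feat.amplitude * (depth_factor if feat.amplitude < 0 else 1.0)
                curve = curve + replace(feat, amplitude=amp).curve(wl)
            curves[(polymer, conc)] = np.clip(curve, 0.0, 1.0)
    return ClassProfileSet(
        wavelengths=wl,
        mean_curves=curves,
        config=config,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# labelled spectra
# ---------------------------------------------------------------------------


def simulate_spectra(
    profiles: ClassProfileSet,
    n_per_class: int = 300,
    seed: int | None = None,
) -> LabeledSpectra:
    """Draw ``n_per_class`` leaf spectra per (polymer, class).

    Each sample is its class mean plus i.i.d. Gaussian band noise
    (``profiles.noise_sd``), clipped to [0, 1].  With ``noise_sd = 0``
    every sample equals its class mean exactly.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    if not profiles.mean_curves:
        raise ValueError("empty profile set")
    rng = np.random.default_rng(profiles.seed if seed is None else seed)
    B = profiles.wavelengths.size
    rows, polymers, concs, ids = [], [], [], []
    for (polymer, conc), mean in profiles.mean_curves.items():
        noise = rng.normal(0.0, 1.0, size=(n_per_class, B)) * profiles.noise_sd
        rows.append(np.clip(mean[None, :] + noise, 0.0, 1.0))
        polymers.extend([polymer] * n_per_class)
        concs.extend([conc] * n_per_class)
        ids.extend(f"{polymer}_{conc}mgL_{i:04d}" for i in range(n_per_class))
    return LabeledSpectra(
        X=np.vstack(rows),
        wavelengths=profiles.wavelengths.copy(),
        polymer=np.array(polymers, dtype=object),
        concentration=np.array(concs),
        sample_ids=np.array(ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# cubes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseRegion:
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (semi-axis rows, semi-axis cols)
    class_key: tuple[str, int]  # (polymer, concentration)


@dataclass
class CubeLayout:
    """Scene geometry: up to ~ten elliptical leaves on a bright flat board."""

    height: int = 200
    width: int = 300
    leaf_regions: list[EllipseRegion] = field(default_factory=list)
    background_reflectance: float = 0.9

    def region_mask(self, region: EllipseRegion) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.height, 0 : self.width]
        (cy, cx), (ay, ax) = region.center, region.axes
        return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def ten_leaf_layout(
    profiles: ClassProfileSet,
    height: int = 220,
    width: int = 420,
) -> CubeLayout:
    """Board layout with ten narrow leaves in two rows, classes cycling."""
    keys = profiles.class_keys
    regions = []
    for i in range(10):
        row = 60 + 110 * (i // 5)
        col = 45 + 82 * (i % 5)
        regions.append(
            EllipseRegion(center=(row, col), axes=(42.0, 13.0), class_key=keys[i % len(keys)])
        )
    return CubeLayout(height=height, width=width, leaf_regions=regions)


def simulate_cube(
    layout: CubeLayout,
    profiles: ClassProfileSet,
    seed: int = 0,
) -> tuple[SpectralCube, LeafMask]:
    """Render a cube from a layout: bright flat background, leaves with class spectra.

    Returns the cube plus a ground-truth mask labelling the regions 1..n in
    the layout's reading order.  Overlapping regions are an error — the
    ground truth would be ambiguous.
    """
    H, W, B = layout.height, layout.width, profiles.wavelengths.size
    masks = []
    for region in layout.leaf_regions:
        (cy, cx), (ay, ax) = region.center, region.axes
        if not (0 <= cy - ay and cy + ay < H and 0 <= cx - ax and cx + ax < W):
            raise ValueError(f"region at {region.center} exceeds image bounds ({H}x{W})")
        masks.append(layout.region_mask(region))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(f"leaf regions {i + 1} and {j + 1} overlap")

    rng = np.random.default_rng(seed)
    data = np.full((H, W, B), layout.background_reflectance, dtype=np.float64)
    labels = np.zeros((H, W), dtype=np.int32)
    # reading order of centroids, matching segment_leaves' labelling rule
    order = sorted(range(len(masks)), key=lambda i: layout.leaf_regions[i].center)
    for new_label, i in enumerate(order, start=1):
        region, m = layout.leaf_regions[i], masks[i]
        curve = profiles.mean_curves[region.class_key]
        n_pix = int(m.sum())
        block = curve[None, :] + rng.normal(0.0, 1.0, (n_pix, B)) * profiles.noise_sd
        data[m] = np.clip(block, 0.0, 1.0)
        labels[m] = new_label
    cube = SpectralCube(
        data=data,
        wavelengths=profiles.wavelengths.copy(),
        meta={"source": "leafspec.synth.simulate_cube", "seed": seed},
    )
    return cube, LeafMask(labels=labels, threshold_used=float("nan"), band_used_nm=float("nan"))


# ---------------------------------------------------------------------------
# planted informative bands (wavelength-selection benchmark)
# ---------------------------------------------------------------------------


def simulate_informative_bands(
    n_per_class: int = 40,
    n_bands: int = 24,
    informative: Sequence[int] = (4, 11, 19),
    effect: float = 0.08,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> LabeledSpectra:
    """Three-class spectra where only ``informative`` bands carry class signal.

    The informative bands are complementary, one marker per class: band
    ``informative[k]`` is elevated by ``effect`` only in class k, so no
    single band separates all three classes and a correct selector must
    retain at least two of them.  Every other band is pure noise around a
    flat base.  Ground truth for selector recovery tests.
    """
    informative = np.asarray(informative, dtype=int)
    if np.any(informative < 0) or np.any(informative >= n_bands):
        raise ValueError("informative band indices out of range")
    if informative.size != len(CONCENTRATIONS_DEFAULT):
        raise ValueError("need one informative marker band per concentration class")
    rng = np.random.default_rng(seed)
    wl = np.linspace(425.0, 965.0, n_bands)
    rows, concs, ids = [], [], []
    for k, conc in enumerate(CONCENTRATIONS_DEFAULT):
        mean = np.full(n_bands, 0.4)
        mean[informative[k]] += effect
        rows.append(mean[None, :] + rng.normal(0.0, noise_sd, (n_per_class, n_bands)))
        concs.extend([conc] * n_per_class)
        ids.extend(f"planted_{conc}mgL_{i:03d}" for i in range(n_per_class))
    return LabeledSpectra(
        X=np.clip(np.vstack(rows), 0.0, 1.0),
        wavelengths=wl,
        polymer=np.array(["PET"] * 3 * n_per_class, dtype=object),
        concentration=np.array(concs),
        sample_ids=np.array(ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# FTIR series
# ---------------------------------------------------------------------------


def simulate_ftir_series(
    band_specs: Sequence[tuple[float, float, int]],
    n_levels: int = 16,
    seed: int = 0,
    amplitude: float = 0.8,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
    response: str = "sigmoid",
    onset_step: float = 0.15,
    phase_step_deg: float = 45.0,
    wavenumber_range: tuple[float, float] = (4000.0, 800.0),
    wavenumber_step: float = 4.0,
    mode: str = "transmission",
):
    """Synthesize a perturbation-ordered FTIR series with a planted band order.

    ``band_specs`` is a list of ``(center cm^-1, width cm^-1, onset_rank)``
    where the onset ranks are a permutation (ties allowed — tied bands
    respond simultaneously).  Band intensity follows a monotone response
    curve of the normalised perturbation coordinate t in [0, 1]:

    * ``response='sigmoid'`` — logistic onset at ``0.25 + rank*onset_step``
      (an intensity ramp that switches on later for higher ranks),
    * ``response='sin'`` — half-period raised-cosine rise delayed in phase
      by ``rank * phase_step_deg`` (used to probe the asynchronous map at
      controlled phase leads between band responses).

    Returns ``(series, planted_order)`` where ``planted_order`` groups band
    centers by onset rank, earliest first; a single group means all bands
    respond simultaneously.
    """
    from .ftir import FTIRSeries  # local import to avoid a cycle

    if n_levels < 3:
        raise ValueError(f"n_levels must be >= 3, got {n_levels}")
    centers = [c for c, _, _ in band_specs]
    if len(set(centers)) != len(centers):
        raise ValueError(f"duplicate band centers in band_specs: {sorted(centers)}")
    ranks = [r for _, _, r in band_specs]
    if sorted(set(ranks)) != list(range(len(set(ranks)))):
        raise ValueError("onset ranks must be 0-based consecutive (ties allowed)")

    hi, lo = wavenumber_range
    wn = np.arange(hi, lo - 0.5 * wavenumber_step, -wavenumber_step)
    t = np.linspace(0.0, 1.0, n_levels)
    rng = np.random.default_rng(seed)

    A = np.full((n_levels, wn.size), baseline)
    for center, width, rank in band_specs:
        if response == "sigmoid":
            onset = 0.25 + rank * onset_step
            resp = 1.0 / (1.0 + np.exp(-(t - onset) / 0.06))
        elif response == "sin":
            phi = math.radians(rank * phase_step_deg)
            # half-period raised-cosine rise delayed in phase: monotone in t,
            # onset shift = phase lead between bands
            resp = 0.5 * (1.0 - np.cos(np.clip(np.pi * t - phi, 0.0, np.pi)))
        else:
            raise ValueError(f"unknown response kind {response!r}")
        shape = np.exp(-0.5 * ((wn - center) / width) ** 2)
        A = A + amplitude * resp[:, None] * shape[None, :]
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, A.shape)
        A = np.maximum(A, 0.0)

    if mode == "transmission":
        spectra = np.power(10.0, -A)  # T in (0, 1] since A >= 0
    elif mode == "absorbance":
        spectra = A
    else:
        raise ValueError(f"unknown mode {mode!r}")

    series = FTIRSeries(
        wavenumbers=wn,
        spectra=spectra,
        mode=mode,
        levels=list(range(n_levels)),
        tissue="synthetic",
    )
    groups: dict[int, list[float]] = {}
    for center, _, rank in band_specs:
        groups.setdefault(rank, []).append(center)
    planted_order = [tuple(sorted(groups[r])) for r in sorted(groups)]
    return series, planted_order
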