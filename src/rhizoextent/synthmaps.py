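"""Seeded synthetic μ-XRF-like element maps with known ground truth.

The generator emulates the features of real element-count maps that matter
for the radial-profile statistic: a central root disc, a substrate-dependent
pore/grain structure (well-sorted grains with inter-grain pores for "sand",
a fine matrix with sparse pores for "loam"), a near-root element enrichment
with a known radial envelope (exponential or step) that can be concentrated
in patches at grain contacts, and Poisson count noise.  The injected
envelope extent is recorded as ground truth so that the profile/extent
pipeline can be validated end to end without experimental data.

It is a statistical emulator, not a physical XRF forward model: there are no
matrix effects, no screening, no spectral response.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .xrf import MaskSet, RadialProfile, distance_map

__all__ = ["MapRecipe", "generate_map", "generate_profile_fixture"]


@dataclass(frozen=True)
class MapRecipe:
    """Recipe for one synthetic element map; identical recipe + seed give
    bit-identical output."""

    style: str = "loam"               # "sand" | "loam"
    shape: tuple[int, int] = (401, 401)
    pixel_size: float = 20.0          # μm
    root_radius: float = 500.0        # μm
    background: float = 100.0         # mean counts on soil matrix
    amplitude: float = 200.0          # enrichment peak counts at the root
    extent: float = 300.0             # envelope extent E, μm
    envelope: str = "exponential"     # "exponential" | "step"
    patchiness: float = 0.0           # fraction of enrichment moved to patches
    poisson: bool = True
    seed: int = 0
    grain_radius: float = 100.0       # μm, sand grains (±10 %)
    pore_fraction: float = 0.05       # loam pore area fraction
    pore_level: float = 25.0          # counts inside pores
    texture: float = 0.1              # loam fine-matrix variability (rel.)

    def __post_init__(self) -> None:
        if self.style not in ("sand", "loam"):
            raise ValueError(f"unknown substrate style {self.style!r}")
        if self.envelope not in ("exponential", "step"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if not 0 <= self.patchiness <= 1:
            raise ValueError("patchiness must be within [0, 1]")
        half_fov = min(self.shape) * self.pixel_size / 2.0
        if not 0 < self.extent < half_fov - self.root_radius:
            raise ValueError("envelope extent must fit inside the field of view")


def _root_disc(recipe: MapRecipe) -> np.ndarray:
    ny, nx = recipe.shape
    yy, xx = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rr = np.hypot(yy - cy, xx - cx) * recipe.pixel_size
    return rr <= recipe.root_radius


def _sand_pores(recipe: MapRecipe, root: np.ndarray,
                rng: np.random.Generator, max_tries: int = 3) -> np.ndarray:
    """Random sequential addition of non-overlapping grain discs; the pore
    mask is everything between the grains (excluding the root)."""
    ny, nx = recipe.shape
    rg_px = recipe.grain_radius / recipe.pixel_size
    # random sequential addition jams near 0.55 area fraction for discs;
    # aim safely below that
    target = 0.50 * ny * nx                 # solid area target, px
    for attempt in range(max_tries):
        centers: list[tuple[float, float, float]] = []
        placed_area = 0.0
        misses = 0
        cys = np.empty(0)
        cxs = np.empty(0)
        rads = np.empty(0)
        while placed_area < target and misses < 20000:
            cy = rng.uniform(0, ny)
            cx = rng.uniform(0, nx)
            rad = rg_px * rng.uniform(0.9, 1.1)
            if cys.size and np.any(np.hypot(cys - cy, cxs - cx)
                                   < 0.97 * (rads + rad)):
                misses += 1
                continue
            centers.append((cy, cx, rad))
            cys = np.append(cys, cy)
            cxs = np.append(cxs, cx)
            rads = np.append(rads, rad)
            placed_area += np.pi * rad * rad
        if placed_area >= 0.8 * target:
            break
    else:
        raise RuntimeError("grain packing failed to reach the target density")
    grain = np.zeros(recipe.shape, dtype=bool)
    yy, xx = np.mgrid[:ny, :nx]
    for cy, cx, rad in centers:
        y0, y1 = max(0, int(cy - rad) - 1), min(ny, int(cy + rad) + 2)
        x0, x1 = max(0, int(cx - rad) - 1), min(nx, int(cx + rad) + 2)
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
        grain[y0:y1, x0:x1] |= sub <= rad * rad
    pore = ~grain
    pore[root] = False
    return pore


def _loam_pores(recipe: MapRecipe, root: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Sparse small pores in an otherwise continuous fine matrix."""
    ny, nx = recipe.shape
    pore = np.zeros(recipe.shape, dtype=bool)
    pore_r_px = 2.5
    n_pores = int(recipe.pore_fraction * ny * nx / (np.pi * pore_r_px ** 2))
    yy, xx = np.mgrid[:ny, :nx]
    for _ in range(n_pores):
        cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
        rad = pore_r_px * rng.uniform(0.7, 1.3)
        y0, y1 = max(0, int(cy - rad) - 1), min(ny, int(cy + rad) + 2)
        x0, x1 = max(0, int(cx - rad) - 1), min(nx, int(cx + rad) + 2)
        sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
        pore[y0:y1, x0:x1] |= sub <= rad * rad
    pore[root] = False
    return pore


def generate_map(recipe: MapRecipe) -> tuple[np.ndarray, MaskSet, dict]:
    """Generate one synthetic element map with masks and ground truth.

    Returns ``(counts, masks, truth)``; counts are float for noiseless maps
    and non-negative integers (as float array) after Poisson sampling.  The
    enrichment deposit is mass-conserving under patchiness: redistributing
    counts into patches preserves the total injected enrichment on the
    non-pore support exactly.
    """
    rng = np.random.default_rng(recipe.seed)
    root = _root_disc(recipe)
    if recipe.style == "sand":
        pore = _sand_pores(recipe, root, rng)
    else:
        pore = _loam_pores(recipe, root, rng)
    solid = ~root & ~pore

    base = np.zeros(recipe.shape, dtype=float)
    base[pore] = recipe.pore_level
    if recipe.style == "loam" and recipe.texture > 0:
        texture = 1.0 + recipe.texture * ndimage.gaussian_filter(
            rng.standard_normal(recipe.shape), 2.0)
        base[solid] = recipe.background * np.clip(texture, 0.5, 1.5)[solid]
    else:
        base[solid] = recipe.background

    d = distance_map(root, recipe.pixel_size)
    if recipe.envelope == "exponential":
        env = np.exp(-d / recipe.extent)
    else:
        env = (d < recipe.extent).astype(float)
    env[~solid] = 0.0

    if recipe.patchiness > 0:
        if recipe.style == "sand":
            # grain contacts: thin solid bridges close to the pore space
            edt_solid = ndimage.distance_transform_edt(solid)
            contact = solid & (edt_solid <= 2.0)
        else:
            field = ndimage.gaussian_filter(rng.standard_normal(recipe.shape), 3.0)
            contact = solid & (field > np.quantile(field[solid], 0.7))
        w = np.where(contact, 1.0, 0.0) * recipe.patchiness \
            + (1.0 - recipe.patchiness)
        weighted = env * w
        total = weighted.sum()
        if total > 0:
            weighted *= env.sum() / total       # conserve injected mass
        env = weighted

    counts = base + recipe.amplitude * env
    if recipe.poisson:
        counts = rng.poisson(counts).astype(float)
    counts[root] = 0.0

    truth = dict(asdict(recipe), bulk_level=recipe.background,
                 injected_mass=float((recipe.amplitude * env).sum()))
    return counts, MaskSet(root=root, pore=pore), truth


def generate_profile_fixture(n_bins: int | None = None,
                             weights=None, values=None, seed: int = 0,
                             bin_width: float = 20.0) -> RadialProfile:
    """Deterministic RadialProfile fixture for unit tests.

    Either pass equal-length ``weights`` and ``values`` explicitly, or give
    ``n_bins`` and a seed to draw a random (but reproducible) profile.
    """
    if values is None or weights is None:
        if n_bins is None:
            raise ValueError("give n_bins for a random fixture")
        rng = np.random.default_rng(seed)
        values = rng.uniform(50, 150, n_bins)
        weights = rng.integers(10, 200, n_bins).astype(float)
    weights = np.asarray(weights, dtype=float)
    values = np.asarray(values, dtype=float)
    if weights.shape != values.shape:
        raise ValueError("weights and values must have equal length")
    edges = bin_width * np.arange(values.size + 1)
    return RadialProfile(bin_edges=edges, mean=values.copy(),
                         weight=weights.copy(), sd=np.zeros_like(values))
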