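"""Seeded generators of pore windows, nuclear point patterns and
fluorescence-like images with known ground truth.

The generators emulate the image material the pipeline quantifies —
circular pore cross-sections in a solid matrix, nuclei scattered at
complete spatial randomness or clumped by a Thomas cluster process, and
two-channel fields where a marker partitions between nuclear and
cytosolic compartments with a known fraction — so every stage can be
tested by parameter recovery without any external data.

Every generator is a pure function of its parameters and seed: the same
call yields a bit-identical result.

Default scenes mirror the two pore regimes under study: a
"small-pore-like" scene is a disc window of 92.5 μm diameter with Thomas
clustering (small pores promote cell clustering), a "large-pore-like"
scene a 337.5 μm disc with CSR; the diameters are the midpoints of the
nominal 60–125 μm and 250–425 μm porogen sieve ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .errors import InvalidInputError
from .pointpattern import ObservationWindow, PointPattern, _sample_uniform

__all__ = [
    "SyntheticTruth",
    "SyntheticField",
    "make_window",
    "sample_csr",
    "sample_thomas",
    "render_nuclei_image",
    "render_coloc_image",
    "sample_ct_table",
    "SMALL_PORE_SCENE",
    "LARGE_PORE_SCENE",
    "make_scene_window",
    "sample_scene_pattern",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record of a generated field."""

    process: str  # "csr" | "thomas" | "hardcore"
    params: dict
    n_realized: int
    seed: int | None
    true_nar: float | None = None
    nuclear_red_fraction: float | None = None


@dataclass(frozen=True)
class SyntheticField:
    """A rendered scene: window, points, image, and its generating truth."""

    window: ObservationWindow
    pattern: PointPattern
    image: np.ndarray  # (H, W, 3) uint8
    truth: SyntheticTruth
    pixel_size_um: float
    overlap_count: int = 0


def make_window(
    kind: Literal["full_rect", "disc", "multi_pore"],
    pixel_size_um: float = 1.0,
    shape_px: tuple[int, int] = (128, 128),
    radius_um: float | None = None,
    pore_centers_px: list[tuple[float, float]] | None = None,
    pore_radii_um: list[float] | None = None,
    pad_px: int = 2,
) -> ObservationWindow:
    """Build an observation window mask.

    ``full_rect``: all pixels available.  ``disc``: a single circular pore
    of ``radius_um`` centered in a square frame (frame sized to fit, plus
    ``pad_px`` of matrix).  ``multi_pore``: circular pores at
    ``pore_centers_px`` with ``pore_radii_um`` inside a ``shape_px`` frame;
    pores clipped by the frame raise a warning.
    """
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel size must be positive")
    if kind == "full_rect":
        return ObservationWindow(np.ones(shape_px, dtype=bool), pixel_size_um)
    if kind == "disc":
        if radius_um is None or radius_um <= 0:
            raise InvalidInputError("disc window needs a positive radius_um")
        r_px = radius_um / pixel_size_um
        size = int(np.ceil(2 * r_px)) + 2 * pad_px + 1
        mask = np.zeros((size, size), dtype=bool)
        c = (size - 1) / 2.0
        rr, cc = draw_disk((c, c), r_px, shape=mask.shape)
        mask[rr, cc] = True
        return ObservationWindow(mask, pixel_size_um)
    if kind == "multi_pore":
        if not pore_centers_px or not pore_radii_um:
            raise InvalidInputError("multi_pore needs pore centers and radii")
        if len(pore_centers_px) != len(pore_radii_um):
            raise InvalidInputError("one radius per pore center required")
        if any(r <= 0 for r in pore_radii_um):
            raise InvalidInputError("pore radii must be positive")
        mask = np.zeros(shape_px, dtype=bool)
        clipped = 0
        for (row, col), r_um in zip(pore_centers_px, pore_radii_um):
            r_px = r_um / pixel_size_um
            if (
                row - r_px < -0.5
                or col - r_px < -0.5
                or row + r_px > shape_px[0] - 0.5
                or col + r_px > shape_px[1] - 0.5
            ):
                clipped += 1
            rr, cc = draw_disk((row, col), r_px, shape=mask.shape)
            mask[rr, cc] = True
        if clipped:
            warnings.warn(f"{clipped} pore(s) clipped by the frame boundary", stacklevel=2)
        return ObservationWindow(mask, pixel_size_um)
    raise InvalidInputError(f"unknown window kind {kind!r}")


def sample_csr(window: ObservationWindow, n: int, seed: int | None = None) -> PointPattern:
    """n points uniform on the window's available space (binomial process)."""
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return PointPattern(_sample_uniform(window, n, rng), window)


def sample_thomas(
    window: ObservationWindow,
    kappa_per_um2: float,
    sigma_um: float,
    mu: float,
    seed: int | None = None,
) -> tuple[PointPattern, SyntheticTruth]:
    """Thomas cluster process restricted to the window.

    Parents are Poisson(κ·|W|), placed uniformly on the available space;
    each parent spawns Poisson(μ) offspring displaced by an isotropic
    Gaussian of scale σ; offspring falling off the available space are
    discarded, so the expected retained count is at most κ|W|μ.
    """
    if kappa_per_um2 <= 0 or sigma_um <= 0 or mu <= 0:
        raise InvalidInputError("kappa, sigma and mu must be positive")
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(kappa_per_um2 * window.area_um2)
    parents = _sample_uniform(window, n_parents, rng)
    pts = []
    for p in parents:
        k = rng.poisson(mu)
        if k:
            pts.append(p + rng.normal(0.0, sigma_um, size=(k, 2)))
    if pts:
        offspring = np.vstack(pts)
        offspring = offspring[window.contains(offspring)]
    else:
        offspring = np.empty((0, 2))
    pattern = PointPattern(offspring, window)
    truth = SyntheticTruth(
        process="thomas",
        params={"kappa_per_um2": kappa_per_um2, "sigma_um": sigma_um, "mu": mu},
        n_realized=pattern.n,
        seed=seed,
    )
    return pattern, truth


def render_nuclei_image(
    pattern: PointPattern,
    nar: float = 0.7,
    nucleus_long_axis_um: float = 12.0,
    seed: int | None = None,
    intensity: int = 255,
    max_retries: int = 10,
    jitter_um: float = 4.0,
) -> SyntheticField:
    """Render each pattern point as a filled ellipse in the blue channel.

    Each nucleus is an ellipse with the given long axis and aspect ratio
    (short = nar × long) at a uniformly random orientation.  Overlap with
    previously drawn nuclei is resolved by jittering the center up to
    ``max_retries`` times; unresolved overlaps are drawn anyway and counted
    in ``overlap_count``.  The realized (possibly jittered) centers become
    the pattern of the returned field, so every rendered nucleus center is
    a pattern point.
    """
    if not (0 < nar <= 1):
        raise InvalidInputError("nar must be in (0, 1]")
    if nucleus_long_axis_um <= 0:
        raise InvalidInputError("nucleus long axis must be positive")
    rng = np.random.default_rng(seed)
    px = pattern.window.pixel_size_um
    h, w = pattern.window.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    a_px = nucleus_long_axis_um / 2.0 / px
    b_px = a_px * nar
    realized = []
    overlaps = 0
    margin = 1.5  # px of clearance so neighbors never touch (8-connectivity)
    for pt in pattern.points:
        theta = rng.uniform(0.0, np.pi)
        center = pt.copy()
        placed = False
        for attempt in range(max_retries + 1):
            row, col = center[1] / px, center[0] / px
            halo = draw_ellipse(
                row, col, b_px + margin, a_px + margin, shape=(h, w), rotation=theta
            )
            rr, cc = draw_ellipse(row, col, b_px, a_px, shape=(h, w), rotation=theta)
            if len(rr) and not occupied[halo].any():
                placed = True
                break
            spread = jitter_um * (1.0 + 0.5 * attempt)  # widen the search on retries
            center = pt + rng.uniform(-spread, spread, size=2)
        if not placed:
            center = pt
            row, col = center[1] / px, center[0] / px
            rr, cc = draw_ellipse(row, col, b_px, a_px, shape=(h, w), rotation=theta)
            overlaps += 1
        occupied[rr, cc] = True
        img[rr, cc, 2] = intensity
        realized.append(center)
    if overlaps:
        warnings.warn(f"{overlaps} nuclei drawn overlapping after retries", stacklevel=2)
    realized_pattern = PointPattern(np.array(realized).reshape(-1, 2), pattern.window)
    truth = SyntheticTruth(
        process="rendered",
        params={"nucleus_long_axis_um": nucleus_long_axis_um},
        n_realized=realized_pattern.n,
        seed=seed,
        true_nar=nar,
    )
    return SyntheticField(
        window=pattern.window,
        pattern=realized_pattern,
        image=img,
        truth=truth,
        pixel_size_um=px,
        overlap_count=overlaps,
    )


def render_coloc_image(
    base: SyntheticField,
    nuclear_red_fraction: float,
    total_red_area_um2: float,
    seed: int | None = None,
    intensity: int = 255,
) -> SyntheticField:
    """Add a red channel partitioned between nuclei and cytosol.

    Red-positive pixels are sampled without replacement so that the total
    red+ area is ``total_red_area_um2`` and the fraction of it inside
    nuclei equals ``nuclear_red_fraction``, both up to one-pixel
    quantization.  Raises if a compartment cannot hold its requested area.
    """
    if not (0 <= nuclear_red_fraction <= 1):
        raise InvalidInputError("nuclear_red_fraction must be in [0, 1]")
    if total_red_area_um2 < 0:
        raise InvalidInputError("total red area must be >= 0")
    rng = np.random.default_rng(seed)
    px2 = base.pixel_size_um**2
    nuclei = base.image[..., 2] > 0
    cyto = base.window.mask & ~nuclei
    total_px = int(round(total_red_area_um2 / px2))
    nuc_px = int(round(total_px * nuclear_red_fraction))
    cyto_px = total_px - nuc_px
    if nuc_px > nuclei.sum():
        raise InvalidInputError(
            f"requested nuclear red area ({nuc_px} px) exceeds nuclear area ({nuclei.sum()} px)"
        )
    if cyto_px > cyto.sum():
        raise InvalidInputError(
            f"requested cytosolic red area ({cyto_px} px) exceeds cytosol area ({cyto.sum()} px)"
        )
    img = base.image.copy()
    for compartment, k in ((nuclei, nuc_px), (cyto, cyto_px)):
        rows, cols = np.nonzero(compartment)
        pick = rng.choice(len(rows), size=k, replace=False)
        img[rows[pick], cols[pick], 0] = intensity
    truth = replace(base.truth, nuclear_red_fraction=nuclear_red_fraction)
    return replace(base, image=img, truth=truth)


def sample_ct_table(
    n_per_condition: int = 4,
    noise_sd_cycles: float = 0.5,
    seed: int | None = None,
    reference_gene: str = "GAPDH",
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-archetype synthetic Ct table for clustering recovery tests.

    Two pore conditions ("large_pore", "small_pore") have opposite
    expression archetypes over a panel of osteogenic/mechanotransduction
    genes — large pores upregulate YAP targets and osteogenic markers
    (lower ΔCt), small pores retain stemness markers — plus a "monolayer"
    baseline condition with a flat intermediate profile, which serves as
    the ΔΔCt calibrator (fold changes are always reported against a
    control, never against one of the contrasted groups, whose within-
    group correlation would otherwise be destroyed).  Per-sample Gaussian
    noise of ``noise_sd_cycles`` (a realistic qPCR replicate spread) is
    added to every well.  Returns the long-format table and the true
    condition of each sample.
    """
    if n_per_condition < 1:
        raise InvalidInputError("need at least one sample per condition")
    if noise_sd_cycles < 0:
        raise InvalidInputError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    # ΔCt archetypes relative to the reference gene (lower = more expressed)
    archetypes = {
        "monolayer": {"CTGF": 7.0, "YAP1": 7.0, "RUNX2": 7.0, "SP7": 8.0, "CD44": 7.0, "GLI1": 7.0},
        "large_pore": {"CTGF": 4.0, "YAP1": 5.0, "RUNX2": 5.5, "SP7": 7.0, "CD44": 9.0, "GLI1": 9.5},
        "small_pore": {"CTGF": 7.5, "YAP1": 7.0, "RUNX2": 8.5, "SP7": 10.0, "CD44": 6.0, "GLI1": 6.5},
    }
    ref_ct = 18.0
    rows = []
    truth = {}
    for cond, profile in archetypes.items():
        for i in range(n_per_condition):
            sample = f"{cond}_{i + 1}"
            truth[sample] = cond
            rows.append(
                {
                    "sample_id": sample,
                    "condition": cond,
                    "gene": reference_gene,
                    "ct": ref_ct + rng.normal(0, noise_sd_cycles),
                }
            )
            for gene, dct in profile.items():
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": cond,
                        "gene": gene,
                        "ct": ref_ct + dct + rng.normal(0, noise_sd_cycles),
                    }
                )
    return pd.DataFrame(rows), pd.Series(truth, name="condition")


# --- default scenes -------------------------------------------------------

SMALL_PORE_SCENE = {
    "window": {"kind": "disc", "radius_um": 46.25, "pixel_size_um": 1.0},
    "process": "thomas",
    "kappa_per_um2": 9e-4,
    "sigma_um": 6.0,
    "mu": 6.0,
}
"""Small-pore regime: 92.5 μm disc (midpoint of the 60–125 μm sieve range)
with Thomas clustering — about 6 cluster seeds of ~6 cells each, spread
6 μm (roughly one cell diameter), i.e. a few tight multicellular clumps
per pore section."""

LARGE_PORE_SCENE = {
    "window": {"kind": "disc", "radius_um": 168.75, "pixel_size_um": 2.0},
    "process": "csr",
    "n": 120,
}
"""Large-pore regime: 337.5 μm disc (midpoint of 250–425 μm) with 120
randomly placed cells — a lower areal density than the clustered regime,
matching the sparser spread of cells lining large pores."""


def make_scene_window(scene: dict) -> ObservationWindow:
    return make_window(**scene["window"])


def sample_scene_pattern(
    scene: dict,
    seed: int | None = None,
    window: ObservationWindow | None = None,
    min_points: int = 5,
) -> tuple[PointPattern, SyntheticTruth]:
    """Draw the point pattern of a scene description (see the scene dicts).

    Cluster-process scenes are conditioned on containing at least
    ``min_points`` events (re-drawn deterministically from the seed stream
    otherwise): a field with only a couple of cells carries no spatial
    information and would not be analyzed.
    """
    if window is None:
        window = make_scene_window(scene)
    if scene["process"] == "thomas":
        rng = np.random.default_rng(seed)
        for _ in range(1000):
            sub_seed = int(rng.integers(2**31))
            pattern, truth = sample_thomas(
                window, scene["kappa_per_um2"], scene["sigma_um"], scene["mu"], seed=sub_seed
            )
            if pattern.n >= min_points:
                break
        return pattern, replace(truth, seed=seed)
    if scene["process"] == "csr":
        pattern = sample_csr(window, scene["n"], seed=seed)
        truth = SyntheticTruth("csr", {"n": scene["n"]}, pattern.n, seed)
        return pattern, truth
    raise InvalidInputError(f"unknown scene process {scene['process']!r}")
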