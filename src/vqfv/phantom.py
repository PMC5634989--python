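"""Digital thoracic phantoms: paired CT + V/Q PET with known ground truth.

The phantom stands in for a clinical cohort.  Each case is a pair of
ellipsoidal lungs inside a soft-tissue body on CT, with a PET activity
map that carries the features that matter to percentage-of-maximum
delineation:

* a gravity-dependent anterior-posterior activity gradient,
* focal functional defects (spheres of reduced tracer uptake),
* airway-deposition hot spots (ventilation only by default),
* Gaussian point-spread blur and Poisson counting noise,
* pulmonary-function indices linearly coupled (with noise) to the true
  functional fraction.

Ground truth is defined on the noiseless, unblurred, gradient-free
activity: a lung voxel is functional iff its defect multiplier is at
least 50% of normal uptake.  This keeps truth independent of the
gradient (which rescales activity of tissue that is functional either
way) and of the image-degradation chain, emulating an expert's
physiological reference contour rather than the %max method under test.

Determinism: ``(spec, seed)`` fully determines every array.  Poisson
noise is drawn by inverse-CDF transform of a seed-determined uniform
field, so two phantoms that differ only locally (e.g. a hot spot added)
share identical noise away from the difference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import poisson

from .core import BinaryMask, CaseRecord, ImageVolume, Modality, PFT_INDICES, sphere_mask

DEFAULT_SHAPE = (64, 64, 48)
DEFAULT_SPACING = (4.0, 4.0, 4.0)

#: lung voxels are functional iff defect multiplier >= this fraction of normal
TRUTH_MULTIPLIER = 0.5


@dataclass(frozen=True)
class Defect:
    """Sphere of reduced uptake. ``activity_multiplier`` in [0, 1)."""

    center: tuple[float, float, float]  # voxel coordinates
    radius_mm: float
    activity_multiplier: float = 0.0


@dataclass(frozen=True)
class HotSpot:
    """Focal airway tracer deposition: additive truncated-Gaussian blob.

    Peak total activity at the centre is ``intensity_multiplier`` times
    the local activity; the blob sigma is ``radius_mm / 1.5`` and its
    support is cut at two sigma.  The default radius corresponds to a
    ~1 ml deposition.
    """

    center: tuple[float, float, float]
    radius_mm: float = 6.0
    intensity_multiplier: float = 5.0


def default_lung_geometry(shape: Sequence[int]) -> tuple[tuple, tuple]:
    """Two (center_vox, half_axes_vox) ellipsoid parameter sets."""
    nx, ny, nz = shape
    half = (0.16 * nx, 0.22 * ny, 0.375 * nz)
    left = ((0.31 * nx, 0.5 * ny, 0.5 * nz), half)
    right = ((0.69 * nx, 0.5 * ny, 0.5 * nz), half)
    return (left, right)


@dataclass
class PhantomSpec:
    """Full description of one synthetic case (plus its seed).

    ``defects=None`` asks the generator to synthesise defects matching
    ``functional_fraction``; an explicit (possibly empty) defect list is
    used as given and the realised fraction is whatever it produces.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    lung_geometry: Optional[tuple] = None  # ((center, half_axes), (center, half_axes)), voxels
    background_hu: float = 40.0
    lung_hu: float = -750.0
    body_hu: float = 300.0
    air_hu: float = -1000.0
    functional_fraction: float = 1.0
    ap_gradient: float = 0.5
    defects: Optional[tuple[Defect, ...]] = None
    auto_defect_count: Optional[int] = None
    hotspots: tuple[HotSpot, ...] = ()
    base_activity: float = 200.0
    psf_fwhm_mm: float = 8.0
    noise: str = "poisson"  # or "none"
    scatter_fraction: float = 0.02
    ct_noise_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.functional_fraction <= 1.0):
            raise ValueError(f"functional_fraction must be in (0, 1], got {self.functional_fraction}")
        if self.ap_gradient < 0:
            raise ValueError("ap_gradient must be >= 0")
        if self.base_activity <= 0:
            raise ValueError("base_activity must be > 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.lung_geometry is None:
            self.lung_geometry = default_lung_geometry(self.shape)
        if self.defects is not None:
            self.defects = tuple(self.defects)
        self.hotspots = tuple(self.hotspots)


@dataclass
class PhantomCase:
    """A generated case bundled with its ground truth."""

    case: CaseRecord
    truth_wl: BinaryMask
    truth_functional_vent: Optional[BinaryMask]
    truth_functional_perf: Optional[BinaryMask]
    true_fraction_vent: float
    true_fraction_perf: float
    spec: PhantomSpec


def _ellipsoid(shape, center, half_axes) -> np.ndarray:
    idx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape, dtype=float)
    for ax in range(3):
        acc = acc + ((idx[ax] - center[ax]) / half_axes[ax]) ** 2
    return acc <= 1.0


def _lung_mask(spec: PhantomSpec) -> np.ndarray:
    (c1, h1), (c2, h2) = spec.lung_geometry
    return _ellipsoid(spec.shape, c1, h1) | _ellipsoid(spec.shape, c2, h2)


def _auto_defects(spec: PhantomSpec, lung: np.ndarray, rng: np.random.Generator) -> tuple[Defect, ...]:
    """Synthesise spherical defects realising the target functional fraction.

    Centres are drawn uniformly over lung voxels; per-defect radii get a
    random relative size and a common scale factor solved by bisection
    so the rasterised nonfunctional volume matches the target.
    """
    f = spec.functional_fraction
    lung_count = int(lung.sum())
    deficit = (1.0 - f) * lung_count
    if deficit < 0.5:
        return ()
    k = spec.auto_defect_count
    if k is None:
        # ~one defect per 150 ml of deficit, between 1 and 3
        vox_ml = math.prod(spec.spacing) / 1000.0
        k = int(np.clip(round(deficit * vox_ml / 150.0), 1, 3))
    if k <= 0:
        raise ValueError(f"functional_fraction {f} unreachable with 0 defects")
    flat = np.flatnonzero(lung)
    centers = np.array(np.unravel_index(rng.choice(flat, size=k, replace=False), lung.shape)).T
    # sub-voxel jitter breaks lattice symmetry so sphere volume grows in
    # small voxel increments and the bisection can hit the target tightly
    centers = centers + rng.uniform(-0.49, 0.49, size=centers.shape)
    rel = rng.uniform(0.7, 1.3, size=k)
    mults = rng.uniform(0.0, 0.3, size=k)
    vox_mm3 = math.prod(spec.spacing)
    r0 = ((3.0 * deficit * vox_mm3) / (4.0 * math.pi * k)) ** (1.0 / 3.0)

    def realised(scale: float) -> int:
        hit = np.zeros(spec.shape, dtype=bool)
        for c, r in zip(centers, rel):
            hit |= sphere_mask(spec.shape, spec.spacing, c, scale * r * r0)
        return int((hit & lung).sum())

    lo, hi = 0.1, 6.0
    if realised(hi) < deficit:
        raise ValueError(f"functional_fraction {f} unreachable with {k} defect(s)")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realised(mid) < deficit:
            lo = mid
        else:
            hi = mid
    scale = hi
    got = realised(scale)
    if abs(got - deficit) / lung_count > 0.015:
        raise ValueError(
            f"functional_fraction {f} unreachable: realised deficit {got / lung_count:.3f} "
            f"vs target {1 - f:.3f}")
    return tuple(
        Defect(tuple(float(x) for x in c), float(scale * r * r0), float(m))
        for c, r, m in zip(centers, rel, mults)
    )


def truth_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, tuple[Defect, ...], float]:
    """Lung mask, defect multiplier map, defects used, realised fraction.

    Cheap (no blur/noise/image synthesis); shared by the full generator
    and by truth-only cohort simulation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    lung = _lung_mask(spec)
    if spec.defects is None:
        defects = _auto_defects(spec, lung, rng)
    else:
        defects = spec.defects
        for d in defects:
            c = tuple(int(round(x)) for x in d.center)
            if not (all(0 <= c[i] < spec.shape[i] for i in range(3)) and lung[c]):
                raise ValueError(f"defect centred outside the lungs: {d.center}")
    mult = np.ones(spec.shape, dtype=float)
    for d in defects:
        sph = sphere_mask(spec.shape, spec.spacing, d.center, d.radius_mm)
        mult[sph] = np.minimum(mult[sph], d.activity_multiplier)
    truth = lung & (mult >= TRUTH_MULTIPLIER)
    frac = float(truth.sum()) / float(lung.sum())
    return lung, mult, defects, frac


def _depth_fraction(lung: np.ndarray) -> np.ndarray:
    """Anterior->posterior depth in [0, 1] over the lung extent (axis 1)."""
    ys = np.where(lung.any(axis=(0, 2)))[0]
    y0, y1 = int(ys.min()), int(ys.max())
    depth = np.zeros(lung.shape[1])
    if y1 > y0:
        depth[y0 : y1 + 1] = (np.arange(y0, y1 + 1) - y0) / (y1 - y0)
        depth[y1 + 1 :] = 1.0
    return depth[None, :, None]


def _activity_map(spec: PhantomSpec, lung: np.ndarray, mult: np.ndarray) -> np.ndarray:
    act = np.full(spec.shape, spec.scatter_fraction * spec.base_activity, dtype=float)
    depth = _depth_fraction(lung)
    grad = spec.base_activity * (1.0 + spec.ap_gradient * depth)
    act[lung] = (grad * np.ones_like(mult))[lung] * mult[lung]
    return act


def _add_hotspots(act: np.ndarray, spec: PhantomSpec, lung: np.ndarray) -> np.ndarray:
    """Add deposition blobs.  The peak is ``intensity_multiplier`` times
    the *normal-lung* activity at the centre's depth: deposition happens
    in the airways and is intense regardless of parenchymal defects."""
    out = act.copy()
    depth = _depth_fraction(lung)
    for h in spec.hotspots:
        c = tuple(int(round(x)) for x in h.center)
        if not (all(0 <= c[i] < spec.shape[i] for i in range(3)) and lung[c]):
            raise ValueError(f"hot spot centred outside the lungs: {h.center}")
        sigma = h.radius_mm / 1.5
        support = 2.0 * sigma
        local = spec.base_activity * (1.0 + spec.ap_gradient * float(depth[0, c[1], 0]))
        box = sphere_mask(spec.shape, spec.spacing, h.center, support)
        idx = np.nonzero(box)
        d2 = np.zeros(len(idx[0]))
        for ax in range(3):
            d2 += ((idx[ax] - h.center[ax]) * spec.spacing[ax]) ** 2
        out[idx] += (h.intensity_multiplier - 1.0) * local * np.exp(-d2 / (2.0 * sigma**2))
    return out


def _blur(act: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.psf_fwhm_mm <= 0:
        return act
    sigmas = [spec.psf_fwhm_mm / 2.3548 / s for s in spec.spacing]
    return ndimage.gaussian_filter(act, sigma=sigmas, mode="nearest")


def _poissonise(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson counts via inverse CDF of a uniform field (common random numbers)."""
    u = np.clip(rng.random(lam.shape), 1e-12, 1.0 - 1e-12)
    return poisson.ppf(u, np.maximum(lam, 1e-12))


def generate_phantom(spec: PhantomSpec, modalities: Sequence[str] = ("vent", "perf")) -> PhantomCase:
    """Generate one paired CT + V/Q PET case with ground truth.

    Ventilation and perfusion share geometry but receive independent
    noise; hot spots go on the ventilation image only (airway deposition
    is an inhaled-tracer artifact).
    """
    ss = np.random.SeedSequence([int(spec.seed), 1])
    r_vent, r_perf, r_ct = (np.random.default_rng(c) for c in ss.spawn(3))
    lung, mult, defects, frac = truth_geometry(spec)

    nx, ny, nz = spec.shape
    body = _ellipsoid(spec.shape, (0.5 * nx, 0.5 * ny, 0.5 * nz), (0.45 * nx, 0.42 * ny, 0.48 * nz))
    shell = body & ~ndimage.binary_erosion(body)
    ct_data = np.full(spec.shape, spec.air_hu, dtype=float)
    ct_data[body] = spec.background_hu
    ct_data[shell] = spec.body_hu
    ct_data[lung] = spec.lung_hu
    if spec.ct_noise_hu > 0:
        ct_data = ct_data + r_ct.normal(0.0, spec.ct_noise_hu, size=spec.shape)
    ct = ImageVolume(ct_data, spec.spacing, modality=Modality.CT)

    act0 = _activity_map(spec, lung, mult)

    def make_pet(with_hotspots: bool, rng: np.random.Generator, modality: Modality) -> ImageVolume:
        act = _add_hotspots(act0, spec, lung) if with_hotspots else act0
        act = _blur(act, spec)
        if spec.noise == "poisson":
            act = _poissonise(act, rng)
        return ImageVolume(act, spec.spacing, modality=modality)

    pet_vent = make_pet(True, r_vent, Modality.PET_VENT) if "vent" in modalities else None
    pet_perf = make_pet(False, r_perf, Modality.PET_PERF) if "perf" in modalities else None

    truth_wl = BinaryMask(lung, spec.spacing, label="truth_wl")
    truth_fn = lung & (mult >= TRUTH_MULTIPLIER)
    t_vent = BinaryMask(truth_fn, spec.spacing, label="truth") if pet_vent is not None else None
    t_perf = BinaryMask(truth_fn.copy(), spec.spacing, label="truth") if pet_perf is not None else None

    case = CaseRecord(case_id=f"phantom-{spec.seed}", ct=ct, pet_vent=pet_vent, pet_perf=pet_perf)
    return PhantomCase(
        case=case,
        truth_wl=truth_wl,
        truth_functional_vent=t_vent,
        truth_functional_perf=t_perf,
        true_fraction_vent=frac,
        true_fraction_perf=frac,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortVariability:
    """Case-to-case variation in a synthetic cohort."""

    fraction_range: tuple[float, float] = (0.4, 0.9)
    defect_count_range: tuple[int, int] = (1, 3)
    hotspot_probability: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"fraction_range must satisfy 0 < min <= max <= 1, got {self.fraction_range}")
        if self.defect_count_range[0] > self.defect_count_range[1]:
            raise ValueError("defect_count_range min > max")


@dataclass(frozen=True)
class PftCoupling:
    """Linear coupling of one PFT index to the true functional fraction."""

    slope: float
    intercept: float
    noise_sd: float
    clip: tuple[float, float]


# Defaults emulate the typical clinical pattern: the obstruction ratio
# (FEV1/FVC) couples strongly to the functional fraction, FEV1 and DLCO
# moderately, FVC weakly.  Under fractions ~ U(0.4, 0.9) the population
# correlations are ~0.78, 0.61, 0.43, 0.30 respectively.
DEFAULT_PFT_COUPLINGS: dict[str, PftCoupling] = {
    "FEV1_FVC": PftCoupling(0.5, 0.30, 0.058, (0.2, 0.95)),
    "FEV1_pct_pred": PftCoupling(60.0, 30.0, 11.25, (20.0, 150.0)),
    "DLCO_pct_pred": PftCoupling(50.0, 40.0, 15.15, (20.0, 150.0)),
    "FVC_pct_pred": PftCoupling(40.0, 60.0, 18.36, (20.0, 150.0)),
}


def coupling_for_r(slope: float, intercept: float, target_r: float,
                   fraction_range: tuple[float, float] = (0.4, 0.9),
                   clip: tuple[float, float] = (0.0, np.inf)) -> PftCoupling:
    """Coupling whose population correlation with a uniform fraction is ``target_r``."""
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must be in (0, 1)")
    sd_f = (fraction_range[1] - fraction_range[0]) / math.sqrt(12.0)
    noise_sd = abs(slope) * sd_f * math.sqrt(1.0 / target_r**2 - 1.0)
    return PftCoupling(slope, intercept, noise_sd, clip)


def _cohort_case_spec(i: int, rng: np.random.Generator, base_spec: PhantomSpec,
                      variability: CohortVariability, case_seed: int) -> PhantomSpec:
    lo, hi = variability.fraction_range
    f = float(rng.uniform(lo, hi))
    klo, khi = variability.defect_count_range
    k = int(rng.integers(klo, khi + 1))
    spec = replace(base_spec, functional_fraction=f, auto_defect_count=k,
                   defects=None, hotspots=(), seed=case_seed)
    if rng.random() < variability.hotspot_probability:
        # airway deposition sits in ventilated lung: jitter around a lung
        # centre and keep the first draw that lands in functional tissue
        geom = spec.lung_geometry or default_lung_geometry(spec.shape)
        lung, mult, _, _ = truth_geometry(spec)
        functional = lung & (mult >= TRUTH_MULTIPLIER)
        for _ in range(50):
            side = int(rng.integers(0, 2))
            c, h = geom[side]
            cand = np.asarray(c) + rng.uniform(-0.3, 0.3, size=3) * np.asarray(h)
            ci = tuple(int(round(x)) for x in cand)
            if functional[ci]:
                spec = replace(spec, hotspots=(HotSpot(
                    tuple(float(x) for x in cand), radius_mm=6.0,
                    intensity_multiplier=float(rng.uniform(3.0, 6.0))),))
                break
    return spec


def _draw_pft(rng: np.random.Generator, frac: float,
              couplings: dict[str, PftCoupling]) -> dict[str, float]:
    out = {}
    for name in PFT_INDICES:
        c = couplings[name]
        v = c.intercept + c.slope * frac + rng.normal(0.0, c.noise_sd)
        out[name] = float(np.clip(v, *c.clip))
    return out


def generate_cohort(n: int, base_spec: Optional[PhantomSpec] = None,
                    variability: Optional[CohortVariability] = None,
                    pft_couplings: Optional[dict[str, PftCoupling]] = None,
                    seed: int = 0,
                    modalities: Sequence[str] = ("vent", "perf")) -> list[PhantomCase]:
    """Generate ``n`` cases with per-case seeds derived from ``seed``.

    Functional fractions are uniform over ``variability.fraction_range``;
    each PFT index is ``intercept + slope * true_fraction + N(0, sd)``,
    clipped to its physiological range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec = base_spec or PhantomSpec()
    variability = variability or CohortVariability()
    pft_couplings = pft_couplings or DEFAULT_PFT_COUPLINGS
    cases = []
    for i, child in enumerate(np.random.SeedSequence(int(seed)).spawn(n)):
        rng = np.random.default_rng(child)
        case_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        spec_i = _cohort_case_spec(i, rng, base_spec, variability, case_seed)
        pc = generate_phantom(spec_i, modalities=modalities)
        pc.case.case_id = f"case{i:03d}"
        pc.case.pft = _draw_pft(rng, pc.true_fraction_vent, pft_couplings)
        cases.append(pc)
    return cases


def simulate_cohort_truth(n: int, base_spec: Optional[PhantomSpec] = None,
                          variability: Optional[CohortVariability] = None,
                          pft_couplings: Optional[dict[str, PftCoupling]] = None,
                          seed: int = 0) -> pd.DataFrame:
    """Truth-only cohort draw: realised fractions and PFT rows, no images.

    Uses the same per-case random streams as :func:`generate_cohort`, so
    with identical arguments the fractions and PFT values coincide; only
    the (expensive) image synthesis is skipped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec = base_spec or PhantomSpec()
    variability = variability or CohortVariability()
    pft_couplings = pft_couplings or DEFAULT_PFT_COUPLINGS
    rows = []
    for i, child in enumerate(np.random.SeedSequence(int(seed)).spawn(n)):
        rng = np.random.default_rng(child)
        case_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        spec_i = _cohort_case_spec(i, rng, base_spec, variability, case_seed)
        _, _, _, frac = truth_geometry(spec_i)
        row = {"case_id": f"case{i:03d}", "true_fraction": frac}
        row.update(_draw_pft(rng, frac, pft_couplings))
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")


def cohort_table(cases: Iterable[PhantomCase]) -> pd.DataFrame:
    """Per-case summary table (true fractions + PFT indices)."""
    rows = []
    for pc in cases:
        row = {"case_id": pc.case.case_id,
               "true_fraction_vent": pc.true_fraction_vent,
               "true_fraction_perf": pc.true_fraction_perf}
        row.update(pc.case.pft or {})
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")
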