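"""Phantom generator: determinism, ground-truth control, cohort coupling."""
from dataclasses import replace

import numpy as np
import pytest

from vqfv import (Defect, HotSpot, PhantomSpec, coupling_for_r,
                  generate_cohort, generate_phantom, simulate_cohort_truth)
from vqfv.phantom import TRUTH_MULTIPLIER, truth_geometry
from tests.conftest import small_spec


def test_degenerate_phantom_is_two_valued(noiseless_case):
    pc = noiseless_case
    pet = pc.case.pet_vent.data
    lung = pc.truth_wl.data
    base = pc.spec.base_activity
    np.testing.assert_array_equal(pc.truth_functional_vent.data, lung)
    assert set(np.unique(pet[lung])) == {base}
    assert set(np.unique(pet[~lung])) == {pc.spec.scatter_fraction * base}


def test_same_spec_same_seed_bit_identical():
    spec = small_spec(functional_fraction=0.6, seed=5)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    np.testing.assert_array_equal(a.case.pet_vent.data, b.case.pet_vent.data)
    np.testing.assert_array_equal(a.case.pet_perf.data, b.case.pet_perf.data)
    np.testing.assert_array_equal(a.case.ct.data, b.case.ct.data)
    c = generate_phantom(replace(spec, seed=6))
    assert not np.array_equal(a.case.pet_vent.data, c.case.pet_vent.data)


def test_explicit_defect_gives_expected_fraction():
    # one zero-uptake defect; expected fraction from brute-force voxel count
    spec = small_spec(defects=())
    lung, _, _, _ = truth_geometry(spec)
    center = tuple(float(x) for x in spec.lung_geometry[0][0])
    radius = 28.0
    spec_d = replace(spec, defects=(Defect(center, radius, 0.0),))
    pc = generate_phantom(spec_d, modalities=("vent",))

    ii, jj, kk = np.nonzero(lung)
    d2 = sum(((x - c) * s) ** 2 for x, c, s in zip((ii, jj, kk), center, spec.spacing))
    expected = 1.0 - np.count_nonzero(d2 <= radius**2) / lung.sum()
    assert pc.true_fraction_vent == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("target", [0.5, 0.7, 0.9])
def test_auto_defects_hit_target_fraction(target):
    spec = small_spec(functional_fraction=target, seed=9)
    pc = generate_phantom(spec, modalities=("vent",))
    assert abs(pc.true_fraction_vent - target) <= 0.02
    assert (pc.truth_functional_vent.data <= pc.truth_wl.data).all()


def test_adding_defect_never_increases_fraction():
    spec = small_spec(defects=())
    _, _, _, f0 = truth_geometry(spec)
    lung, _, _, _ = truth_geometry(spec)
    center = tuple(float(c) for c in np.argwhere(lung)[50])
    for r in (8.0, 16.0, 24.0):
        _, _, _, f = truth_geometry(replace(spec, defects=(Defect(center, r, 0.0),)))
        assert f <= f0
        f0 = f


def test_gradient_does_not_change_truth():
    for g in (0.0, 0.5, 1.0):
        spec = small_spec(functional_fraction=0.7, ap_gradient=g, seed=4)
        pc = generate_phantom(spec, modalities=("vent",))
        if g == 0.0:
            ref = pc.truth_functional_vent.data
        else:
            np.testing.assert_array_equal(pc.truth_functional_vent.data, ref)


def test_gradient_raises_posterior_activity():
    spec = small_spec(functional_fraction=1.0, ap_gradient=1.0, defects=(),
                      psf_fwhm_mm=0.0, noise="none")
    pc = generate_phantom(spec, modalities=("vent",))
    lung = pc.truth_wl.data
    pet = pc.case.pet_vent.data
    ys = np.where(lung.any(axis=(0, 2)))[0]
    anterior = pet[:, ys.min(), :][lung[:, ys.min(), :]].mean()
    posterior = pet[:, ys.max(), :][lung[:, ys.max(), :]].mean()
    assert posterior == pytest.approx(2.0 * anterior, rel=1e-9)


def test_hotspot_locality():
    """Voxels beyond 3x the hot-spot radius keep their pre-noise activity."""
    spec = small_spec(functional_fraction=1.0, defects=(), noise="none", seed=2)
    center = tuple(float(x) for x in spec.lung_geometry[0][0])
    radius = 6.0
    plain = generate_phantom(spec, modalities=("vent",))
    hot = generate_phantom(replace(spec, hotspots=(HotSpot(center, radius, 5.0),)),
                           modalities=("vent",))
    ii, jj, kk = np.indices(spec.shape)
    d2 = sum(((x - c) * s) ** 2 for x, c, s in zip((ii, jj, kk), center, spec.spacing))
    far = d2 > (3 * radius) ** 2
    diff = np.abs(hot.case.pet_vent.data - plain.case.pet_vent.data)[far]
    # identical up to the (truncated) tail of the PSF kernel
    assert diff.max() < 1e-3 * spec.base_activity


def test_defect_outside_lung_rejected():
    spec = small_spec(defects=(Defect((0.0, 0.0, 0.0), 8.0, 0.0),))
    with pytest.raises(ValueError, match="outside the lungs"):
        generate_phantom(spec)


def test_unreachable_fraction_rejected():
    spec = small_spec(functional_fraction=0.6, auto_defect_count=0, seed=1)
    with pytest.raises(ValueError, match="unreachable"):
        generate_phantom(spec)


def test_noiseless_coupling_gives_perfect_correlation():
    from vqfv.phantom import DEFAULT_PFT_COUPLINGS, PftCoupling

    couplings = {k: PftCoupling(c.slope, c.intercept, 0.0, (-1e9, 1e9))
                 for k, c in DEFAULT_PFT_COUPLINGS.items()}
    df = simulate_cohort_truth(30, base_spec=small_spec(), pft_couplings=couplings, seed=3)
    r = np.corrcoef(df["FEV1_FVC"], df["true_fraction"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_cohort_reproducible_and_matches_truth_only_path():
    spec = small_spec()
    cases = generate_cohort(3, base_spec=spec, seed=7, modalities=("vent",))
    df = simulate_cohort_truth(3, base_spec=spec, seed=7)
    for pc in cases:
        row = df.loc[pc.case.case_id]
        assert pc.true_fraction_vent == pytest.approx(row["true_fraction"], abs=1e-12)
        for k, v in pc.case.pft.items():
            assert v == pytest.approx(row[k], abs=1e-12)
    again = generate_cohort(3, base_spec=spec, seed=7, modalities=("vent",))
    np.testing.assert_array_equal(cases[1].case.pet_vent.data,
                                  again[1].case.pet_vent.data)


def test_single_case_cohort():
    cases = generate_cohort(1, base_spec=small_spec(), seed=11, modalities=("vent",))
    assert len(cases) == 1
    assert cases[0].case.pft is not None


def test_degenerate_fraction_range_rejected():
    from vqfv import CohortVariability

    with pytest.raises(ValueError):
        CohortVariability(fraction_range=(0.9, 0.4))
    CohortVariability(fraction_range=(0.6, 0.6))  # min == max allowed


def test_coupling_for_r_population_value():
    c = coupling_for_r(0.5, 0.3, 0.8)
    sd_f = 0.5 / np.sqrt(12)
    rho = 0.5 * sd_f / np.hypot(0.5 * sd_f, c.noise_sd)
    assert rho == pytest.approx(0.8, abs=1e-12)
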