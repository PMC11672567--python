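"""SASA engine validation against closed forms and the Monte-Carlo oracle."""

import math

import numpy as np
import pytest

from abdev.sasa import (SasaParams, analytic_sphere_sasa, compute_sasa,
                        golden_spiral_points, monte_carlo_sasa, two_sphere_sasa)
from abdev.structure import StructureError
from conftest import build_structure, random_cluster_structure


def test_analytic_sphere_closed_form():
    assert analytic_sphere_sasa(1.9, 1.4) == pytest.approx(4 * math.pi * 3.3**2)
    assert analytic_sphere_sasa(1.0, 0.0) == pytest.approx(4 * math.pi)
    with pytest.raises(ValueError):
        analytic_sphere_sasa(0.0, 1.4)
    with pytest.raises(ValueError):
        analytic_sphere_sasa(-1.0, 1.4)


def test_two_sphere_cap_formula():
    # R = 3.3, h = R - d/2 = 1.65: area = 4*pi*R^2 - 2*pi*R*h = 102.64
    assert two_sphere_sasa(1.9, 1.4, 3.3) == pytest.approx(102.6358, abs=1e-3)
    with pytest.raises(ValueError):
        two_sphere_sasa(1.9, 1.4, 7.0)   # no overlap


def test_isolated_sphere_quadrature_error_below_1pct_and_converging():
    st = build_structure([("A", 1, "X", [("X1", "C", (0, 0, 0), 1.9)])])
    exact = analytic_sphere_sasa(1.9, 1.4)
    errors = []
    for n in (96, 960, 4800):
        area = list(compute_sasa(st, SasaParams(n_sphere_points=n)).per_atom.values())[0]
        errors.append(abs(area - exact) / exact)
    assert errors[1] < 0.01
    assert errors[2] <= errors[1] <= errors[0] + 1e-12


def test_two_sphere_quadrature_matches_cap_formula(two_atom_structure):
    exact = two_sphere_sasa(1.9, 1.4, 3.3)
    result = compute_sasa(two_atom_structure, SasaParams(n_sphere_points=960))
    for area in result.per_atom.values():
        assert area == pytest.approx(exact, rel=0.01)


def test_monte_carlo_oracle_on_analytic_cases(two_atom_structure):
    single = build_structure([("A", 1, "X", [("X1", "C", (0, 0, 0), 1.9)])])
    mc = monte_carlo_sasa(single, n_samples_per_atom=100_000, seed=3)
    area, se = next(iter(mc.per_atom.values())), next(iter(mc.standard_errors.values()))
    # isolated sphere: every sample exposed, zero variance
    assert area == pytest.approx(analytic_sphere_sasa(1.9, 1.4), abs=max(3 * se, 1e-9))

    mc2 = monte_carlo_sasa(two_atom_structure, n_samples_per_atom=100_000, seed=4)
    exact = two_sphere_sasa(1.9, 1.4, 3.3)
    for key, area in mc2.per_atom.items():
        assert abs(area - exact) < 3 * mc2.standard_errors[key] + 1e-9


def test_quadrature_agrees_with_monte_carlo_on_random_clusters():
    rng = np.random.default_rng(2024)
    for trial in range(20):
        st = random_cluster_structure(rng, int(rng.integers(3, 16)))
        quad = compute_sasa(st, SasaParams(n_sphere_points=2000))
        mc = monte_carlo_sasa(st, n_samples_per_atom=20_000, seed=trial)
        for key in quad.per_atom:
            se = mc.standard_errors[key]
            # 3 SE of the MC estimate plus the quadrature's own resolution
            tol = 3 * se + 4.0 * math.pi * 4.0**2 / 2000
            assert abs(quad.per_atom[key] - mc.per_atom[key]) < tol


def test_fully_caged_atom_has_zero_area():
    from abdev.synthetic import make_toy_structure
    bundle = make_toy_structure("cage")
    result = compute_sasa(bundle.structure)
    center_key = next(iter(result.per_atom))
    assert result.per_atom[center_key] == 0.0
    mc = monte_carlo_sasa(bundle.structure, n_samples_per_atom=10_000, seed=0)
    assert mc.per_atom[center_key] == 0.0


def test_additivity_per_residue_equals_atom_sum(rng):
    st = build_structure([
        ("A", 1, "X", [("X1", "C", (0, 0, 0), 1.7), ("X2", "C", (1.5, 0, 0), 1.7)]),
        ("A", 2, "X", [("X1", "C", (4.0, 0, 0), 1.7)]),
    ])
    result = compute_sasa(st)
    for key, total in result.per_residue.items():
        atom_sum = sum(v for (k, _n), v in result.per_atom.items() if k == key)
        assert total == atom_sum  # exact, not approximate


def test_translation_leaves_areas_exactly_unchanged(rng):
    # the point set rides with each atom centre, so translation is exact
    st = random_cluster_structure(rng, 8)
    base = compute_sasa(st, SasaParams(n_sphere_points=2000))
    for _res, atom in st.iter_atoms():
        atom.coords = atom.coords + np.array([5.0, -2.0, 1.0])
    moved = compute_sasa(st, SasaParams(n_sphere_points=2000))
    for key in base.per_atom:
        assert moved.per_atom[key] == base.per_atom[key]


def test_rotation_changes_areas_by_at_most_quadrature_jitter(rng):
    # the point orientation is global, so rotating the structure reshuffles
    # which boundary points count as exposed; at 50k points the jitter on
    # any atom stays below 0.1 A^2
    st = random_cluster_structure(rng, 8)
    base = compute_sasa(st, SasaParams(n_sphere_points=50_000))
    theta = 0.7
    R = np.array([[math.cos(theta), -math.sin(theta), 0],
                  [math.sin(theta), math.cos(theta), 0],
                  [0, 0, 1.0]])
    for _res, atom in st.iter_atoms():
        atom.coords = R @ atom.coords + np.array([5.0, -2.0, 1.0])
    moved = compute_sasa(st, SasaParams(n_sphere_points=50_000))
    for key in base.per_atom:
        assert abs(base.per_atom[key] - moved.per_atom[key]) < 0.1


def test_monotone_burial_adding_atom_never_increases_area(rng):
    for trial in range(5):
        st = random_cluster_structure(rng, 6)
        before = compute_sasa(st)
        extra = build_structure([("B", 1, "X", [("X1", "C", rng.uniform(-3, 3, 3), 1.8)])])
        st.chains.append(extra.chains[0])
        after = compute_sasa(st)
        for key, area in before.per_atom.items():
            assert after.per_atom[key] <= area + 1e-9


def test_grid_neighbor_search_matches_all_pairs(rng):
    for n in (5, 12, 40, 80):
        st = random_cluster_structure(rng, n, box=12.0)
        grid = compute_sasa(st, use_grid=True)
        brute = compute_sasa(st, use_grid=False)
        for key in grid.per_atom:
            assert grid.per_atom[key] == pytest.approx(brute.per_atom[key], abs=1e-9)


def test_param_validation_and_empty_structure():
    with pytest.raises(ValueError):
        SasaParams(probe_radius=-0.1)
    with pytest.raises(ValueError):
        SasaParams(n_sphere_points=4)
    with pytest.raises(ValueError):
        SasaParams(point_set="cubes")
    empty = build_structure([("A", 1, "X", [("X1", "C", (0, 0, 0), 1.7)])])
    empty.chains[0].residues[0].atoms = []
    with pytest.raises(StructureError):
        compute_sasa(empty)


def test_golden_spiral_points_are_unit_and_deterministic():
    pts = golden_spiral_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, golden_spiral_points(960))
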