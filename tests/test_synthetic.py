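"""Synthetic generators: geometry, point patterns, cohorts."""

import numpy as np
import pytest

from immunogradient import (
    ARTIFACT,
    CohortSpec,
    GradientSpec,
    MaskSpec,
    assign_cells_to_bands,
    band_density_profile,
    center_of_mass,
    compute_band_map,
    extract_interface,
    filter_short_boundaries,
    generate_cells,
    generate_papillary_mask,
    immunodrop,
    simulate_cohort,
    univariable_cox,
)


def straight_frond_spec(seed=0):
    return MaskSpec(
        canvas_um=(2400.0, 400.0),
        n_papillae=1,
        width_range_um=(60.0, 60.0),
        length_range_um=(2000.0, 2000.0),
        n_segments=1,
        curvature=0.0,
        pixel_size_um=1.0,
        seed=seed,
    )


def test_straight_frond_interface_length_matches_rectangle():
    mask = generate_papillary_mask(straight_frond_spec(0))
    iface = extract_interface(mask)
    assert len(iface) == 1
    expected = 2 * 2000.0 + 2 * 60.0
    assert iface.total_length_um == pytest.approx(expected, rel=0.05)


def test_artifact_fraction_zero_gives_no_artifacts():
    mask = generate_papillary_mask(MaskSpec(seed=1, canvas_um=(300, 300), n_papillae=2,
                                            length_range_um=(150, 250), pixel_size_um=1.0))
    assert not (mask.labels == ARTIFACT).any()


def test_artifact_fraction_positive_paints_artifacts():
    mask = generate_papillary_mask(
        MaskSpec(seed=1, canvas_um=(300, 300), n_papillae=2,
                 length_range_um=(150, 250), artifact_fraction=0.05, pixel_size_um=1.0)
    )
    frac = (mask.labels == ARTIFACT).mean()
    assert 0.02 <= frac <= 0.15


def test_mask_deterministic_per_seed():
    spec = MaskSpec(seed=7, canvas_um=(400, 400), n_papillae=3,
                    length_range_um=(200, 350), pixel_size_um=1.0)
    a = generate_papillary_mask(spec)
    b = generate_papillary_mask(spec)
    np.testing.assert_array_equal(a.labels, b.labels)


@pytest.fixture(scope="module")
def small_slide():
    spec = MaskSpec(seed=3, canvas_um=(500, 500), n_papillae=3,
                    width_range_um=(60, 100), length_range_um=(250, 400),
                    pixel_size_um=1.0)
    mask = generate_papillary_mask(spec)
    iface = filter_short_boundaries(extract_interface(mask), 500.0)
    bm = compute_band_map(mask, iface, 10.0, 150.0)
    return mask, bm


def test_cell_counts_match_programmed_intensity(small_slide):
    mask, bm = small_slide
    gspec = GradientSpec(seed=5)
    cells = generate_cells(bm, gspec, mask)
    from immunogradient import EPITHELIUM, STROMA
    from immunogradient.bands import OUTSIDE

    px_area = mask.pixel_size_um**2 * 1e-6
    expected = sum(
        gspec.expected_density(r) * bm.areas_mm2[r] for r in bm.ranks
    )
    out = bm.rank_raster == OUTSIDE
    expected += (out & (mask.labels == EPITHELIUM)).sum() * px_area * gspec.rho_epithelium
    expected += (out & (mask.labels == STROMA)).sum() * px_area * gspec.rho_stroma
    assert abs(len(cells) - expected) <= 4 * np.sqrt(expected)


def test_cells_deterministic_per_seed(small_slide):
    mask, bm = small_slide
    gspec = GradientSpec(seed=9)
    a = generate_cells(bm, gspec, mask)
    b = generate_cells(bm, gspec, mask)
    np.testing.assert_array_equal(a.xy_um, b.xy_um)


def pooled_profile(bm, mask, seeds, **gkwargs):
    """Pool band counts over several generator seeds into one profile."""
    total = {r: 0 for r in bm.ranks}
    for seed in seeds:
        cells = generate_cells(bm, GradientSpec(seed=seed, **gkwargs), mask)
        counts = assign_cells_to_bands(cells, bm).counts
        for r in bm.ranks:
            total[r] += counts[r]
    areas = {r: bm.areas_mm2[r] * len(seeds) for r in bm.ranks}
    return band_density_profile(total, areas)


def test_flat_gradient_recovers_id_1_cm_0(small_slide):
    """lambda = 0 and equal plateaus: pooled ID within Poisson sampling
    error of 1, pooled CM within sampling error of 0."""
    mask, bm = small_slide
    prof = pooled_profile(
        bm, mask, range(10),
        rho_stroma=2000.0, rho_epithelium=2000.0, decay_epithelial=0.0,
    )
    n_neg, n_pos = prof.counts[-2], prof.counts[2]
    sigma_log_id = np.sqrt(1 / n_neg + 1 / n_pos)
    assert abs(np.log(immunodrop(prof, 2))) <= 4 * sigma_log_id
    cm = center_of_mass(prof, 2)
    # delta-method sd of the density-weighted mean rank under Poisson counts
    w = {r: prof.densities[r] for r in (-2, -1, 1, 2)}
    total_d = sum(w.values())
    var = sum(
        (r - cm) ** 2 * w[r] / prof.areas_mm2[r] for r in w
    ) / total_d**2
    assert abs(cm) <= 4 * np.sqrt(var)


def test_epithelial_decay_gives_stromal_excess_signature(small_slide):
    mask, bm = small_slide
    hits = 0
    for seed in range(10):
        gspec = GradientSpec(rho_stroma=1000.0, rho_epithelium=1000.0,
                             decay_epithelial=1.0, seed=seed)
        cells = generate_cells(bm, gspec, mask)
        prof = band_density_profile(assign_cells_to_bands(cells, bm), bm.areas_mm2)
        if center_of_mass(prof, 2) < 0 and immunodrop(prof, 2) > 1:
            hits += 1
    assert hits >= 9


def test_cohort_determinism_and_schema():
    spec = CohortSpec(n=157, seed=42)
    a, b = simulate_cohort(spec), simulate_cohort(spec)
    assert a.equals(b)
    assert {"rfs_months", "event", "grade", "stage", "positive_retur",
            "recurrent_tumor", "retur_or_recurrent", "id_value"} <= set(a.columns)
    assert ((a["retur_or_recurrent"] == 1) == (
        (a["positive_retur"] == 1) | (a["recurrent_tumor"] == 1))).all()
    assert (a["rfs_months"] > 0).all()
    assert (a.loc[a["rfs_months"] < 60, "event"] == 1).all()


def test_cohort_event_fraction_near_calibrated_target():
    cohort = simulate_cohort(CohortSpec(n=4000, seed=0))
    assert cohort["event"].mean() == pytest.approx(0.248, abs=0.03)


def test_large_n_univariable_hr_consistency():
    """With the other effects switched off (hazard-ratio estimates are not
    collapsible over omitted covariates), the univariable estimate converges
    to the programmed history hazard ratio."""
    spec = CohortSpec(n=2000, beta_g3=0.0, beta_id=0.0, seed=13)
    cohort = simulate_cohort(spec)
    res = univariable_cox(cohort, "retur_or_recurrent")
    assert res.hr["retur_or_recurrent"] == pytest.approx(4.4492, rel=0.10)


def test_multivariable_fit_recovers_all_betas_jointly():
    cohort = simulate_cohort(CohortSpec(n=2000, seed=14))
    from immunogradient.survival import fit_multivariable

    res = fit_multivariable(cohort, ("retur_or_recurrent", "g3", "id_value"))
    assert res.hr["retur_or_recurrent"] == pytest.approx(4.4492, rel=0.15)
    assert res.hr["g3"] == pytest.approx(2.3672, rel=0.15)
    assert res.hr["id_value"] == pytest.approx(5.5072, rel=0.15)


def test_censoring_rate_monotone_in_baseline_scale():
    fracs = []
    for rate in (5e-5, 1.5e-4, 6e-4):
        cohort = simulate_cohort(CohortSpec(n=1500, baseline_rate=rate, seed=2))
        fracs.append(1 - cohort["event"].mean())  # censoring fraction
    assert fracs[0] > fracs[1] > fracs[2]


def test_supplied_id_values_are_used():
    ids = np.array([0.5, 1.5, 2.5])
    cohort = simulate_cohort(CohortSpec(n=6, seed=1), id_values=ids)
    np.testing.assert_allclose(np.sort(np.unique(cohort["id_value"])), ids)
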