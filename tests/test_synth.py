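"""Synthetic-data generator: determinism, hierarchy, limits, grids, time-courses."""

import numpy as np
import pytest

from sersnet import (
    ClassProfile,
    SyntheticConfig,
    TimecourseConfig,
    class_template,
    generate_dataset,
    generate_mapping_grid,
    generate_timecourse,
    make_axis,
)
from sersnet.errors import ConfigError
from sersnet.interpret import band_intensities
from sersnet.synth import BAND_CATALOG, default_profiles


def test_default_config_matches_study_design():
    cfg = SyntheticConfig()
    assert cfg.n_cells == (196, 210)
    assert cfg.spectra_per_cell == 50
    assert cfg.axis.size == 1015
    # total spectra count: 406 cells x 50 replicates
    assert sum(cfg.n_cells) * cfg.spectra_per_cell == 20300


def test_generated_counts_and_metadata(small_config, small_dataset):
    n_expected = sum(small_config.n_cells) * small_config.spectra_per_cell
    assert small_dataset.n_spectra == n_expected
    assert small_dataset.n_points == small_config.axis.size
    labels, counts = np.unique(small_dataset.labels, return_counts=True)
    expected = {
        "mature": small_config.n_cells[0] * small_config.spectra_per_cell,
        "immature": small_config.n_cells[1] * small_config.spectra_per_cell,
    }
    assert dict(zip(labels, counts)) == expected
    assert small_dataset.meta["cell_id"].nunique() == sum(small_config.n_cells)


def test_seeded_determinism(small_config):
    a = generate_dataset(small_config)
    b = generate_dataset(small_config)
    assert np.array_equal(a.intensities, b.intensities)
    assert a.meta.equals(b.meta)
    c = generate_dataset(SyntheticConfig(
        n_cells=small_config.n_cells,
        spectra_per_cell=small_config.spectra_per_cell,
        seed=small_config.seed + 1,
    ))
    assert not np.array_equal(a.intensities, c.intensities)


def test_noiseless_single_spectrum_equals_class_template():
    mature, immature = default_profiles()
    zeroed = tuple(
        ClassProfile(p.label, p.amp_means, tuple(0.0 for _ in p.amp_sds), p.baseline_coeffs)
        for p in (mature, immature)
    )
    cfg = SyntheticConfig(
        profiles=zeroed, n_cells=(1, 1), spectra_per_cell=1,
        cell_scale_sd=0.0, noise_sd=0.0, seed=7,
    )
    ds = generate_dataset(cfg)
    for label in ("mature", "immature"):
        spectrum = ds.intensities[ds.labels == label][0]
        np.testing.assert_allclose(spectrum, class_template(cfg, label), atol=1e-12)


def test_mature_template_elevated_at_tryptophan_band():
    cfg = SyntheticConfig()
    w = cfg.axis
    i1623 = np.argmin(np.abs(w - 1623.0))
    mat = class_template(cfg, "mature")
    imm = class_template(cfg, "immature")
    assert mat[i1623] > 2.0 * imm[i1623]
    # bands without a class effect coincide
    i1000 = np.argmin(np.abs(w - 1000.0))
    np.testing.assert_allclose(mat[i1000], imm[i1000], rtol=0.05)


def test_cell_hierarchy_intra_less_than_inter_variance():
    """With cell_scale_sd >> noise_sd, replicates of a cell cluster tightly
    around the cell template while cells spread widely."""
    cfg = SyntheticConfig(
        n_cells=(40, 40), spectra_per_cell=12, cell_scale_sd=0.3, noise_sd=0.01, seed=21,
    )
    ds = generate_dataset(cfg)
    values = band_intensities(ds, 1444.0)
    cells = ds.cell_ids
    intra = np.mean([values[cells == c].var(ddof=1) for c in np.unique(cells)])
    cell_means = np.array([values[cells == c].mean() for c in np.unique(cells)])
    inter = cell_means.var(ddof=1)
    assert intra < inter


def test_separability_dial_bayes_error_decreases_with_tryptophan_gap():
    """A likelihood-ratio (nearest-template) oracle on noisy template draws:
    larger 1623 cm^-1 amplitude gaps yield monotonically smaller error."""
    rng = np.random.default_rng(0)
    errors = []
    for ratio in (1.0, 1.3, 2.0):
        mature, immature = default_profiles()
        means = tuple(
            m * (ratio if b.center == 1623.0 else 1.0)
            for m, b in zip(immature.amp_means, BAND_CATALOG)
        )
        cfg = SyntheticConfig(
            profiles=(
                ClassProfile("mature", means, tuple(0.0 for _ in means)),
                ClassProfile("immature", immature.amp_means, tuple(0.0 for _ in means)),
            ),
            cell_scale_sd=0.0, noise_sd=0.5, seed=1,
        )
        t_mat = class_template(cfg, "mature")
        t_imm = class_template(cfg, "immature")
        n = 1500
        draws = t_mat + rng.normal(0, cfg.noise_sd, (n, t_mat.size))
        # iso-Gaussian likelihood ratio = nearest template; exact distance
        # ties (identical templates) count half, as a random tie-break would
        d_mat = ((draws - t_mat) ** 2).sum(axis=1)
        d_imm = ((draws - t_imm) ** 2).sum(axis=1)
        errors.append(np.mean(d_mat > d_imm) + 0.5 * np.mean(d_mat == d_imm))
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[0] == pytest.approx(0.5, abs=0.05)  # identical templates


@pytest.mark.parametrize(
    "kwargs",
    [
        {"axis": make_axis(600, 700, 5)},  # too few points
        {"n_cells": (0, 5)},
        {"spectra_per_cell": 0},
        {"noise_sd": -0.1},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SyntheticConfig(**kwargs).validate()


# ---------------------------------------------------------------------------
# time-course


def test_timecourse_shapes_ids_and_monotone_tryptophan():
    tc = TimecourseConfig(base=SyntheticConfig(n_cells=(20, 20), spectra_per_cell=5, seed=3))
    datasets = generate_timecourse(tc)
    assert list(datasets) == [2.0, 4.0, 6.0]
    cell_sets = [set(d.cell_ids) for d in datasets.values()]
    assert cell_sets[0] == cell_sets[1] == cell_sets[2]
    treated_means = [
        band_intensities(d.subset(d.labels == "mature"), 1623.0).mean()
        for d in datasets.values()
    ]
    assert treated_means[0] <= treated_means[1] <= treated_means[2]
    for d in datasets.values():
        assert set(np.unique(d.meta["time_point_h"])) == {d.meta["time_point_h"].iloc[0]}


def test_timecourse_zero_progress_arms_exchangeable():
    """At progress 0 the treated arm still has the immature profile, so the
    two arms' tryptophan intensities are statistically indistinguishable."""
    from scipy import stats

    tc = TimecourseConfig(
        base=SyntheticConfig(n_cells=(60, 60), spectra_per_cell=2, seed=9),
        time_points_h=(2.0,),
        maturation_progress=(0.0,),
    )
    ds = generate_timecourse(tc)[2.0]
    treated = band_intensities(ds.subset(ds.labels == "mature"), 1623.0)
    control = band_intensities(ds.subset(ds.labels == "immature"), 1623.0)
    p = stats.ttest_ind(treated, control, equal_var=False).pvalue
    assert p > 0.01


def test_timecourse_full_progress_matches_mature_profile():
    base = SyntheticConfig(n_cells=(30, 30), spectra_per_cell=3, seed=13)
    tc = TimecourseConfig(base=base, time_points_h=(2.0,), maturation_progress=(1.0,))
    ds = generate_timecourse(tc)[2.0]
    static = generate_dataset(base)
    for d in (ds, static):
        ratio = (
            band_intensities(d.subset(d.labels == "mature"), 1623.0).mean()
            / band_intensities(d.subset(d.labels == "immature"), 1623.0).mean()
        )
        assert ratio > 2.0  # both draws show the full mature/immature contrast


@pytest.mark.parametrize(
    "kwargs",
    [
        {"time_points_h": (), "maturation_progress": ()},
        {"maturation_progress": (0.5, 0.4, 1.0)},  # decreasing
        {"maturation_progress": (0.5, 0.8, 1.2)},  # out of range
    ],
)
def test_timecourse_invalid_configs(kwargs):
    with pytest.raises(ConfigError):
        TimecourseConfig(base=SyntheticConfig(), **kwargs).validate()


# ---------------------------------------------------------------------------
# mapping grids


def test_mapping_grid_single_node():
    cfg = SyntheticConfig(n_cells=(1, 1), spectra_per_cell=1, seed=5)
    ds = generate_mapping_grid(cfg, (1, 1))
    assert ds.n_spectra == 1
    assert ds.meta.loc[0, ["x", "y"]].tolist() == [0.0, 0.0]


def test_mapping_grid_interior_exceeds_periphery_and_class_contrast():
    cfg = SyntheticConfig(seed=17)
    mature_grid = generate_mapping_grid(cfg, (20, 20), label="mature")
    immature_grid = generate_mapping_grid(cfg, (20, 20), label="immature")

    def contrast(ds):
        inside = ds.meta["cell_id"] == "cell"
        v = band_intensities(ds, 1623.0)
        return v[inside.to_numpy()].mean() - v[~inside.to_numpy()].mean()

    c_mat, c_imm = contrast(mature_grid), contrast(immature_grid)
    assert c_mat > 0
    assert c_imm < c_mat  # tryptophan contrast far weaker in immature cells
    # carbohydrate channel: similar contrast in both classes
    def contrast1025(ds):
        inside = (ds.meta["cell_id"] == "cell").to_numpy()
        v = band_intensities(ds, 1025.0)
        return v[inside].mean() - v[~inside].mean()

    assert contrast1025(mature_grid) == pytest.approx(contrast1025(immature_grid), rel=0.5)


def test_mapping_grid_zero_size_rejected():
    with pytest.raises(ConfigError):
        generate_mapping_grid(SyntheticConfig(), (0, 5))
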