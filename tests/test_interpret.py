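"""Band intensities, the tryptophan/carbohydrate ratio marker, model
contributions and mapping images."""

import numpy as np
import pandas as pd
import pytest

from sersnet import (
    ClassProfile,
    ModelConfig,
    SpectraDataset,
    SplitSpec,
    SyntheticConfig,
    TrainConfig,
    band_intensity,
    build_model,
    generate_dataset,
    generate_mapping_grid,
    map_channel_image,
    minmax_normalize,
    peak_contribution,
    probability_heatmap,
    ratio_statistic,
    split_dataset,
    train,
)
from sersnet.errors import (
    DegenerateRatioError,
    IntegrityError,
    RangeError,
    StateError,
)
from sersnet.interpret import band_intensities
from sersnet.preprocess import average_per_cell
from sersnet.synth import BAND_CATALOG, default_profiles


# ---------------------------------------------------------------------------
# band intensity


def test_band_intensity_zero_spectrum(default_axis):
    assert band_intensity(np.zeros(default_axis.size), default_axis, 1623.0) == 0.0


def test_band_intensity_gaussian_window(default_axis):
    """Unit Gaussian (FWHM 12) averaged over +/-6: compare to an
    independent discrete quadrature over the same window."""
    spectrum = np.exp(-4 * np.log(2) * ((default_axis - 1623.0) / 12.0) ** 2)
    value = band_intensity(spectrum, default_axis, 1623.0, half_window=6.0)
    mask = np.abs(default_axis - 1623.0) <= 6.0
    expected = spectrum[mask].sum() / mask.sum()  # oracle: direct window mean
    assert value == pytest.approx(expected, abs=1e-12)
    assert 0.7 <= value <= 1.0


def test_band_intensity_whole_axis_equals_global_mean(default_axis):
    rng = np.random.default_rng(0)
    spectrum = rng.random(default_axis.size)
    full = band_intensity(spectrum, default_axis, 1150.0, half_window=600.0)
    assert full == pytest.approx(spectrum.mean())


def test_band_intensity_window_outside_axis(default_axis):
    with pytest.raises(RangeError):
        band_intensity(np.zeros(default_axis.size), default_axis, 3000.0, 6.0)


# ---------------------------------------------------------------------------
# ratio marker


def _percell(config):
    return average_per_cell(minmax_normalize(generate_dataset(config)))


def test_ratio_mature_exceeds_immature(small_config):
    report = ratio_statistic(_percell(small_config))
    assert report.group_means()["mature"] > report.group_means()["immature"]
    assert report.pvalue < 1e-4


def test_ratio_null_calibration():
    """Two identically generated groups: p-values are ~uniform, so ~5% of
    seeded replicates are significant at 0.05."""
    mature, immature = default_profiles()
    # null: the "mature" arm uses the immature profile (same amplitudes)
    null_profiles = (
        ClassProfile("mature", immature.amp_means, immature.amp_sds),
        immature,
    )
    axis_cfg = dict(
        profiles=null_profiles, n_cells=(40, 40), spectra_per_cell=1,
        cell_scale_sd=0.15, noise_sd=0.02,
    )
    hits = 0
    n_rep = 400
    for seed in range(n_rep):
        ds = _percell(SyntheticConfig(seed=seed, **axis_cfg))
        if ratio_statistic(ds).pvalue < 0.05:
            hits += 1
    assert hits / n_rep == pytest.approx(0.05, abs=0.03)


def test_ratio_mann_whitney_option(small_config):
    report = ratio_statistic(_percell(small_config), test="mann_whitney")
    assert report.test == "mann_whitney"
    assert report.pvalue < 1e-4


def test_ratio_identical_constant_groups_degenerate():
    w = np.linspace(600, 1700, 300)
    spectrum = np.ones(300)
    meta = pd.DataFrame(
        {
            "spectrum_id": ["a", "b", "c", "d"],
            "cell_id": ["a", "b", "c", "d"],
            "label": ["mature", "mature", "immature", "immature"],
        }
    )
    ds = SpectraDataset(w, np.tile(spectrum, (4, 1)), meta)

    report = ratio_statistic(ds)
    assert report.statistic == 0.0
    assert report.pvalue == 1.0


def test_ratio_zero_denominator_named():
    w = np.linspace(600, 1700, 200)
    X = np.zeros((4, 200))
    X[:, np.abs(w - 1623) <= 6] = 1.0  # numerator present, denominator zero
    meta = pd.DataFrame(
        {
            "spectrum_id": list("abcd"),
            "cell_id": list("abcd"),
            "label": ["mature", "mature", "immature", "immature"],
        }
    )
    with pytest.raises(DegenerateRatioError, match="'a'"):
        ratio_statistic(SpectraDataset(w, X, meta))


def test_ratio_invariant_to_global_rescaling(small_config):
    """Pre-normalization rescaling of raw intensities does not change the
    per-cell ratios (normalization absorbs the scale)."""
    raw = generate_dataset(small_config)
    scaled = SpectraDataset(raw.wavenumbers, raw.intensities * 37.5, raw.meta)
    r1 = ratio_statistic(average_per_cell(minmax_normalize(raw)))
    r2 = ratio_statistic(average_per_cell(minmax_normalize(scaled)))
    np.testing.assert_allclose(r1.ratios["mature"], r2.ratios["mature"], rtol=1e-9)
    assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# contributions


def _train_quick(config, seed=0, epochs=3, arch="cnn"):
    data = minmax_normalize(generate_dataset(config))
    tr, va, te = split_dataset(data, SplitSpec(seed=seed))
    net, _ = build_model(arch, ModelConfig(), data.n_points, seed=seed)
    train(net, tr, va, TrainConfig(epochs=epochs, seed=seed))
    return net, te


def test_contributions_sum_to_100(trained_cnn):
    _, _, te = trained_cnn["splits"]
    for method in ("occlusion", "weight_backprojection"):
        report = peak_contribution(trained_cnn["model"], te, method=method)
        assert report.contributions.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(report.contributions >= 0)


def test_untrained_model_rejected(small_normalized):
    net, _ = build_model("cnn", ModelConfig(), small_normalized.n_points, seed=0)
    with pytest.raises(StateError):
        peak_contribution(net, small_normalized)


def test_tryptophan_top_band_when_only_informative():
    """Generator where only 1623 cm^-1 differs between classes: both
    contribution methods must rank it first."""
    mature, immature = default_profiles()
    only_trp = tuple(
        m * (3.0 if b.center == 1623.0 else 1.0)
        for m, b in zip(immature.amp_means, BAND_CATALOG)
    )
    cfg = SyntheticConfig(
        profiles=(
            ClassProfile("mature", only_trp, tuple(0.1 * m for m in only_trp)),
            immature,
        ),
        n_cells=(20, 20), spectra_per_cell=6, seed=31,
    )
    net, te = _train_quick(cfg, seed=31, epochs=4)
    for method in ("occlusion", "weight_backprojection"):
        report = peak_contribution(net, te, method=method)
        assert report.top_band() == 1623.0, method


def test_shuffled_labels_no_dominant_band():
    """Models trained on label-shuffled data carry no band information:
    no band exceeds twice the uniform share (5-seed median of the max)."""
    rng = np.random.default_rng(7)
    maxima = []
    for seed in range(5):
        cfg = SyntheticConfig(n_cells=(12, 12), spectra_per_cell=4, seed=seed)
        data = minmax_normalize(generate_dataset(cfg))
        shuffled = data.meta.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        data = SpectraDataset(data.wavenumbers, data.intensities, shuffled)
        try:
            tr, va, te = split_dataset(data, SplitSpec(unit="spectrum", seed=seed))
            net, _ = build_model("cnn", ModelConfig(), data.n_points, seed=seed)
            train(net, tr, va, TrainConfig(epochs=2, seed=seed))
        except Exception:  # pragma: no cover - shuffle can unbalance tiny sets
            continue
        report = peak_contribution(net, te, method="occlusion")
        maxima.append(report.contributions.max())
    uniform = 100.0 / len(BAND_CATALOG)
    assert np.median(maxima) <= 2.0 * uniform


def test_occlusion_and_backprojection_correlate(trained_cnn):
    from scipy import stats

    _, _, te = trained_cnn["splits"]
    occ = peak_contribution(trained_cnn["model"], te, method="occlusion")
    bp = peak_contribution(trained_cnn["model"], te, method="weight_backprojection")
    rho = stats.spearmanr(occ.contributions, bp.contributions).statistic
    assert rho > 0


# ---------------------------------------------------------------------------
# mapping images and probability heatmaps


def test_map_single_spectrum():
    cfg = SyntheticConfig(seed=5)
    ds = generate_mapping_grid(cfg, (1, 1))
    img = map_channel_image(ds, 1623.0)
    assert img.shape == (1, 1)
    assert img.iloc[0, 0] == pytest.approx(band_intensities(ds, 1623.0)[0])


def test_map_interior_exceeds_periphery():
    cfg = SyntheticConfig(seed=5)
    ds = generate_mapping_grid(cfg, (20, 20), label="mature")
    img = map_channel_image(ds, 1623.0).to_numpy()
    inside = (ds.meta["cell_id"] == "cell").to_numpy().reshape(20, 20)
    assert img[inside].mean() > img[~inside].mean()


def test_map_constant_field_is_constant():
    w = np.linspace(600, 1700, 64)
    n = 9
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "x": [float(i % 3) for i in range(n)],
            "y": [float(i // 3) for i in range(n)],
        }
    )
    ds = SpectraDataset(w, np.full((n, 64), 2.5), meta)
    img = map_channel_image(ds, 1025.0)
    assert np.allclose(img.to_numpy(), 2.5)


def test_map_duplicate_positions_rejected():
    w = np.linspace(600, 1700, 16)
    meta = pd.DataFrame(
        {"spectrum_id": ["a", "b"], "x": [0.0, 0.0], "y": [0.0, 0.0]}
    )
    with pytest.raises(IntegrityError, match="duplicate"):
        map_channel_image(SpectraDataset(w, np.zeros((2, 16)), meta), 1025.0)


def test_probability_heatmap_predictions(trained_cnn):
    from sersnet import evaluate

    _, _, te = trained_cnn["splits"]
    report = evaluate(trained_cnn["model"], te)
    table = probability_heatmap(report)
    assert len(table) == te.n_spectra
    mismatch = np.mean(table["true_label"] != table["predicted_label"])
    assert mismatch == pytest.approx(1.0 - report.accuracy, abs=1e-12)
    # tie rule: probability exactly at threshold -> positive class
    row = table.iloc[0]
    assert set(table["predicted_label"]) <= {"mature", "immature"}
    assert row is not None
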