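"""Seeded synthetic single-cell SERS datasets for dendritic-cell maturation.

Real single-cell SERS acquisitions of mature vs immature dendritic cells are
not publicly deposited, so this module simulates datasets with the same
statistical structure the downstream analysis assumes:

* a shared uniform wavenumber axis (default 600-1700 cm^-1, 1015 points);
* a catalog of biologically assigned Raman bands modeled as Gaussians
  (methionine 647, O-P-O of DNA 826, phenylalanine 1000, ribose C-O 1018,
  carbohydrates 1025, protein C-C/C-N 1161, tyrosine 1206, fatty acid 1444,
  COO- 1562, tryptophan 1623 cm^-1);
* class-dependent band amplitudes — maturation chiefly elevates the
  tryptophan band at 1623 cm^-1;
* a cell hierarchy: per-cell band amplitudes and a per-cell multiplicative
  scale (log-normal, emulating nanoparticle-uptake variation) shared by all
  replicate spectra of that cell, plus additive per-spectrum noise;
* a smooth quadratic substrate baseline;
* time-course variants in which treated cells interpolate from the immature
  toward the mature profile, and mapping grids in which an interior cell
  region sits on a baseline-only periphery.

Everything is driven by explicit config records and a single integer seed,
so identical configs reproduce bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SpectraDataset, make_axis, validate_axis
from .errors import ConfigError

__all__ = [
    "Band",
    "ClassProfile",
    "SyntheticConfig",
    "TimecourseConfig",
    "BAND_CATALOG",
    "default_profiles",
    "class_template",
    "generate_dataset",
    "generate_timecourse",
    "generate_mapping_grid",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class Band:
    """A Raman band: Gaussian line at ``center`` with the given FWHM (cm^-1)."""

    center: float
    fwhm: float = 12.0
    assignment: str = ""

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian line shape evaluated on the axis."""
        return np.exp(-_LN2_4 * ((wavenumbers - self.center) / self.fwhm) ** 2)


#: Band catalog with the literature assignments used throughout the package.
BAND_CATALOG: tuple[Band, ...] = (
    Band(647.0, 12.0, "methionine"),
    Band(826.0, 12.0, "O-P-O stretch of DNA"),
    Band(1000.0, 12.0, "phenylalanine"),
    Band(1018.0, 12.0, "C-O stretch of ribose"),
    Band(1025.0, 12.0, "carbohydrates"),
    Band(1161.0, 12.0, "C-C/C-N stretch of proteins"),
    Band(1206.0, 12.0, "tyrosine"),
    Band(1444.0, 12.0, "fatty acid"),
    Band(1562.0, 12.0, "COO-"),
    Band(1623.0, 12.0, "tryptophan"),
)

# Baseline immature-cell mean amplitudes (arbitrary units), one per catalog
# band, and the mature/immature amplitude ratio per band. Maturation mainly
# triples the tryptophan band and mildly elevates the DNA- and
# protein-backbone bands.
_IMMATURE_MEANS = {
    647.0: 0.30,
    826.0: 0.45,
    1000.0: 0.80,
    1018.0: 0.40,
    1025.0: 0.60,
    1161.0: 0.40,
    1206.0: 0.35,
    1444.0: 0.70,
    1562.0: 0.45,
    1623.0: 0.35,
}
_MATURE_RATIOS = {826.0: 1.15, 1161.0: 1.15, 1623.0: 3.0}

#: Fraction of the mean used as the cell-to-cell amplitude standard deviation.
_AMP_SD_FRACTION = 0.10

#: Quadratic substrate baseline coefficients in the reduced coordinate
#: u = (w - w_min) / (w_max - w_min):  b(u) = c0 + c1 u + c2 u^2.
_BASELINE_COEFFS = (0.05, 0.03, 0.02)


@dataclass(frozen=True)
class ClassProfile:
    """Generative description of one cell class.

    ``amp_means``/``amp_sds`` align with the band catalog of the owning
    config; ``baseline_coeffs`` are quadratic-polynomial coefficients in the
    reduced axis coordinate u in [0, 1].
    """

    label: str
    amp_means: tuple[float, ...]
    amp_sds: tuple[float, ...]
    baseline_coeffs: tuple[float, float, float] = _BASELINE_COEFFS

    def validate(self, n_bands: int) -> None:
        if self.label not in ("mature", "immature"):
            raise ConfigError(f"profile label must be mature/immature, got {self.label!r}")
        if len(self.amp_means) != n_bands or len(self.amp_sds) != n_bands:
            raise ConfigError(
                f"profile {self.label!r}: amplitude vectors must have {n_bands} entries"
            )
        if any(m < 0 for m in self.amp_means):
            raise ConfigError(f"profile {self.label!r}: amplitude means must be >= 0")
        if any(s < 0 for s in self.amp_sds):
            raise ConfigError(f"profile {self.label!r}: amplitude SDs must be >= 0")


def default_profiles() -> tuple[ClassProfile, ClassProfile]:
    """Return the default (mature, immature) class profiles."""
    imm = tuple(_IMMATURE_MEANS[b.center] for b in BAND_CATALOG)
    mat = tuple(
        _IMMATURE_MEANS[b.center] * _MATURE_RATIOS.get(b.center, 1.0)
        for b in BAND_CATALOG
    )
    return (
        ClassProfile("mature", mat, tuple(_AMP_SD_FRACTION * m for m in mat)),
        ClassProfile("immature", imm, tuple(_AMP_SD_FRACTION * m for m in imm)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative description of a two-class synthetic SERS dataset.

    Defaults reproduce the study design: 196 mature + 210 immature cells at
    50 spectra per cell (20,300 spectra), per-cell log-normal scale SD 0.15,
    additive noise SD 0.02 on the O(1) amplitude scale.
    """

    axis: np.ndarray = field(default_factory=make_axis)
    bands: tuple[Band, ...] = BAND_CATALOG
    profiles: tuple[ClassProfile, ClassProfile] = field(default_factory=default_profiles)
    n_cells: tuple[int, int] = (196, 210)  # (mature, immature)
    spectra_per_cell: int = 50
    cell_scale_sd: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        axis = validate_axis(self.axis)
        if axis.size < 8:
            raise ConfigError(f"axis must have >= 8 points, got {axis.size}")
        for band in self.bands:
            if band.fwhm <= 0:
                raise ConfigError(f"band {band.center} cm^-1: FWHM must be > 0")
            if not (axis[0] <= band.center <= axis[-1]):
                raise ConfigError(
                    f"band center {band.center} cm^-1 outside axis "
                    f"[{axis[0]:g}, {axis[-1]:g}]"
                )
        labels = sorted(p.label for p in self.profiles)
        if labels != ["immature", "mature"]:
            raise ConfigError("profiles must be one mature and one immature record")
        for p in self.profiles:
            p.validate(len(self.bands))
        if min(self.n_cells) < 1 or self.spectra_per_cell < 1:
            raise ConfigError(
                f"cell/spectrum counts must be >= 1, got n_cells={self.n_cells}, "
                f"spectra_per_cell={self.spectra_per_cell}"
            )
        if self.noise_sd < 0 or self.cell_scale_sd < 0:
            raise ConfigError("noise_sd and cell_scale_sd must be >= 0")
        return self

    def profile(self, label: str) -> ClassProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise ConfigError(f"no profile with label {label!r}")


@dataclass(frozen=True)
class TimecourseConfig:
    """A maturation time-course: treated cells drift from immature to mature.

    ``maturation_progress`` gives, per time point, the interpolation weight
    w in [0, 1] applied to the treated arm's band amplitudes:
    amp(t) = (1 - w) * immature + w * mature. Control cells stay immature.
    Default kinetics (0.5, 0.8, 1.0) at 2/4/6 h reflect maturation being
    well underway by 2 h and complete by 6 h.
    """

    base: SyntheticConfig = field(default_factory=SyntheticConfig)
    time_points_h: tuple[float, ...] = (2.0, 4.0, 6.0)
    maturation_progress: tuple[float, ...] = (0.5, 0.8, 1.0)

    def validate(self) -> "TimecourseConfig":
        self.base.validate()
        if len(self.time_points_h) == 0:
            raise ConfigError("time_points_h must not be empty")
        if len(self.maturation_progress) != len(self.time_points_h):
            raise ConfigError("one maturation_progress weight per time point required")
        w = self.maturation_progress
        if any(not (0.0 <= x <= 1.0) for x in w):
            raise ConfigError("maturation_progress weights must lie in [0, 1]")
        if any(b < a for a, b in zip(w, w[1:])):
            raise ConfigError("maturation_progress must be non-decreasing")
        if list(self.time_points_h) != sorted(self.time_points_h):
            raise ConfigError("time_points_h must be ordered")
        return self


# ---------------------------------------------------------------------------
# template construction


def _band_matrix(config: SyntheticConfig) -> np.ndarray:
    """(n_points, n_bands) matrix of unit-amplitude band line shapes."""
    return np.stack([b.profile(config.axis) for b in config.bands], axis=1)


def _baseline(config: SyntheticConfig, coeffs: Sequence[float]) -> np.ndarray:
    w = config.axis
    u = (w - w[0]) / (w[-1] - w[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def class_template(config: SyntheticConfig, label: str) -> np.ndarray:
    """Noiseless mean spectrum of a class: baseline + sum of mean-amplitude bands."""
    config.validate()
    p = config.profile(label)
    G = _band_matrix(config)
    return _baseline(config, p.baseline_coeffs) + G @ np.asarray(p.amp_means)


# ---------------------------------------------------------------------------
# dataset generation


def _draw_cell_effects(
    rng: np.random.Generator, n_cells: int, n_bands: int, cell_scale_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell band z-scores and multiplicative scales (shared by replicates)."""
    z = rng.standard_normal((n_cells, n_bands))
    scales = np.exp(rng.normal(0.0, cell_scale_sd, size=n_cells)) if cell_scale_sd > 0 \
        else np.ones(n_cells)
    return z, scales


def _cell_block(
    config: SyntheticConfig,
    rng: np.random.Generator,
    amp_means: np.ndarray,
    amp_sds: np.ndarray,
    baseline_coeffs: Sequence[float],
    z: np.ndarray,
    scales: np.ndarray,
    cell_ids: Sequence[str],
    label: str,
    spectra_per_cell: int,
    G: np.ndarray,
    id_suffix: str = "",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Spectra + metadata for one arm given frozen per-cell effects."""
    amps = np.clip(amp_means[None, :] + z * amp_sds[None, :], 0.0, None)
    templates = _baseline(config, baseline_coeffs)[None, :] + (
        scales[:, None] * (amps @ G.T)
    )
    n_cells, n_points = templates.shape
    block = np.repeat(templates, spectra_per_cell, axis=0)
    if config.noise_sd > 0:
        block = block + rng.normal(0.0, config.noise_sd, size=block.shape)
    else:
        # keep the stream position independent of noise_sd == 0 vs > 0 is not
        # required; a zero-noise draw is simply skipped.
        block = block.copy()
    meta = pd.DataFrame(
        {
            "spectrum_id": [
                f"{cid}{id_suffix}_s{k:03d}"
                for cid in cell_ids
                for k in range(spectra_per_cell)
            ],
            "cell_id": np.repeat(list(cell_ids), spectra_per_cell),
            "label": label,
        }
    )
    return block, meta


def generate_dataset(config: SyntheticConfig) -> SpectraDataset:
    """Draw a seeded two-class dataset of ``sum(n_cells) * spectra_per_cell`` spectra.

    Each spectrum is its cell's template (class baseline plus per-cell-and-band
    Gaussian amplitudes, scaled by the cell's log-normal uptake factor) plus
    i.i.d. additive noise. Identical configs yield bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = _band_matrix(config)
    blocks, metas = [], []
    for label, n_cells, prefix in (
        ("mature", config.n_cells[0], "M"),
        ("immature", config.n_cells[1], "I"),
    ):
        p = config.profile(label)
        z, scales = _draw_cell_effects(rng, n_cells, len(config.bands), config.cell_scale_sd)
        cell_ids = [f"{prefix}{i + 1:04d}" for i in range(n_cells)]
        block, meta = _cell_block(
            config,
            rng,
            np.asarray(p.amp_means),
            np.asarray(p.amp_sds),
            p.baseline_coeffs,
            z,
            scales,
            cell_ids,
            label,
            config.spectra_per_cell,
            G,
        )
        blocks.append(block)
        metas.append(meta)
    ds = SpectraDataset(
        config.axis.copy(),
        np.vstack(blocks),
        pd.concat(metas, ignore_index=True),
    )
    return ds.validate()


def generate_timecourse(config: TimecourseConfig) -> dict[float, SpectraDataset]:
    """One dataset per time point with persistent cell identities.

    The treated arm (labeled ``mature``) interpolates its band amplitudes
    from the immature toward the mature profile by the per-time-point
    progress weight; the control arm stays immature. Per-cell random effects
    (band z-scores and uptake scale) are drawn once and reused at every time
    point, so a treated cell's tryptophan intensity rises monotonically with
    the progress weight; only the additive noise is redrawn per acquisition.
    """
    config.validate()
    base = config.base
    rng = np.random.default_rng(base.seed)
    G = _band_matrix(base)
    mat = base.profile("mature")
    imm = base.profile("immature")
    n_treated, n_control = base.n_cells
    z_t, s_t = _draw_cell_effects(rng, n_treated, len(base.bands), base.cell_scale_sd)
    z_c, s_c = _draw_cell_effects(rng, n_control, len(base.bands), base.cell_scale_sd)
    treated_ids = [f"T{i + 1:04d}" for i in range(n_treated)]
    control_ids = [f"C{i + 1:04d}" for i in range(n_control)]
    mat_means, imm_means = np.asarray(mat.amp_means), np.asarray(imm.amp_means)
    mat_sds, imm_sds = np.asarray(mat.amp_sds), np.asarray(imm.amp_sds)

    out: dict[float, SpectraDataset] = {}
    for t, w in zip(config.time_points_h, config.maturation_progress):
        means_t = (1.0 - w) * imm_means + w * mat_means
        sds_t = (1.0 - w) * imm_sds + w * mat_sds
        suffix = f"_t{t:g}h"
        blk_t, meta_t = _cell_block(
            base, rng, means_t, sds_t, imm.baseline_coeffs, z_t, s_t,
            treated_ids, "mature", base.spectra_per_cell, G, suffix,
        )
        blk_c, meta_c = _cell_block(
            base, rng, imm_means, imm_sds, imm.baseline_coeffs, z_c, s_c,
            control_ids, "immature", base.spectra_per_cell, G, suffix,
        )
        meta = pd.concat([meta_t, meta_c], ignore_index=True)
        meta["time_point_h"] = float(t)
        out[float(t)] = SpectraDataset(
            base.axis.copy(), np.vstack([blk_t, blk_c]), meta
        ).validate()
    return out


def generate_mapping_grid(
    config: SyntheticConfig,
    grid_shape: tuple[int, int] = (20, 20),
    label: str = "mature",
    cell_radius_fraction: float = 0.35,
) -> SpectraDataset:
    """A rows x cols mapping acquisition: one spectrum per 1-um grid node.

    Nodes within ``cell_radius_fraction * min(grid_shape)`` of the grid
    center carry one simulated cell's spectrum (shared per-cell effects,
    independent noise per node); peripheral nodes carry baseline-only
    background plus noise. x/y metadata hold the node coordinates.
    """
    config.validate()
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ConfigError(f"grid_shape must be >= 1x1, got {grid_shape}")
    p = config.profile(label)
    rng = np.random.default_rng(config.seed)
    G = _band_matrix(config)
    z, scales = _draw_cell_effects(rng, 1, len(config.bands), config.cell_scale_sd)
    amps = np.clip(np.asarray(p.amp_means) + z[0] * np.asarray(p.amp_sds), 0.0, None)
    cell_spectrum = _baseline(config, p.baseline_coeffs) + scales[0] * (G @ amps)
    background = _baseline(config, p.baseline_coeffs)

    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    radius = cell_radius_fraction * min(rows, cols)
    inside = ((yy - cy) ** 2 + (xx - cx) ** 2) <= max(radius, 0.5) ** 2
    inside_flat = inside.ravel()

    spectra = np.where(inside_flat[:, None], cell_spectrum[None, :], background[None, :])
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, size=spectra.shape)
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"g_{r}_{c}" for r, c in zip(yy.ravel(), xx.ravel())],
            "cell_id": np.where(inside_flat, "cell", "background"),
            "label": np.where(inside_flat, label, "unknown"),
            "x": xx.ravel().astype(float),
            "y": yy.ravel().astype(float),
        }
    )
    return SpectraDataset(config.axis.copy(), spectra, meta).validate()


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: the same generative conditions under a different seed."""
    return replace(config, seed=int(seed))


# ---------------------------------------------------------------------------
# dict construction (YAML/JSON config support)


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain mapping (YAML/JSON).

    Recognized keys: ``axis`` ({start, stop, n_points}), ``bands`` (list of
    {center, fwhm, assignment}), ``profiles`` (list of {label, amp_means,
    amp_sds, baseline_coeffs}), plus the scalar fields. Omitted keys keep
    their defaults.
    """
    allowed = {"axis", "bands", "profiles", "n_cells", "spectra_per_cell",
               "cell_scale_sd", "noise_sd", "seed"}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown synthetic-config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "axis" in d:
        a = d["axis"]
        kwargs["axis"] = make_axis(
            a.get("start", 600.0), a.get("stop", 1700.0), a.get("n_points", 1015)
        )
    if "bands" in d:
        kwargs["bands"] = tuple(
            Band(b["center"], b.get("fwhm", 12.0), b.get("assignment", ""))
            for b in d["bands"]
        )
    if "profiles" in d:
        kwargs["profiles"] = tuple(
            ClassProfile(
                p["label"],
                tuple(p["amp_means"]),
                tuple(p["amp_sds"]),
                tuple(p.get("baseline_coeffs", _BASELINE_COEFFS)),
            )
            for p in d["profiles"]
        )
    for key in ("n_cells", "spectra_per_cell", "cell_scale_sd", "noise_sd", "seed"):
        if key in d:
            kwargs[key] = tuple(d[key]) if key == "n_cells" else d[key]
    return SyntheticConfig(**kwargs).validate()


def timecourse_config_from_dict(d: dict) -> TimecourseConfig:
    unknown = set(d) - {"base", "time_points_h", "maturation_progress"}
    if unknown:
        raise ConfigError(f"unknown time-course config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "base" in d:
        kwargs["base"] = synthetic_config_from_dict(d["base"])
    if "time_points_h" in d:
        kwargs["time_points_h"] = tuple(float(t) for t in d["time_points_h"])
    if "maturation_progress" in d:
        kwargs["maturation_progress"] = tuple(float(w) for w in d["maturation_progress"])
    return TimecourseConfig(**kwargs).validate()
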