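"""Band-level interpretation of trained spectral classifiers.

Covers: window-averaged band intensities; the per-cell tryptophan (1623
cm^-1) to carbohydrate (1025 cm^-1) intensity ratio with a two-group test —
the proposed maturation marker; per-band model contributions by occlusion
(mask a band, measure the balanced-accuracy drop) or by back-projecting
absolute final-layer weights onto input wavenumbers; channel images from
mapping grids; and the per-sample probability heatmap table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._nn import Conv1D, Dense, Flatten, MaxPool1D, Network, conv_output_length
from .dataset import SpectraDataset
from .errors import (
    ConfigError,
    DegenerateRatioError,
    InsufficientDataError,
    IntegrityError,
    RangeError,
    StateError,
)
from .model import EvaluationReport, labels_to_binary, predict
from .synth import BAND_CATALOG, Band

__all__ = [
    "ContributionReport",
    "RatioReport",
    "band_intensity",
    "band_intensities",
    "ratio_statistic",
    "peak_contribution",
    "map_channel_image",
    "probability_heatmap",
]

DEFAULT_HALF_WINDOW = 6.0  # cm^-1; matches the default band FWHM of 12
TRP_BAND = 1623.0
CARB_BAND = 1025.0


@dataclass
class ContributionReport:
    """Per-band percent contributions to classification performance."""

    centers: tuple[float, ...]
    assignments: tuple[str, ...]
    contributions: np.ndarray  # percent, sums to 100
    method: str

    @property
    def ranking(self) -> np.ndarray:
        """Band indices sorted by decreasing contribution (stable)."""
        return np.argsort(-self.contributions, kind="stable")

    def top_band(self) -> float:
        return self.centers[int(self.ranking[0])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center": self.centers,
                "assignment": self.assignments,
                "contribution_pct": self.contributions,
            }
        ).sort_values("contribution_pct", ascending=False, ignore_index=True)


@dataclass
class RatioReport:
    """Per-cell band-intensity ratios by group plus a two-group test."""

    numerator: float
    denominator: float
    ratios: dict[str, np.ndarray]  # label -> per-cell ratios
    cell_ids: dict[str, list[str]]
    test: str
    statistic: float
    pvalue: float

    def group_means(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.ratios.items()}

    def group_sds(self) -> dict[str, float]:
        return {k: float(np.std(v, ddof=1)) for k, v in self.ratios.items()}

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "group_means": self.group_means(),
            "group_sds": self.group_sds(),
            "group_n": {k: int(len(v)) for k, v in self.ratios.items()},
        }


# ---------------------------------------------------------------------------
# band intensities


def _window_mask(wavenumbers: np.ndarray, center: float, half_window: float) -> np.ndarray:
    if half_window <= 0:
        raise ConfigError(f"half_window must be > 0, got {half_window}")
    if center + half_window < wavenumbers[0] or center - half_window > wavenumbers[-1]:
        raise RangeError(
            f"band window {center}±{half_window} cm^-1 lies outside the axis "
            f"[{wavenumbers[0]:g}, {wavenumbers[-1]:g}]"
        )
    mask = np.abs(wavenumbers - center) <= half_window
    if not mask.any():
        raise RangeError(
            f"band window {center}±{half_window} cm^-1 contains no axis points"
        )
    return mask


def band_intensity(
    spectrum: np.ndarray,
    wavenumbers: np.ndarray,
    center: float,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> float:
    """Mean intensity of one spectrum over the ±half_window band window."""
    mask = _window_mask(np.asarray(wavenumbers, dtype=float), center, half_window)
    return float(np.asarray(spectrum, dtype=float)[mask].mean())


def band_intensities(
    dataset: SpectraDataset,
    center: float,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> np.ndarray:
    """Vectorized :func:`band_intensity` over all spectra of a dataset."""
    mask = _window_mask(dataset.wavenumbers, center, half_window)
    return dataset.intensities[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# ratio marker


def ratio_statistic(
    dataset: SpectraDataset,
    numerator: float = TRP_BAND,
    denominator: float = CARB_BAND,
    half_window: float = DEFAULT_HALF_WINDOW,
    test: str = "welch_t",
) -> RatioReport:
    """Two-group test on per-cell numerator/denominator band ratios.

    Expects a per-cell averaged, labeled dataset (one spectrum per cell;
    both classes with >= 2 cells). Default bands: tryptophan 1623 over
    carbohydrates 1025 cm^-1, compared by Welch's two-sided t-test
    (``test="mann_whitney"`` for the rank alternative).
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ConfigError(f"unknown test {test!r}")
    labels_to_binary(dataset, context="ratio statistic")  # rejects unknowns
    num = band_intensities(dataset, numerator, half_window)
    den = band_intensities(dataset, denominator, half_window)
    bad = den <= 0
    if bad.any():
        cid = dataset.meta.loc[np.flatnonzero(bad)[0], "cell_id"]
        raise DegenerateRatioError(
            f"cell {cid!r}: non-positive {denominator} cm^-1 intensity; "
            "ratio undefined"
        )
    ratio = num / den
    groups: dict[str, np.ndarray] = {}
    cells: dict[str, list[str]] = {}
    for lab in ("mature", "immature"):
        sel = dataset.labels == lab
        groups[lab] = ratio[sel]
        cells[lab] = list(dataset.meta.loc[sel, "cell_id"])
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {lab!r} has {len(vals)} cells; >= 2 required"
            )
    a, b = groups["mature"], groups["immature"]
    if test == "welch_t":
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            # degenerate: no within-group variation at all
            equal = np.isclose(a.mean(), b.mean())
            stat, p = (0.0, 1.0) if equal else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return RatioReport(
        numerator=numerator, denominator=denominator,
        ratios=groups, cell_ids=cells, test=test,
        statistic=stat, pvalue=p,
    )


# ---------------------------------------------------------------------------
# model contributions


def _balanced_accuracy(probs: np.ndarray, y: np.ndarray, threshold: float) -> float:
    pred = probs >= threshold
    pos, neg = y == 1, y == 0
    sens = np.mean(pred[pos]) if pos.any() else np.nan
    spec = np.mean(~pred[neg]) if neg.any() else np.nan
    return float(np.nanmean([sens, spec]))


def _occlusion_scores(
    model: Network,
    dataset: SpectraDataset,
    bands: Sequence[Band],
    half_window: float,
    threshold: float,
) -> np.ndarray:
    y = labels_to_binary(dataset, context="occlusion contribution")
    base = _balanced_accuracy(predict(model, dataset), y, threshold)
    drops = np.zeros(len(bands))
    for i, band in enumerate(bands):
        mask = _window_mask(dataset.wavenumbers, band.center, half_window)
        occluded = dataset.intensities.copy()
        occluded[:, mask] = 0.0
        probs = model.predict_proba(occluded)
        drops[i] = max(0.0, base - _balanced_accuracy(probs, y, threshold))
    return drops


def _backprojection_scores(
    model: Network,
    wavenumbers: np.ndarray,
    bands: Sequence[Band],
    half_window: float,
) -> np.ndarray:
    """Propagate absolute final-layer weights back to input wavenumber bins.

    Dense layers multiply the relevance vector by |W|; pooling spreads a
    pooled position's relevance uniformly over its window; the convolution
    spreads a position's relevance over its receptive field weighted by the
    filters' absolute coefficients. ReLU/dropout pass relevance through.
    """
    relevance: np.ndarray | None = None
    shape_stack: list[tuple[int, int]] = []  # (positions, filters) entering Flatten
    for layer in reversed(model.layers):
        if isinstance(layer, Dense):
            if relevance is None:
                relevance = np.abs(layer.W).sum(axis=1)
            else:
                relevance = np.abs(layer.W) @ relevance
        elif isinstance(layer, Flatten):
            pass  # relevance stays flat; reshaped by the next spatial layer
        elif isinstance(layer, MaxPool1D):
            assert relevance is not None
            # recover (positions, filters) from the conv layer below and pad
            # back to the conv output length (pooling a window sweep can drop
            # trailing positions when the length is not a multiple of stride)
            conv = next(l for l in model.layers if isinstance(l, Conv1D))
            F = conv.filters
            Lp = relevance.size // F
            v = relevance.reshape(Lp, F)
            L_target = conv_output_length(model.input_len, conv.kernel, conv.stride)
            up = np.zeros((L_target, F))
            share = v / layer.pool_size
            for k in range(layer.pool_size):
                up[k : k + (Lp - 1) * layer.stride + 1 : layer.stride] += share
            relevance = up
        elif isinstance(layer, Conv1D):
            assert relevance is not None and relevance.ndim == 2
            v = relevance  # (Lc, F)
            Lc = v.shape[0]
            L_in = (Lc - 1) * layer.stride + layer.kernel
            r = np.zeros(L_in)
            absW = np.abs(layer.W)  # (F, K)
            for k in range(layer.kernel):
                r[k : k + (Lc - 1) * layer.stride + 1 : layer.stride] += v @ absW[:, k]
            relevance = r
    assert relevance is not None
    relevance = np.asarray(relevance, dtype=float).ravel()
    if relevance.size != wavenumbers.size:
        # fully connected models map first-layer weights directly to bins
        raise StateError(
            f"backprojected relevance length {relevance.size} != axis length "
            f"{wavenumbers.size}"
        )
    scores = np.zeros(len(bands))
    for i, band in enumerate(bands):
        mask = _window_mask(wavenumbers, band.center, half_window)
        scores[i] = relevance[mask].sum()
    return scores


def peak_contribution(
    model: Network,
    dataset: SpectraDataset,
    bands: Sequence[Band] = BAND_CATALOG,
    method: str = "occlusion",
    half_window: float = DEFAULT_HALF_WINDOW,
    threshold: float = 0.5,
) -> ContributionReport:
    """Percent contribution of each catalog band to the classification.

    ``occlusion`` (default) zeroes each band window and measures the drop in
    balanced accuracy, clipping negative drops to zero; ``weight_backprojection``
    reads the trained weights directly. Scores are normalized to sum to
    100%; if every score is zero (an uninformative model) the contribution
    is reported as uniform across the catalog.
    """
    if not model.trained:
        raise StateError("peak_contribution requires a trained model")
    if method == "occlusion":
        scores = _occlusion_scores(model, dataset, bands, half_window, threshold)
    elif method == "weight_backprojection":
        scores = _backprojection_scores(model, dataset.wavenumbers, bands, half_window)
    else:
        raise ConfigError(f"unknown method {method!r}")
    total = scores.sum()
    pct = scores / total * 100.0 if total > 0 else np.full(len(bands), 100.0 / len(bands))
    return ContributionReport(
        centers=tuple(b.center for b in bands),
        assignments=tuple(b.assignment for b in bands),
        contributions=pct,
        method=method,
    )


# ---------------------------------------------------------------------------
# mapping and heatmaps


def map_channel_image(
    dataset: SpectraDataset,
    center: float,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> pd.DataFrame:
    """Band-intensity image of a mapping grid, indexed by y, columns x.

    Grid nodes without a spectrum are NaN; duplicate positions raise.
    """
    meta = dataset.meta
    if meta["x"].isna().any() or meta["y"].isna().any():
        sid = meta.loc[meta[["x", "y"]].isna().any(axis=1), "spectrum_id"].iloc[0]
        raise IntegrityError(f"spectrum {sid!r} lacks x/y position metadata")
    dup = meta.duplicated(subset=["x", "y"])
    if dup.any():
        row = meta.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate grid position ({row['x']:g}, {row['y']:g}) "
            f"at spectrum {row['spectrum_id']!r}"
        )
    values = band_intensities(dataset, center, half_window)
    frame = pd.DataFrame({"x": meta["x"], "y": meta["y"], "value": values})
    return frame.pivot(index="y", columns="x", values="value")


def probability_heatmap(report: EvaluationReport, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample probability table with true and predicted label rows.

    Predicted label is ``mature`` when probability >= threshold (ties go to
    the positive class). Rows are ordered by true label then descending
    probability, matching the usual rendering.
    """
    probs = np.asarray(report.probabilities)
    n = probs.size
    frame = pd.DataFrame(
        {
            "sample_id": list(ids) if ids is not None else [f"s{i}" for i in range(n)],
            "probability": probs,
            "true_label": np.asarray(report.true_labels),
            "predicted_label": np.where(
                probs >= report.threshold, "mature", "immature"
            ),
        }
    )
    return frame.sort_values(
        ["true_label", "probability"], ascending=[True, False], ignore_index=True
    )
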