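"""Normalization, per-cell summaries, confidence bands and dataset splitting.

The preprocessing chain mirrors the study protocol: per-spectrum max-min
normalization to [0, 1], optional per-cell averaging for single-cell models,
pointwise 95% confidence bands for mean spectra, and a seeded 70/20/10
train/validation/test split at spectrum or cell granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectraDataset
from .errors import ConfigError, FormatError, InsufficientDataError, IntegrityError, SizingError

__all__ = [
    "SplitSpec",
    "minmax_normalize",
    "average_per_cell",
    "confidence_band",
    "split_dataset",
    "largest_remainder_sizes",
]


def minmax_normalize(dataset: SpectraDataset) -> SpectraDataset:
    """Map each spectrum linearly so its minimum is 0 and maximum is 1.

    Constant spectra map to all zeros. Axis and metadata are unchanged;
    an empty dataset passes through; non-finite intensities are rejected.
    The map is idempotent: normalizing twice equals normalizing once.
    """
    X = dataset.intensities
    if X.size and not np.all(np.isfinite(X)):
        i = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise FormatError(
            f"spectrum {dataset.spectrum_ids[i]!r} contains non-finite intensities"
        )
    lo = X.min(axis=1, keepdims=True) if X.size else np.zeros((X.shape[0], 1))
    span = X.max(axis=1, keepdims=True) - lo if X.size else np.ones((X.shape[0], 1))
    safe = np.where(span > 0, span, 1.0)
    out = np.where(span > 0, (X - lo) / safe, 0.0)
    return SpectraDataset(dataset.wavenumbers.copy(), out, dataset.meta.copy())


def average_per_cell(dataset: SpectraDataset) -> SpectraDataset:
    """Arithmetic mean spectrum per cell; one output spectrum per cell_id.

    The cell inherits its spectra's label (conflicting labels raise), its
    time point when unique, and uses the cell_id as spectrum_id. Output cell
    order follows first appearance, so the result is invariant to
    permutations of spectra within cells.
    """
    meta = dataset.meta
    if meta["cell_id"].isna().any():
        sid = meta.loc[meta["cell_id"].isna(), "spectrum_id"].iloc[0]
        raise IntegrityError(f"spectrum {sid!r} has no cell_id; cannot average per cell")
    order = list(dict.fromkeys(meta["cell_id"]))
    rows, recs = [], []
    grouped = meta.groupby("cell_id", sort=False)
    for cid in order:
        idx = grouped.get_group(cid).index.to_numpy()
        labels = set(meta.loc[idx, "label"])
        if len(labels) > 1:
            raise IntegrityError(
                f"cell {cid!r} carries conflicting labels {sorted(labels)}"
            )
        times = meta.loc[idx, "time_point_h"].dropna().unique()
        rows.append(dataset.intensities[idx].mean(axis=0))
        recs.append(
            {
                "spectrum_id": cid,
                "cell_id": cid,
                "label": labels.pop(),
                "time_point_h": float(times[0]) if len(times) == 1 else np.nan,
            }
        )
    return SpectraDataset(
        dataset.wavenumbers.copy(), np.vstack(rows), pd.DataFrame(recs)
    )


def confidence_band(dataset: SpectraDataset, level: float = 0.95) -> pd.DataFrame:
    """Pointwise t confidence band for the mean spectrum.

    Returns a frame with columns ``wavenumber, mean, lower, upper`` where
    lower <= mean <= upper everywhere (a Student-t interval per wavenumber).
    """
    n = dataset.n_spectra
    if n < 2:
        raise InsufficientDataError(f"confidence band needs >= 2 spectra, got {n}")
    if not 0 < level < 1:
        raise ConfigError(f"confidence level must be in (0, 1), got {level}")
    X = dataset.intensities
    mean = X.mean(axis=0)
    sem = X.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sem
    return pd.DataFrame(
        {
            "wavenumber": dataset.wavenumbers,
            "mean": mean,
            "lower": mean - half,
            "upper": mean + half,
        }
    )


@dataclass(frozen=True)
class SplitSpec:
    """Seeded train/validation/test split specification.

    ``unit="cell"`` (default) keeps all replicate spectra of a cell in one
    subset, preventing leakage; ``unit="spectrum"`` splits individual
    spectra, replicating the multicell-model protocol. Stratification by
    label is on by default to preserve class balance in small subsets.
    """

    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    unit: str = "cell"
    seed: int = 0
    shuffle: bool = True
    stratify: bool = True

    def validate(self) -> "SplitSpec":
        f = self.fractions
        if len(f) != 3 or any(not (0.0 <= x <= 1.0) for x in f):
            raise ConfigError(f"fractions must be three numbers in [0,1], got {f}")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ConfigError(f"fractions must sum to 1, got sum {sum(f)!r}")
        if self.unit not in ("spectrum", "cell"):
            raise ConfigError(f"unit must be 'spectrum' or 'cell', got {self.unit!r}")
        return self


def largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer subset sizes summing to n by largest-remainder rounding.

    Ties on the fractional remainder break toward the earlier subset, so the
    allocation is deterministic.
    """
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    leftover = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_dataset(
    dataset: SpectraDataset, spec: SplitSpec
) -> tuple[SpectraDataset, SpectraDataset, SpectraDataset]:
    """Partition a dataset into (train, validation, test).

    The partition is disjoint and exhaustive over the chosen unit; subset
    sizes follow largest-remainder rounding of the fractions (within each
    label stratum when stratification is on); with ``unit="cell"`` no cell
    contributes spectra to two subsets. A nonzero fraction that receives no
    units raises :class:`SizingError`.
    """
    spec.validate()
    if dataset.n_spectra == 0:
        raise SizingError("cannot split an empty dataset")
    meta = dataset.meta
    if spec.unit == "cell":
        if meta["cell_id"].isna().any():
            raise IntegrityError("unit='cell' split requires a cell_id on every spectrum")
        unit_ids = meta["cell_id"].to_numpy()
    else:
        unit_ids = meta["spectrum_id"].to_numpy()
    units = list(dict.fromkeys(unit_ids))

    # label of each unit (first spectrum's label), used for stratification
    unit_label = {}
    for uid, lab in zip(unit_ids, meta["label"]):
        unit_label.setdefault(uid, lab)

    if spec.stratify:
        strata: dict[str, list] = {}
        for uid in units:
            strata.setdefault(unit_label[uid], []).append(uid)
        groups = list(strata.values())
    else:
        groups = [units]

    rng = np.random.default_rng(spec.seed)
    assignment: dict[object, int] = {}
    for group in groups:
        group = list(group)
        if spec.shuffle:
            rng.shuffle(group)
        sizes = largest_remainder_sizes(len(group), spec.fractions)
        start = 0
        for subset_idx, size in enumerate(sizes):
            for uid in group[start : start + size]:
                assignment[uid] = subset_idx
            start += size

    counts = [sum(1 for v in assignment.values() if v == i) for i in range(3)]
    for i, (frac, cnt) in enumerate(zip(spec.fractions, counts)):
        if frac > 0 and cnt == 0:
            name = ("train", "validation", "test")[i]
            raise SizingError(
                f"{name} fraction {frac} yields 0 of {len(units)} {spec.unit} units "
                f"(allocation {counts})"
            )

    subsets = []
    for i in range(3):
        mask = np.array([assignment[u] == i for u in unit_ids])
        subsets.append(dataset.subset(mask))
    return subsets[0], subsets[1], subsets[2]
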