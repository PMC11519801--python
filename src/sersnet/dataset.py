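"""The spectral dataset container passed between all pipeline stages.

A :class:`SpectraDataset` holds a collection of single-cell SERS spectra that
share one wavenumber axis, together with per-spectrum metadata (spectrum id,
cell id, class label, optional acquisition time in hours and optional x/y
stage position for mapping experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "ALLOWED_LABELS",
    "META_COLUMNS",
    "SpectraDataset",
    "make_axis",
    "validate_axis",
]

#: Labels a spectrum may carry. ``mature`` is the positive class throughout.
ALLOWED_LABELS = ("mature", "immature", "unknown")

#: Canonical metadata columns, in serialization order.
META_COLUMNS = ("spectrum_id", "cell_id", "label", "time_point_h", "x", "y")

#: Default axis geometry: 600-1700 cm^-1 sampled at 1015 points, the input
#: length the convolutional architecture is sized for.
DEFAULT_AXIS_START = 600.0
DEFAULT_AXIS_STOP = 1700.0
DEFAULT_AXIS_POINTS = 1015


def make_axis(
    start: float = DEFAULT_AXIS_START,
    stop: float = DEFAULT_AXIS_STOP,
    n_points: int = DEFAULT_AXIS_POINTS,
) -> np.ndarray:
    """Return a uniform wavenumber axis in cm^-1."""
    if n_points < 2:
        raise FormatError(f"axis needs at least 2 points, got {n_points}")
    if not stop > start:
        raise FormatError(f"axis stop ({stop}) must exceed start ({start})")
    return np.linspace(float(start), float(stop), int(n_points))


def validate_axis(wavenumbers: np.ndarray, *, uniform: bool = True) -> np.ndarray:
    """Validate a wavenumber axis: strictly increasing, optionally uniform.

    Uniformity is checked to a 1e-9 relative tolerance on the spacing.
    """
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise FormatError("wavenumber axis must be a 1-D array of >= 2 points")
    d = np.diff(w)
    if not np.all(d > 0):
        i = int(np.argmax(d <= 0))
        raise FormatError(
            f"wavenumber axis not strictly increasing at index {i + 1} "
            f"({w[i]:g} -> {w[i + 1]:g})"
        )
    if uniform:
        step = (w[-1] - w[0]) / (w.size - 1)
        if not np.allclose(d, step, rtol=1e-9, atol=1e-9 * abs(step)):
            raise FormatError("wavenumber axis spacing is not uniform")
    return w


def _empty_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [f"s{i:06d}" for i in range(n)],
            "cell_id": pd.array([None] * n, dtype="object"),
            "label": ["unknown"] * n,
            "time_point_h": np.full(n, np.nan),
            "x": np.full(n, np.nan),
            "y": np.full(n, np.nan),
        }
    )


@dataclass
class SpectraDataset:
    """Spectra on a shared wavenumber axis plus per-spectrum metadata.

    Parameters
    ----------
    wavenumbers:
        Shared axis, shape ``(n_points,)``, strictly increasing, cm^-1.
    intensities:
        Matrix of shape ``(n_spectra, n_points)``, arbitrary units.
    meta:
        One row per spectrum with columns :data:`META_COLUMNS`. Missing
        metadata is filled with defaults (label ``unknown``, NaN elsewhere).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.meta is None:
            self.meta = _empty_meta(self.intensities.shape[0])
        else:
            self.meta = self.meta.reset_index(drop=True).copy()
            for col in META_COLUMNS:
                if col not in self.meta.columns:
                    if col == "label":
                        self.meta[col] = "unknown"
                    else:
                        self.meta[col] = np.nan
            self.meta.loc[self.meta["label"].isna(), "label"] = "unknown"
            self.meta = self.meta[list(META_COLUMNS)]

    # -- basic properties -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.intensities.shape[1])

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.meta["cell_id"].to_numpy()

    @property
    def spectrum_ids(self) -> np.ndarray:
        return self.meta["spectrum_id"].to_numpy()

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_spectra

    # -- validation --------------------------------------------------------
    def validate(self, *, uniform_axis: bool = True) -> "SpectraDataset":
        """Check all container invariants; return self for chaining.

        Raises :class:`~sersnet.errors.FormatError` on the first violation.
        """
        validate_axis(self.wavenumbers, uniform=uniform_axis)
        if self.intensities.ndim != 2:
            raise FormatError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise FormatError(
                f"intensity columns ({self.intensities.shape[1]}) != axis length "
                f"({self.wavenumbers.size})"
            )
        if len(self.meta) != self.n_spectra:
            raise FormatError(
                f"metadata rows ({len(self.meta)}) != spectra ({self.n_spectra})"
            )
        ids = self.meta["spectrum_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate spectrum_id: {dup.iloc[0]!r}")
        bad = ~self.meta["label"].isin(ALLOWED_LABELS)
        if bad.any():
            row = self.meta.loc[bad].iloc[0]
            raise FormatError(
                f"spectrum {row['spectrum_id']!r} has invalid label {row['label']!r}"
            )
        return self

    # -- manipulation -------------------------------------------------------
    def subset(self, index: np.ndarray) -> "SpectraDataset":
        """Row-subset by positional index or boolean mask, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraDataset(
            self.wavenumbers.copy(),
            self.intensities[index].copy(),
            self.meta.iloc[index].reset_index(drop=True),
        )

    def copy(self) -> "SpectraDataset":
        return SpectraDataset(
            self.wavenumbers.copy(), self.intensities.copy(), self.meta.copy()
        )

    def equals(self, other: "SpectraDataset", *, atol: float = 0.0) -> bool:
        """Numerically compare two datasets (metadata compared exactly)."""
        if self.intensities.shape != other.intensities.shape:
            return False
        if not np.allclose(self.wavenumbers, other.wavenumbers, atol=atol, rtol=0):
            return False
        if not np.allclose(self.intensities, other.intensities, atol=atol, rtol=0):
            return False
        a = self.meta.fillna("<na>")
        b = other.meta.fillna("<na>")
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))
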