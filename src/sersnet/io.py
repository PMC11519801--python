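"""Plain-text I/O for spectra, configs and reports.

Two CSV dialects are supported:

``wide_csv``
    First column ``wavenumber``; one additional column per spectrum, headed
    by its spectrum_id. Per-spectrum metadata travels in a sidecar CSV
    (default: same path with a ``.meta.csv`` suffix) keyed by spectrum_id.

``long_csv``
    Columns ``spectrum_id, wavenumber, intensity``, one row per
    (spectrum, wavenumber) pair, spectra in serialization order. The same
    sidecar convention carries the metadata.

Numbers are serialized with 17 significant digits so a write/read round
trip is exact. Reports are JSON; configs are YAML or JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dataset import META_COLUMNS, SpectraDataset
from .errors import FormatError

__all__ = [
    "read_spectra",
    "write_spectra",
    "default_meta_path",
    "read_config_file",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"
_FORMATS = ("wide_csv", "long_csv")


def default_meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.csv")


def _read_meta(meta_path: Path, spectrum_ids: list[str]) -> pd.DataFrame | None:
    if not meta_path.exists():
        return None
    meta = pd.read_csv(meta_path, dtype={"spectrum_id": str, "cell_id": str, "label": str})
    if "spectrum_id" not in meta.columns:
        raise FormatError(f"{meta_path}: sidecar metadata lacks a spectrum_id column")
    dup = meta["spectrum_id"][meta["spectrum_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{meta_path}: duplicate spectrum_id {dup.iloc[0]!r}")
    order = pd.DataFrame({"spectrum_id": pd.Series(spectrum_ids, dtype="object")})
    meta["spectrum_id"] = meta["spectrum_id"].astype("object")
    merged = order.merge(meta, on="spectrum_id", how="left")
    return merged


def write_spectra(
    dataset: SpectraDataset,
    path: str | Path,
    format: str = "wide_csv",
    meta_path: str | Path | None = None,
) -> Path:
    """Serialize a dataset (and its metadata sidecar); returns the data path."""
    if format not in _FORMATS:
        raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
    dataset.validate()
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else default_meta_path(path)

    ids = [str(s) for s in dataset.spectrum_ids]
    if format == "wide_csv":
        frame = pd.DataFrame(
            dataset.intensities.T, columns=ids, index=dataset.wavenumbers
        )
        frame.index.name = "wavenumber"
        frame.to_csv(path, float_format=_FLOAT_FMT)
    else:
        n, L = dataset.intensities.shape
        frame = pd.DataFrame(
            {
                "spectrum_id": np.repeat(ids, L),
                "wavenumber": np.tile(dataset.wavenumbers, n),
                "intensity": dataset.intensities.ravel(),
            }
        )
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    dataset.meta.to_csv(meta_path, index=False, float_format=_FLOAT_FMT)
    return path


def _wide_header_ids(path: Path) -> list[str]:
    # pandas mangles duplicate column names; read the raw header to detect them
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "wavenumber":
        raise FormatError(f"{path}: wide CSV must start with a 'wavenumber' column")
    return header[1:]


def read_spectra(
    path: str | Path,
    format: str = "wide_csv",
    meta_path: str | Path | None = None,
) -> SpectraDataset:
    """Parse a spectra file (plus metadata sidecar, if present) and validate it.

    Spectra without sidecar metadata load with label ``unknown``; training
    and evaluation stages, not I/O, reject unlabeled data.
    """
    if format not in _FORMATS:
        raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = Path(meta_path) if meta_path is not None else default_meta_path(path)

    if format == "wide_csv":
        ids = _wide_header_ids(path)
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise FormatError(f"{path}: duplicate spectrum_id {dup!r}")
        table = pd.read_csv(path)
        if table.isna().any().any():
            raise FormatError(f"{path}: ragged or missing values in wide CSV")
        wavenumbers = table["wavenumber"].to_numpy(dtype=float)
        intensities = table.iloc[:, 1:].to_numpy(dtype=float).T
    else:
        table = pd.read_csv(path, dtype={"spectrum_id": str})
        required = {"spectrum_id", "wavenumber", "intensity"}
        if not required.issubset(table.columns):
            raise FormatError(f"{path}: long CSV needs columns {sorted(required)}")
        if table.isna().any().any():
            raise FormatError(f"{path}: missing values in long CSV")
        ids = list(dict.fromkeys(table["spectrum_id"]))
        groups = table.groupby("spectrum_id", sort=False)
        first_axis = None
        rows = []
        for sid in ids:
            g = groups.get_group(sid)
            w = g["wavenumber"].to_numpy(dtype=float)
            if first_axis is None:
                first_axis = w
            elif w.shape != first_axis.shape or not np.array_equal(w, first_axis):
                raise FormatError(
                    f"{path}: spectrum {sid!r} has a different wavenumber axis"
                )
            rows.append(g["intensity"].to_numpy(dtype=float))
        if first_axis is None:
            raise FormatError(f"{path}: long CSV contains no spectra")
        wavenumbers = first_axis
        intensities = np.vstack(rows)

    meta = _read_meta(meta_path, [str(i) for i in ids])
    if meta is None:
        meta = pd.DataFrame({"spectrum_id": [str(i) for i in ids]})
    ds = SpectraDataset(wavenumbers, intensities, meta)
    try:
        return ds.validate(uniform_axis=False)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configs and reports


def read_config_file(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        out = json.loads(text)
    else:
        out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: config file must contain a mapping")
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, allow_nan=True) + "\n")
    return path


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
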