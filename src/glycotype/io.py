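"""Profile-matrix container and TSV/CSV input/output.

A :class:`ProfileMatrix` holds serum antibody signals for a set of
samples over a set of array components, with two isotype channels (IgG
and IgM).  All downstream thresholding logic assumes signals on a log2
relative-fluorescence-unit (RFU) scale; raw linear-scale input must pass
through :func:`log2_normalize` first, and the container tracks which
scale it is on so the transform cannot be applied twice.

Two on-disk dialects are supported:

* long format (canonical): columns ``sample_id, component, isotype,
  signal``, one row per measurement;
* wide format (convenience): columns ``sample_id, isotype,
  <component>, <component>, ...``, one row per (sample, isotype).

Sample metadata travels in a companion table with columns ``sample_id,
recorded_blood_type`` and optionally ``cohort_arm``.

Ingestion of the deposited public microarray series (GEO GSE68405) is
deliberately not implemented: building and testing must not require a
download.  The expected mapping is: one long-format row per (sample,
array component, detection channel) with the median-spot RFU as the
signal, passed through :func:`log2_normalize`; see
:func:`load_geo_series` for the documented stub.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .components import GlycanComponent, normalize_name, parse_component_name

logger = logging.getLogger(__name__)

ISOTYPES = ("IgG", "IgM")
BLOOD_TYPES = ("A", "B", "AB", "O")


class ProfileError(ValueError):
    """Malformed profile input."""


@dataclass
class ProfileMatrix:
    """Samples x components signal table with IgG and IgM channels.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with a two-level column
        MultiIndex ``(component, isotype)``; values are signals.
    metadata:
        Per-sample table indexed like ``data`` with at least a
        ``recorded_blood_type`` column (values in A/B/AB/O/unknown).
    scale:
        Either ``"log2"`` (the working scale) or ``"linear"``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ProfileError(f"duplicate sample IDs: {list(dupes)}")
        if self.data.columns.nlevels != 2:
            raise ProfileError(
                "data columns must be a (component, isotype) MultiIndex"
            )
        if self.data.columns.has_duplicates:
            raise ProfileError("duplicate (component, isotype) columns")
        bad_iso = set(self.data.columns.get_level_values(1)) - set(ISOTYPES)
        if bad_iso:
            raise ProfileError(f"unknown isotype channel(s): {sorted(bad_iso)}")
        if self.scale not in ("log2", "linear"):
            raise ProfileError(f"scale must be 'log2' or 'linear', not {self.scale!r}")
        self.data.index = self.data.index.astype(str).rename(None)
        self.data.columns = self.data.columns.set_names(["component", "isotype"])
        if self.metadata.empty:
            self.metadata = pd.DataFrame(
                {"recorded_blood_type": "unknown"}, index=self.data.index
            )
        else:
            self.metadata = self.metadata.reindex(self.data.index)
            if "recorded_blood_type" not in self.metadata.columns:
                self.metadata["recorded_blood_type"] = "unknown"
            self.metadata["recorded_blood_type"] = (
                self.metadata["recorded_blood_type"].fillna("unknown")
            )

    # -- introspection -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def component_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.data.columns.get_level_values(0):
            seen.setdefault(name, None)
        return list(seen)

    @property
    def components(self) -> list[GlycanComponent]:
        return [parse_component_name(n) for n in self.component_names]

    def recorded_blood_types(self) -> pd.Series:
        return self.metadata["recorded_blood_type"]

    def signal(self, sample: str, component: str, isotype: str) -> float:
        """The signal for one (sample, component, isotype) triple."""
        try:
            value = self.data.at[sample, (component, isotype)]
        except KeyError as exc:
            raise KeyError(
                f"no signal for sample={sample!r}, component={component!r}, "
                f"isotype={isotype!r}"
            ) from exc
        return float(value)

    def to_frame(self) -> pd.DataFrame:
        """The underlying (component, isotype) MultiIndex frame."""
        return self.data

    def subset(self, samples: Sequence[str]) -> "ProfileMatrix":
        return ProfileMatrix(
            self.data.loc[list(samples)],
            self.metadata.loc[list(samples)],
            scale=self.scale,
        )


def _validate_long(table: pd.DataFrame, path: object) -> pd.DataFrame:
    required = {"sample_id", "component", "isotype", "signal"}
    missing = required - set(table.columns)
    if missing:
        raise ProfileError(
            f"{path}: malformed header, missing column(s) {sorted(missing)}"
        )
    table = table.copy()
    table["component"] = table["component"].astype(str).map(normalize_name)
    table["isotype"] = table["isotype"].astype(str).str.strip()
    bad_iso = set(table["isotype"]) - set(ISOTYPES)
    if bad_iso:
        raise ProfileError(f"{path}: unknown isotype value(s) {sorted(bad_iso)}")
    signal = pd.to_numeric(table["signal"], errors="coerce")
    bad = signal.isna() & table["signal"].notna()
    if bad.any():
        row = table.index[bad][0]
        raise ProfileError(
            f"{path}: non-numeric signal {table.loc[row, 'signal']!r} in row "
            f"{row} (sample {table.loc[row, 'sample_id']!r}, "
            f"component {table.loc[row, 'component']!r})"
        )
    table["signal"] = signal
    return table


def load_profiles(
    path: Union[str, Path],
    dialect: str = "long",
    metadata_path: Optional[Union[str, Path]] = None,
    scale: str = "log2",
    sep: Optional[str] = None,
) -> ProfileMatrix:
    """Read a profile matrix from a long- or wide-format delimited file.

    Rows whose signal is missing are reported and dropped (long format);
    the separator is sniffed from the extension unless given (``.csv``
    -> comma, otherwise tab).

    Raises
    ------
    ProfileError
        On a malformed header, duplicate sample IDs, a non-numeric
        signal (naming the offending row and column), or an empty file.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        table = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ProfileError(f"{path}: no samples (empty file)") from None
    if table.empty:
        raise ProfileError(f"{path}: no samples")

    if dialect == "long":
        table = _validate_long(table, path)
        n_missing = int(table["signal"].isna().sum())
        if n_missing:
            logger.warning("%s: dropped %d rows with missing signals", path, n_missing)
            table = table.dropna(subset=["signal"])
        dup = table.duplicated(subset=["sample_id", "component", "isotype"])
        if dup.any():
            key = table.loc[dup.idxmax(), ["sample_id", "component", "isotype"]]
            raise ProfileError(
                f"{path}: duplicate measurement for sample "
                f"{key['sample_id']!r} / {key['component']!r} / {key['isotype']!r}"
            )
        wide = table.pivot(
            index="sample_id", columns=["component", "isotype"], values="signal"
        )
    elif dialect == "wide":
        if "sample_id" not in table.columns or "isotype" not in table.columns:
            raise ProfileError(
                f"{path}: malformed header, wide format needs 'sample_id' and "
                f"'isotype' columns"
            )
        dup = table.duplicated(subset=["sample_id", "isotype"])
        if dup.any():
            sid = table.loc[dup.idxmax(), "sample_id"]
            raise ProfileError(f"{path}: duplicate sample ID {sid!r}")
        comp_cols = [c for c in table.columns if c not in ("sample_id", "isotype")]
        if not comp_cols:
            raise ProfileError(f"{path}: no component columns")
        long = table.melt(
            id_vars=["sample_id", "isotype"],
            value_vars=comp_cols,
            var_name="component",
            value_name="signal",
        )
        return load_profiles_from_long_frame(
            long, metadata_path=metadata_path, scale=scale
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    wide.index = wide.index.astype(str)
    wide = wide.sort_index(axis=1)
    metadata = load_metadata(metadata_path) if metadata_path else pd.DataFrame()
    return ProfileMatrix(wide, metadata, scale=scale)


def load_profiles_from_long_frame(
    long: pd.DataFrame,
    metadata_path: Optional[Union[str, Path]] = None,
    scale: str = "log2",
) -> ProfileMatrix:
    """Build a ProfileMatrix from an in-memory long-format frame."""
    long = _validate_long(long, "<frame>").dropna(subset=["signal"])
    wide = long.pivot(
        index="sample_id", columns=["component", "isotype"], values="signal"
    )
    wide.index = wide.index.astype(str)
    wide = wide.sort_index(axis=1)
    metadata = load_metadata(metadata_path) if metadata_path else pd.DataFrame()
    return ProfileMatrix(wide, metadata, scale=scale)


def load_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample metadata table (``sample_id, recorded_blood_type
    [, cohort_arm]``)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep)
    if "sample_id" not in meta.columns:
        raise ProfileError(f"{path}: metadata needs a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        sid = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ProfileError(f"{path}: duplicate sample ID {sid!r} in metadata")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta.set_index("sample_id")


def write_profiles(
    profiles: ProfileMatrix,
    path: Union[str, Path],
    dialect: str = "long",
    metadata_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a profile matrix (and optionally its metadata) to disk.

    Long format round-trips signals at full precision via ``repr``-level
    float formatting.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if dialect == "long":
        long = (
            profiles.data.stack(level=[0, 1], future_stack=True)
            .rename("signal")
            .reset_index()
        )
        long.columns = ["sample_id", "component", "isotype", "signal"]
        long = long.dropna(subset=["signal"])
        long.to_csv(path, sep=sep, index=False, float_format="%.17g")
    elif dialect == "wide":
        rows = []
        for iso in ISOTYPES:
            cols = [c for c in profiles.data.columns if c[1] == iso]
            if not cols:
                continue
            block = profiles.data[cols]
            block.columns = [c[0] for c in cols]
            block = block.reset_index(names="sample_id")
            block.insert(1, "isotype", iso)
            rows.append(block)
        pd.concat(rows, ignore_index=True).to_csv(
            path, sep=sep, index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata_path is not None:
        meta = profiles.metadata.reset_index(names="sample_id")
        msep = "," if str(metadata_path).lower().endswith(".csv") else "\t"
        meta.to_csv(metadata_path, sep=msep, index=False)


def log2_normalize(
    raw: ProfileMatrix, floor: float = 1.0, hook=None
) -> ProfileMatrix:
    """Transform a linear-scale matrix onto the log2 working scale.

    Each signal becomes ``log2(max(raw, floor))``.  ``hook``, if given,
    is a callable applied to the linear-scale frame first (a pluggable
    per-array normalisation step; no particular procedure is assumed).

    Raises
    ------
    ValueError
        If the matrix is already on the log2 scale (idempotence guard)
        or any raw signal is negative.
    """
    if raw.scale == "log2":
        raise ValueError("matrix is already log2-scaled; refusing to re-apply")
    if floor <= 0:
        raise ValueError("floor must be positive")
    values = raw.data
    if hook is not None:
        values = hook(values)
    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("negative raw signal encountered; expected linear RFU >= 0")
    transformed = pd.DataFrame(
        np.log2(np.maximum(arr, floor)), index=values.index, columns=values.columns
    )
    return ProfileMatrix(transformed, raw.metadata.copy(), scale="log2")


def log2_denormalize(profiles: ProfileMatrix) -> ProfileMatrix:
    """Inverse of :func:`log2_normalize` (exact above the floor)."""
    if profiles.scale != "log2":
        raise ValueError("matrix is not log2-scaled")
    linear = pd.DataFrame(
        np.exp2(profiles.data.to_numpy(dtype=float)),
        index=profiles.data.index,
        columns=profiles.data.columns,
    )
    return ProfileMatrix(linear, profiles.metadata.copy(), scale="linear")


def load_geo_series(accession: str = "GSE68405"):  # pragma: no cover - stub
    """Documented stub for public-repository ingestion (not implemented).

    The deposited series stores one sample table per serum with
    per-spot RFU values.  The expected mapping onto this package is:
    aggregate replicate spots by their mean, emit one long-format row
    per (sample, component, detection channel) and pass the result
    through :func:`log2_normalize`.  Implementing the download is out of
    scope so that building and testing never require network access.
    """
    raise NotImplementedError(
        "public-series ingestion is documented but intentionally not "
        "implemented; supply profiles as long/wide TSV instead"
    )
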