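"""Core containers: LC-MS feature tables and per-sample metadata.

A :class:`FeatureTable` holds a nonnegative intensity matrix (features x
samples) where each feature is identified by a retention time (minutes) and a
mass-to-charge ratio, and zeros encode missing (below detection limit)
measurements.  :class:`SampleMetadata` carries the clinical annotation of each
sample: diagnostic group, study cohort, acquisition batch, QC flag, clinical
marker values (e.g. serum CA125 in U/mL) and optional FIGO stage.

Both round-trip through plain delimited text (see :func:`read_feature_table`,
:func:`write_feature_table`, :func:`read_metadata`, :func:`write_metadata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("normal", "benign", "borderline", "malignant")
QC_GROUP = "qc"
COHORTS = ("discovery", "validation")
STAGES = ("I", "II", "III", "IV")

#: metadata columns that are not clinical markers
_META_FIXED = ("group", "cohort", "batch", "is_qc", "stage")


class DataError(ValueError):
    """Raised on malformed feature tables or metadata."""


def parse_feature_label(label: str) -> tuple[float, float]:
    """Parse an ``"RT_mz"`` feature label, e.g. ``"5.7625_477.3462"``."""
    parts = str(label).split("_")
    if len(parts) != 2:
        raise DataError(f"feature label {label!r} is not of the form 'RT_mz'")
    try:
        rt, mz = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise DataError(f"feature label {label!r} has non-numeric RT or m/z") from exc
    return rt, mz


def make_feature_label(rt: float, mz: float) -> str:
    return f"{rt:.4f}_{mz:.4f}"


@dataclass
class FeatureTable:
    """Feature (rows) x sample (columns) intensity matrix.

    Parameters
    ----------
    intensities
        DataFrame indexed by unique feature labels with unique sample-id
        columns; values nonnegative, zeros meaning missing.
    features
        DataFrame indexed like ``intensities`` with columns ``rt`` (minutes)
        and ``mz``.  Built from the labels when omitted.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        if self.features is None:
            parsed = [parse_feature_label(lbl) for lbl in self.intensities.index]
            self.features = pd.DataFrame(
                parsed, columns=["rt", "mz"], index=self.intensities.index
            )
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def labels(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.features.copy())

    def validate(self) -> None:
        ints = self.intensities
        if ints.index.duplicated().any():
            dup = ints.index[ints.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature labels: {dup}")
        if ints.columns.duplicated().any():
            dup = ints.columns[ints.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dup}")
        vals = ints.to_numpy()
        if np.isnan(vals).any():
            rows, cols = np.where(np.isnan(vals))
            raise DataError(
                "NaN intensities are not accepted (zeros encode missing); first at "
                f"feature {ints.index[rows[0]]!r}, sample {ints.columns[cols[0]]!r}"
            )
        if (vals < 0).any():
            rows, cols = np.where(vals < 0)
            raise DataError(
                f"negative intensity at feature {ints.index[rows[0]]!r}, "
                f"sample {ints.columns[cols[0]]!r}"
            )
        if not self.features.index.equals(ints.index):
            raise DataError("feature annotation index does not match intensity rows")

    # -- subsetting --------------------------------------------------------
    def select_features(self, labels: Sequence[str] | pd.Index) -> "FeatureTable":
        labels = pd.Index(labels)
        missing = labels.difference(self.labels)
        if len(missing):
            raise DataError(f"unknown feature labels: {missing.tolist()[:5]}")
        return FeatureTable(self.intensities.loc[labels], self.features.loc[labels])

    def select_samples(self, sample_ids: Sequence[str] | pd.Index) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.sample_ids)
        if len(missing):
            raise DataError(f"unknown sample ids: {missing.tolist()[:5]}")
        return FeatureTable(self.intensities.loc[:, ids], self.features.copy())

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing (zero) entries."""
        return self.intensities == 0.0


@dataclass
class SampleMetadata:
    """Per-sample clinical and acquisition annotation.

    ``table`` is indexed by sample id with columns ``group``, ``cohort``,
    ``batch``, ``is_qc``, ``stage`` plus one column per clinical marker
    (e.g. ``ca125``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"group", "cohort", "batch", "is_qc"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"metadata missing columns: {sorted(missing)}")
        if t.index.duplicated().any():
            raise DataError("duplicate sample ids in metadata")
        if "stage" not in t.columns:
            t = t.assign(stage=pd.NA)
        t = t.copy()
        t["is_qc"] = t["is_qc"].astype(bool)
        t["batch"] = t["batch"].astype(int)
        self.table = t
        bad_group = ~t["group"].isin(GROUPS + (QC_GROUP,))
        if bad_group.any():
            raise DataError(
                f"unknown group values: {sorted(t.loc[bad_group, 'group'].unique())}"
            )
        nonqc = t[~t["is_qc"]]
        if nonqc["group"].isin([QC_GROUP]).any() or nonqc["group"].isna().any():
            raise DataError("every non-QC sample must carry a biological group")
        if (~nonqc["cohort"].isin(COHORTS)).any():
            raise DataError("every non-QC sample must carry a cohort label")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def qc_ids(self) -> pd.Index:
        return self.table.index[self.table["is_qc"]]

    @property
    def non_qc_ids(self) -> pd.Index:
        return self.table.index[~self.table["is_qc"]]

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in _META_FIXED]

    def samples(
        self,
        groups: Iterable[str] | None = None,
        cohort: str | None = None,
        stages: Iterable[str] | None = None,
        include_qc: bool = False,
    ) -> pd.Index:
        """Sample ids matching the given filters (QC excluded by default)."""
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if not include_qc:
            mask &= ~t["is_qc"].to_numpy()
        if groups is not None:
            mask &= t["group"].isin(list(groups)).to_numpy()
        if cohort is not None:
            mask &= (t["cohort"] == cohort).to_numpy()
        if stages is not None:
            mask &= t["stage"].isin(list(stages)).to_numpy()
        return t.index[mask]

    def marker(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise DataError(f"unknown clinical marker {name!r}")
        return self.table[name]

    def subset(self, sample_ids: Sequence[str] | pd.Index) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[pd.Index(sample_ids)].copy())

    def relabel_group(self, old: str, new: str) -> "SampleMetadata":
        """Return a copy with group ``old`` relabelled ``new`` (e.g. merging
        borderline tumours into the malignant group)."""
        t = self.table.copy()
        t.loc[t["group"] == old, "group"] = new
        return SampleMetadata(t)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(path: str | Path, layout: str = "features") -> FeatureTable:
    """Read a delimited feature table.

    ``layout="features"`` expects features as rows (first column the
    ``"RT_mz"`` label, remaining columns samples); ``layout="samples"`` the
    transpose.  Separator (comma/tab) is sniffed from the header.
    """
    path = Path(path)
    if layout not in ("features", "samples"):
        raise ValueError(f"layout must be 'features' or 'samples', got {layout!r}")
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if layout == "features" and len(set(header)) < len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicated sample column name(s): {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index.name = None
    df.columns.name = None
    if layout == "samples":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated feature label(s): {dup}")
    try:
        ints = df.astype(float)
    except ValueError as exc:
        raise DataError(f"non-numeric intensity in {path.name}: {exc}") from exc
    if ints.isna().any().any():
        raise DataError(
            f"{path.name} contains empty/NaN intensities; encode missing as 0"
        )
    return FeatureTable(ints)


def write_feature_table(
    table: FeatureTable, path: str | Path, layout: str = "features", sep: str = ","
) -> None:
    df = table.intensities
    if layout == "samples":
        df = df.T
    df.to_csv(path, sep=sep, index_label="feature")


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col="sample_id")
    if "stage" in df.columns:
        df["stage"] = df["stage"].astype("string")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path, sep: str = ",") -> None:
    meta.table.to_csv(path, sep=sep, index_label="sample_id")
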