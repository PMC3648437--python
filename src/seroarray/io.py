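"""Spot-level array file handling.

Reads GenePix-results style (GPR) tab-delimited files into per-array scans,
applies background subtraction, and assembles scans plus sample metadata into
the features x samples :class:`ExperimentSet` that the rest of the pipeline
consumes.

The GPR dialect accepted here is deliberately loose: any tab-delimited file
whose column header row carries ``Name``, ``ID``, ``F635 Median`` and
``B635 Median`` is read, and unknown columns are ignored (real scanner
exports carry ~50 of them).  Leading ``key=value`` header lines are retained
as a string map on the scan.
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, RowParseError, ValidationError

REQUIRED_COLUMNS = ("Name", "ID", "F635 Median", "B635 Median")

#: regular expression applied to feature IDs/names to designate control spots
DEFAULT_CONTROL_PATTERN = r"^CTRL"

VALID_GROUPS = ("case", "control")
VALID_TIMEPOINTS = ("pre", "post", "na")


@dataclass(frozen=True)
class ProteinFeature:
    """One printed protein spot (collapsed over duplicates)."""

    feature_id: str
    gene_symbol: str = ""
    description: str = ""
    is_control: bool = False
    block: int = 0
    row: int = 0
    col: int = 0


@dataclass(frozen=True)
class SampleMeta:
    """Per-serum annotations: group label, surgical timepoint, demographics."""

    sample_id: str
    group: str
    timepoint: str = "na"
    subject_id: str | None = None
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be one of {VALID_GROUPS}, got {self.group!r}"
            )
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint must be one of {VALID_TIMEPOINTS}, "
                f"got {self.timepoint!r}"
            )


@dataclass
class ArrayScan:
    """Spot-level signal for one scanned array.

    ``data`` holds one row per spot in file order with at least the four
    required GPR columns; ``header`` is the key=value preamble of the file.
    """

    sample_id: str
    data: pd.DataFrame
    header: dict[str, str] = field(default_factory=dict)

    @property
    def signal(self) -> np.ndarray:
        return self.data["F635 Median"].to_numpy(dtype=float)

    @property
    def background(self) -> np.ndarray:
        return self.data["B635 Median"].to_numpy(dtype=float)

    @property
    def feature_ids(self) -> pd.Series:
        return self.data["ID"].astype(str)

    def __len__(self) -> int:
        return len(self.data)


def read_gpr(path: str | Path, sample_id: str | None = None) -> ArrayScan:
    """Read a GPR-subset file into an :class:`ArrayScan`.

    Raises :class:`FormatError` naming the first missing required column and
    :class:`RowParseError` (with the 1-based file line number) on the first
    non-numeric signal value.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    col_idx: int | None = None
    for i, line in enumerate(lines):
        fields = [f.strip().strip('"') for f in line.split("\t")]
        if any(c in fields for c in REQUIRED_COLUMNS):
            col_idx = i
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip().strip('"')] = val.strip().strip('"')
    if col_idx is None:
        raise FormatError(
            f"{path.name}: no column header row found; required column 'Name' missing"
        )
    data = pd.read_csv(_io.StringIO("\n".join(lines[col_idx:])), sep="\t")
    data.columns = [str(c).strip() for c in data.columns]
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            raise FormatError(f"{path.name}: required column {col!r} missing")
    for col in ("F635 Median", "B635 Median"):
        values = pd.to_numeric(data[col], errors="coerce")
        bad = values.isna().to_numpy().nonzero()[0]
        if bad.size:
            line_no = col_idx + 2 + int(bad[0])  # 1-based; header row is col_idx + 1
            raise RowParseError(
                f"{path.name} line {line_no}: non-numeric value "
                f"{data[col].iloc[bad[0]]!r} in column {col!r}"
            )
        data[col] = values.astype(float)
    data["Name"] = data["Name"].astype(str)
    data["ID"] = data["ID"].astype(str)
    return ArrayScan(sample_id=sample_id or path.stem, data=data, header=header)


def background_subtract(scan: ArrayScan, floor: float = 1.0) -> ArrayScan:
    """Net signal = max(foreground - background, floor), elementwise.

    The floor keeps the subsequent log2 transform defined on spots whose
    background exceeds the foreground.  Returns a new scan whose foreground
    column holds the net signal and whose background column is zeroed.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    net = np.maximum(scan.signal - scan.background, float(floor))
    data = scan.data.copy()
    data["F635 Median"] = net
    data["B635 Median"] = 0.0
    return ArrayScan(sample_id=scan.sample_id, data=data, header=dict(scan.header))


def features_from_scan(
    scan: ArrayScan, control_pattern: str = DEFAULT_CONTROL_PATTERN
) -> pd.DataFrame:
    """Derive a feature annotation table from one scan's spot rows."""
    pat = re.compile(control_pattern)
    frame = pd.DataFrame(
        {
            "feature_id": scan.feature_ids.to_numpy(),
            "gene_symbol": scan.data["Name"].to_numpy(),
        }
    )
    frame["description"] = ""
    frame["is_control"] = [
        bool(pat.search(fid) or pat.search(name))
        for fid, name in zip(frame["feature_id"], frame["gene_symbol"])
    ]
    for src, dst in (("Block", "block"), ("Row", "row"), ("Column", "col")):
        frame[dst] = (
            pd.to_numeric(scan.data[src], errors="coerce").fillna(0).astype(int)
            if src in scan.data.columns
            else 0
        )
    return frame.set_index("feature_id")


@dataclass
class ExperimentSet:
    """A validated features x samples net-signal matrix with annotations.

    ``features`` is indexed by feature_id (columns gene_symbol, is_control, ...),
    ``samples`` by sample_id (columns group, timepoint, subject_id, age, sex),
    and ``net_signal`` is the matrix with features as rows and samples as
    columns, in the same order as the two tables.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    net_signal: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if not self.net_signal.index.equals(self.features.index):
            raise DimensionError("net_signal rows do not match the feature table")
        if not self.net_signal.columns.equals(self.samples.index):
            raise DimensionError("net_signal columns do not match the sample table")
        bad = set(self.samples["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if (self.net_signal.to_numpy() < 0).any():
            raise ValidationError("net_signal contains negative entries")

    # -- convenience views -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def case_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "control"])

    @property
    def control_features(self) -> pd.Index:
        if "is_control" not in self.features.columns:
            return pd.Index([])
        return self.features.index[self.features["is_control"].astype(bool)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExperimentSet":
        ids = list(sample_ids)
        return ExperimentSet(
            features=self.features,
            samples=self.samples.loc[ids],
            net_signal=self.net_signal[ids],
        )

    # -- serialization -----------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, sidecar_path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar of annotations."""
        self.net_signal.to_csv(matrix_path, sep="\t", index_label="feature_id")
        sidecar = {
            "samples": self.samples.reset_index()
            .rename(columns={"index": "sample_id"})
            .where(self.samples.reset_index().notna(), None)
            .to_dict(orient="records"),
            "features": self.features.reset_index().to_dict(orient="records"),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, default=str))


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, group, timepoint, subject_id, age, sex)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise FormatError(f"{Path(path).name}: metadata needs 'sample_id' and 'group' columns")
    for col in ("timepoint", "subject_id", "sex"):
        if col not in meta.columns:
            meta[col] = "na" if col == "timepoint" else None
    meta["timepoint"] = meta["timepoint"].fillna("na")
    if "age" not in meta.columns:
        meta["age"] = np.nan
    meta = meta.set_index("sample_id")
    bad = set(meta["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels in metadata: {sorted(bad)}")
    return meta


def _collapse_duplicates(
    matrix: pd.DataFrame, features: pd.DataFrame, policy: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not matrix.index.has_duplicates:
        return matrix, features
    if policy == "mean":
        collapsed = matrix.groupby(level=0, sort=False).mean()
    elif policy == "median":
        collapsed = matrix.groupby(level=0, sort=False).median()
    elif policy == "first":
        collapsed = matrix[~matrix.index.duplicated(keep="first")]
    else:
        raise ValidationError(
            f"duplicate_policy must be 'mean', 'median' or 'first', got {policy!r}"
        )
    feat = features[~features.index.duplicated(keep="first")].copy()
    if "is_control" in feat.columns:
        feat["is_control"] = (
            features["is_control"].astype(bool).groupby(level=0, sort=False).any()
        )
    return collapsed.loc[feat.index.intersection(collapsed.index)], feat.loc[collapsed.index]


def merge_scans(
    scans: Iterable[ArrayScan],
    features: pd.DataFrame | Sequence[ProteinFeature] | None = None,
    metadata: pd.DataFrame | Sequence[SampleMeta] | None = None,
    duplicate_policy: str = "mean",
    control_pattern: str = DEFAULT_CONTROL_PATTERN,
) -> ExperimentSet:
    """Assemble background-subtracted scans into an :class:`ExperimentSet`.

    Column order follows metadata order.  Duplicate spots printed for one
    protein are collapsed keyed on feature_id (``duplicate_policy`` one of
    mean/median/first).
    """
    scans = list(scans)
    if not scans:
        raise ValidationError("no scans supplied")
    n = len(scans[0])
    for scan in scans:
        if len(scan) != n:
            raise DimensionError(
                f"scan {scan.sample_id!r} has {len(scan)} spots, expected {n}"
            )
    seen: set[str] = set()
    for scan in scans:
        if scan.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {scan.sample_id!r}")
        seen.add(scan.sample_id)

    if features is None:
        feat = features_from_scan(scans[0], control_pattern=control_pattern)
    elif isinstance(features, pd.DataFrame):
        feat = features.copy()
        if feat.index.name != "feature_id" and "feature_id" in feat.columns:
            feat = feat.set_index("feature_id")
    else:
        feat = pd.DataFrame([vars(f) for f in features]).set_index("feature_id")
    if len(feat) != n:
        raise DimensionError(f"feature table has {len(feat)} rows, scans have {n} spots")

    if metadata is None:
        meta = pd.DataFrame(
            {"group": "case", "timepoint": "na", "subject_id": None, "age": np.nan, "sex": None},
            index=pd.Index(sorted(seen), name="sample_id"),
        )
    elif isinstance(metadata, pd.DataFrame):
        meta = metadata
    else:
        meta = pd.DataFrame([vars(s) for s in metadata]).set_index("sample_id")
    missing = seen - set(meta.index)
    if missing:
        raise ValidationError(f"metadata missing sample(s): {sorted(missing)}")

    by_id = {scan.sample_id: scan for scan in scans}
    order = [sid for sid in meta.index if sid in by_id]
    matrix = pd.DataFrame(
        {sid: by_id[sid].signal for sid in order}, index=feat.index.copy()
    )
    matrix, feat = _collapse_duplicates(matrix, feat, duplicate_policy)
    return ExperimentSet(features=feat, samples=meta.loc[order], net_signal=matrix)
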