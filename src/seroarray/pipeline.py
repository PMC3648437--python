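"""Library-level stage chaining used by the command-line interface and tests."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .differential import DifferentialReactivityAnalysis, DifferentialResults, Thresholds
from .errors import ValidationError
from .io import (
    DEFAULT_CONTROL_PATTERN,
    ExperimentSet,
    background_subtract,
    merge_scans,
    read_gpr,
    read_metadata,
)
from .normalization import NormalizationResult, rlm_normalize


def load_experiment(
    gpr_dir: str | Path,
    metadata_path: str | Path,
    floor: float = 1.0,
    duplicate_policy: str = "mean",
    control_pattern: str = DEFAULT_CONTROL_PATTERN,
) -> ExperimentSet:
    """Read every ``*.gpr`` under ``gpr_dir``, subtract background, and merge."""
    gpr_dir = Path(gpr_dir)
    paths = sorted(gpr_dir.glob("*.gpr"))
    if not paths:
        raise ValidationError(f"no .gpr files found in {gpr_dir}")
    scans = [background_subtract(read_gpr(p), floor=floor) for p in paths]
    metadata = read_metadata(metadata_path)
    return merge_scans(
        scans,
        metadata=metadata,
        duplicate_policy=duplicate_policy,
        control_pattern=control_pattern,
    )


def discovery_analysis(
    experiment: ExperimentSet,
    thresholds: Thresholds | None = None,
    huber_c: float = 1.345,
    welch: bool = True,
) -> tuple[NormalizationResult, DifferentialResults]:
    """Normalize then compute the full differential table."""
    normalized = rlm_normalize(experiment, huber_c=huber_c)
    results = DifferentialReactivityAnalysis(
        normalized, thresholds=thresholds, welch=welch
    ).fit()
    return normalized, results


def experiment_from_matrix(
    matrix_path: str | Path, metadata_path: str | Path, log2_scale: bool = False
) -> ExperimentSet:
    """Rebuild an ExperimentSet from a saved matrix TSV plus metadata TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if log2_scale:
        matrix = 2.0**matrix
    metadata = read_metadata(metadata_path)
    features = pd.DataFrame(
        {
            "gene_symbol": matrix.index,
            "description": "",
            "is_control": [fid.startswith("CTRL") for fid in matrix.index.astype(str)],
        },
        index=matrix.index.rename("feature_id"),
    )
    return ExperimentSet(
        features=features, samples=metadata.loc[matrix.columns], net_signal=matrix
    )
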