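"""Seeded generators for array, annotation and ELISA fixtures.

Every generator is a pure function of its arguments (seed included) and
returns the simulated object together with a :class:`GroundTruth` record, so
each pipeline stage can be tested against known answers without any
downloads.

The array generator emulates the discovery study conditions: 8268-feature
arrays, 10 case vs 10 control sera (the case sera being 5 subjects sampled
pre- and post-operatively), 165 reactivities elevated 2-85x (log-uniform),
multiplicative lognormal spot noise at a fixed CV, per-array multiplicative
scale effects, and a designated set of control spots that receive no group
effect.  The ELISA generator draws a 46 vs 22 panel whose per-antigen
standardized effects are calibrated so the optimal linear score has a
target AUC in expectation (normal-theory closed form AUC = Phi(D/sqrt(2))
for combined effect D).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from .errors import ValidationError
from .io import ExperimentSet
from .prioritization import MMD_CANDIDATE_PANEL
from .validation import ElisaPanel


@dataclass
class GroundTruth:
    """What the generator injected, serialized alongside every fixture."""

    seed: int
    elevated_features: list[tuple[str, float]] = field(default_factory=list)
    array_effects_log2: dict[str, float] = field(default_factory=dict)
    elisa_effect_sizes: dict[str, float] = field(default_factory=dict)

    @property
    def elevated_ids(self) -> set[str]:
        return {fid for fid, _ in self.elevated_features}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "seed": self.seed,
                "elevated_features": self.elevated_features,
                "array_effects_log2": self.array_effects_log2,
                "elisa_effect_sizes": self.elisa_effect_sizes,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def gen_array_dataset(
    n_features: int = 8268,
    n_case: int = 10,
    n_control: int = 10,
    n_elevated: int = 165,
    fold_range: tuple[float, float] = (2.0, 85.0),
    cv: float = 0.2,
    array_effect_sd: float = 0.3,
    n_control_spots: int = 100,
    baseline_log_mean: float = math.log(300.0),
    baseline_log_sigma: float = 1.0,
    n_prepost_subjects: int | None = None,
    array_effects: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ExperimentSet, GroundTruth]:
    """Simulate a spot-level case/control array experiment.

    Per-feature baseline means are lognormal; in case arrays the elevated
    features are multiplied by true folds drawn log-uniformly from
    ``fold_range``; every array gets a multiplicative effect
    ``2**N(0, array_effect_sd)`` (equivalently exp of a normal with SD
    ``array_effect_sd * ln 2``); spot noise is multiplicative lognormal at
    the given CV.  ``array_effects`` (log2 units, one per array, cases
    first) overrides the random draw when supplied.  Net signals are
    integer-rounded RFU floored at 1.
    """
    if n_elevated >= n_features:
        raise ValidationError("n_elevated must be smaller than n_features")
    if n_control_spots >= n_features:
        raise ValidationError("n_control_spots must be smaller than n_features")
    if not 0 < fold_range[0] <= fold_range[1]:
        raise ValidationError(f"bad fold_range {fold_range}")
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control

    feature_ids = [f"CTRL_{i + 1:04d}" for i in range(n_control_spots)] + [
        f"FEAT_{i + 1:05d}" for i in range(n_features - n_control_spots)
    ]
    gene_symbols = ["CTRL"] * n_control_spots + [
        f"GENE{i + 1:05d}" for i in range(n_features - n_control_spots)
    ]
    features = pd.DataFrame(
        {
            "gene_symbol": gene_symbols,
            "description": "",
            "is_control": [i < n_control_spots for i in range(n_features)],
            "block": 1,
            "row": [i // 96 + 1 for i in range(n_features)],
            "col": [i % 96 + 1 for i in range(n_features)],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    if n_prepost_subjects is None:
        n_prepost_subjects = 5 if n_case == 10 else 0
    if 2 * n_prepost_subjects > n_case:
        raise ValidationError("2 * n_prepost_subjects cannot exceed n_case")
    sample_rows = []
    for k in range(n_case):
        if k < 2 * n_prepost_subjects:
            subject = f"subj{k // 2 + 1:02d}"
            timepoint = "pre" if k % 2 == 0 else "post"
        else:
            subject, timepoint = f"subj{k + 1:02d}", "na"
        sample_rows.append((f"MMD_{k + 1:02d}", "case", timepoint, subject))
    for k in range(n_control):
        sample_rows.append((f"HC_{k + 1:02d}", "control", "na", f"hc{k + 1:02d}"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "timepoint", "subject_id"]
    ).set_index("sample_id")
    samples["age"] = np.round(rng.uniform(18, 55, size=n_samples), 1)
    samples["sex"] = rng.choice(["F", "M"], size=n_samples)

    baseline = rng.lognormal(baseline_log_mean, baseline_log_sigma, size=n_features)
    candidates = np.arange(n_control_spots, n_features)
    elevated_idx = rng.choice(candidates, size=n_elevated, replace=False)
    folds = np.exp(
        rng.uniform(math.log(fold_range[0]), math.log(fold_range[1]), size=n_elevated)
    )
    if array_effects is None:
        a_log2 = rng.normal(0.0, array_effect_sd, size=n_samples)
    else:
        a_log2 = np.asarray(array_effects, dtype=float)
        if a_log2.size != n_samples:
            raise ValidationError(
                f"array_effects has {a_log2.size} entries, expected {n_samples}"
            )
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    noise = rng.lognormal(-sigma * sigma / 2.0, sigma, size=(n_features, n_samples))

    signal = np.tile(baseline[:, None], (1, n_samples))
    signal[elevated_idx, :n_case] *= folds[:, None]
    signal = signal * (2.0 ** a_log2)[None, :] * noise

    background = rng.lognormal(math.log(40.0), 0.3, size=(n_features, n_samples))
    foreground = np.round(signal + background)
    background = np.round(background)
    net = np.maximum(foreground - background, 1.0)

    experiment = ExperimentSet(
        features=features,
        samples=samples,
        net_signal=pd.DataFrame(net, index=features.index, columns=samples.index),
    )
    # stash spot-level channels so GPR writing round-trips exactly
    experiment.foreground = pd.DataFrame(  # type: ignore[attr-defined]
        foreground, index=features.index, columns=samples.index
    )
    experiment.background = pd.DataFrame(  # type: ignore[attr-defined]
        background, index=features.index, columns=samples.index
    )
    truth = GroundTruth(
        seed=seed,
        elevated_features=[
            (feature_ids[i], float(f)) for i, f in zip(elevated_idx, folds)
        ],
        array_effects_log2={sid: float(a) for sid, a in zip(samples.index, a_log2)},
    )
    return experiment, truth


# ---------------------------------------------------------------------------
# writers (GPR subset + metadata), so array_io round-trips are testable
# ---------------------------------------------------------------------------

def write_gpr_files(experiment: ExperimentSet, out_dir: str | Path) -> list[Path]:
    """Write one GPR-subset file per array; returns the paths written.

    Foreground/background channels stashed by the generator are used when
    present; otherwise a flat synthetic background of 50 RFU is added so
    that read + background-subtract reproduces the net signal exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fg = getattr(experiment, "foreground", experiment.net_signal + 50.0)
    bg = getattr(
        experiment,
        "background",
        pd.DataFrame(
            50.0, index=experiment.net_signal.index, columns=experiment.net_signal.columns
        ),
    )
    feat = experiment.features
    paths = []
    for sid in experiment.samples.index:
        path = out_dir / f"{sid}.gpr"
        lines = [
            "Type=seroarray GPR subset 1.0",
            f"SampleID={sid}",
            "Wavelength=635",
            "\t".join(["Block", "Column", "Row", "Name", "ID", "F635 Median", "B635 Median"]),
        ]
        for fid, f, b in zip(feat.index, fg[sid].to_numpy(), bg[sid].to_numpy()):
            row = feat.loc[fid]
            lines.append(
                f"{row['block']}\t{row['col']}\t{row['row']}\t"
                f"{row['gene_symbol']}\t{fid}\t{f:.10g}\t{b:.10g}"
            )
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def write_metadata(experiment: ExperimentSet, path: str | Path) -> Path:
    path = Path(path)
    experiment.samples.to_csv(path, sep="\t", index_label="sample_id")
    return path


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

def gen_annotation(
    gene_symbols,
    reference_panel: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table (gene_symbol, cytoband, der, neuro_variant).

    With ``reference_panel=True`` the six-record validated candidate panel
    is emitted verbatim on top of the supplied background genes, which get
    DER ~ Uniform(0, 1), random cytobands, and a 10% neurological-variant
    rate; otherwise every gene is randomly annotated.
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in gene_symbols]
    panel_genes = set(MMD_CANDIDATE_PANEL["gene_symbol"]) if reference_panel else set()
    background = [g for g in genes if g not in panel_genes]
    n = len(background)
    chroms = rng.choice([str(i) for i in range(1, 23)], size=n)
    arms = rng.choice(["p", "q"], size=n)
    major = rng.integers(11, 37, size=n)
    sub = rng.integers(0, 4, size=n)  # 0 -> no sub-band
    cytobands = [
        f"{c}{a}{m}" + (f".{s}" if s else "")
        for c, a, m, s in zip(chroms, arms, major, sub)
    ]
    frame = pd.DataFrame(
        {
            "gene_symbol": background,
            "cytoband": cytobands,
            "der": rng.uniform(0.0, 1.0, size=n),
            "neuro_variant": rng.random(size=n) < 0.1,
        }
    )
    if reference_panel:
        panel = MMD_CANDIDATE_PANEL[["gene_symbol", "cytoband", "der", "neuro_variant"]]
        frame = pd.concat([panel, frame], ignore_index=True)
    return frame


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = annotation.copy()
    out["neuro_variant"] = out["neuro_variant"].astype(int)
    out.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# ELISA panel
# ---------------------------------------------------------------------------

def calibrate_elisa_effects(target_auc: float, n_antigens: int) -> np.ndarray:
    """Per-antigen standardized effects whose optimal combination hits target_auc.

    Solves AUC = Phi(D / sqrt(2)) for the combined effect D by root
    bracketing, then splits it equally: d_k = D / sqrt(n_antigens).
    """
    if not 0.5 < target_auc < 1.0:
        raise ValidationError(f"target_auc must lie in (0.5, 1), got {target_auc}")
    D = brentq(lambda d: ndtr(d / math.sqrt(2.0)) - target_auc, 0.0, 12.0)
    return np.full(n_antigens, D / math.sqrt(n_antigens))


def gen_elisa(
    n_case: int = 46,
    n_control: int = 22,
    n_antigens: int = 6,
    target_auc: float = 0.76,
    antigens: list[str] | None = None,
    seed: int = 0,
) -> tuple[ElisaPanel, GroundTruth]:
    """Simulate a case/control ELISA OD(405) panel with a calibrated AUC.

    Values are Gaussian on the log scale (case means shifted by the
    calibrated per-antigen effects), exponentiated and shifted positive.
    """
    d = calibrate_elisa_effects(target_auc, n_antigens)
    rng = np.random.default_rng(seed)
    if antigens is None:
        antigens = (
            list(MMD_CANDIDATE_PANEL["gene_symbol"])
            if n_antigens == 6
            else [f"AG{k + 1:02d}" for k in range(n_antigens)]
        )
    if len(antigens) != n_antigens:
        raise ValidationError("antigens list does not match n_antigens")
    n = n_case + n_control
    g = rng.normal(0.0, 1.0, size=(n, n_antigens))
    g[:n_case] += d[None, :]
    od = 0.05 + 0.6 * np.exp(0.35 * g)
    sample_ids = [f"MMD_{k + 1:02d}" for k in range(n_case)] + [
        f"CVD_{k + 1:02d}" for k in range(n_control)
    ]
    samples = pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * n_control,
            "sex": rng.choice(["F", "M"], size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    panel = ElisaPanel(
        od=pd.DataFrame(od, index=samples.index, columns=antigens), samples=samples
    )
    truth = GroundTruth(
        seed=seed,
        elisa_effect_sizes={a: float(x) for a, x in zip(antigens, d)},
    )
    return panel, truth
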