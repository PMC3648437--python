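"""Candidate prioritization over cytogenetic loci and fitSNP DER scores.

Differentially reactive antigens are intersected with (a) membership of
linkage loci previously associated with moyamoya disease and (b) per-gene
fitSNP differential expression ratios (DER) — the fraction of public mRNA
microarray experiments in which a gene is differentially expressed — plus a
flag for genes carrying variants linked to neurological disease.  Two
admission stages are applied and their union returned:

* locus stage:   significant at p <= p1, cytoband inside one of the loci,
                 DER > der1;
* variant stage: neurological-variant gene, significant at p <= p2,
                 DER > der2.

DER scores are consumed from an annotation table; computing them from raw
expression corpora is out of scope here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import CytobandParseError, ValidationError

#: linkage loci reported for moyamoya disease (OMIM-derived)
MMD_LINKAGE_LOCI = ("3p26-p24.2", "8q23", "17q25")

#: Reference panel of the six validated MMD-associated autoantigens:
#: cytogenetic location, fitSNP DER, neurological-variant flag, and the
#: discovery-phase array p-value for each.
MMD_CANDIDATE_PANEL = pd.DataFrame(
    [
        ("APP", "21q21.3", 0.604, True, 0.029),
        ("CTNNB1", "3p21", 0.555, False, 0.0197),
        ("EDIL3", "5q14", 0.484, True, 0.0003),
        ("ROR1", "1p32-p31", 0.586, True, 0.0029),
        ("GPS1", "17q25.3", 0.46, False, 0.07),
        ("STRA13", "17q25.3", 0.581, False, 0.0021),
    ],
    columns=["gene_symbol", "cytoband", "der", "neuro_variant", "p"],
)

_VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])
_CYTOBAND_RE = re.compile(
    r"^(\d{1,2}|X|Y)([pq])(\d+(?:\.\d+)?)?(?:-([pq])?(\d+(?:\.\d+)?))?$"
)


@dataclass(frozen=True)
class Cytoband:
    """A chromosome-arm-band coordinate, possibly a band range.

    Band labels are kept as the original strings so that parsing and
    re-serialization are lossless; ``start`` is the more distal
    (higher-numbered) endpoint of a range.
    """

    chromosome: str
    arm: str
    start: str | None = None
    end: str | None = None

    @property
    def is_range(self) -> bool:
        return self.end is not None

    @property
    def start_value(self) -> float | None:
        return None if self.start is None else float(self.start)

    @property
    def end_value(self) -> float | None:
        return None if self.end is None else float(self.end)

    def __str__(self) -> str:
        text = f"{self.chromosome}{self.arm}{self.start or ''}"
        if self.end is not None:
            text += f"-{self.arm}{self.end}"
        return text


def parse_cytoband(text: str) -> Cytoband:
    """Parse e.g. ``17q25.3`` or the range ``3p26-p24.2``.

    Range endpoints are ordered so the first is the more distal
    (higher-numbered) band.  Malformed text raises
    :class:`CytobandParseError` naming the offending token.
    """
    token = str(text).strip()
    m = _CYTOBAND_RE.match(token)
    if not m:
        raise CytobandParseError(f"malformed cytoband {token!r}")
    chrom, arm, band1, arm2, band2 = m.groups()
    if chrom not in _VALID_CHROMOSOMES:
        raise CytobandParseError(f"malformed cytoband {token!r}: bad chromosome {chrom!r}")
    if arm2 is not None and arm2 != arm:
        raise CytobandParseError(
            f"malformed cytoband {token!r}: range crosses arms ({arm} vs {arm2})"
        )
    if band2 is not None and band1 is None:
        raise CytobandParseError(f"malformed cytoband {token!r}: range without start band")
    if band1 is not None and float(band1) <= 0:
        raise CytobandParseError(f"malformed cytoband {token!r}: band must be > 0")
    if band2 is None:
        return Cytoband(chromosome=chrom, arm=arm, start=band1)
    hi, lo = (band1, band2) if float(band1) >= float(band2) else (band2, band1)
    return Cytoband(chromosome=chrom, arm=arm, start=hi, end=lo)


def _cover(label: str) -> tuple[float, float]:
    """Half-open numeric interval covered by a band label and its sub-bands.

    ``"25"`` covers [25, 26) so 25.3 is inside; ``"24.2"`` covers [24.2, 24.3).
    """
    value = float(label)
    decimals = len(label.split(".", 1)[1]) if "." in label else 0
    return value, value + 10.0 ** (-decimals)


def _interval(band: Cytoband) -> tuple[float, float]:
    los, his = [], []
    for label in filter(None, (band.start, band.end)):
        lo, hi = _cover(label)
        los.append(lo)
        his.append(hi)
    return min(los), max(his)


def band_in_range(band: Cytoband, locus: Cytoband, granularity: str = "band") -> bool:
    """Is ``band`` inside ``locus``?

    ``granularity='arm'`` requires only the same chromosome arm.  At band
    granularity the numeric band must fall inside the locus interval,
    endpoints inclusive, with prefix matching for sub-bands (25.3 is inside
    a locus ending at 25).
    """
    if granularity not in ("band", "arm"):
        raise ValidationError(f"granularity must be 'band' or 'arm', got {granularity!r}")
    if band.chromosome != locus.chromosome or band.arm != locus.arm:
        return False
    if granularity == "arm":
        return True
    if locus.start is None or band.start is None:
        return True  # an arm-level coordinate admits every band on the arm
    q_lo, q_hi = _interval(band)
    r_lo, r_hi = _interval(locus)
    return q_lo < r_hi and r_lo < q_hi


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-gene annotation consumed by the prioritization cascade."""

    gene_symbol: str
    cytoband: Cytoband
    der: float
    neuro_variant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.der <= 1.0:
            raise ValidationError(
                f"gene {self.gene_symbol!r}: DER must lie in [0, 1], got {self.der}"
            )


@dataclass(frozen=True)
class PrioritizationConfig:
    """Thresholds and loci for the two-stage candidate cascade."""

    loci: tuple[str, ...] = MMD_LINKAGE_LOCI
    p1: float = 0.05
    p2: float = 0.05
    der1: float = 0.45
    der2: float = 0.6
    granularity: str = "band"

    @classmethod
    def strict(cls) -> "PrioritizationConfig":
        """Literal thresholds at band granularity."""
        return cls()

    @classmethod
    def panel_recovery(cls) -> "PrioritizationConfig":
        """Relaxed settings (arm granularity, p1=0.1, der2=0.45) that recover
        the published six-antigen panel; see the methods note for why the
        literal thresholds do not."""
        return cls(p1=0.1, p2=0.05, der1=0.45, der2=0.45, granularity="arm")


@dataclass(frozen=True)
class Candidate:
    gene_symbol: str
    stage: str  # 'locus' or 'variant'
    der: float
    p: float


@dataclass
class CandidateSet:
    """Ordered prioritized genes with the stage that admitted each."""

    candidates: list[Candidate] = field(default_factory=list)
    config: PrioritizationConfig | None = None

    @property
    def genes(self) -> list[str]:
        return [c.gene_symbol for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.gene_symbol, c.stage, c.der, c.p) for c in self.candidates],
            columns=["gene_symbol", "stage", "der", "p"],
        )


def read_annotation(path) -> pd.DataFrame:
    """Read the annotation TSV (gene_symbol, cytoband, der, neuro_variant as 0/1)."""
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "cytoband", "der", "neuro_variant"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
    ann["neuro_variant"] = ann["neuro_variant"].astype(int).astype(bool)
    return ann


def fitsnp_prioritize(
    diff_results: pd.DataFrame,
    annotations: pd.DataFrame,
    config: PrioritizationConfig | None = None,
) -> CandidateSet:
    """Run the two-stage cascade over a differential table.

    ``diff_results`` needs ``gene_symbol`` and a p-value column (``p`` or
    ``p_m``).  Genes lacking an annotation are excluded with a warning.
    The result is the union of the two stages (locus stage recorded when a
    gene satisfies both), ordered by ascending p then gene symbol.
    """
    cfg = config or PrioritizationConfig.strict()
    p_col = "p" if "p" in diff_results.columns else "p_m"
    if p_col not in diff_results.columns:
        raise ValidationError("differential table needs a 'p' or 'p_m' column")

    ann = annotations
    if "gene_symbol" in ann.columns:
        ann = ann.set_index("gene_symbol")
    loci = [parse_cytoband(t) for t in cfg.loci]

    admitted: dict[str, Candidate] = {}
    for row in diff_results.itertuples(index=False):
        gene = getattr(row, "gene_symbol")
        p = float(getattr(row, p_col))
        if gene in admitted:
            continue
        if gene not in ann.index:
            warnings.warn(f"gene {gene!r} has no annotation; excluded", UserWarning, stacklevel=2)
            continue
        rec = ann.loc[gene]
        band = parse_cytoband(rec["cytoband"])
        der = float(rec["der"])
        neuro = bool(rec["neuro_variant"])
        in_locus = any(band_in_range(band, locus, cfg.granularity) for locus in loci)
        if p <= cfg.p1 and der > cfg.der1 and in_locus:
            admitted[gene] = Candidate(gene, "locus", der, p)
        elif neuro and p <= cfg.p2 and der > cfg.der2:
            admitted[gene] = Candidate(gene, "variant", der, p)
    ordered = sorted(admitted.values(), key=lambda c: (c.p, c.gene_symbol))
    return CandidateSet(candidates=ordered, config=cfg)
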