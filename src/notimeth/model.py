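"""Core domain objects shared across the NotI-microarray analysis pipeline.

The central abstraction is the *NotI site*: a genomic clone flanking a NotI
restriction site (5'-GCGGCCGC-3', cleaved only when unmethylated), spotted on
a two-channel tumor/normal microarray. Because NotI digestion is blocked by
CpG methylation, a drop in tumor-channel signal reports promoter methylation
and/or deletion (MD) jointly; a gain reports amplification/demethylation (AD).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Arm",
    "CallState",
    "CALL_TOKENS",
    "CallThresholds",
    "ClassifierMetrics",
    "ConfigError",
    "FormatError",
    "NormalizationError",
    "NotISite",
    "NotimethError",
    "PanelSpec",
    "QpcrSampleSet",
    "RelExpr",
    "BisulfiteCloneSet",
    "SampleMeta",
    "StructuralError",
    "TestResult",
    "ValidationError",
    "parse_arm",
]


class NotimethError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NotimethError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(NotimethError):
    """A parsed value violates a domain invariant."""


class ConfigError(NotimethError):
    """A simulation or run configuration is inconsistent."""


class NormalizationError(NotimethError):
    """No usable log-ratios were available to centre a hybridization."""


class StructuralError(NotimethError):
    """Inputs that must share structure (clone sets, samples) do not."""


class CallState(str, enum.Enum):
    """Per-site, per-sample categorical state from a tumor/normal hybridization.

    MD = methylation and/or deletion (decreased tumor signal),
    AD = amplification and/or demethylation (increased tumor signal),
    RET = retention, NODATA = no information.
    """

    MD = "MD"
    AD = "AD"
    RET = "RET"
    NODATA = "NA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Tokens used on disk for call matrices, in canonical order.
CALL_TOKENS = tuple(s.value for s in CallState)

_LOCUS_RE = re.compile(r"^3(?P<arm>[pq])")


class Arm(str, enum.Enum):
    """Chromosome arm of a cytoband locus on chromosome 3."""

    P = "p"
    Q = "q"


def parse_arm(locus: str) -> Arm:
    """Derive the chromosome arm from a cytoband string such as ``3p24.2``.

    Raises :class:`ValidationError` for loci not on chromosome 3.
    """
    m = _LOCUS_RE.match(locus.strip())
    if not m:
        raise ValidationError(
            f"locus {locus!r} is not a chromosome 3 cytoband (expected '3p...' or '3q...')"
        )
    return Arm(m.group("arm"))


@dataclass(frozen=True)
class NotISite:
    """A NotI-linking clone with its associated gene(s) and cytoband locus.

    One clone may span the shared CpG island of two divergently transcribed
    genes; such clones carry both symbols (slash-separated in source tables).
    """

    clone_id: str
    gene_names: tuple[str, ...]
    locus: str

    def __post_init__(self) -> None:
        if not self.clone_id:
            raise ValidationError("clone_id must be nonempty")
        if not self.gene_names:
            raise ValidationError(f"site {self.clone_id}: at least one gene name required")
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        parse_arm(self.locus)  # validates

    @property
    def arm(self) -> Arm:
        return parse_arm(self.locus)


_STAGES = ("I", "II", "III")
_HISTOLOGIES = ("ccRCC", "pRCC")


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotation of one tumor sample (histology, TNM stage)."""

    sample_id: str
    histology: str
    stage: str
    tnm: str = ""

    def __post_init__(self) -> None:
        if self.histology not in _HISTOLOGIES:
            raise ValidationError(f"unknown histology {self.histology!r}")
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class CallThresholds:
    """Log-ratio cutoffs for turning a centred tumor/normal ratio into a state.

    Defaults call a state at a 1.5-fold change (|log2 ratio| >= 0.58), a
    conservative margin for detecting the 2-fold drop expected from a
    hemizygous loss or full monoallelic methylation. Boundary equality calls
    the event state. ``min_valid`` is the minimum number of unflagged
    replicate spots per channel for a site to yield data at all.
    """

    md_log_ratio: float = -0.58
    ad_log_ratio: float = 0.58
    min_valid: int = 4

    def __post_init__(self) -> None:
        if not (self.md_log_ratio < 0.0 < self.ad_log_ratio):
            raise ConfigError(
                f"thresholds must satisfy md < 0 < ad, got {self.md_log_ratio}, {self.ad_log_ratio}"
            )
        if self.min_valid < 1:
            raise ConfigError("min_valid must be >= 1")


@dataclass(frozen=True)
class PanelSpec:
    """A methylation marker panel with its k-of-m decision threshold.

    A sample is classified positive when at least ``k`` of the panel's
    markers are in the MD state.
    """

    marker_clone_ids: tuple[str, ...]
    k: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_clone_ids", tuple(self.marker_clone_ids))
        if len(set(self.marker_clone_ids)) != len(self.marker_clone_ids):
            raise ValidationError("panel markers must be distinct")
        if not self.marker_clone_ids:
            raise ValidationError("panel must contain at least one marker")
        if not 1 <= self.k <= len(self.marker_clone_ids):
            raise ValidationError(
                f"k={self.k} outside [1, {len(self.marker_clone_ids)}]"
            )

    @property
    def size(self) -> int:
        return len(self.marker_clone_ids)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and derived metrics of a binary marker panel.

    ``gini`` is 2*AUC - 1 where the AUC ranks tumors against negatives by
    the integer marker-count score (midrank handling of ties).
    """

    tp: int
    fn: int
    tn: int
    fp: int
    gini: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)


@dataclass(frozen=True)
class QpcrSampleSet:
    """Replicate Ct values for one target gene in one paired tumor/normal sample.

    Reference-gene Cts and amplification efficiencies are keyed by reference
    symbol. Efficiency ``E`` is fractional (0.9-1.0 in practice); one cycle
    multiplies template by ``1 + E``.
    """

    gene: str
    sample_id: str
    ct_tar_normal: np.ndarray
    ct_tar_tumor: np.ndarray
    ct_ref_normal: dict[str, np.ndarray]
    ct_ref_tumor: dict[str, np.ndarray]
    e_tar: float
    e_ref: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ct_tar_normal", np.asarray(self.ct_tar_normal, float))
        object.__setattr__(self, "ct_tar_tumor", np.asarray(self.ct_tar_tumor, float))
        for name, arrs in (("ct_ref_normal", self.ct_ref_normal), ("ct_ref_tumor", self.ct_ref_tumor)):
            object.__setattr__(self, name, {r: np.asarray(v, float) for r, v in arrs.items()})
        if set(self.ct_ref_normal) != set(self.ct_ref_tumor) or set(self.ct_ref_normal) != set(self.e_ref):
            raise ValidationError("reference genes inconsistent across tissues/efficiencies")
        if not self.ct_ref_normal:
            raise ValidationError("at least one reference gene is required")
        for arr in (self.ct_tar_normal, self.ct_tar_tumor, *self.ct_ref_normal.values(), *self.ct_ref_tumor.values()):
            if arr.size < 1:
                raise ValidationError("each assay needs at least one Ct replicate")
            if np.any(arr <= 0):
                raise ValidationError("all Ct values must be positive")
        for e in (self.e_tar, *self.e_ref.values()):
            if not 0 < e <= 1:
                raise ValidationError(f"efficiency {e} outside (0, 1]")

    @property
    def references(self) -> tuple[str, ...]:
        return tuple(sorted(self.ct_ref_normal))


@dataclass(frozen=True)
class RelExpr:
    """Relative mRNA level of one gene in one sample (tumor relative to normal).

    ``r`` < 1 means downregulation in the tumor. ``fold`` is the magnitude
    max(r, 1/r); ``direction`` applies the study's 2-fold significance rule.
    """

    gene: str
    sample_id: str
    r: float
    per_reference: dict[str, float] = field(default_factory=dict)
    direction: str = "unchanged"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError("relative expression must be positive")
        if self.direction not in ("down", "up", "unchanged"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    @property
    def fold(self) -> float:
        return max(self.r, 1.0 / self.r)


@dataclass(frozen=True)
class BisulfiteCloneSet:
    """Per-clone methylation across ordered CpG positions of one amplicon.

    ``matrix`` is clones x CpGs, True = methylated. ``noti_cpg_indices`` are
    the 1-based positions of the CpGs forming the NotI recognition site.
    """

    gene: str
    sample_id: str
    matrix: np.ndarray
    noti_cpg_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, bool)
        if m.ndim != 2:
            raise ValidationError("clone matrix must be 2-dimensional (clones x CpGs)")
        object.__setattr__(self, "matrix", m)
        idx = tuple(int(i) for i in self.noti_cpg_indices)
        if not idx:
            raise ValidationError("noti_cpg_indices must be nonempty")
        if any(not 1 <= i <= m.shape[1] for i in idx):
            raise ValidationError(
                f"NotI CpG indices {idx} outside 1..{m.shape[1]}"
            )
        object.__setattr__(self, "noti_cpg_indices", idx)

    @property
    def n_clones(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_cpg(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical test with an explicit method annotation.

    ``method_note`` records whether an exact or approximate branch produced
    the p-value and how ties/zeros were handled, so every p in a report is
    attributable.
    """

    test_name: str
    statistic: float
    p_value: float
    method_note: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")
        if not self.method_note:
            raise ValidationError("method_note must be populated")
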