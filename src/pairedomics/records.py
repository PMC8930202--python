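"""Validated domain records shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .channels import BASES
from .errors import ValidationError

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "silent", "frameshift", "inframe", "other"}
)
#: Classes counted as protein-changing for neoantigen denominators.
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "frameshift", "inframe"}
)
TX_STRANDS = frozenset({"transcribed", "untranscribed", "unknown"})
GROUPS = frozenset(
    {"primary_no_relapse", "primary_with_relapse", "relapsed", "control"}
)
_INDEL_CLASSES = frozenset({"frameshift", "inframe"})


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic variant with trinucleotide context and strand annotation."""

    sample_id: str
    patient_id: str
    timepoint_label: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    gene: str
    context3: str | None = None
    tx_strand: str = "unknown"
    cluster_id: str | None = None
    is_neoantigenic: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")
        if self.tx_strand not in TX_STRANDS:
            raise ValidationError(f"unknown tx_strand {self.tx_strand!r}")
        if self.is_snv:
            if self.variant_class in _INDEL_CLASSES:
                raise ValidationError(
                    f"variant_class {self.variant_class!r} inconsistent with "
                    f"single-base alleles {self.ref_allele}>{self.alt_allele}"
                )
            if self.context3 is not None:
                ctx = self.context3
                if len(ctx) != 3 or any(b not in BASES for b in ctx):
                    raise ValidationError(f"context3 must be an ACGT 3-mer, got {ctx!r}")
                if ctx[1] != self.ref_allele:
                    raise ValidationError(
                        f"context3 {ctx!r} middle base does not match ref "
                        f"{self.ref_allele!r}"
                    )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in BASES
            and self.alt_allele in BASES
        )

    @property
    def key(self) -> str:
        """Identity used for sharing classes and neoantigen linkage."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True, slots=True)
class SegmentRecord:
    """A copy-number segment (SEG convention: 1-based, inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_value: float
    zscore: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} "
                f"({self.sample_id} {self.chrom})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class Clonotype:
    """A CDR3 sequence with read count and productivity flags."""

    sample_id: str
    cdr3_aa: str
    read_count: int
    productive: bool
    in_frame: bool
    cdr3_nt: str | None = None
    v_gene: str | None = None
    j_gene: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValidationError(f"read_count must be >= 1, got {self.read_count}")
        if not self.cdr3_aa:
            raise ValidationError("cdr3_aa must be nonempty")
        if self.cdr3_nt is not None and self.in_frame and len(self.cdr3_nt) % 3 != 0:
            raise ValidationError(
                f"in-frame cdr3_nt length {len(self.cdr3_nt)} not divisible by 3"
            )


@dataclass(frozen=True, slots=True)
class NeoantigenCandidate:
    """A mutant peptide with predicted mutant/wild-type dissociation constants."""

    sample_id: str
    mutation_key: str
    peptide: str
    hla_allele: str
    kd_mutant_nM: float
    kd_wildtype_nM: float
    expressed: bool = True

    def __post_init__(self) -> None:
        if not 9 <= len(self.peptide) <= 11:
            raise ValidationError(
                f"peptide length must be 9-11 aa, got {len(self.peptide)}"
            )
        if not (self.kd_mutant_nM > 0 and self.kd_wildtype_nM > 0):
            raise ValidationError("K_D values must be positive")


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Sample-to-patient mapping with group and timepoint order."""

    sample_id: str
    patient_id: str
    group: str
    timepoint: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")


@dataclass(frozen=True, slots=True)
class ClusterRecord:
    """A clonal cluster consumed from upstream clonal-deconvolution output."""

    patient_id: str
    cluster_id: str
    n_variants: int
    prevalence: dict[str, float] = field(default_factory=dict)
    contains_driver: bool = False

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValidationError(f"n_variants must be >= 1, got {self.n_variants}")
        for sample, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"prevalence {p} for sample {sample} outside [0, 1]"
                )
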