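"""Readers and writers for every table the pipeline touches.

All tables are plain TSV/CSV.  Coordinates follow each format's native
convention: MAF-like and SEG tables are 1-based inclusive.  Readers are
strict — an invalid row raises a :class:`ValidationError` naming the row
rather than being dropped silently — and every reader/writer pair is an
identity on valid data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS
from .errors import FormatError, ValidationError
from .records import (
    Clonotype,
    ClusterRecord,
    MutationRecord,
    NeoantigenCandidate,
    SampleMeta,
    SegmentRecord,
)
from .signatures import SignatureCatalog

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "Patient_ID",
    "Timepoint",
    "context3",
    "tx_strand",
    "cluster_id",
    "is_neoantigenic",
]
_MAF_REQUIRED = MAF_COLUMNS[:7]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "seg.mean", "zscore"]
_SEG_REQUIRED = SEG_COLUMNS[:5]

AIRR_COLUMNS = [
    "sample_id",
    "junction_aa",
    "junction",
    "v_call",
    "j_call",
    "duplicate_count",
    "productive",
    "vj_in_frame",
]
_AIRR_REQUIRED = ["sample_id", "junction_aa", "duplicate_count", "productive"]

NEO_COLUMNS = [
    "sample_id",
    "mutation_key",
    "peptide",
    "hla_allele",
    "kd_mutant_nM",
    "kd_wildtype_nM",
    "expressed",
]

META_COLUMNS = ["sample_id", "patient_id", "group", "timepoint"]

_BUNDLED_CATALOG = "reference_signatures.csv"


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column {missing[0]!r}")


def _opt(value) -> str | None:
    """None for NA/empty cells, str otherwise."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s not in ("", "nan", ".") else None


def _flag(value) -> bool:
    return str(value).strip().upper() in ("T", "TRUE", "1", "YES")


# ---------------------------------------------------------------- mutations

def read_mutations(path: str | Path, dialect: str = "maf") -> list[MutationRecord]:
    """Read a MAF-like mutation TSV into validated records (order preserved)."""
    if dialect != "maf":
        raise FormatError(f"unknown mutation dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _MAF_REQUIRED, f"mutation table {path}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            neo = _opt(row.get("is_neoantigenic"))
            records.append(
                MutationRecord(
                    sample_id=row["Tumor_Sample_Barcode"],
                    patient_id=_opt(row.get("Patient_ID")) or "",
                    timepoint_label=_opt(row.get("Timepoint")) or "",
                    chrom=row["Chromosome"],
                    pos=int(row["Start_Position"]),
                    ref_allele=row["Reference_Allele"],
                    alt_allele=row["Tumor_Seq_Allele2"],
                    variant_class=row["Variant_Classification"],
                    gene=row["Hugo_Symbol"],
                    context3=_opt(row.get("context3")),
                    tx_strand=_opt(row.get("tx_strand")) or "unknown",
                    cluster_id=_opt(row.get("cluster_id")),
                    is_neoantigenic=_flag(neo) if neo is not None else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "Hugo_Symbol": m.gene,
            "Chromosome": m.chrom,
            "Start_Position": m.pos,
            "Reference_Allele": m.ref_allele,
            "Tumor_Seq_Allele2": m.alt_allele,
            "Variant_Classification": m.variant_class,
            "Tumor_Sample_Barcode": m.sample_id,
            "Patient_ID": m.patient_id,
            "Timepoint": m.timepoint_label,
            "context3": m.context3 or "",
            "tx_strand": m.tx_strand,
            "cluster_id": m.cluster_id or "",
            "is_neoantigenic": (
                "" if m.is_neoantigenic is None else ("T" if m.is_neoantigenic else "F")
            ),
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- segments

def read_segments(path: str | Path) -> list[SegmentRecord]:
    """Read a SEG-style TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _SEG_REQUIRED, f"segment table {path}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            z = _opt(row.get("zscore"))
            records.append(
                SegmentRecord(
                    sample_id=row["ID"],
                    chrom=row["chrom"],
                    start=int(row["loc.start"]),
                    end=int(row["loc.end"]),
                    log2_value=float(row["seg.mean"]),
                    zscore=float(z) if z is not None else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_segments(records: Iterable[SegmentRecord], path: str | Path) -> None:
    rows = [
        {
            "ID": s.sample_id,
            "chrom": s.chrom,
            "loc.start": s.start,
            "loc.end": s.end,
            "seg.mean": repr(s.log2_value),
            "zscore": "" if s.zscore is None else repr(s.zscore),
        }
        for s in records
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- clonotypes

def read_clonotypes(path: str | Path) -> list[Clonotype]:
    """Read an AIRR-style clonotype TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _AIRR_REQUIRED, f"clonotype table {path}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            in_frame_raw = _opt(row.get("vj_in_frame"))
            records.append(
                Clonotype(
                    sample_id=row["sample_id"],
                    cdr3_aa=row["junction_aa"],
                    cdr3_nt=_opt(row.get("junction")),
                    v_gene=_opt(row.get("v_call")),
                    j_gene=_opt(row.get("j_call")),
                    read_count=int(row["duplicate_count"]),
                    productive=_flag(row["productive"]),
                    in_frame=_flag(in_frame_raw) if in_frame_raw is not None else True,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_clonotypes(records: Iterable[Clonotype], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "junction_aa": c.cdr3_aa,
            "junction": c.cdr3_nt or "",
            "v_call": c.v_gene or "",
            "j_call": c.j_gene or "",
            "duplicate_count": c.read_count,
            "productive": "T" if c.productive else "F",
            "vj_in_frame": "T" if c.in_frame else "F",
        }
        for c in records
    ]
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- neoantigens

def read_neoantigens(path: str | Path) -> list[NeoantigenCandidate]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, NEO_COLUMNS[:6], f"neoantigen table {path}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            records.append(
                NeoantigenCandidate(
                    sample_id=row["sample_id"],
                    mutation_key=row["mutation_key"],
                    peptide=row["peptide"],
                    hla_allele=row["hla_allele"],
                    kd_mutant_nM=float(row["kd_mutant_nM"]),
                    kd_wildtype_nM=float(row["kd_wildtype_nM"]),
                    expressed=_flag(row.get("expressed", "T")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_neoantigens(records: Iterable[NeoantigenCandidate], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "mutation_key": c.mutation_key,
            "peptide": c.peptide,
            "hla_allele": c.hla_allele,
            "kd_mutant_nM": repr(c.kd_mutant_nM),
            "kd_wildtype_nM": repr(c.kd_wildtype_nM),
            "expressed": "T" if c.expressed else "F",
        }
        for c in records
    ]
    pd.DataFrame(rows, columns=NEO_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- meta

def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, META_COLUMNS[:3], f"sample metadata {path}")
    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            sid = row["sample_id"]
            if sid in seen:
                raise ValidationError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            records.append(
                SampleMeta(
                    sample_id=sid,
                    patient_id=row["patient_id"],
                    group=row["group"],
                    timepoint=int(_opt(row.get("timepoint")) or 0),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_sample_meta(records: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "group": s.group,
            "timepoint": s.timepoint,
        }
        for s in records
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- catalog

def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a signature catalog CSV (96 channel rows x signature columns).

    The first column must be the channel label; rows may appear in any
    order and are reindexed onto the fixed channel order.  Each signature
    column must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"catalog {path}: need a channel column plus signatures")
    channel_col = df.columns[0]
    labels = set(df[channel_col])
    missing = [c for c in CHANNELS if c not in labels]
    if missing or len(df) != len(CHANNELS):
        raise FormatError(
            f"catalog {path}: expected the 96 channel labels exactly "
            f"(missing {missing[:3]}..., {len(df)} rows)"
        )
    df = df.set_index(channel_col).loc[list(CHANNELS)]
    names = tuple(str(c) for c in df.columns)
    probs = df.to_numpy(dtype=float).T
    sums = probs.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
    if bad.size:
        raise ValidationError(
            f"catalog {path}: signature {names[bad[0]]!r} sums to {sums[bad[0]]:.8f}"
        )
    return SignatureCatalog(names, probs)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        catalog.probs.T, index=list(CHANNELS), columns=list(catalog.names)
    )
    df.index.name = "channel"
    df.to_csv(path, float_format="%.10g")


def load_reference_catalog() -> SignatureCatalog:
    """The packaged COSMIC-v2-style 30-signature reference catalog."""
    ref = resources.files("pairedomics.data").joinpath(_BUNDLED_CATALOG)
    with resources.as_file(ref) as p:
        return read_catalog(p)


# ---------------------------------------------------------------- clusters

CLUSTER_COLUMNS = [
    "patient_id",
    "cluster_id",
    "n_variants",
    "sample_id",
    "prevalence",
    "contains_driver",
]


def read_clusters(path: str | Path) -> list[ClusterRecord]:
    """Read clonal clusters from a long-format TSV (one row per
    cluster x sample prevalence measurement)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, CLUSTER_COLUMNS[:5], f"cluster table {path}")
    grouped: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            key = (row["patient_id"], row["cluster_id"])
            entry = grouped.setdefault(
                key,
                {"n_variants": int(row["n_variants"]), "prev": {}, "driver": False},
            )
            entry["prev"][row["sample_id"]] = float(row["prevalence"])
            entry["driver"] = entry["driver"] or _flag(row.get("contains_driver", "F"))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return [
        ClusterRecord(
            patient_id=pid,
            cluster_id=cid,
            n_variants=e["n_variants"],
            prevalence=e["prev"],
            contains_driver=e["driver"],
        )
        for (pid, cid), e in grouped.items()
    ]


def write_clusters(records: Iterable[ClusterRecord], path: str | Path) -> None:
    rows = []
    for c in records:
        for sid, p in c.prevalence.items():
            rows.append(
                {
                    "patient_id": c.patient_id,
                    "cluster_id": c.cluster_id,
                    "n_variants": c.n_variants,
                    "sample_id": sid,
                    "prevalence": repr(p),
                    "contains_driver": "T" if c.contains_driver else "F",
                }
            )
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)
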