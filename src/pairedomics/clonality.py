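"""Cluster-retention rule and mutation-sharing classes across serial samples."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .records import ClusterRecord, MutationRecord

SHARING_CLASSES = ("common", "shared", "private")


@dataclass(frozen=True, slots=True)
class SharingClass:
    mutation_key: str
    sharing: str                 # common | shared | private
    samples: tuple[str, ...]     # samples carrying the mutation


@dataclass(frozen=True, slots=True)
class SharingSummary:
    classes: list[SharingClass]
    private_counts: dict[str, int]   # per-sample private mutation counts
    mean_private: float
    sd_private: float


def retain_clusters(
    clusters: Sequence[ClusterRecord],
    driver_genes: Iterable[str] | None = None,
    cluster_genes: dict[str, Iterable[str]] | None = None,
) -> list[ClusterRecord]:
    """Apply the retention rule to one patient's clusters.

    A cluster is retained iff it has >= 2 variants, OR it contains a
    driver-gene variant, OR its cellular prevalence is the per-sample
    maximum in more than one sample (ties count every tied cluster as
    top).  Driver content comes from the record's flag or, if
    ``cluster_genes`` maps cluster_id to gene lists, from membership in
    ``driver_genes``.  Idempotent; output preserves input order.
    """
    clusters = list(clusters)
    if not clusters:
        return []
    patients = {c.patient_id for c in clusters}
    if len(patients) > 1:
        raise ValidationError(
            f"retain_clusters expects one patient's clusters, got {sorted(patients)}"
        )
    drivers = set(driver_genes or ())

    # per sample, the max prevalence across clusters reporting that sample
    sample_max: dict[str, float] = {}
    for c in clusters:
        for sid, p in c.prevalence.items():
            if p > sample_max.get(sid, -1.0):
                sample_max[sid] = p

    def has_driver(c: ClusterRecord) -> bool:
        if c.contains_driver:
            return True
        if cluster_genes and c.cluster_id in cluster_genes:
            return bool(drivers.intersection(cluster_genes[c.cluster_id]))
        return False

    retained = []
    for c in clusters:
        n_top = sum(
            1 for sid, p in c.prevalence.items() if p == sample_max.get(sid)
        )
        if c.n_variants >= 2 or has_driver(c) or n_top > 1:
            retained.append(c)
    return retained


def classify_sharing(mutations: Iterable[MutationRecord]) -> SharingSummary:
    """Classify one patient's mutations by presence across serial samples.

    Identity is (chrom, pos, ref, alt).  A mutation present in every
    sample is "common", in more than one but not all is "shared", in
    exactly one is "private".  Requires >= 2 samples for the patient.
    """
    per_key: dict[str, set[str]] = {}
    samples: list[str] = []
    patients = set()
    for m in mutations:
        patients.add(m.patient_id)
        if m.sample_id not in samples:
            samples.append(m.sample_id)
        per_key.setdefault(m.key, set()).add(m.sample_id)
    if len(patients) > 1:
        raise ValidationError(
            f"classify_sharing expects one patient, got {sorted(patients)}"
        )
    if len(samples) < 2:
        raise ValidationError(
            "patient has fewer than 2 samples; skip sharing classification"
        )
    n_samples = len(samples)
    classes = []
    private_counts = {s: 0 for s in samples}
    for key in sorted(per_key):
        carriers = per_key[key]
        if len(carriers) == n_samples:
            cls = "common"
        elif len(carriers) > 1:
            cls = "shared"
        else:
            cls = "private"
            private_counts[next(iter(carriers))] += 1
        classes.append(SharingClass(key, cls, tuple(sorted(carriers))))
    counts = np.array(list(private_counts.values()), dtype=float)
    return SharingSummary(
        classes=classes,
        private_counts=private_counts,
        mean_private=float(counts.mean()),
        sd_private=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
    )
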