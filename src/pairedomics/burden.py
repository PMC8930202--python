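"""Mutation burden, MSI class bands, and neoantigen filtering/rates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .records import NONSYNONYMOUS_CLASSES, MutationRecord, NeoantigenCandidate

DEFAULT_REGION_MB = 34.0
KD_THRESHOLD_NM = 500.0

MSI_CLASSES = ("MSS", "indeterminate", "MSI_high")


@dataclass(frozen=True, slots=True)
class BurdenResult:
    sample_id: str
    n_missense: int
    tmb_per_mb: float
    msi_score: float | None
    msi_class: str | None
    n_nonsynonymous: int
    n_neoantigens: int
    neoantigen_pct: float | None


@dataclass(frozen=True, slots=True)
class RejectedCandidate:
    candidate: NeoantigenCandidate
    reason: str


def tmb(
    mutations: Iterable[MutationRecord], region_mb: float = DEFAULT_REGION_MB
) -> dict[str, float]:
    """Missense mutations per megabase of targeted coding territory."""
    if region_mb <= 0:
        raise ValidationError(f"region_mb must be positive, got {region_mb}")
    counts: dict[str, int] = {}
    for m in mutations:
        counts.setdefault(m.sample_id, 0)
        if m.variant_class == "missense":
            counts[m.sample_id] += 1
    return {sid: n / region_mb for sid, n in counts.items()}


def classify_msi(score: float) -> str:
    """MSI class bands: < 3 stable, 3-10 inclusive indeterminate, > 10 unstable."""
    if score < 0:
        raise ValidationError(f"MSI score must be nonnegative, got {score}")
    if score < 3:
        return "MSS"
    if score <= 10:
        return "indeterminate"
    return "MSI_high"


def filter_neoantigens(
    candidates: Iterable[NeoantigenCandidate],
    kd_threshold: float = KD_THRESHOLD_NM,
    require_expressed: bool = False,
) -> tuple[list[NeoantigenCandidate], list[RejectedCandidate]]:
    """Keep candidates with K_D(mutant) <= threshold and mutant tighter than WT.

    "Greater binding affinity" means strictly lower dissociation constant.
    Returns (kept, rejected-with-reason); the filter is idempotent and
    order-independent.
    """
    kept: list[NeoantigenCandidate] = []
    rejected: list[RejectedCandidate] = []
    for c in candidates:
        if c.kd_mutant_nM > kd_threshold:
            rejected.append(RejectedCandidate(c, "kd_above_threshold"))
        elif not c.kd_mutant_nM < c.kd_wildtype_nM:
            rejected.append(RejectedCandidate(c, "mutant_not_tighter"))
        elif require_expressed and not c.expressed:
            rejected.append(RejectedCandidate(c, "not_expressed"))
        else:
            kept.append(c)
    return kept, rejected


def neoantigen_percentage(
    mutations: Iterable[MutationRecord],
    kept_candidates: Iterable[NeoantigenCandidate],
    sample_id: str | None = None,
) -> float | None:
    """Percentage of a sample's nonsynonymous mutations with a kept peptide.

    100 * (distinct nonsynonymous mutations with >= 1 kept candidate) /
    (nonsynonymous mutations).  Duplicate candidate rows for the same
    mutation do not change the result.  Returns None (with a warning)
    when the sample has no nonsynonymous mutations.
    """
    muts = [m for m in mutations if sample_id is None or m.sample_id == sample_id]
    nonsyn = {m.key for m in muts if m.variant_class in NONSYNONYMOUS_CLASSES}
    if not nonsyn:
        warnings.warn(
            f"sample {sample_id or '<all>'} has no nonsynonymous mutations; "
            "neoantigen percentage undefined",
            stacklevel=2,
        )
        return None
    antigenic_keys = {
        c.mutation_key
        for c in kept_candidates
        if (sample_id is None or c.sample_id == sample_id)
    }
    n_hit = len(nonsyn & antigenic_keys)
    return 100.0 * n_hit / len(nonsyn)


def cluster_neoantigen_fraction(
    mutations: Iterable[MutationRecord],
    kept_candidates: Iterable[NeoantigenCandidate],
) -> tuple[pd.DataFrame, int]:
    """Per-cluster fraction of neoantigenic mutations, ranked descending.

    Returns (table, n_unassigned).  Mutations without a cluster_id are
    counted separately and excluded from the table.
    """
    antigenic = {c.mutation_key for c in kept_candidates}
    per_cluster: dict[str, set[str]] = {}
    unassigned = 0
    for m in mutations:
        if m.cluster_id is None:
            unassigned += 1
            continue
        per_cluster.setdefault(m.cluster_id, set()).add(m.key)
    rows = []
    for cid, keys in per_cluster.items():
        n_neo = len(keys & antigenic)
        rows.append((cid, len(keys), n_neo, n_neo / len(keys)))
    df = pd.DataFrame(
        rows, columns=["cluster_id", "n_mutations", "n_neoantigenic", "fraction"]
    )
    if df.empty:
        warnings.warn("no cluster assignments present", stacklevel=2)
        df["rank"] = []
        return df, unassigned
    df = df.sort_values(
        ["fraction", "cluster_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df, unassigned


def burden_summary(
    mutations: Sequence[MutationRecord],
    candidates: Sequence[NeoantigenCandidate],
    msi_scores: dict[str, float] | None = None,
    region_mb: float = DEFAULT_REGION_MB,
    require_expressed: bool = False,
) -> list[BurdenResult]:
    """Assemble per-sample burden results from mutations and candidates."""
    kept, _ = filter_neoantigens(candidates, require_expressed=require_expressed)
    sample_ids: list[str] = []
    for m in mutations:
        if m.sample_id not in sample_ids:
            sample_ids.append(m.sample_id)
    tmb_by_sample = tmb(mutations, region_mb)
    results = []
    for sid in sample_ids:
        muts = [m for m in mutations if m.sample_id == sid]
        n_missense = sum(1 for m in muts if m.variant_class == "missense")
        nonsyn = {m.key for m in muts if m.variant_class in NONSYNONYMOUS_CLASSES}
        kept_s = [c for c in kept if c.sample_id == sid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = neoantigen_percentage(muts, kept_s, sid)
        msi = msi_scores.get(sid) if msi_scores else None
        results.append(
            BurdenResult(
                sample_id=sid,
                n_missense=n_missense,
                tmb_per_mb=tmb_by_sample[sid],
                msi_score=msi,
                msi_class=classify_msi(msi) if msi is not None else None,
                n_nonsynonymous=len(nonsyn),
                n_neoantigens=len({c.mutation_key for c in kept_s}),
                neoantigen_pct=pct,
            )
        )
    return results
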