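"""96-channel spectra, NMF signature extraction, catalog matching,
exposure refitting, strand-bias testing, and APOBEC enrichment.

Signature extraction uses KL-divergence multiplicative-update NMF with
multiple random restarts per candidate rank; the selected rank is the
largest one whose components are stable (mean matched cosine >= 0.85)
across restarts.  Extracted signatures are normalized to probability
vectors over the fixed channel order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from . import stats
from .channels import (
    CHANNELS,
    N_CHANNELS,
    SUBSTITUTION_CLASSES,
    channel_of,
    substitution_class_of,
)
from .errors import ValidationError
from .records import MutationRecord

DEFAULT_STABILITY_THRESHOLD = 0.85
# Restart stability alone admits inflated ranks on low-rank data, where
# extra components reproducibly split noise along similar directions.  A
# candidate rank must therefore also have well-separated component
# clusters (min silhouette over components, cosine distance) and no
# near-duplicate components within its best solution.
DEFAULT_REDUNDANCY_THRESHOLD = 0.95
DEFAULT_SEPARATION_THRESHOLD = 0.88

# Exome-wide cytosine-centered trinucleotide abundances (counts per 10 kb of
# target territory, both strands pyrimidine-normalized).  Used as the default
# background for the tCw enrichment statistic and by the synthetic generator.
CONTEXT_BACKGROUND_C: dict[str, int] = {
    "ACA": 1210, "ACC": 730, "ACG": 160, "ACT": 950,
    "CCA": 1110, "CCC": 790, "CCG": 180, "CCT": 1060,
    "GCA": 870, "GCC": 810, "GCG": 150, "GCT": 890,
    "TCA": 1010, "TCC": 900, "TCG": 140, "TCT": 1130,
}

_TCW_CONTEXTS = ("TCA", "TCT")


def tcw_background(context_counts: Mapping[str, float] | None = None) -> tuple[float, float]:
    """(ctx_tcw, ctx_c) totals from a C-centered trinucleotide count table."""
    counts = CONTEXT_BACKGROUND_C if context_counts is None else context_counts
    ctx_tcw = sum(counts[c] for c in _TCW_CONTEXTS)
    ctx_c = sum(counts.values())
    return float(ctx_tcw), float(ctx_c)


@dataclass(frozen=True, slots=True)
class SpectrumMatrix:
    """Per-sample 96-channel mutation counts in the fixed channel order."""

    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_samples, 96) nonnegative integers
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), N_CHANNELS):
            raise ValidationError(
                f"counts must be ({len(self.sample_ids)}, {N_CHANNELS}), "
                f"got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValidationError("spectrum counts must be nonnegative")

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]


@dataclass(frozen=True, slots=True)
class SignatureCatalog:
    """Named signatures as probability vectors over the 96 channels."""

    names: tuple[str, ...]
    probs: np.ndarray  # (n_signatures, 96), rows sum to 1

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape != (len(self.names), N_CHANNELS):
            raise ValidationError(
                f"probs must be ({len(self.names)}, {N_CHANNELS}), got {probs.shape}"
            )
        if np.any(probs < 0):
            raise ValidationError("signature probabilities must be nonnegative")
        sums = probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"signature {self.names[bad[0]]!r} sums to {sums[bad[0]]:.8f}, not 1"
            )

    def vector(self, name: str) -> np.ndarray:
        return self.probs[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(tuple(names), self.probs[idx])


@dataclass(frozen=True, slots=True)
class ExposureMatrix:
    """Nonnegative per-sample signature exposures with relative contributions."""

    sample_ids: tuple[str, ...]
    signature_names: tuple[str, ...]
    exposures: np.ndarray  # (n_samples, n_signatures), >= 0
    flags: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exp = np.asarray(self.exposures, dtype=float)
        if exp.shape != (len(self.sample_ids), len(self.signature_names)):
            raise ValidationError("exposures shape does not match labels")
        if np.any(exp < -1e-12):
            raise ValidationError("exposures must be nonnegative")

    @property
    def relative(self) -> np.ndarray:
        """Per-sample contributions normalized to sum to 1 (0 rows stay 0)."""
        totals = self.exposures.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.exposures / totals, 0.0)
        return rel


@dataclass(frozen=True, slots=True)
class ApobecResult:
    sample_id: str
    n_tcw_mut: int
    n_c_mut: int
    ctx_tcw: float
    ctx_c: float
    enrichment: float
    p_value: float
    fdr: float
    label: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class MatchResult:
    name: str
    cosine: float
    tied: bool = False


@dataclass(frozen=True, slots=True)
class ExtractionResult:
    catalog: SignatureCatalog        # extracted signatures S1..Sk
    exposures: ExposureMatrix
    k: int
    stability: dict[int, float]      # candidate rank -> mean matched cosine
    reconstruction_error: dict[int, float]
    redundancy: dict[int, float] | None = None  # rank -> max pairwise cosine
    separation: dict[int, float] | None = None  # rank -> min component silhouette
    low_stability: bool = False


def build_spectrum(
    mutations: Iterable[MutationRecord],
    sample_ids: Sequence[str] | None = None,
) -> SpectrumMatrix:
    """Count SNVs with valid context into a samples x 96 matrix.

    Non-SNVs and SNVs without a context are excluded and tallied in
    ``n_excluded``.  Samples listed in ``sample_ids`` but absent from the
    mutations get zero rows (with a warning).
    """
    mutations = list(mutations)
    if sample_ids is None:
        seen: dict[str, None] = {}
        for m in mutations:
            seen.setdefault(m.sample_id, None)
        sample_ids = list(seen)
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), N_CHANNELS), dtype=np.int64)
    excluded = 0
    for m in mutations:
        if m.sample_id not in index:
            continue
        if not m.is_snv or m.context3 is None:
            excluded += 1
            continue
        ch = channel_of(m.ref_allele, m.alt_allele, m.context3)
        counts[index[m.sample_id], ch] += 1
    for s, i in index.items():
        if counts[i].sum() == 0:
            warnings.warn(f"sample {s} has zero SNVs in spectrum", stacklevel=2)
    return SpectrumMatrix(tuple(sample_ids), counts, n_excluded=excluded)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("cosine undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def match_to_catalog(signature: np.ndarray, catalog: SignatureCatalog) -> MatchResult:
    """Best-cosine match of a 96-vector against a catalog.

    Ties (within 1e-12) are broken by catalog order and flagged.
    """
    sig = np.asarray(signature, dtype=float)
    if np.any(sig < 0):
        raise ValidationError("signature vector must be nonnegative")
    sims = np.array([cosine(sig, row) for row in catalog.probs])
    best = int(np.argmax(sims))
    tied = bool(np.sum(sims >= sims[best] - 1e-12) > 1)
    return MatchResult(catalog.names[best], float(sims[best]), tied)


def _nmf_once(X: np.ndarray, k: int, seed: int, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    # normalize signatures to probability vectors, fold scale into exposures
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    H = H / scale[:, None]
    W = W * scale[None, :]
    return W, H, float(model.reconstruction_err_)


def _cluster_restarts(
    ref_H: np.ndarray, runs: list[np.ndarray]
) -> tuple[float, float]:
    """(stability, min silhouette) of components clustered across restarts.

    Every restart's components are matched to the reference run by
    Hungarian assignment on cosine; stability is the mean matched cosine.
    The silhouette (cosine distance, per component cluster) measures how
    separated the k component clusters are from each other.
    """
    k = ref_H.shape[0]
    clusters: list[list[np.ndarray]] = [[ref_H[i]] for i in range(k)]
    sims = []
    for H in runs:
        cost = np.zeros((k, H.shape[0]))
        for i, u in enumerate(ref_H):
            for j, v in enumerate(H):
                cost[i, j] = -cosine(u, v)
        ri, ci = linear_sum_assignment(cost)
        sims.extend(-cost[ri, ci])
        for i, j in zip(ri, ci):
            clusters[i].append(H[j])
    stability = float(np.mean(sims)) if sims else 1.0
    if k == 1:
        return stability, 1.0
    sil = []
    for a in range(k):
        own = clusters[a]
        within = (
            float(np.mean([1 - cosine(u, v) for i, u in enumerate(own) for v in own[:i]]))
            if len(own) > 1
            else 0.0
        )
        between = min(
            float(np.mean([1 - cosine(u, v) for u in own for v in clusters[o]]))
            for o in range(k)
            if o != a
        )
        denom = max(within, between)
        sil.append((between - within) / denom if denom > 0 else 1.0)
    return stability, float(min(sil))


def extract_signatures(
    spectrum: SpectrumMatrix,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_restarts: int = 20,
    seed: int = 0,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    redundancy_threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
    separation_threshold: float = DEFAULT_SEPARATION_THRESHOLD,
    max_iter: int = 2000,
) -> ExtractionResult:
    """Multi-restart KL-NMF with stability-based rank selection.

    For each candidate rank k the factorization is run ``n_restarts``
    times from random starts; components of every restart are matched by
    cosine (Hungarian assignment) to the lowest-error restart, and the
    mean matched cosine is the stability of k.  A rank is admissible when
    it is stable, its component clusters are well separated (min
    silhouette over components at cosine distance), and its best solution
    contains no near-duplicate components.  The selected rank is the
    largest admissible k; if none is admissible, k = 1 is returned
    flagged.  Deterministic given ``seed``.
    """
    X = np.asarray(spectrum.counts, dtype=float)
    if X.sum() == 0:
        raise ValidationError("spectrum is empty; nothing to factorize")
    max_k = min(X.shape[0], N_CHANNELS)
    ks = sorted({int(k) for k in k_range if 1 <= int(k) <= max_k})
    if not ks:
        raise ValidationError(f"k_range {k_range!r} has no usable rank <= {max_k}")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(ks) * n_restarts, dtype=np.uint32)
    stability: dict[int, float] = {}
    errors: dict[int, float] = {}
    redundancy: dict[int, float] = {}
    separation: dict[int, float] = {}
    best_solutions: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ki, k in enumerate(ks):
        runs = []
        for r in range(n_restarts):
            s = int(child_seeds[ki * n_restarts + r])
            runs.append(_nmf_once(X, k, s, max_iter))
        best_idx = int(np.argmin([e for _, _, e in runs]))
        W_best, H_best, err_best = runs[best_idx]
        others = [H for i, (_, H, _) in enumerate(runs) if i != best_idx]
        stability[k], separation[k] = _cluster_restarts(H_best, others)
        errors[k] = err_best
        redundancy[k] = max(
            (cosine(H_best[i], H_best[j]) for i in range(k) for j in range(i)),
            default=0.0,
        )
        best_solutions[k] = (W_best, H_best)

    stable_ks = [
        k
        for k in ks
        if stability[k] >= stability_threshold
        and redundancy[k] <= redundancy_threshold
        and separation[k] >= separation_threshold
    ]
    low_stability = not stable_ks
    k_sel = max(stable_ks) if stable_ks else min(ks)
    W, H = best_solutions[k_sel]
    names = tuple(f"S{i + 1}" for i in range(k_sel))
    # guard against numerically all-zero components
    H = np.maximum(H, 0.0)
    row_sums = H.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    catalog = SignatureCatalog(names, H / row_sums)
    exposures = ExposureMatrix(spectrum.sample_ids, names, np.maximum(W, 0.0))
    return ExtractionResult(
        catalog, exposures, k_sel, stability, errors, redundancy, separation,
        low_stability,
    )


def refit_exposures(spectrum: SpectrumMatrix, catalog: SignatureCatalog) -> ExposureMatrix:
    """Per-sample nonnegative least squares against a fixed catalog."""
    if len(catalog.names) == 0:
        raise ValidationError("catalog is empty")
    A = catalog.probs.T  # (96, n_signatures)
    exposures = np.zeros((len(spectrum.sample_ids), len(catalog.names)))
    flags: dict[str, tuple[str, ...]] = {}
    for i, sid in enumerate(spectrum.sample_ids):
        row = spectrum.counts[i].astype(float)
        if row.sum() == 0:
            flags[sid] = ("zero_spectrum",)
            continue
        exposures[i], _ = nnls(A, row)
    return ExposureMatrix(spectrum.sample_ids, catalog.names, exposures, flags)


def strand_bias_test(
    mutations: Iterable[MutationRecord], substitution_class: str
) -> tuple[int, int, float]:
    """Exact two-sided binomial test of transcribed vs untranscribed counts.

    Only SNVs of the given pyrimidine substitution class with a known
    transcript strand enter the test; the null is a 50/50 split.
    """
    if substitution_class not in SUBSTITUTION_CLASSES:
        raise ValidationError(f"unknown substitution class {substitution_class!r}")
    n_t = n_u = 0
    for m in mutations:
        if not m.is_snv or m.context3 is None or m.tx_strand == "unknown":
            continue
        ch = channel_of(m.ref_allele, m.alt_allele, m.context3)
        if substitution_class_of(ch) != substitution_class:
            continue
        if m.tx_strand == "transcribed":
            n_t += 1
        else:
            n_u += 1
    n = n_t + n_u
    if n == 0:
        raise ValidationError(
            f"no usable records for class {substitution_class} (known strand required)"
        )
    from scipy.stats import binomtest

    p = binomtest(n_t, n, 0.5).pvalue
    return n_t, n_u, float(p)


def _is_c_mutation(m: MutationRecord) -> bool:
    """C>T or C>G in pyrimidine representation."""
    if not m.is_snv or m.context3 is None:
        return False
    ch = channel_of(m.ref_allele, m.alt_allele, m.context3)
    return substitution_class_of(ch) in ("C>T", "C>G")


def _is_tcw(m: MutationRecord) -> bool:
    from .channels import parse_channel

    ch = channel_of(m.ref_allele, m.alt_allele, m.context3)
    _, _, ctx = parse_channel(CHANNELS[ch])
    return ctx in _TCW_CONTEXTS


def apobec_enrichment(
    mutations: Iterable[MutationRecord],
    context_counts: Mapping[str, float] | None = None,
    enrichment_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> list[ApobecResult]:
    """Per-sample tCw fold enrichment with Fisher test and BH labels.

    enrichment = (n_tcw_mut / n_c_mut) / (ctx_tcw / ctx_c) over C>T/C>G
    mutations at cytosines; the Fisher test is one-sided in the
    enrichment direction on the 2x2 of mutated vs background context
    counts; BH adjustment runs across samples with a defined statistic.
    A sample is labeled APOBEC_high iff enrichment > 2 and FDR < 0.05.
    """
    ctx_tcw, ctx_c = tcw_background(context_counts)
    per_sample: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        per_sample.setdefault(m.sample_id, []).append(m)

    rows = []
    for sid, muts in per_sample.items():
        c_muts = [m for m in muts if _is_c_mutation(m)]
        n_c = len(c_muts)
        n_tcw = sum(1 for m in c_muts if _is_tcw(m))
        rows.append((sid, n_tcw, n_c))

    results: list[ApobecResult] = []
    testable = []
    pvals = []
    for sid, n_tcw, n_c in rows:
        if n_c == 0:
            results.append(
                ApobecResult(
                    sid, n_tcw, n_c, ctx_tcw, ctx_c,
                    np.nan, np.nan, np.nan, "APOBEC_low", ("no_c_mutations",),
                )
            )
            continue
        enr = (n_tcw / n_c) / (ctx_tcw / ctx_c)
        table = [[n_tcw, n_c - n_tcw], [round(ctx_tcw), round(ctx_c - ctx_tcw)]]
        _, p = stats.fisher_exact_2x2(table, alternative="greater")
        testable.append((sid, n_tcw, n_c, enr))
        pvals.append(p)
    if pvals:
        fdrs = stats.bh_fdr(pvals)
        for (sid, n_tcw, n_c, enr), p, q in zip(testable, pvals, fdrs):
            label = (
                "APOBEC_high"
                if enr > enrichment_threshold and q < fdr_threshold
                else "APOBEC_low"
            )
            results.append(
                ApobecResult(sid, n_tcw, n_c, ctx_tcw, ctx_c, enr, p, q, label)
            )
    order = {sid: i for i, (sid, *_rest) in enumerate(rows)}
    results.sort(key=lambda r: order[r.sample_id])
    return results


def apobec_group_genes(
    mutations: Iterable[MutationRecord], labels: Mapping[str, str]
):
    """Per-gene 2x2 Fisher comparison of APOBEC_high vs APOBEC_low samples.

    Returns a pandas DataFrame with mutated/unmutated sample counts per
    label, the two-sided Fisher p, and the BH FDR across genes.  Genes
    mutated in no sample are excluded by construction.
    """
    import pandas as pd

    high = sorted(s for s, l in labels.items() if l == "APOBEC_high")
    low = sorted(s for s, l in labels.items() if l == "APOBEC_low")
    if not high or not low:
        raise ValidationError("need at least one sample per APOBEC label")
    mutated: dict[str, set[str]] = {}
    for m in mutations:
        if m.sample_id in labels:
            mutated.setdefault(m.gene, set()).add(m.sample_id)
    recs = []
    for gene in sorted(mutated):
        carriers = mutated[gene]
        a = sum(1 for s in high if s in carriers)
        b = len(high) - a
        c = sum(1 for s in low if s in carriers)
        d = len(low) - c
        _, p = stats.fisher_exact_2x2([[a, b], [c, d]], alternative="two-sided")
        recs.append((gene, a, b, c, d, p))
    df = pd.DataFrame(
        recs, columns=["gene", "n_high_mut", "n_high_wt", "n_low_mut", "n_low_wt", "p_value"]
    )
    if len(df):
        df["fdr"] = stats.bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr"] = []
    return df
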