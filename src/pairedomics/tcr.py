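"""TCR-beta repertoire summaries: productive filtering, Shannon diversity,
CDR3 length spectra, and clonotype abundance classes.

Clonotype identity is the CDR3 amino-acid sequence; read counts of
identical sequences are merged before any frequency is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .records import Clonotype

#: Default clonotype-frequency classes on (0, 1].
DEFAULT_ABUNDANCE_BINS: tuple[tuple[str, float, float], ...] = (
    ("rare", 0.0, 1e-4),
    ("small", 1e-4, 1e-3),
    ("medium", 1e-3, 1e-2),
    ("large", 1e-2, 1e-1),
    ("hyperexpanded", 1e-1, 1.0),
)


@dataclass(frozen=True, slots=True)
class RepertoireSummary:
    sample_id: str
    n_reads_productive: int
    n_clonotypes: int
    sdi: float
    length_histogram: dict[int, float]
    length_mode: int
    length_mode_tied: bool
    abundance_fractions: dict[str, float]


def productive_filter(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    """Keep clonotypes that are both productive and in-frame."""
    return [c for c in clonotypes if c.productive and c.in_frame]


def _merged_counts(clonotypes: Iterable[Clonotype]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in clonotypes:
        counts[c.cdr3_aa] = counts.get(c.cdr3_aa, 0) + c.read_count
    return counts


def clonotype_frequencies(
    clonotypes: Iterable[Clonotype], weighting: str = "reads"
) -> dict[str, float]:
    """CDR3-keyed frequencies, read-weighted or uniform per clonotype."""
    counts = _merged_counts(clonotypes)
    if not counts:
        raise ValidationError("no clonotypes; frequencies undefined")
    if weighting == "reads":
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}
    if weighting == "clonotypes":
        n = len(counts)
        return {k: 1.0 / n for k in counts}
    raise ValidationError(f"unknown weighting {weighting!r}")


def shannon_diversity(
    clonotypes: Iterable[Clonotype], weighting: str = "reads"
) -> float:
    """-sum p_i ln p_i over merged clonotype frequencies (natural log)."""
    freqs = clonotype_frequencies(clonotypes, weighting)
    return -sum(p * math.log(p) for p in freqs.values() if p > 0)


def length_distribution(
    clonotypes: Iterable[Clonotype], weighting: str = "reads"
) -> tuple[dict[int, float], int, bool]:
    """Histogram over CDR3 amino-acid lengths with its mode.

    Weighting "reads" weighs each clonotype by read count, "clonotypes"
    uniformly.  Returns (histogram of fractions, mode length, tie flag);
    ties resolve to the smallest length.
    """
    counts = _merged_counts(clonotypes)
    if not counts:
        raise ValidationError("no clonotypes; length distribution undefined")
    hist: dict[int, float] = {}
    for aa, n in counts.items():
        w = float(n) if weighting == "reads" else 1.0
        if weighting not in ("reads", "clonotypes"):
            raise ValidationError(f"unknown weighting {weighting!r}")
        hist[len(aa)] = hist.get(len(aa), 0.0) + w
    total = sum(hist.values())
    hist = {k: v / total for k, v in sorted(hist.items())}
    peak = max(hist.values())
    modes = [k for k, v in hist.items() if v == peak]
    return hist, min(modes), len(modes) > 1


def abundance_classes(
    clonotypes: Iterable[Clonotype],
    bins: Sequence[tuple[str, float, float]] = DEFAULT_ABUNDANCE_BINS,
) -> dict[str, float]:
    """Fraction of unique clonotypes per frequency class.

    Classes are half-open on the left: a clonotype with frequency f falls
    in (lo, hi] of the first matching bin.  Bin edges must be strictly
    increasing and tile (0, 1].
    """
    edges = [b[1] for b in bins] + [bins[-1][2]]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing")
    if bins[0][1] != 0.0 or bins[-1][2] != 1.0:
        raise ValidationError("bins must tile (0, 1]")
    freqs = clonotype_frequencies(clonotypes, weighting="reads")
    out = {name: 0 for name, _, _ in bins}
    for f in freqs.values():
        if not 0.0 < f <= 1.0:
            raise ValidationError(f"frequency {f} outside (0, 1]")
        for name, lo, hi in bins:
            if lo < f <= hi:
                out[name] += 1
                break
    n = len(freqs)
    return {name: c / n for name, c in out.items()}


def repertoire_summary(
    clonotypes: Iterable[Clonotype],
    sample_id: str | None = None,
    weighting: str = "reads",
) -> RepertoireSummary:
    """Full per-sample summary on the productive, in-frame subset."""
    clons = list(clonotypes)
    if sample_id is not None:
        clons = [c for c in clons if c.sample_id == sample_id]
    else:
        ids = {c.sample_id for c in clons}
        if len(ids) > 1:
            raise ValidationError(f"multiple samples present: {sorted(ids)}")
        sample_id = next(iter(ids)) if ids else ""
    productive = productive_filter(clons)
    if not productive:
        raise ValidationError(f"sample {sample_id}: no productive in-frame clonotypes")
    counts = _merged_counts(productive)
    hist, mode, tied = length_distribution(productive, weighting)
    return RepertoireSummary(
        sample_id=sample_id,
        n_reads_productive=sum(counts.values()),
        n_clonotypes=len(counts),
        sdi=shannon_diversity(productive, weighting),
        length_histogram=hist,
        length_mode=mode,
        length_mode_tied=tied,
        abundance_fractions=abundance_classes(productive),
    )
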