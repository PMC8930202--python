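"""Chromosomal-instability scoring from copy-number segments.

Tumor segments are referenced against a panel of controls on a fixed
genomic bin grid: per bin, the control mean and SD of the log2 value
define a Z-score, and each tumor segment's V is the length-weighted mean
Z over the bins it covers.  The CIN score is the sum of V_k * L_k over a
sample's segments; "absolute" mode sums |V_k| * L_k, avoiding the signed
cancellation of the literal formula.  A sample is flagged elevated when
its score strictly exceeds mean(controls) + 3 * SD(controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .records import SegmentRecord

DEFAULT_BIN_SIZE = 1_000_000
SD_FLOOR = 1e-6

MODES = ("as_printed", "absolute")


@dataclass(frozen=True, slots=True)
class CinResult:
    sample_id: str
    cin_score: float
    n_segments: int
    mode: str
    threshold: float | None = None
    elevated: bool | None = None


def _bins_of(seg: SegmentRecord, bin_size: int) -> list[tuple[str, int, int]]:
    """(chrom, bin index, overlap bp) for every bin the segment touches."""
    first = (seg.start - 1) // bin_size
    last = (seg.end - 1) // bin_size
    out = []
    for b in range(first, last + 1):
        lo = max(seg.start, b * bin_size + 1)
        hi = min(seg.end, (b + 1) * bin_size)
        out.append((seg.chrom, b, hi - lo + 1))
    return out


def _sample_bin_values(
    segments: Iterable[SegmentRecord], bin_size: int
) -> dict[tuple[str, int], float]:
    """Length-weighted mean log2 per bin for one sample."""
    weight: dict[tuple[str, int], float] = {}
    total: dict[tuple[str, int], float] = {}
    for seg in segments:
        for chrom, b, bp in _bins_of(seg, bin_size):
            key = (chrom, b)
            weight[key] = weight.get(key, 0.0) + bp
            total[key] = total.get(key, 0.0) + bp * seg.log2_value
    return {k: total[k] / weight[k] for k in weight}


def segment_zscores(
    tumor_segments: Iterable[SegmentRecord],
    control_segments: Iterable[SegmentRecord],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[SegmentRecord]:
    """Attach control-referenced Z-scores to tumor segments.

    Controls (>= 2 samples) define per-bin mean and SD (n-1 denominator)
    of the log2 value; an SD floor of 1e-6 guards constant bins.  Each
    tumor segment's Z is the length-weighted mean of (value - mean)/SD
    over the control-covered bins it overlaps.
    """
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    controls: dict[str, list[SegmentRecord]] = {}
    for seg in control_segments:
        controls.setdefault(seg.sample_id, []).append(seg)
    if len(controls) < 2:
        raise ValidationError(
            f"need >= 2 control samples for SD, got {len(controls)}"
        )
    per_control = [_sample_bin_values(segs, bin_size) for segs in controls.values()]
    all_bins = sorted(set().union(*per_control))
    mean: dict[tuple[str, int], float] = {}
    sd: dict[tuple[str, int], float] = {}
    floored = 0
    for key in all_bins:
        vals = [bv[key] for bv in per_control if key in bv]
        if len(vals) < 2:
            continue  # SD undefined from one control; bin unusable
        mean[key] = float(np.mean(vals))
        s = float(np.std(vals, ddof=1))
        if s < SD_FLOOR:
            s = SD_FLOOR
            floored += 1
        sd[key] = s
    if floored:
        warnings.warn(f"{floored} control bins hit the SD floor", stacklevel=2)
    if not mean:
        raise ValidationError("no genomic bin is covered by >= 2 controls")

    out: list[SegmentRecord] = []
    for seg in tumor_segments:
        zw = 0.0
        w = 0.0
        for chrom, b, bp in _bins_of(seg, bin_size):
            key = (chrom, b)
            if key not in mean:
                continue
            zw += bp * (seg.log2_value - mean[key]) / sd[key]
            w += bp
        if w == 0:
            raise ValidationError(
                f"segment {seg.sample_id} {seg.chrom}:{seg.start}-{seg.end} "
                "overlaps no control-covered bin"
            )
        out.append(
            SegmentRecord(
                seg.sample_id, seg.chrom, seg.start, seg.end,
                seg.log2_value, zscore=zw / w,
            )
        )
    return out


def cin_score(
    segments: Sequence[SegmentRecord], mode: str = "as_printed"
) -> tuple[float, int]:
    """Sum of V_k * L_k (or |V_k| * L_k in absolute mode) over segments."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    score = 0.0
    n = 0
    for seg in segments:
        if seg.zscore is None:
            raise ValidationError(
                f"segment {seg.sample_id} {seg.chrom}:{seg.start}-{seg.end} "
                "has no zscore"
            )
        v = abs(seg.zscore) if mode == "absolute" else seg.zscore
        score += v * seg.length_bp
        n += 1
    return score, n


def cin_threshold(control_scores: Sequence[float]) -> float:
    """Elevation threshold: mean + 3 * sample SD (n-1) of control scores."""
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 2:
        raise ValidationError(f"need >= 2 control scores, got {scores.size}")
    return float(scores.mean() + 3.0 * scores.std(ddof=1))


def flag_elevated(scores: Mapping[str, float], threshold: float) -> dict[str, bool]:
    """Strict-greater elevation flags per sample."""
    return {sid: score > threshold for sid, score in scores.items()}


def score_cohort(
    tumor_segments: Iterable[SegmentRecord],
    control_segments: Iterable[SegmentRecord],
    bin_size: int = DEFAULT_BIN_SIZE,
    mode: str = "as_printed",
) -> list[CinResult]:
    """End-to-end CIN scoring: Z-scores, per-sample scores, threshold, flags.

    Control segments are both the Z-score reference and, scored against
    the same reference, the source of the elevation threshold.
    """
    control_list = list(control_segments)
    tumor_list = list(tumor_segments)
    scored_tumor = segment_zscores(tumor_list, control_list, bin_size)
    scored_controls = segment_zscores(control_list, control_list, bin_size)

    def per_sample(segs: Iterable[SegmentRecord]) -> dict[str, list[SegmentRecord]]:
        d: dict[str, list[SegmentRecord]] = {}
        for s in segs:
            d.setdefault(s.sample_id, []).append(s)
        return d

    control_scores = {
        sid: cin_score(segs, mode)[0] for sid, segs in per_sample(scored_controls).items()
    }
    threshold = cin_threshold(list(control_scores.values()))
    results = []
    for sid, segs in per_sample(scored_tumor).items():
        score, n = cin_score(segs, mode)
        results.append(
            CinResult(sid, score, n, mode, threshold, score > threshold)
        )
    return results
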