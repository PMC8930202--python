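"""The fixed 96-channel single-base-substitution encoding.

Channel order is the conventional one: the six pyrimidine substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), and within each class the 16
flanking-base contexts ordered alphabetically by 5' base then 3' base.
A purine-reference mutation is reverse-complemented onto the strand
carrying the pyrimidine before channel assignment, so every (ref, alt,
context) triple maps onto exactly one of the 96 channels.
"""

from __future__ import annotations

from .errors import ValidationError

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Channel labels in the fixed order, e.g. "A[C>A]A".
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

N_CHANNELS = len(CHANNELS)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValidationError(f"ambiguous or invalid base in {seq!r}") from exc


def _check_base(b: str, what: str) -> None:
    if len(b) != 1 or b not in BASES:
        raise ValidationError(f"{what} must be one of A/C/G/T, got {b!r}")


def channel_of(ref: str, alt: str, context3: str) -> int:
    """Map a single-base substitution to its channel index.

    ``context3`` is the reference plus-strand trinucleotide centered on the
    mutated base.  Purine-reference mutations are reverse-complemented so
    the central base of the reported channel is C or T.

    Raises
    ------
    ValidationError
        If a base is ambiguous, ``ref == alt``, or the context is not a
        3-mer centered on ``ref``.
    """
    _check_base(ref, "ref")
    _check_base(alt, "alt")
    if ref == alt:
        raise ValidationError("ref and alt must differ")
    if len(context3) != 3 or any(b not in BASES for b in context3):
        raise ValidationError(f"context3 must be an ACGT 3-mer, got {context3!r}")
    if context3[1] != ref:
        raise ValidationError(
            f"context3 {context3!r} is not centered on ref {ref!r}"
        )
    if ref not in PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context3 = revcomp(context3)
    return _CHANNEL_INDEX[f"{context3[0]}[{ref}>{alt}]{context3[2]}"]


def channel_label(index: int) -> str:
    """Label ("A[C>A]A") for a channel index."""
    return CHANNELS[index]


def parse_channel(label: str) -> tuple[str, str, str]:
    """Inverse of :func:`channel_label`: returns (ref, alt, context3)."""
    if label not in _CHANNEL_INDEX:
        raise ValidationError(f"unknown channel label {label!r}")
    five, rest = label[0], label[2:5]
    ref, alt = rest[0], rest[2]
    three = label[-1]
    return ref, alt, f"{five}{ref}{three}"


def substitution_class_of(index: int) -> str:
    """Pyrimidine substitution class ("C>A" ... "T>G") of a channel index."""
    return SUBSTITUTION_CLASSES[index // 16]
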