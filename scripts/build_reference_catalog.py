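"""Regenerate the packaged 30-signature reference catalog CSV.

The catalog is COSMIC-v2-*style*: 30 named probability vectors over the
96 channels.  Signatures 1, 2, 13, and 22 are hand-shaped to carry the
etiologies the pipeline's analyses key on (CpG deamination, APOBEC C>T at
tCw, APOBEC C>G at tCw, and the aristolochic-acid T>A pattern peaking at
the T[T>A]G channel); the remaining 26 are deterministic pseudo-random
sparse vectors providing realistic matching competition.  Run from the
repository root:

    python scripts/build_reference_catalog.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pairedomics.channels import CHANNELS  # noqa: E402
from pairedomics.io import write_catalog  # noqa: E402
from pairedomics.signatures import SignatureCatalog  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src/pairedomics/data/reference_signatures.csv"

IDX = {label: i for i, label in enumerate(CHANNELS)}


def peaked(peaks: dict[str, float], background: float) -> np.ndarray:
    """Probability vector with named channel peaks plus uniform background."""
    v = np.full(96, background / 96.0)
    for label, mass in peaks.items():
        v[IDX[label]] += mass
    return v / v.sum()


def class_spread(cls: str, mass: float) -> dict[str, float]:
    """Spread mass uniformly over the 16 channels of a substitution class."""
    labels = [c for c in CHANNELS if f"[{cls}]" in c]
    return {c: mass / len(labels) for c in labels}


def main() -> None:
    rng = np.random.default_rng(20220303)
    sigs: dict[str, np.ndarray] = {}

    # 1: 5-methylcytosine deamination — C>T at NpCpG
    sigs["1"] = peaked(
        {
            "A[C>T]G": 0.22, "C[C>T]G": 0.19, "G[C>T]G": 0.17, "T[C>T]G": 0.20,
            **class_spread("C>T", 0.18),
        },
        background=0.04,
    )
    # 2: APOBEC — C>T at tCw
    sigs["2"] = peaked(
        {"T[C>T]A": 0.40, "T[C>T]T": 0.36, "T[C>T]G": 0.11, "T[C>T]C": 0.09},
        background=0.04,
    )
    # 13: APOBEC — C>G at tCw
    sigs["13"] = peaked(
        {"T[C>G]A": 0.43, "T[C>G]T": 0.41, "T[C>G]C": 0.11},
        background=0.05,
    )
    # 22: aristolochic acid — T>A, strongest at the T[T>A]G channel
    sigs["22"] = peaked(
        {"T[T>A]G": 0.38, "C[T>A]G": 0.15, **class_spread("T>A", 0.42)},
        background=0.05,
    )

    for i in range(1, 31):
        name = str(i)
        if name in sigs:
            continue
        # sparse pseudo-random signature: a handful of peaks over one or
        # two substitution classes plus a soft background
        raw = rng.dirichlet(np.full(96, 0.08))
        v = raw + 0.04 / 96.0
        sigs[name] = v / v.sum()

    names = tuple(str(i) for i in range(1, 31))
    probs = np.vstack([sigs[n] for n in names])
    catalog = SignatureCatalog(names, probs)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_catalog(catalog, OUT)
    print(f"wrote {OUT} ({probs.shape[0]} signatures x {probs.shape[1]} channels)")


if __name__ == "__main__":
    main()
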