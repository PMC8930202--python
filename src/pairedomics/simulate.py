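"""Seeded synthetic cohort generator.

Produces a paired primary/relapsed cohort plus healthy controls with the
statistical structure the downstream analyses assume: mutation catalogs
drawn from group-specific signature mixtures with configurable
transcriptional strand bias, control-referenced CNV segments with
group-shifted aberrations, neoantigen candidate tables with group-shifted
passing rates, Zipf-distributed clonotype tables with group-shifted
clonality and CDR3 length modes, and an exponential survival table.

One global seed fans out deterministically to per-table child streams, so
identical seeds give identical cohorts while individual tables can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .channels import CHANNELS, parse_channel
from .errors import ConfigError
from .records import (
    Clonotype,
    MutationRecord,
    NeoantigenCandidate,
    SampleMeta,
    SegmentRecord,
)
from .signatures import CONTEXT_BACKGROUND_C, SignatureCatalog

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_GENES = [
    "TP53", "FDFT1", "KRT4", "TTN", "AHNAK2", "CDKN1A", "ARID1A", "KMT2D",
    "HAUS5", "STOX1", "PIK3CA", "MTOR", "AKAP13", "FGFR3", "STAG2", "E2F3",
    "PPARG", "CDKN2A", "GFRA2", "DOK2", "EXOSC10", "DGAT2L6", "CRLS1", "DRD5",
    "ERBB2", "KDM6A", "RB1", "ATM", "EP300", "CREBBP",
]
DRIVER_GENES = ("TP53", "PIK3CA", "MTOR", "FGFR3", "CDKN1A", "ARID1A")

#: Genome model used for CNV segments: chromosome -> length in bp.
GENOME = {f"chr{i}": 50_000_000 for i in range(1, 23)}
SEGMENT_BP = 5_000_000

_SNV_CLASS_PROBS = (
    ("missense", 0.70),
    ("silent", 0.18),
    ("nonsense", 0.07),
    ("splice", 0.05),
)


@dataclass(frozen=True, slots=True)
class CnvConfig:
    n_aberrant: int = 4
    mean_shift: float = 0.8
    noise_sd: float = 0.1


@dataclass(frozen=True, slots=True)
class NeoConfig:
    candidate_prob: float = 0.7     # nonsynonymous mutation yields a candidate
    pass_prob: float = 0.3          # candidate passes both filters
    kd_log_mean: float = 5.0        # ln-scale location of passing mutant K_D
    kd_log_sd: float = 0.8


@dataclass(frozen=True, slots=True)
class TcrConfig:
    zipf_a: float = 1.1
    n_clones: int = 1500
    reads: int = 30_000
    len_mode: int = 15
    len_sd: float = 1.6
    nonproductive_frac: float = 0.03


@dataclass(frozen=True, slots=True)
class CohortConfig:
    n_patients: int = 8
    relapse_fraction: float = 0.5
    mutation_mean: float = 150.0
    mutation_dispersion: float = 10.0
    group_exposures: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "primary_no_relapse": {"2": 0.65, "1": 0.35},
            "primary_with_relapse": {"2": 0.70, "1": 0.30},
            "relapsed": {"13": 0.45, "22": 0.35, "1": 0.20},
        }
    )
    strand_bias: Mapping[str, float] = field(
        default_factory=lambda: {"T>A": 0.75}
    )
    unknown_strand_frac: float = 0.0
    shared_fraction: float = 0.3    # fraction of primary mutations kept at relapse
    cnv: Mapping[str, CnvConfig] = field(
        default_factory=lambda: {
            "primary_no_relapse": CnvConfig(n_aberrant=3, mean_shift=0.6),
            "primary_with_relapse": CnvConfig(n_aberrant=4, mean_shift=0.7),
            "relapsed": CnvConfig(n_aberrant=10, mean_shift=1.0),
        }
    )
    n_controls: int = 10
    neo: Mapping[str, NeoConfig] = field(
        default_factory=lambda: {
            "primary_no_relapse": NeoConfig(pass_prob=0.30),
            "primary_with_relapse": NeoConfig(pass_prob=0.30),
            "relapsed": NeoConfig(pass_prob=0.15),
        }
    )
    tcr: Mapping[str, TcrConfig] = field(
        default_factory=lambda: {
            "primary_no_relapse": TcrConfig(zipf_a=1.05, len_mode=15),
            "primary_with_relapse": TcrConfig(zipf_a=1.10, len_mode=15),
            "relapsed": TcrConfig(zipf_a=1.45, len_mode=14),
        }
    )
    relapse_hazard: float = 0.03    # events/month for relapse patients
    no_relapse_hazard: float = 0.005
    censor_months: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ConfigError("relapse_fraction must be in [0, 1]")
        if self.mutation_mean <= 0:
            raise ConfigError("zero mutations requested; refusing to emit empty files")
        for group, exp in self.group_exposures.items():
            total = sum(exp.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"exposures for {group} sum to {total!r}, expected 1"
                )
            if any(w < 0 for w in exp.values()):
                raise ConfigError(f"negative exposure weight in {group}")
        for cls, p in self.strand_bias.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"strand_bias[{cls}] outside [0, 1]")
        for group, t in self.tcr.items():
            if t.n_clones < 1:
                raise ConfigError(f"zero clones requested for {group}")


@dataclass(slots=True)
class Cohort:
    meta: list[SampleMeta]
    mutations: list[MutationRecord]
    segments: list[SegmentRecord]          # tumor samples
    control_segments: list[SegmentRecord]  # healthy controls
    neoantigens: list[NeoantigenCandidate]
    clonotypes: list[Clonotype]
    survival: list[dict]                   # patient_id, time_months, event, group
    config: CohortConfig


def _child_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def mixture_vector(
    catalog: SignatureCatalog, weights: Mapping[str, float]
) -> np.ndarray:
    """Channel distribution of a signature mixture."""
    v = np.zeros(96)
    for name, w in weights.items():
        v += w * catalog.vector(str(name))
    return v / v.sum()


def sample_channel_mutations(
    rng: np.random.Generator,
    channel_probs: np.ndarray,
    n: int,
    sample_id: str,
    patient_id: str,
    timepoint_label: str,
    strand_bias: Mapping[str, float],
    unknown_strand_frac: float = 0.0,
    pos_offset: int = 0,
) -> list[MutationRecord]:
    """Draw n SNVs from a 96-channel distribution.

    Contexts are the literal channel trinucleotides (plus-strand pyrimidine
    representation); loci are synthetic but unique within the sample.
    """
    if n < 1:
        raise ConfigError("zero mutations requested")
    channels = rng.choice(96, size=n, p=channel_probs)
    class_names = [c for c, _ in _SNV_CLASS_PROBS]
    class_p = np.array([p for _, p in _SNV_CLASS_PROBS])
    class_p = class_p / class_p.sum()
    classes = rng.choice(len(class_names), size=n, p=class_p)
    chroms = rng.choice(list(GENOME), size=n)
    records = []
    for j in range(n):
        ref, alt, ctx = parse_channel(CHANNELS[channels[j]])
        sub = f"{ref}>{alt}"
        p_untx = strand_bias.get(sub, 0.5)
        if unknown_strand_frac and rng.random() < unknown_strand_frac:
            strand = "unknown"
        else:
            strand = "untranscribed" if rng.random() < p_untx else "transcribed"
        records.append(
            MutationRecord(
                sample_id=sample_id,
                patient_id=patient_id,
                timepoint_label=timepoint_label,
                chrom=str(chroms[j]),
                pos=pos_offset + j * 10 + int(rng.integers(1, 10)),
                ref_allele=ref,
                alt_allele=alt,
                variant_class=class_names[classes[j]],
                gene=str(rng.choice(_GENES)),
                context3=ctx,
                tx_strand=strand,
                cluster_id=f"C{int(rng.integers(1, 4))}",
            )
        )
    return records


def simulate_context_mutations(
    n: int,
    tcw_fold: float,
    rng: np.random.Generator,
    sample_id: str = "S1",
    context_counts: Mapping[str, float] | None = None,
) -> list[MutationRecord]:
    """Simulate C>T/C>G mutations whose contexts follow the background
    trinucleotide abundances with tCw sites upweighted ``tcw_fold``-fold.

    Used to exercise the tCw enrichment statistic against generator truth.
    """
    counts = dict(CONTEXT_BACKGROUND_C if context_counts is None else context_counts)
    contexts = sorted(counts)
    weights = np.array(
        [counts[c] * (tcw_fold if c in ("TCA", "TCT") else 1.0) for c in contexts],
        dtype=float,
    )
    weights /= weights.sum()
    picks = rng.choice(len(contexts), size=n, p=weights)
    alts = rng.choice(["T", "G"], size=n)
    records = []
    for j in range(n):
        ctx = contexts[picks[j]]
        records.append(
            MutationRecord(
                sample_id=sample_id,
                patient_id="P1",
                timepoint_label="s0",
                chrom="chr1",
                pos=j * 10 + 1,
                ref_allele="C",
                alt_allele=str(alts[j]),
                variant_class="missense",
                gene="TP53",
                context3=ctx,
            )
        )
    return records


def _baseline_segments(
    rng: np.random.Generator, sample_id: str, noise_sd: float
) -> list[SegmentRecord]:
    segs = []
    for chrom, length in GENOME.items():
        for start in range(1, length + 1, SEGMENT_BP):
            end = min(start + SEGMENT_BP - 1, length)
            value = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            segs.append(SegmentRecord(sample_id, chrom, start, end, value))
    return segs


def _aberrate(
    rng: np.random.Generator, segs: list[SegmentRecord], cnv: CnvConfig
) -> list[SegmentRecord]:
    n = min(cnv.n_aberrant, len(segs))
    idx = rng.choice(len(segs), size=n, replace=False)
    out = list(segs)
    for i in idx:
        s = out[i]
        shift = cnv.mean_shift * (1 if rng.random() < 0.5 else -1)
        shift *= float(rng.uniform(0.8, 1.2))
        out[i] = SegmentRecord(
            s.sample_id, s.chrom, s.start, s.end, s.log2_value + shift
        )
    return out


def simulate_controls(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[SegmentRecord]:
    """Aberration-free control segment sets (noise around the diploid baseline)."""
    if config.n_controls < 2:
        raise ConfigError("need >= 2 controls (SD undefined below that)")
    if rng is None:
        rng = _child_rngs(config.seed, ("controls",))["controls"]
    noise = next(iter(config.cnv.values())).noise_sd if config.cnv else 0.1
    segs: list[SegmentRecord] = []
    for i in range(config.n_controls):
        segs.extend(_baseline_segments(rng, f"CTRL{i + 1}", noise))
    return segs


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(9, 12))
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def _simulate_neoantigens(
    rng: np.random.Generator,
    mutations: list[MutationRecord],
    neo: NeoConfig,
) -> tuple[list[NeoantigenCandidate], set[str]]:
    from .records import NONSYNONYMOUS_CLASSES

    hlas = ["HLA-A*02:01", "HLA-A*11:01", "HLA-B*07:02", "HLA-C*07:01"]
    candidates = []
    antigenic: set[str] = set()
    for m in mutations:
        if m.variant_class not in NONSYNONYMOUS_CLASSES:
            continue
        if rng.random() >= neo.candidate_prob:
            continue
        passing = rng.random() < neo.pass_prob
        if passing:
            kd_mut = float(
                min(499.0, np.exp(rng.normal(neo.kd_log_mean, neo.kd_log_sd)))
            )
            kd_wt = kd_mut * float(rng.uniform(1.5, 10.0))
            antigenic.add(m.key)
        elif rng.random() < 0.5:
            kd_mut = float(rng.uniform(501.0, 5000.0))  # fails the 500 nM rule
            kd_wt = kd_mut * float(rng.uniform(1.5, 5.0))
        else:
            kd_mut = float(rng.uniform(50.0, 499.0))    # fails mutant-tighter
            kd_wt = kd_mut * float(rng.uniform(0.1, 1.0))
        candidates.append(
            NeoantigenCandidate(
                sample_id=m.sample_id,
                mutation_key=m.key,
                peptide=_random_peptide(rng),
                hla_allele=str(rng.choice(hlas)),
                kd_mutant_nM=kd_mut,
                kd_wildtype_nM=kd_wt,
                expressed=bool(rng.random() < 0.9),
            )
        )
    return candidates, antigenic


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    middle = "".join(rng.choice(list(_AMINO_ACIDS), size=max(0, length - 2)))
    return ("C" + middle + "F")[:length]


def _simulate_clonotypes(
    rng: np.random.Generator, sample_id: str, tcr: TcrConfig
) -> list[Clonotype]:
    if tcr.n_clones < 1:
        raise ConfigError("zero clones requested")
    ranks = np.arange(1, tcr.n_clones + 1, dtype=float)
    probs = ranks ** (-tcr.zipf_a)
    probs /= probs.sum()
    reads = rng.multinomial(tcr.reads, probs)
    lengths = np.clip(
        np.rint(rng.normal(tcr.len_mode, tcr.len_sd, size=tcr.n_clones)), 8, 25
    ).astype(int)
    codons = ["TGT", "GCA", "AGT", "GGA", "ACC", "TTC"]
    clons = []
    seen: set[str] = set()
    for i in range(tcr.n_clones):
        if reads[i] == 0:
            continue
        aa = _random_cdr3(rng, lengths[i])
        while aa in seen:
            aa = _random_cdr3(rng, lengths[i])
        seen.add(aa)
        productive = rng.random() >= tcr.nonproductive_frac
        clons.append(
            Clonotype(
                sample_id=sample_id,
                cdr3_aa=aa,
                cdr3_nt="".join(rng.choice(codons, size=len(aa))),
                v_gene=f"TRBV{int(rng.integers(2, 30))}",
                j_gene=f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}",
                read_count=int(reads[i]),
                productive=bool(productive),
                in_frame=bool(productive or rng.random() < 0.5),
            )
        )
    return clons


def simulate_cohort(
    config: CohortConfig, catalog: SignatureCatalog | None = None
) -> Cohort:
    """Generate the full cohort bundle.  Deterministic given ``config.seed``."""
    config.validate()
    if catalog is None:
        from .io import load_reference_catalog

        catalog = load_reference_catalog()
    rngs = _child_rngs(
        config.seed,
        ("meta", "mutations", "segments", "controls", "neo", "tcr", "survival"),
    )

    n_relapse = int(round(config.n_patients * config.relapse_fraction))
    meta: list[SampleMeta] = []
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i + 1}"
        relapses = i < n_relapse
        group0 = "primary_with_relapse" if relapses else "primary_no_relapse"
        meta.append(SampleMeta(f"{pid}_s0", pid, group0, 0))
        if relapses:
            meta.append(SampleMeta(f"{pid}_s1", pid, "relapsed", 1))
        patients.append((pid, relapses))

    group_of = {m.sample_id: m.group for m in meta}
    mixtures = {
        g: mixture_vector(catalog, w) for g, w in config.group_exposures.items()
    }

    rng_m = rngs["mutations"]
    nb_n = config.mutation_dispersion
    nb_p = nb_n / (nb_n + config.mutation_mean)
    mutations: list[MutationRecord] = []
    per_sample_muts: dict[str, list[MutationRecord]] = {}
    for m in meta:
        n_mut = max(1, int(rng_m.negative_binomial(nb_n, nb_p)))
        recs = sample_channel_mutations(
            rng_m,
            mixtures[m.group],
            n_mut,
            m.sample_id,
            m.patient_id,
            f"s{m.timepoint}",
            config.strand_bias,
            config.unknown_strand_frac,
            pos_offset=1 if m.timepoint == 0 else 10_000_000,
        )
        if m.timepoint > 0:
            # carry over a trunk of the primary's mutations (shared/common)
            primary = per_sample_muts[f"{m.patient_id}_s0"]
            n_shared = int(round(config.shared_fraction * len(primary)))
            if n_shared:
                picked = rng_m.choice(len(primary), size=n_shared, replace=False)
                carried = [
                    dataclasses.replace(
                        primary[k],
                        sample_id=m.sample_id,
                        timepoint_label=f"s{m.timepoint}",
                    )
                    for k in sorted(picked)
                ]
                recs = carried + recs
        per_sample_muts[m.sample_id] = recs
        mutations.extend(recs)

    rng_s = rngs["segments"]
    segments: list[SegmentRecord] = []
    for m in meta:
        cnv = config.cnv[m.group]
        base = _baseline_segments(rng_s, m.sample_id, cnv.noise_sd)
        segments.extend(_aberrate(rng_s, base, cnv))
    control_segments = simulate_controls(config, rngs["controls"])

    rng_n = rngs["neo"]
    neoantigens: list[NeoantigenCandidate] = []
    antigenic_keys: dict[str, set[str]] = {}
    for m in meta:
        cands, antigenic = _simulate_neoantigens(
            rng_n, per_sample_muts[m.sample_id], config.neo[m.group]
        )
        neoantigens.extend(cands)
        antigenic_keys[m.sample_id] = antigenic
    mutations = [
        dataclasses.replace(
            mu, is_neoantigenic=mu.key in antigenic_keys[mu.sample_id]
        )
        for mu in mutations
    ]

    rng_t = rngs["tcr"]
    clonotypes: list[Clonotype] = []
    for m in meta:
        clonotypes.extend(
            _simulate_clonotypes(rng_t, m.sample_id, config.tcr[m.group])
        )

    rng_v = rngs["survival"]
    survival = []
    for pid, relapses in patients:
        hazard = config.relapse_hazard if relapses else config.no_relapse_hazard
        t = float(rng_v.exponential(1.0 / hazard))
        event = t <= config.censor_months
        survival.append(
            {
                "patient_id": pid,
                "time_months": round(min(t, config.censor_months), 3),
                "event": int(event),
                "group": "relapse" if relapses else "no_relapse",
            }
        )

    return Cohort(
        meta=meta,
        mutations=mutations,
        segments=segments,
        control_segments=control_segments,
        neoantigens=neoantigens,
        clonotypes=clonotypes,
        survival=survival,
        config=config,
    )
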