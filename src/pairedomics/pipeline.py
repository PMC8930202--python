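"""Config-driven end-to-end orchestration.

``run_pipeline`` takes a :class:`RunConfig`, simulates (or loads) a
cohort, executes the analysis stages in dependency order, writes every
stage table as plain TSV under the output directory, and aggregates a
deterministic ``report.json`` carrying a manifest (package version,
config hash, seed).  A stage failure raises :class:`StageError` naming
the stage; tables written before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, burden, cin, clonality, io, signatures, stats, tcr
from .errors import PairedomicsError, StageError
from .records import NONSYNONYMOUS_CLASSES
from .simulate import CohortConfig, Cohort, simulate_cohort

ALL_STAGES = (
    "spectra",
    "signatures",
    "apobec",
    "cin",
    "burden",
    "clonality",
    "tcr",
    "compare",
)


@dataclass(slots=True)
class RunConfig:
    simulate: CohortConfig = field(default_factory=CohortConfig)
    stages: dict[str, bool] = field(default_factory=dict)
    bin_size: int = cin.DEFAULT_BIN_SIZE
    region_mb: float = burden.DEFAULT_REGION_MB
    kd_threshold: float = burden.KD_THRESHOLD_NM
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    n_restarts: int = 10
    cin_mode: str = "absolute"
    seed: int = 0
    outdir: str = "pairedomics_out"

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        if isinstance(sim, dict):
            sim_fields = {f.name for f in dataclasses.fields(CohortConfig)}
            unknown = set(sim) - sim_fields
            if unknown:
                raise PairedomicsError(f"unknown simulate keys: {sorted(unknown)}")
            sim = CohortConfig(**sim)
        cfg = cls(simulate=sim, **d)
        if "seed" not in d:
            cfg.seed = cfg.simulate.seed
        cfg.simulate = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = _jsonable(dataclasses.asdict(self.simulate))
        d["k_range"] = list(self.k_range)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute the enabled stages; returns the output directory."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "manifest": {
            "version": __version__,
            "config_hash": config_hash(config),
            "seed": config.seed,
        }
    }
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    t0 = time.monotonic()
    cohort = _stage("simulate", lambda: _simulate(config, out))
    _log(f"[simulate] done in {time.monotonic() - t0:.1f}s")

    catalog = io.load_reference_catalog()
    spectrum = None
    ctx: dict = {}
    for stage in ALL_STAGES:
        if not config.enabled(stage):
            continue
        t0 = time.monotonic()
        if stage == "spectra":
            spectrum = _stage(stage, lambda: _spectra(cohort, out))
        elif stage == "signatures":
            if spectrum is None:
                spectrum = _stage("spectra", lambda: _spectra(cohort, out))
            report[stage] = _stage(
                stage, lambda: _signatures(spectrum, catalog, config, out)
            )
        elif stage == "apobec":
            report[stage] = _stage(stage, lambda: _apobec(cohort, out))
        elif stage == "cin":
            report[stage] = _stage(stage, lambda: _cin(cohort, config, out, ctx))
        elif stage == "burden":
            report[stage] = _stage(stage, lambda: _burden(cohort, config, out, ctx))
        elif stage == "clonality":
            report[stage] = _stage(stage, lambda: _clonality(cohort, out))
        elif stage == "tcr":
            report[stage] = _stage(stage, lambda: _tcr(cohort, out, ctx))
        elif stage == "compare":
            report[stage] = _stage(stage, lambda: _compare(cohort, ctx, out))
        _log(f"[{stage}] done in {time.monotonic() - t0:.1f}s")

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return out


def _stage(name: str, fn):
    try:
        return fn()
    except PairedomicsError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the failing stage
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def _simulate(config: RunConfig, out: Path) -> Cohort:
    cohort = simulate_cohort(config.simulate)
    io.write_sample_meta(cohort.meta, out / "samples.tsv")
    io.write_mutations(cohort.mutations, out / "mutations.tsv")
    io.write_segments(cohort.segments, out / "segments.tsv")
    io.write_segments(cohort.control_segments, out / "control_segments.tsv")
    io.write_neoantigens(cohort.neoantigens, out / "neoantigens.tsv")
    io.write_clonotypes(cohort.clonotypes, out / "clonotypes.tsv")
    pd.DataFrame(cohort.survival).to_csv(out / "survival.tsv", sep="\t", index=False)
    return cohort


def _spectra(cohort: Cohort, out: Path):
    sample_ids = [m.sample_id for m in cohort.meta]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spectrum = signatures.build_spectrum(cohort.mutations, sample_ids)
    df = pd.DataFrame(
        spectrum.counts, index=list(spectrum.sample_ids),
        columns=list(signatures.CHANNELS),
    )
    df.index.name = "sample_id"
    df.to_csv(out / "spectrum.tsv", sep="\t")
    return spectrum


def _signatures(spectrum, catalog, config: RunConfig, out: Path) -> dict:
    res = signatures.extract_signatures(
        spectrum,
        k_range=config.k_range,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    io.write_catalog(res.catalog, out / "extracted_signatures.csv")
    matches = {}
    for name in res.catalog.names:
        m = signatures.match_to_catalog(res.catalog.vector(name), catalog)
        matches[name] = {"best": m.name, "cosine": round(m.cosine, 4), "tied": m.tied}
    refit = signatures.refit_exposures(spectrum, catalog.subset(
        sorted({m["best"] for m in matches.values()})
    ))
    rel = pd.DataFrame(
        refit.relative, index=list(refit.sample_ids),
        columns=list(refit.signature_names),
    )
    rel.index.name = "sample_id"
    rel.to_csv(out / "exposures.tsv", sep="\t")
    return {
        "k": res.k,
        "stability": {str(k): round(v, 4) for k, v in res.stability.items()},
        "low_stability": res.low_stability,
        "matches": matches,
    }


def _apobec(cohort: Cohort, out: Path) -> dict:
    results = signatures.apobec_enrichment(cohort.mutations)
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df["flags"] = [";".join(r.flags) for r in results]
    df.to_csv(out / "apobec.tsv", sep="\t", index=False)
    labels = {r.sample_id: r.label for r in results}
    genes = signatures.apobec_group_genes(cohort.mutations, labels) if (
        "APOBEC_high" in labels.values() and "APOBEC_low" in labels.values()
    ) else None
    if genes is not None:
        genes.to_csv(out / "apobec_genes.tsv", sep="\t", index=False)
    return {
        "n_high": sum(1 for r in results if r.label == "APOBEC_high"),
        "n_samples": len(results),
    }


def _cin(cohort: Cohort, config: RunConfig, out: Path, ctx: dict) -> dict:
    results = cin.score_cohort(
        cohort.segments, cohort.control_segments,
        bin_size=config.bin_size, mode=config.cin_mode,
    )
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df.to_csv(out / "cin.tsv", sep="\t", index=False)
    ctx["cin_scores"] = {r.sample_id: r.cin_score for r in results}
    return {
        "mode": config.cin_mode,
        "threshold": results[0].threshold if results else None,
        "n_elevated": sum(1 for r in results if r.elevated),
        "n_samples": len(results),
    }


def _burden(cohort: Cohort, config: RunConfig, out: Path, ctx: dict) -> dict:
    results = burden.burden_summary(
        cohort.mutations, cohort.neoantigens, region_mb=config.region_mb
    )
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df.to_csv(out / "burden.tsv", sep="\t", index=False)
    ctx["tmb"] = {r.sample_id: r.tmb_per_mb for r in results}
    ctx["neo_pct"] = {
        r.sample_id: r.neoantigen_pct for r in results if r.neoantigen_pct is not None
    }
    kept, _ = burden.filter_neoantigens(cohort.neoantigens)
    frac, n_unassigned = burden.cluster_neoantigen_fraction(cohort.mutations, kept)
    frac.to_csv(out / "cluster_neoantigen.tsv", sep="\t", index=False)
    return {
        "mean_tmb": float(np.mean(list(ctx["tmb"].values()))),
        "n_unassigned_cluster": n_unassigned,
    }


def _clonality(cohort: Cohort, out: Path) -> dict:
    per_sample = {m.sample_id: m.patient_id for m in cohort.meta}
    by_patient: dict[str, list] = {}
    for mu in cohort.mutations:
        by_patient.setdefault(per_sample[mu.sample_id], []).append(mu)
    rows = []
    summaries = {}
    for pid, muts in by_patient.items():
        if len({m.sample_id for m in muts}) < 2:
            continue
        summary = clonality.classify_sharing(muts)
        summaries[pid] = summary
        for sc in summary.classes:
            rows.append(
                {
                    "patient_id": pid,
                    "mutation_key": sc.mutation_key,
                    "class": sc.sharing,
                    "samples": ";".join(sc.samples),
                }
            )
    pd.DataFrame(rows).to_csv(out / "sharing.tsv", sep="\t", index=False)
    privates = [
        n for s in summaries.values() for n in s.private_counts.values()
    ]
    return {
        "n_patients_classified": len(summaries),
        "mean_private": float(np.mean(privates)) if privates else None,
        "sd_private": float(np.std(privates, ddof=1)) if len(privates) > 1 else None,
    }


def _tcr(cohort: Cohort, out: Path, ctx: dict) -> dict:
    sample_ids = sorted({c.sample_id for c in cohort.clonotypes})
    rows = []
    sdi = {}
    for sid in sample_ids:
        summary = tcr.repertoire_summary(cohort.clonotypes, sample_id=sid)
        sdi[sid] = summary.sdi
        rows.append(
            {
                "sample_id": sid,
                "n_reads_productive": summary.n_reads_productive,
                "n_clonotypes": summary.n_clonotypes,
                "sdi": summary.sdi,
                "length_mode": summary.length_mode,
                **{f"abund_{k}": v for k, v in summary.abundance_fractions.items()},
            }
        )
    pd.DataFrame(rows).to_csv(out / "tcr.tsv", sep="\t", index=False)
    ctx["sdi"] = sdi
    return {"n_samples": len(sample_ids)}


def _paired(metric: dict[str, float], cohort: Cohort) -> tuple[list, list]:
    pre, post = [], []
    by_patient: dict[str, dict[int, str]] = {}
    for m in cohort.meta:
        by_patient.setdefault(m.patient_id, {})[m.timepoint] = m.sample_id
    for pid, tps in sorted(by_patient.items()):
        if 0 in tps and 1 in tps and tps[0] in metric and tps[1] in metric:
            pre.append(metric[tps[0]])
            post.append(metric[tps[1]])
    return pre, post


def _compare(cohort: Cohort, ctx: dict, out: Path) -> dict:
    rows = []
    for name in ("cin_scores", "tmb", "neo_pct", "sdi"):
        metric = ctx.get(name)
        if not metric:
            continue
        pre, post = _paired(metric, cohort)
        if len(pre) < 1:
            continue
        try:
            res = stats.wilcoxon_signed_rank(post, pre)
        except PairedomicsError:
            continue
        rows.append(
            {
                "metric": name,
                "n_pairs": len(pre),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "exact": res.exact,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = stats.bh_fdr(df["p_value"].to_numpy())
    df.to_csv(out / "comparisons.tsv", sep="\t", index=False)

    surv = pd.DataFrame(cohort.survival)
    km_section = None
    if len(surv) and surv["group"].nunique() == 2:
        lr = stats.log_rank(
            surv["time_months"].to_numpy(),
            surv["event"].to_numpy().astype(bool),
            surv["group"].to_numpy(),
        )
        km_section = {
            "log_rank_chi2": None if np.isnan(lr.statistic) else lr.statistic,
            "log_rank_p": None if np.isnan(lr.p_value) else lr.p_value,
            "flags": list(lr.flags),
        }
    return {
        "paired_tests": rows,
        "survival": km_section,
    }
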