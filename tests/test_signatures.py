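import numpy as np
import pytest

from pairedomics.channels import CHANNELS, channel_of
from pairedomics.errors import ValidationError
from pairedomics.records import MutationRecord
from pairedomics.signatures import (
    CONTEXT_BACKGROUND_C,
    SignatureCatalog,
    SpectrumMatrix,
    apobec_enrichment,
    apobec_group_genes,
    build_spectrum,
    cosine,
    extract_signatures,
    match_to_catalog,
    refit_exposures,
    strand_bias_test,
    tcw_background,
)
from pairedomics.simulate import (
    mixture_vector,
    sample_channel_mutations,
    simulate_context_mutations,
)


def _snv(sample, pos, ref, alt, ctx, strand="unknown", gene="TP53", cls="missense"):
    return MutationRecord(
        sample, "P1", "s0", "chr1", pos, ref, alt, cls, gene,
        context3=ctx, tx_strand=strand,
    )


class TestBuildSpectrum:
    def test_single_mutation_single_channel(self):
        spec = build_spectrum([_snv("S1", 1, "C", "T", "ACG")])
        assert spec.counts.sum() == 1
        assert spec.counts[0, CHANNELS.index("A[C>T]G")] == 1

    def test_non_snv_excluded_and_counted(self):
        muts = [
            _snv("S1", 1, "C", "T", "ACG"),
            MutationRecord("S1", "P1", "s0", "chr1", 5, "C", "CAT", "frameshift", "TP53"),
        ]
        spec = build_spectrum(muts)
        assert spec.counts.sum() == 1
        assert spec.n_excluded == 1

    def test_zero_snv_sample_warns_not_fails(self):
        with pytest.warns(UserWarning, match="zero SNVs"):
            spec = build_spectrum([_snv("S1", 1, "C", "T", "ACG")], ["S1", "S2"])
        assert spec.counts[1].sum() == 0

    def test_pure_signature_spectrum_close(self, reference_catalog, rng):
        # empirical spectrum concentrates on the generating signature;
        # the tolerance comes from a direct multinomial resampling oracle
        target = reference_catalog.vector("22")
        n = 10_000
        muts = sample_channel_mutations(rng, target, n, "S1", "P1", "s0", {}, 0.0)
        spec = build_spectrum(muts)
        empirical = spec.counts[0] / spec.counts[0].sum()
        l1 = np.abs(empirical - target).sum()
        oracle = np.random.default_rng(12345)
        l1_null = [
            np.abs(oracle.multinomial(n, target) / n - target).sum()
            for _ in range(300)
        ]
        assert l1 <= np.quantile(l1_null, 0.995)
        # at larger n the distance shrinks as 1/sqrt(n)
        muts5 = sample_channel_mutations(rng, target, 5 * n, "S1", "P1", "s0", {}, 0.0)
        spec5 = build_spectrum(muts5)
        emp5 = spec5.counts[0] / spec5.counts[0].sum()
        assert np.abs(emp5 - target).sum() < 0.05


class TestMatchToCatalog:
    def test_self_match(self, reference_catalog):
        m = match_to_catalog(reference_catalog.vector("22"), reference_catalog)
        assert m.name == "22"
        assert m.cosine == pytest.approx(1.0)

    def test_orthogonal_indicator(self):
        cat = SignatureCatalog(("only",), np.eye(96)[:1])
        v = np.zeros(96)
        v[1] = 1.0
        assert match_to_catalog(v, cat).cosine == pytest.approx(0.0)

    def test_brute_force_argmax(self, reference_catalog, rng):
        v = rng.dirichlet(np.ones(96))
        m = match_to_catalog(v, reference_catalog)
        brute = max(
            (cosine(v, row), name)
            for name, row in zip(reference_catalog.names, reference_catalog.probs)
        )
        assert m.cosine == pytest.approx(brute[0])
        assert m.name == brute[1]

    def test_zero_vector_error(self, reference_catalog):
        with pytest.raises(ValidationError):
            match_to_catalog(np.zeros(96), reference_catalog)


class TestExtractSignatures:
    def test_single_signature_recovers_k1(self, reference_catalog, rng):
        target = reference_catalog.vector("22")
        muts = []
        for i in range(6):
            muts += sample_channel_mutations(
                rng, target, 3000, f"S{i}", f"P{i}", "s0", {}, 0.0
            )
        spec = build_spectrum(muts)
        res = extract_signatures(spec, k_range=(1, 2, 3), n_restarts=8, seed=0)
        assert res.k == 1
        assert cosine(res.catalog.probs[0], target) >= 0.99

    def test_two_separated_signatures_recovered(self, reference_catalog, rng):
        a = reference_catalog.vector("2")
        b = reference_catalog.vector("22")
        assert cosine(a, b) < 0.3  # well separated
        muts = []
        for i in range(6):
            w = 0.8 if i % 2 == 0 else 0.2
            mix = w * a + (1 - w) * b
            muts += sample_channel_mutations(
                rng, mix / mix.sum(), 5000, f"S{i}", f"P{i}", "s0", {}, 0.0
            )
        spec = build_spectrum(muts)
        res = extract_signatures(spec, k_range=(1, 2, 3), n_restarts=8, seed=0)
        assert res.k == 2
        best_a = max(cosine(v, a) for v in res.catalog.probs)
        best_b = max(cosine(v, b) for v in res.catalog.probs)
        assert best_a >= 0.95
        assert best_b >= 0.95

    def test_reconstruction_error_monotone_in_k(self, reference_catalog, rng):
        a = reference_catalog.vector("2")
        b = reference_catalog.vector("13")
        muts = []
        for i in range(5):
            w = [0.9, 0.5, 0.1, 0.7, 0.3][i]
            mix = w * a + (1 - w) * b
            muts += sample_channel_mutations(
                rng, mix / mix.sum(), 2000, f"S{i}", f"P{i}", "s0", {}, 0.0
            )
        spec = build_spectrum(muts)
        res = extract_signatures(spec, k_range=(1, 2, 3), n_restarts=10, seed=1)
        errs = res.reconstruction_error
        assert errs[2] <= errs[1] * (1 + 1e-6)
        assert errs[3] <= errs[2] * (1 + 1e-6)

    def test_deterministic_given_seed(self, reference_catalog, rng):
        target = reference_catalog.vector("2")
        muts = []
        for i in range(4):
            muts += sample_channel_mutations(
                rng, target, 1000, f"S{i}", f"P{i}", "s0", {}, 0.0
            )
        spec = build_spectrum(muts)
        r1 = extract_signatures(spec, k_range=(1, 2), n_restarts=5, seed=11)
        r2 = extract_signatures(spec, k_range=(1, 2), n_restarts=5, seed=11)
        assert r1.k == r2.k
        assert np.array_equal(r1.catalog.probs, r2.catalog.probs)

    def test_sample_order_invariance(self, reference_catalog, rng):
        a = reference_catalog.vector("2")
        b = reference_catalog.vector("22")
        muts = []
        for i in range(6):
            w = 0.85 if i < 3 else 0.15
            mix = w * a + (1 - w) * b
            muts += sample_channel_mutations(
                rng, mix / mix.sum(), 4000, f"S{i}", f"P{i}", "s0", {}, 0.0
            )
        spec = build_spectrum(muts)
        perm = [4, 2, 0, 5, 1, 3]
        spec_perm = SpectrumMatrix(
            tuple(spec.sample_ids[i] for i in perm), spec.counts[perm]
        )
        r1 = extract_signatures(spec, k_range=(2,), n_restarts=8, seed=3)
        r2 = extract_signatures(spec_perm, k_range=(2,), n_restarts=8, seed=3)
        # converged components agree up to permutation, independent of row order
        for v in r1.catalog.probs:
            assert max(cosine(v, u) for u in r2.catalog.probs) >= 0.99

    def test_empty_spectrum_error(self):
        spec = SpectrumMatrix(("S1",), np.zeros((1, 96), dtype=int))
        with pytest.raises(ValidationError):
            extract_signatures(spec)


class TestRefitExposures:
    def test_pure_signature_contribution_one(self, reference_catalog):
        sub = reference_catalog.subset(["1", "2"])
        counts = np.rint(1000 * sub.probs[1]).astype(int)[None, :]
        spec = SpectrumMatrix(("S1",), counts)
        exp = refit_exposures(spec, sub)
        assert exp.relative[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_weight_recovery(self, reference_catalog, rng):
        sub = reference_catalog.subset(["2", "22"])
        mix = 0.7 * sub.probs[0] + 0.3 * sub.probs[1]
        muts = sample_channel_mutations(rng, mix, 10_000, "S1", "P1", "s0", {}, 0.0)
        spec = build_spectrum(muts)
        exp = refit_exposures(spec, sub)
        assert np.abs(exp.relative[0] - [0.7, 0.3]).sum() < 0.05

    def test_nnls_optimality_spot_check(self, reference_catalog, rng):
        sub = reference_catalog.subset(["1", "2", "13", "22"])
        counts = rng.integers(0, 40, size=96)[None, :]
        spec = SpectrumMatrix(("S1",), counts)
        exp = refit_exposures(spec, sub)
        A = sub.probs.T
        resid = np.linalg.norm(A @ exp.exposures[0] - counts[0])
        for _ in range(200):
            candidate = np.abs(
                exp.exposures[0] + rng.normal(0, 10, size=4)
            )
            assert np.linalg.norm(A @ candidate - counts[0]) >= resid - 1e-9

    def test_zero_row_flagged(self, reference_catalog):
        spec = SpectrumMatrix(("S1", "S2"), np.vstack(
            [np.zeros(96, dtype=int), np.rint(100 * reference_catalog.probs[0])]
        ).astype(int))
        exp = refit_exposures(spec, reference_catalog.subset(["1"]))
        assert exp.flags["S1"] == ("zero_spectrum",)
        assert exp.exposures[0].sum() == 0


class TestStrandBias:
    def test_even_split_p_one(self):
        muts = [
            _snv("S1", i + 1, "T", "A", "TTG",
                 "transcribed" if i < 5 else "untranscribed")
            for i in range(10)
        ]
        n_t, n_u, p = strand_bias_test(muts, "T>A")
        assert (n_t, n_u) == (5, 5)
        assert p == pytest.approx(1.0)

    def test_ninety_ten_closed_form(self):
        from scipy.stats import binom

        muts = [
            _snv("S1", i + 1, "T", "A", "TTG",
                 "transcribed" if i < 90 else "untranscribed")
            for i in range(100)
        ]
        _, _, p = strand_bias_test(muts, "T>A")
        # two-sided exact binomial tail oracle (symmetric null)
        expected = binom.sf(89, 100, 0.5) + binom.cdf(10, 100, 0.5)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 1e-14

    def test_single_observation(self):
        muts = [_snv("S1", 1, "T", "A", "TTG", "untranscribed")]
        _, _, p = strand_bias_test(muts, "T>A")
        assert p == pytest.approx(1.0)

    def test_unknown_strand_excluded_and_empty_errors(self):
        muts = [_snv("S1", 1, "T", "A", "TTG", "unknown")]
        with pytest.raises(ValidationError):
            strand_bias_test(muts, "T>A")

    def test_purine_records_counted_via_normalization(self):
        # A>T at CAA is T>A at TTG on the pyrimidine strand
        muts = [_snv("S1", 1, "A", "T", "CAA", "transcribed")]
        n_t, n_u, _ = strand_bias_test(muts, "T>A")
        assert (n_t, n_u) == (1, 0)


class TestApobecEnrichment:
    def test_proportional_mutations_enrichment_one(self):
        # counts exactly proportional to context abundances
        muts = []
        pos = 1
        for ctx, n in CONTEXT_BACKGROUND_C.items():
            for _ in range(n // 10):
                muts.append(_snv("S1", pos, "C", "T", ctx))
                pos += 1
        (res,) = apobec_enrichment(muts)
        assert res.enrichment == pytest.approx(1.0, abs=1e-12)
        assert res.label == "APOBEC_low"

    def test_fourfold_simulation_labeled_high(self, rng):
        muts = simulate_context_mutations(500, 4.0, rng)
        (res,) = apobec_enrichment(muts)
        assert res.enrichment > 2
        assert res.fdr < 0.05
        assert res.label == "APOBEC_high"

    def test_enrichment_without_significance_stays_low(self):
        # enrichment 3.0 on tiny counts: rule requires BOTH conditions
        counts = {"TCA": 100, "TCT": 150, "ACA": 875, "GCC": 875}
        muts = [_snv("S1", i + 1, "C", "T", "TCA") for i in range(3)]
        muts += [_snv("S1", 10 + i, "C", "G", "ACA") for i in range(5)]
        (res,) = apobec_enrichment(muts, context_counts=counts)
        assert res.enrichment == pytest.approx((3 / 8) / (250 / 2000))
        assert res.enrichment == pytest.approx(3.0)
        assert res.fdr >= 0.05
        assert res.label == "APOBEC_low"

    def test_no_c_mutations_flagged_excluded(self):
        muts = [
            _snv("S1", 1, "T", "A", "TTG"),
            _snv("S2", 1, "C", "T", "TCA"),
        ]
        results = apobec_enrichment(muts)
        by_id = {r.sample_id: r for r in results}
        assert "no_c_mutations" in by_id["S1"].flags
        assert np.isnan(by_id["S1"].enrichment)
        assert not np.isnan(by_id["S2"].p_value)

    def test_tcw_background_helper(self):
        ctx_tcw, ctx_c = tcw_background()
        assert ctx_tcw == CONTEXT_BACKGROUND_C["TCA"] + CONTEXT_BACKGROUND_C["TCT"]
        assert ctx_c == sum(CONTEXT_BACKGROUND_C.values())


class TestApobecGroupGenes:
    def _muts(self, carriers, gene, pos):
        return [_snv(s, pos, "C", "T", "TCA", gene=gene) for s in carriers]

    def test_five_vs_zero_closed_form(self):
        high = [f"H{i}" for i in range(5)]
        low = [f"L{i}" for i in range(5)]
        labels = {s: "APOBEC_high" for s in high} | {s: "APOBEC_low" for s in low}
        muts = self._muts(high, "TP53", 1) + self._muts(high + low, "KRT4", 2)
        df = apobec_group_genes(muts, labels)
        p = df.loc[df.gene == "TP53", "p_value"].iloc[0]
        assert p == pytest.approx(2 / 252)  # = 1/126, hypergeometric oracle

    def test_identical_rates_p_one(self):
        labels = {"H1": "APOBEC_high", "H2": "APOBEC_high",
                  "L1": "APOBEC_low", "L2": "APOBEC_low"}
        muts = self._muts(["H1", "L1"], "TP53", 1)
        df = apobec_group_genes(muts, labels)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_bh_applied_across_genes(self):
        from pairedomics.stats import bh_fdr

        high = [f"H{i}" for i in range(5)]
        low = [f"L{i}" for i in range(5)]
        labels = {s: "APOBEC_high" for s in high} | {s: "APOBEC_low" for s in low}
        muts = (
            self._muts(high, "A1", 1)
            + self._muts(high[:4], "B2", 2)
            + self._muts(high[:3] + low[:1], "C3", 3)
        )
        df = apobec_group_genes(muts, labels)
        assert np.allclose(df["fdr"], bh_fdr(df["p_value"].to_numpy()))
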