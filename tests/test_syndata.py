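import math

import numpy as np
import pytest

from fragdms import fragproc, syndata
from fragdms.reference import MutationKey
from fragdms.syndata import (
    FitnessModel,
    LibrarySpec,
    SequencingSpec,
    VariantGenotype,
    generate_library,
    mutation_load,
    simulate_reads,
    simulate_selection,
    trait_fitness,
    variant_sequences,
)


class TestGenerateLibrary:
    def test_zero_rate_gives_wild_type_only(self, ref):
        lib = generate_library(ref, LibrarySpec(50, 0.0, seed=1))
        assert all(len(v.mutations) == 0 for v in lib)

    @pytest.mark.parametrize("rate", [0.0052, 0.00063])
    def test_mutational_load_matches_rate(self, ref, rate):
        # Poisson-binomial mean = rate * CDS length; check within 3 SE.
        n = 4000
        lib = generate_library(ref, LibrarySpec(n, rate, seed=7))
        expected = rate * ref.cds_length
        se = math.sqrt(ref.cds_length * rate * (1 - rate) / n)
        assert abs(mutation_load(lib) - expected) < 3 * se

    def test_mutations_confined_to_cds(self, ref):
        lib = generate_library(ref, LibrarySpec(300, 0.01, seed=2))
        for v in lib:
            for k in v.mutations:
                assert ref.in_cds(k.pos)
                assert ref.sequence[k.pos] == k.ref
                assert k.alt != k.ref

    def test_abundances_sum_to_one(self, ref):
        lib = generate_library(ref, LibrarySpec(123, 0.005, seed=3))
        assert math.isclose(sum(v.abundance for v in lib), 1.0)

    def test_transition_bias_of_default_spectrum(self, ref):
        lib = generate_library(ref, LibrarySpec(3000, 0.0052, seed=4))
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        muts = [k for v in lib for k in v.mutations]
        frac = np.mean([(k.ref, k.alt) in transitions for k in muts])
        assert abs(frac - 2 / 3) < 0.03

    def test_uniform_spectrum_option(self, ref):
        spec = LibrarySpec(
            3000, 0.0052, substitution_spectrum=syndata.UNIFORM_SPECTRUM, seed=4
        )
        muts = [k for v in generate_library(ref, spec) for k in v.mutations]
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        frac = np.mean([(k.ref, k.alt) in transitions for k in muts])
        assert abs(frac - 1 / 3) < 0.03

    def test_rejects_invalid_spec(self):
        with pytest.raises(ValueError):
            LibrarySpec(10, 1.0)
        with pytest.raises(ValueError):
            LibrarySpec(0, 0.01)
        with pytest.raises(ValueError):
            LibrarySpec(10, 0.01, substitution_spectrum=np.ones((4, 4)))

    def test_deterministic_under_seed(self, ref):
        a = generate_library(ref, LibrarySpec(200, 0.005, seed=11))
        b = generate_library(ref, LibrarySpec(200, 0.005, seed=11))
        assert [v.mutations for v in a] == [v.mutations for v in b]


class TestTraitFitness:
    def _model(self, **kwargs):
        defaults = dict(
            stability_cost={},
            lambda_binding_effect={},
            malt_pore_effect={},
            nonsense_keys=frozenset(),
        )
        defaults.update(kwargs)
        return FitnessModel(**defaults)

    def test_wild_type_is_fully_fit(self, ref):
        wt = VariantGenotype(0, frozenset(), 1.0)
        assert trait_fitness(wt, self._model(), ref) == (1.0, 1.0)

    def test_nonsense_nulls_both_traits(self, ref, catalog):
        stop_key = next(
            MutationKey(int(p), r, a)
            for (p, r, a), row in catalog.iterrows()
            if row["effect_class"] == "nonsense"
        )
        v = VariantGenotype(0, frozenset({stop_key}), 1.0)
        model = self._model(nonsense_keys=frozenset({stop_key}))
        assert trait_fitness(v, model, ref) == (0.0, 0.0)

    def test_multiplicative_aggregation(self, ref):
        pos = ref.cds_start
        key = MutationKey(pos, ref.sequence[pos], "C" if ref.sequence[pos] != "C" else "G")
        v = VariantGenotype(0, frozenset({key}), 1.0)
        model = self._model(stability_cost={key: 0.5})
        assert trait_fitness(v, model, ref) == (0.5, 0.5)
        # two mutations compose multiplicatively
        pos2 = pos + 1
        key2 = MutationKey(pos2, ref.sequence[pos2], "A" if ref.sequence[pos2] != "A" else "T")
        v2 = VariantGenotype(1, frozenset({key, key2}), 1.0)
        model2 = self._model(stability_cost={key: 0.5, key2: 0.2})
        f = trait_fitness(v2, model2, ref)
        assert f == (pytest.approx(0.4), pytest.approx(0.4))

    def test_mutation_outside_amplicon_rejected(self, ref):
        bad = VariantGenotype(0, frozenset({MutationKey(len(ref) + 5, "A", "C")}), 1.0)
        with pytest.raises(ValueError):
            trait_fitness(bad, self._model(), ref)

    def test_loop_effects_spare_transport(self, ref):
        model = syndata.default_fitness_model(ref, seed=5)
        effects = syndata.true_mutation_effects(model, ref)
        planted = effects[
            (effects["effect_class"] == "missense")
            & (effects["true_lambda_sensitivity"] < 0.35)
            & (effects["true_malt"] >= 0.5)
        ]
        assert len(planted) > 0
        loop = set(syndata.DEFAULT_LOOP_RESIDUES)
        assert set(planted["residue"]) <= loop
        syn = effects[effects["effect_class"] == "synonymous"]
        assert (syn["true_lambda_sensitivity"] == 1.0).all()
        assert (syn["true_malt"] == 1.0).all()
        stops = effects[effects["effect_class"] == "nonsense"]
        assert (stops[["true_lambda_sensitivity", "true_malt"]] == 0.0).all().all()


class TestSimulateSelection:
    def test_neutral_selection_preserves_frequencies(self):
        pre = np.array([0.25, 0.25, 0.5])
        fits = (np.array([1.0, 0.2, 0.6]), np.array([1.0, 1.0, 1.0]))
        post = simulate_selection(pre, fits, "control", 10)
        np.testing.assert_allclose(post, pre)

    def test_two_variant_weighting(self):
        # w = 1 vs 0 over g = 3 generations: 2^3 : 1 = 8/9 vs 1/9.
        pre = np.array([0.5, 0.5])
        fits = (np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        post = simulate_selection(pre, fits, "lambda", 3)
        np.testing.assert_allclose(post, [8 / 9, 1 / 9])

    def test_nonsense_variant_enriches_under_phage(self):
        pre = np.array([0.5, 0.5])
        fits = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))  # null vs wild type
        post = simulate_selection(pre, fits, "lambda", 5)
        assert post[0] > pre[0]
        # ... and depletes under maltodextrin selection
        post_malt = simulate_selection(pre, fits, "malt", 5)
        assert post_malt[0] < pre[0]

    def test_conserves_total_frequency(self):
        rng = np.random.default_rng(0)
        pre = rng.dirichlet(np.ones(40))
        fits = (rng.random(40), rng.random(40))
        for cond in ("lambda", "malt", "control"):
            post = simulate_selection(pre, fits, cond, 7)
            assert math.isclose(post.sum(), 1.0)
            post_b = simulate_selection(pre, fits, cond, 7, bottleneck=5000, rng=1)
            assert math.isclose(post_b.sum(), 1.0)

    def test_rejects_bad_arguments(self):
        pre = np.array([0.5, 0.5])
        fits = (np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_selection(pre, fits, "lambda", -1)
        with pytest.raises(ValueError):
            simulate_selection(pre, fits, "lambda", 2, bottleneck=-5)
        with pytest.raises(ValueError):
            simulate_selection(np.array([0.5, 0.4]), fits, "lambda", 2)
        with pytest.raises(ValueError):
            simulate_selection(pre, fits, "glucose", 2)


class TestSimulateReads:
    def _library(self, ref, n=40, rate=0.0052, seed=9):
        return generate_library(ref, LibrarySpec(n, rate, seed=seed))

    def test_error_free_duplication_survives_filter(self, ref):
        lib = self._library(ref)
        ab = np.array([v.abundance for v in lib])
        spec = SequencingSpec(
            n_fragments=2000, per_base_error=0.0, duplication=("constant", 5)
        )
        pairs, _ = simulate_reads(lib, ab, ref, spec, rng=np.random.default_rng(1))
        pairs = list(pairs)
        assert all(mult == 5 for _, mult in pairs)
        log = fragproc.DropLog()
        kept = fragproc.collapse_and_filter(pairs, min_raw=5, log=log)
        assert log.n_below_min_raw == 0
        assert kept

    def test_wild_type_reads_match_reference(self, ref):
        lib = [VariantGenotype(0, frozenset(), 1.0)]
        spec = SequencingSpec(n_fragments=300, per_base_error=0.0)
        pairs, truth = simulate_reads(
            lib, np.array([1.0]), ref, spec, rng=np.random.default_rng(2)
        )
        from fragdms.reference import reverse_complement

        for (pair, _), (_, row) in zip(pairs, truth.iterrows()):
            frag = ref.sequence[row["start"] : row["end"]]
            assert pair.seq1 == frag[: len(pair.seq1)]
            assert reverse_complement(pair.seq2) == frag[len(frag) - len(pair.seq2) :]

    def test_far_fewer_unique_fragments_than_raw_pairs(self, ref):
        lib = self._library(ref, n=200)
        ab = np.array([v.abundance for v in lib])
        spec = SequencingSpec(n_fragments=50_000, per_base_error=0.0)
        pairs, truth = simulate_reads(lib, ab, ref, spec, rng=np.random.default_rng(3))
        n_raw = sum(mult for _, mult in pairs)
        distinct = len(set(zip(truth["variant_id"], truth["start"], truth["end"])))
        assert n_raw > 4 * distinct

    def test_fragment_lengths_match_spec(self, ref):
        lib = [VariantGenotype(0, frozenset(), 1.0)]
        spec = SequencingSpec(n_fragments=4000)
        _, truth = simulate_reads(
            lib, np.array([1.0]), ref, spec, rng=np.random.default_rng(4)
        )
        lens = truth["end"] - truth["start"]
        assert 58 <= np.median(lens) <= 68
        assert lens.min() >= spec.min_fragment_length
        assert lens.max() <= spec.max_fragment_length

    def test_truth_substitutions_lie_in_span(self, ref):
        lib = self._library(ref, n=30, rate=0.02)
        ab = np.array([v.abundance for v in lib])
        spec = SequencingSpec(n_fragments=500)
        _, truth = simulate_reads(lib, ab, ref, spec, rng=np.random.default_rng(5))
        for _, row in truth.iterrows():
            for k in row["substitutions"]:
                assert row["start"] <= k.pos < row["end"]
                assert k in lib[row["variant_id"]].mutations

    def test_byte_identical_under_fixed_seed(self, ref, tmp_path):
        lib = self._library(ref, n=20)
        ab = np.array([v.abundance for v in lib])
        spec = SequencingSpec(n_fragments=400, seed=8)
        outputs = []
        for run in range(2):
            pairs, _ = simulate_reads(lib, ab, ref, spec)
            path = tmp_path / f"run{run}"
            syndata.write_fastq_pairs(pairs, f"{path}_R1.fastq", f"{path}_R2.fastq")
            outputs.append(
                (path.with_name(path.name + "_R1.fastq").read_bytes(),
                 path.with_name(path.name + "_R2.fastq").read_bytes())
            )
        assert outputs[0] == outputs[1]

    def test_rejects_fragment_longer_than_amplicon(self, mini_ref):
        lib = [VariantGenotype(0, frozenset(), 1.0)]
        spec = SequencingSpec(n_fragments=10, min_fragment_length=100)
        with pytest.raises(ValueError):
            pairs, _ = simulate_reads(
                lib, np.array([1.0]), mini_ref, spec, rng=np.random.default_rng(0)
            )
            list(pairs)


def test_control_mismatch_rate_recovers_library_rate(ref):
    """Error-free control sequencing recovers the planted per-base rate."""
    rate = 0.0052
    lib = generate_library(ref, LibrarySpec(2000, rate, seed=21))
    ab = np.array([v.abundance for v in lib])
    spec = SequencingSpec(
        n_fragments=8000, per_base_error=0.0, duplication=("constant", 5)
    )
    pairs, _ = simulate_reads(lib, ab, ref, spec, rng=np.random.default_rng(22))
    frags, _, _ = fragproc.process_read_pairs(pairs, ref)
    est = fragproc.estimate_substitution_rate(frags, ref)
    bases = sum(f.raw_count * f.sequenced_bases for f in frags)
    se = math.sqrt(rate * (1 - rate) / (bases / 5))
    assert abs(est - rate / (1 - rate)) < 3 * se + 1e-4
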