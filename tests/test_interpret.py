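"""Filter PWMs, BLOSUM clustering and the GIA experiment suite."""

import itertools

import numpy as np
import pytest

from canya import network
from canya.encoding import AA_ALPHABET, AA_INDEX
from canya.interpret import (
    MotifCluster,
    MotifPWM,
    blosum_cluster,
    embed_kmer,
    extract_pwm,
    gia_importance,
    gia_interaction,
    gia_multiplicity,
    gia_positional,
    kmer_activation_energies,
    kmer_string,
    sample_kmer,
    select_backgrounds,
)
from canya.model import CanyaResults, ModelConfig

from conftest import AdditiveSurrogate, ConstantModel


def _one_filter_results(weights_fn, bias=0.0):
    config = ModelConfig(n_filters=1)
    params = network.init_params(config, np.random.default_rng(0))
    for p in range(3):
        for i, aa in enumerate(AA_ALPHABET):
            params["conv_w"][p, i, 0] = weights_fn(p, aa)
    params["conv_b"][0] = bias
    return CanyaResults(config=config, params=params)


def _pwm_from_kmers(filter_id, kmers):
    pwm = np.zeros((3, 20))
    for k in kmers:
        for p, aa in enumerate(k):
            pwm[p, AA_INDEX[aa]] += 1
    pwm /= len(kmers)
    return MotifPWM(filter_id=filter_id,
                    kmer_set=[(k, 1.0) for k in kmers], pwm=pwm)


class TestPWMExtraction:
    def test_dominating_kmer_gives_one_hot_pwm(self):
        res = _one_filter_results(lambda p, aa: 5.0 if aa == "I" else -5.0)
        pwm = extract_pwm(res, 0)
        assert pwm.kmers == ["III"]
        assert np.allclose(pwm.pwm[:, AA_INDEX["I"]], 1.0)
        assert pwm.pwm.sum() == pytest.approx(3.0)  # rows sum to 1

    def test_uniform_filter_capped_at_ten(self):
        res = _one_filter_results(lambda p, aa: 0.0)
        pwm = extract_pwm(res, 0)
        assert len(pwm.kmer_set) == 10
        # deterministic lexicographic tie-break
        assert pwm.kmers == sorted(pwm.kmers)
        assert pwm.kmers[0] == "AAA"

    def test_matches_brute_force_enumeration(self, random_results):
        energies = kmer_activation_energies(random_results)
        w = random_results.params["conv_w"]
        b = random_results.params["conv_b"]
        rng = np.random.default_rng(0)
        for f in rng.choice(random_results.config.n_filters, 10, replace=False):
            # independent brute force over all 8,000 kmers
            brute = {}
            for kmer in itertools.product(AA_ALPHABET, repeat=3):
                z = sum(w[p, AA_INDEX[aa], f] for p, aa in enumerate(kmer)) + b[f]
                brute["".join(kmer)] = np.exp(z)
            top = max(brute.values())
            eligible = {k for k, v in brute.items() if v >= 0.75 * top}
            expected = sorted(eligible, key=lambda k: (-brute[k], k))[:10]
            pwm = extract_pwm(random_results, int(f), energies)
            assert pwm.kmers == expected
            for k, a in pwm.kmer_set:
                assert a == pytest.approx(brute[k], rel=1e-10)

    def test_kmer_string_roundtrip(self):
        assert kmer_string(0) == "AAA"
        assert kmer_string(7999) == "YYY"
        assert kmer_string(1) == "AAC"


class TestClustering:
    def test_identical_pwms_cluster_together(self):
        pwms = [_pwm_from_kmers(0, ["III"]), _pwm_from_kmers(1, ["III"]),
                _pwm_from_kmers(2, ["DDD"]), _pwm_from_kmers(3, ["EEE"])]
        clusters = blosum_cluster(pwms, {0: 1.0, 1: 0.9, 2: -1.0, 3: -0.8}, seed=0)
        by_filter = {f: c.cluster_id for c in clusters for f in c.members}
        assert by_filter[0] == by_filter[1]
        assert by_filter[2] == by_filter[3]

    def test_hydrophobic_and_acidic_separate(self):
        pwms = [_pwm_from_kmers(0, ["III", "VVV"]), _pwm_from_kmers(1, ["VVV"]),
                _pwm_from_kmers(2, ["DDD", "EEE"]), _pwm_from_kmers(3, ["EEE"])]
        clusters = blosum_cluster(pwms, {0: 1.0, 1: 0.5, 2: -1.0, 3: -0.5}, seed=0)
        by_filter = {f: c.cluster_id for c in clusters for f in c.members}
        assert by_filter[0] == by_filter[1]
        assert by_filter[2] == by_filter[3]
        assert by_filter[0] != by_filter[2]

    def test_sign_discordant_member_pruned(self):
        pwms = [_pwm_from_kmers(0, ["III"]), _pwm_from_kmers(1, ["VVV"]),
                _pwm_from_kmers(2, ["LLL"]), _pwm_from_kmers(3, ["DDD"]),
                _pwm_from_kmers(4, ["EEE"])]
        clusters = blosum_cluster(
            pwms, {0: 0.5, 1: 0.2, 2: -0.01, 3: -1.0, 4: -0.8}, seed=0)
        hydro = next(c for c in clusters if 0 in c.members)
        assert 2 not in hydro.members
        assert 2 in hydro.pruned
        assert hydro.sign == 1
        for c in clusters:  # no discordant members anywhere after pruning
            for f in c.members:
                assert np.sign(c.importances[f]) in (0, c.sign)

    def test_needs_two_pwms(self):
        with pytest.raises(ValueError):
            blosum_cluster([_pwm_from_kmers(0, ["III"])], {0: 1.0})


class TestBackgrounds:
    def test_postconditions(self, random_results, labeled_library):
        df = labeled_library.records
        bgs = select_backgrounds(random_results, df, n=200, seed=0)
        assert len(bgs) == 200
        assert all(len(s) == 20 for s in bgs)
        probs = random_results.predict(bgs)
        labels = df.set_index("aa_seq")["label"]
        for s, p in zip(bgs, probs):
            lab = labels.loc[s]
            lab = lab.iloc[0] if hasattr(lab, "iloc") else lab
            assert (p > 0.3) if lab == 1 else (p < 0.2)

    def test_impossible_thresholds_error(self, random_results, labeled_library):
        with pytest.raises(ValueError):
            select_backgrounds(random_results, labeled_library.records,
                               thresholds=(1.0, 0.0))


class TestGIASingle:
    def test_kmer_sampling_probabilities_are_activation_ratios(self):
        # activations {2,1,1} -> ratios {1,.5,.5} -> probabilities {.5,.25,.25}
        pwm = MotifPWM(filter_id=0, kmer_set=[("III", 2.0), ("VVV", 1.0), ("LLL", 1.0)],
                       pwm=np.zeros((3, 20)))
        rng = np.random.default_rng(0)
        draws = [sample_kmer(pwm, rng) for _ in range(8000)]
        freq = {k: draws.count(k) / len(draws) for k in ("III", "VVV", "LLL")}
        assert freq["III"] == pytest.approx(0.5, abs=0.02)
        assert freq["VVV"] == pytest.approx(0.25, abs=0.02)
        assert freq["LLL"] == pytest.approx(0.25, abs=0.02)

    def test_constant_model_importance_zero(self, backgrounds):
        pwm = _pwm_from_kmers(0, ["III"])
        res = gia_importance(ConstantModel(3.0), pwm, backgrounds, seed=1)
        assert res.importance == 0.0
        assert res.ci[0] <= res.importance <= res.ci[1]

    def test_additive_surrogate_matches_closed_form(self, backgrounds):
        # embedding III at uniform positions on an additive model: importance
        # equals the average over positions/backgrounds of the replaced-weight
        # difference, computable exactly
        rng = np.random.default_rng(3)
        weights = rng.normal(0, 1, (20, 20))
        model = AdditiveSurrogate(weights)
        pwm = _pwm_from_kmers(0, ["III"])
        res = gia_importance(model, pwm, backgrounds, seed=5)
        # brute-force oracle: replay the same embedding decisions
        rng2 = np.random.default_rng(5)
        starts = rng2.integers(0, 18, size=len(backgrounds))
        diffs = []
        for s, st in zip(backgrounds, starts):
            sample_kmer(pwm, rng2)  # same rng stream consumption
            mod = embed_kmer(s, "III", st)
            diffs.append(model.pre_activation([mod])[0] - model.pre_activation([s])[0])
        assert res.importance == pytest.approx(np.mean(diffs))

    def test_fixed_position_policy(self, hydrophobic_surrogate, backgrounds):
        pwm = _pwm_from_kmers(0, ["III"])
        res = gia_importance(hydrophobic_surrogate, pwm, backgrounds,
                             position_policy=1, seed=0)
        assert res.n_backgrounds == len(backgrounds)
        with pytest.raises(ValueError):
            gia_importance(hydrophobic_surrogate, pwm, backgrounds,
                           position_policy=19)

    def test_empty_backgrounds_rejected(self, hydrophobic_surrogate):
        with pytest.raises(ValueError):
            gia_importance(hydrophobic_surrogate, _pwm_from_kmers(0, ["III"]), [])


def _cluster(kmers_by_filter, importances):
    pwms = {f: _pwm_from_kmers(f, ks) for f, ks in kmers_by_filter.items()}
    sign = 1 if max(importances.values(), key=abs) >= 0 else -1
    return MotifCluster(cluster_id=0, members=list(kmers_by_filter),
                        pwms=pwms, importances=importances, sign=sign)


class TestGIAMultiplicity:
    def test_additive_model_exactly_linear(self, unit_kmer_surrogate,
                                           kmer_free_backgrounds):
        # backgrounds lack I/V and only I/V carry weight, so every embedded
        # copy adds exactly 3.0: importance(k) = 3k and R^2 = 1 exactly
        cluster = _cluster({0: ["III"], 1: ["VVV"]}, {0: 1.0, 1: 0.5})
        results, r2 = gia_multiplicity(unit_kmer_surrogate, cluster,
                                       kmer_free_backgrounds[:100], seed=2)
        assert len(results) == 4
        for k, r in enumerate(results, start=1):
            assert r.importance == pytest.approx(3.0 * k, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_model_all_zero(self, backgrounds):
        cluster = _cluster({0: ["III"]}, {0: 1.0})
        results, _ = gia_multiplicity(ConstantModel(), cluster, backgrounds[:50], seed=0)
        assert all(r.importance == 0.0 for r in results)

    def test_copies_recorded(self, hydrophobic_surrogate, backgrounds):
        cluster = _cluster({0: ["III"]}, {0: 1.0})
        results, _ = gia_multiplicity(hydrophobic_surrogate, cluster,
                                      backgrounds[:30], seed=1)
        assert [r.extra["copies"] for r in results] == [1, 2, 3, 4]


class TestGIAPositional:
    def test_output_has_18_positions(self, hydrophobic_surrogate, backgrounds):
        cluster = _cluster({0: ["III"]}, {0: 1.0})
        df = gia_positional(hydrophobic_surrogate, cluster, backgrounds[:50], seed=0)
        assert len(df) == 18
        assert df["position"].tolist() == list(range(1, 19))

    def test_position_invariant_model_flat_profile(self, hydrophobic_surrogate,
                                                   backgrounds):
        cluster = _cluster({0: ["III"]}, {0: 1.0})
        df = gia_positional(hydrophobic_surrogate, cluster, backgrounds[:80], seed=0)
        # position-invariant additive weights: percent changes all ~0 within CI
        half_ci = (df["ci_high"] - df["ci_low"]) / 2
        assert np.all(np.abs(df["importance"] - df["importance"].mean()) <= half_ci + 1e-9)

    def test_nterminal_weighting_detected(self, backgrounds):
        scale = {aa: (1.0 if aa in "ILV" else 0.0) for aa in AA_ALPHABET}
        mult = np.where(np.arange(20) < 9, 2.0, 1.0)
        model = AdditiveSurrogate.from_scale(scale, position_multiplier=mult)
        cluster = _cluster({0: ["III"]}, {0: 1.0})
        df = gia_positional(model, cluster, backgrounds[:80], seed=0)
        assert df.iloc[0]["percent_change"] > 0      # N-terminal boost
        assert df.iloc[-1]["percent_change"] < 0     # C-terminal deficit


class TestGIAInteraction:
    def test_additive_model_zero_interaction(self, hydrophobic_surrogate, backgrounds):
        a = _cluster({0: ["III"]}, {0: 1.0})
        b = _cluster({1: ["DDD"]}, {1: -1.0})
        res = gia_interaction(hydrophobic_surrogate, a, b, backgrounds[:100], seed=0)
        assert res.importance == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_planted_product_interaction_recovered(self, backgrounds):
        class ProductSurrogate(AdditiveSurrogate):
            def pre_activation(self, sequences):
                base = super().pre_activation(sequences)
                for i, s in enumerate(sequences):
                    if "III" in s and "DDD" in s:
                        base[i] += 0.7
                return base

        scale = {aa: 0.1 if aa in "ILV" else 0.0 for aa in AA_ALPHABET}
        model = ProductSurrogate.from_scale(scale)
        a = _cluster({0: ["III"]}, {0: 1.0})
        b = _cluster({1: ["DDD"]}, {1: -1.0})
        res = gia_interaction(model, a, b, backgrounds[:150], seed=1)
        # backgrounds rarely contain III/DDD already; epsilon ~ recovered
        assert res.ci[0] <= 0.7 <= res.ci[1] or abs(res.importance - 0.7) < 0.1

    def test_self_interaction_runs_and_bonferroni_reported(self,
                                                           hydrophobic_surrogate,
                                                           backgrounds):
        a = _cluster({0: ["III"]}, {0: 1.0})
        res = gia_interaction(hydrophobic_surrogate, a, a, backgrounds[:50],
                              seed=0, n_clusters=11)
        assert res.extra["alpha_corrected"] == pytest.approx(0.05 / 121)
        assert res.importance == pytest.approx(0.0, abs=1e-9)

    def test_background_halves_agree(self, backgrounds):
        rng = np.random.default_rng(9)
        model = AdditiveSurrogate(rng.normal(0, 0.5, (20, 20)))
        a = _cluster({0: ["III", "VVV"]}, {0: 1.0})
        r1 = gia_importance(model, a, backgrounds[:150], seed=3)
        r2 = gia_importance(model, a, backgrounds[150:], seed=4)
        # disjoint background halves give estimates within joint CI
        joint = np.hypot(r1.ci[1] - r1.importance, r2.ci[1] - r2.importance)
        assert abs(r1.importance - r2.importance) <= joint + 1e-9
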