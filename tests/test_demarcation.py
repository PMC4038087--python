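import numpy as np
import pandas as pd
import pytest

from mesoni.demarcation import (
    DistanceMatrix,
    cluster_species,
    discrete_gamma_rates,
    distance_matrix,
    extract_domains,
    load_model,
    load_reference_domains,
    poisson_distance_closed_form,
    sliding_window_divergence,
    wag_ml_distance,
)
from mesoni.errors import DomainMissingError, PrecisionError
from mesoni.synthetic_data import evolve_sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# WAG ML distance for the packaged reference concatenation evolved at
# d=0.2 (seed 77), computed independently with phangorn::dist.ml (WAG).
PHANGORN_WAG_D = 0.17394780


def reference_concat() -> str:
    return "".join(r.seq for r in load_reference_domains())


def mutate_exact(seq: str, k: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in rng.choice(len(seq), k, replace=False):
        out[i] = rng.choice([c for c in AA20 if c != out[i]])
    return "".join(out)


class TestModel:
    def test_wag_rate_matrix_normalized(self):
        m = load_model("WAG")
        assert np.allclose(m.Q.sum(axis=1), 0, atol=1e-12)
        assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0)
        # detailed balance of the reversible chain
        flux = m.pi[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_transition_matrix_is_stochastic(self):
        m = load_model("WAG")
        for d in (0.01, 0.5, 3.0):
            P = m.transition_matrix(d)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert (P > 0).all()

    def test_gamma_rates_mean_one(self):
        for shape in (0.3, 1.0, 5.0):
            rates = discrete_gamma_rates(shape)
            assert rates.shape == (4,)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(rates) > 0).all()


class TestMLDistance:
    def test_identical_sequences_give_zero(self):
        s = reference_concat()
        assert wag_ml_distance(s, s) <= 1e-6

    def test_poisson_matches_closed_form_across_p(self):
        n = 4000
        base = (AA20 * (n // 20 + 1))[:n]
        for p in (0.02, 0.1, 0.3, 0.5, 0.7, 0.88):
            k = int(round(p * n))
            other = mutate_exact(base, k, seed=k)
            d_ml = wag_ml_distance(base, other, model="Poisson")
            d_cf = poisson_distance_closed_form(k / n)
            assert d_ml == pytest.approx(d_cf, abs=1e-6)

    def test_agrees_with_phangorn_oracle(self):
        a = reference_concat()
        b = evolve_sequence(a, 0.2, "WAG-aa", 77)
        assert wag_ml_distance(a, b) == pytest.approx(PHANGORN_WAG_D, abs=1e-6)

    def test_symmetric_in_arguments(self):
        a = reference_concat()
        b = evolve_sequence(a, 0.3, "WAG-aa", 5)
        # reversibility makes the likelihood symmetric; agreement is limited
        # only by the optimizer tolerance
        assert wag_ml_distance(a, b) == pytest.approx(wag_ml_distance(b, a), abs=1e-6)

    def test_monotone_in_mismatched_sites(self):
        base = reference_concat()
        prev = -1.0
        for k in (5, 20, 80, 200, 400):
            d = wag_ml_distance(base, mutate_exact(base, k, seed=1))
            assert d > prev
            prev = d

    def test_recovers_simulation_distance(self):
        m = load_model("WAG")
        rng = np.random.default_rng(123)
        a = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 10000, p=m.pi))
        ests = [
            wag_ml_distance(a, evolve_sequence(a, 0.5, "WAG-aa", s))
            for s in (1, 2, 3)
        ]
        assert np.mean(ests) == pytest.approx(0.5, rel=0.05)

    def test_too_few_sites_rejected(self):
        with pytest.raises(PrecisionError):
            wag_ml_distance("ACDEF" * 5, "ACDEF" * 5)

    def test_unequal_lengths_are_aligned_first(self):
        a = reference_concat()
        b = a[:300] + a[310:]  # 10-residue deletion
        assert wag_ml_distance(a, b) == pytest.approx(0.0, abs=1e-6)


class TestClustering:
    def taxa(self, n):
        return [f"t{i}" for i in range(n)]

    def test_infinite_threshold_single_cluster(self):
        d = np.array([[0, 0.5, 0.9], [0.5, 0, 0.4], [0.9, 0.4, 0]], float)
        part = cluster_species(DistanceMatrix(self.taxa(3), d), t=np.inf)
        assert part.clusters == [["t0", "t1", "t2"]]

    def test_pair_below_cutoff_shares_species(self):
        d = np.array([[0, 0.01, 0.5], [0.01, 0, 0.5], [0.5, 0.5, 0]], float)
        part = cluster_species(DistanceMatrix(["A", "B", "C"], d), t=0.032)
        assert part.clusters == [["A", "B"], ["C"]]

    def test_zero_threshold_gives_singletons(self):
        rng = np.random.default_rng(0)
        n = 8
        d = rng.uniform(0.1, 1.0, (n, n))
        d = np.triu(d, 1)
        d = d + d.T
        part = cluster_species(DistanceMatrix(self.taxa(n), d), t=0.0)
        assert all(len(c) == 1 for c in part.clusters)

    def test_merging_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 9
            d = np.triu(rng.uniform(0, 1, (n, n)), 1)
            d = d + d.T
            m = DistanceMatrix(self.taxa(n), d)
            for t1, t2 in ((0.1, 0.3), (0.2, 0.7), (0.0, 1.0)):
                fine = cluster_species(m, t=t1)
                coarse = cluster_species(m, t=t2)
                coarse_of = {
                    t: i for i, c in enumerate(coarse.clusters) for t in c
                }
                for c in fine.clusters:  # each fine cluster inside one coarse
                    assert len({coarse_of[t] for t in c}) == 1

    def test_single_linkage_connects_through_chains(self):
        d = np.array(
            [[0, 0.02, 0.9], [0.02, 0, 0.03], [0.9, 0.03, 0]], float
        )
        m = DistanceMatrix(["A", "B", "C"], d)
        assert len(cluster_species(m, t=0.032, linkage="single").clusters) == 1
        assert len(cluster_species(m, t=0.032, linkage="complete").clusters) == 2


class TestExtractDomains:
    def test_reference_against_itself_exact_spans(self, default_genome):
        rec, truth = default_genome
        ds = extract_domains(truth.pp1ab, taxon="self")
        refs = {r.name: r for r in load_reference_domains()}
        for name, ref in refs.items():
            assert ds.spans[name] == ref.pp1ab_span
            assert ds.domains[name] == ref.seq

    def test_substituted_domains_found_within_two_residues(self, default_genome):
        rec, truth = default_genome
        rng = np.random.default_rng(9)
        pp = list(truth.pp1ab)
        for i in rng.choice(len(pp), int(0.05 * len(pp)), replace=False):
            pp[i] = rng.choice([c for c in AA20 if c != pp[i]])
        ds = extract_domains("".join(pp))
        for name, ref in ((r.name, r) for r in load_reference_domains()):
            ws, we = ref.pp1ab_span
            gs, ge = ds.spans[name]
            assert abs(gs - ws) <= 2 and abs(ge - we) <= 2

    def test_shuffled_protein_raises_domain_missing(self, default_genome):
        rec, truth = default_genome
        rng = np.random.default_rng(3)
        shuffled = "".join(rng.permutation(list(truth.pp1ab)))
        with pytest.raises(DomainMissingError):
            extract_domains(shuffled)

    def test_concat_order_is_fixed(self, default_genome):
        rec, truth = default_genome
        ds = extract_domains(truth.pp1ab)
        assert ds.concat == (
            ds.domains["3CLpro"] + ds.domains["RdRp"] + ds.domains["ZnHel1"]
        )


class TestSlidingWindow:
    def part(self, clusters):
        from mesoni.demarcation import SpeciesPartition

        return SpeciesPartition(threshold=0.032, clusters=clusters)

    def test_identical_sequences_all_zero(self):
        msa = {"a": "ACDEF" * 40, "b": "ACDEF" * 40, "c": "ACDEF" * 40}
        prof = sliding_window_divergence(
            msa, self.part([["a", "b"], ["c"]]), w=50, step=25
        )
        assert (prof.rows["within_mean"] == 0).all()
        assert (prof.rows["between_mean"] == 0).all()

    def test_window_count_formula(self):
        msa = {"a": "A" * 205, "b": "A" * 205}
        prof = sliding_window_divergence(msa, self.part([["a", "b"]]), w=100, step=25)
        assert len(prof.rows) == (205 - 100) // 25 + 1

    def test_hand_computed_three_sequence_profile(self):
        # window 4, step 4; mismatches placed by hand
        msa = {
            "a": "AAAACCCC",
            "b": "AAATCCCC",   # 1 mismatch vs a in window 0
            "c": "TTAACCCC",   # 2 vs a, 3 vs b in window 0
        }
        prof = sliding_window_divergence(
            msa, self.part([["a", "b"], ["c"]]), w=4, step=4
        )
        w0 = prof.rows.iloc[0]
        assert w0["within_mean"] == pytest.approx(1 / 4)
        assert w0["between_mean"] == pytest.approx((2 / 4 + 3 / 4) / 2)
        w1 = prof.rows.iloc[1]
        assert w1["within_mean"] == 0 and w1["between_mean"] == 0

    def test_gap_only_window_recorded_as_missing(self):
        msa = {"a": "ACDE" + "-" * 4, "b": "ACDE" + "-" * 4}
        prof = sliding_window_divergence(msa, self.part([["a", "b"]]), w=4, step=4)
        assert prof.rows["within_mean"].iloc[0] == 0
        assert pd.isna(prof.rows["within_mean"].iloc[1])

    def test_separated_groups_diverge_in_every_window(self):
        base = reference_concat()[:400]
        msa = {
            "a1": base,
            "a2": evolve_sequence(base, 0.01, "WAG-aa", 1),
            "b1": evolve_sequence(base, 0.6, "WAG-aa", 2),
            "b2": evolve_sequence(
                evolve_sequence(base, 0.6, "WAG-aa", 2), 0.01, "WAG-aa", 3
            ),
        }
        prof = sliding_window_divergence(
            msa, self.part([["a1", "a2"], ["b1", "b2"]]), w=100, step=50
        )
        assert (prof.rows["between_mean"] > prof.rows["within_mean"]).all()


class TestDistanceMatrixContainer:
    def test_tsv_round_trip(self, tmp_path):
        d = np.array([[0, 0.1], [0.1, 0]], float)
        m = DistanceMatrix(["x", "y"], d)
        p = tmp_path / "d.tsv"
        m.to_tsv(p)
        back = pd.read_csv(p, sep="\t", index_col=0)
        assert back.loc["x", "y"] == pytest.approx(0.1)
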