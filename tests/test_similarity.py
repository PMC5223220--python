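import math
import warnings

import numpy as np
import pytest

from micropattern import (
    AssociationRecord,
    AssociationTable,
    cosine_similarity,
    run_similarity,
    signed_count,
    weight_matrix,
)


def random_table(rng, n_diseases=4, n_microbes=6, max_count=3) -> AssociationTable:
    """Small random signed table with repeated pairs; at least two diseases touched."""
    diseases = [f"d{i}" for i in range(n_diseases)]
    microbes = [f"m{j}" for j in range(n_microbes)]
    records = []
    for d in diseases:
        for m in microbes:
            if rng.random() < 0.45:
                direction = int(rng.choice([1, -1]))
                records.extend(
                    AssociationRecord(d, m, direction)
                    for _ in range(int(rng.integers(1, max_count + 1)))
                )
    if len({r.disease for r in records}) < 2:  # pragma: no cover - rare under the draw rate
        records.append(AssociationRecord(diseases[0], microbes[0], 1))
        records.append(AssociationRecord(diseases[1], microbes[1], 1))
    return AssociationTable(records)


def brute_force_similarity(table: AssociationTable) -> dict[tuple[str, str], float]:
    """Independent oracle: pure-loop signed counts, idf weights and cosines."""
    N = len(set(r.disease for r in table.records))
    diseases = sorted({r.disease for r in table.records})
    microbes = sorted({r.microbe for r in table.records})
    w = {}
    for d in diseases:
        for m in microbes:
            s = sum(r.direction for r in table.records if (r.disease, r.microbe) == (d, m))
            n_j = len({r.disease for r in table.records if r.microbe == m})
            w[d, m] = s * math.log(N / n_j)
    out = {}
    for a in diseases:
        for b in diseases:
            dot = sum(w[a, m] * w[b, m] for m in microbes)
            na = math.sqrt(sum(w[a, m] ** 2 for m in microbes))
            nb = math.sqrt(sum(w[b, m] ** 2 for m in microbes))
            out[a, b] = dot / (na * nb) if na > 0 and nb > 0 else 0.0
    return out


class TestSignedCount:
    def test_concordant_records_accumulate(self, small_table):
        assert signed_count(small_table, "ibd", "roseburia faecis") == -2

    def test_opposite_directions_cancel(self):
        t = AssociationTable(
            [AssociationRecord("d", "m", 1), AssociationRecord("d", "m", -1),
             AssociationRecord("e", "x", 1)]
        )
        assert signed_count(t, "d", "m") == 0

    def test_absent_pair_is_zero(self, small_table):
        assert signed_count(small_table, "ibd", "veillonella parvula") == 0


class TestWeightMatrix:
    def test_idf_weight_value(self, small_table):
        # roseburia faecis: 2 concordant decrease records in ibd, n_j=2 of N=4
        w = weight_matrix(small_table)
        assert w.loc["ibd", "roseburia faecis"] == pytest.approx(-2 * math.log(2))

    def test_ubiquitous_microbe_has_zero_weight(self, small_table):
        assert (w := weight_matrix(small_table))["bacteroides vulgatus"].eq(0).all()
        assert w.shape == (small_table.n_diseases, small_table.n_microbes)

    def test_zero_weight_for_absent_pair(self, small_table):
        assert weight_matrix(small_table).loc["t2d", "escherichia coli"] == 0.0

    def test_direction_flip_flips_weights(self, small_table):
        flipped = AssociationTable(
            AssociationRecord(r.disease, r.microbe, -r.direction) for r in small_table.records
        )
        a = weight_matrix(small_table)
        b = weight_matrix(flipped)
        assert np.allclose(a.to_numpy(), -b.to_numpy())


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 0.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_vectors(self):
        assert cosine_similarity(np.array([1.0, -2.0]),
                                 np.array([-1.0, 2.0])) == pytest.approx(-1.0, abs=1e-12)

    def test_worked_example(self):
        assert cosine_similarity(np.array([1.0, 1, 0]), np.array([1.0, 0, 1])) == pytest.approx(0.5)

    def test_zero_norm_defined_as_zero(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_mismatched_universes_rejected(self, small_table):
        w = weight_matrix(small_table)
        with pytest.raises(ValueError):
            cosine_similarity(w.iloc[0], w.iloc[1][::-1])
        with pytest.raises(ValueError):
            cosine_similarity(np.ones(3), np.ones(4))


class TestRunSimilarity:
    def test_identical_association_profiles_are_maximally_similar(self):
        rows = [("a", "m1", 1), ("a", "m2", -1), ("b", "m1", 1), ("b", "m2", -1),
                ("c", "m3", 1), ("c", "m1", -1)]
        sim = run_similarity(AssociationTable(AssociationRecord(*r) for r in rows))
        assert sim.loc("a", "b") == pytest.approx(1.0)

    def test_disjoint_profiles_are_orthogonal(self):
        rows = [("a", "m1", 1), ("a", "m2", 1), ("b", "m3", -1), ("b", "m4", 1),
                ("c", "m1", 1), ("c", "m3", 1)]
        sim = run_similarity(AssociationTable(AssociationRecord(*r) for r in rows))
        assert sim.loc("a", "b") == 0.0

    def test_single_disease_rejected(self):
        t = AssociationTable([AssociationRecord("a", "m1", 1), AssociationRecord("a", "m2", 1)])
        with pytest.raises(ValueError, match="two"):
            run_similarity(t)

    def test_row_order_invariance(self, small_table):
        shuffled = AssociationTable(reversed(small_table.records))
        a, b = run_similarity(small_table), run_similarity(shuffled)
        assert a.diseases == b.diseases
        assert np.allclose(a.values, b.values)

    def test_symmetry_range_and_diagonal(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t = random_table(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-norm draws are legitimate here
                sim = run_similarity(t)
            assert np.allclose(sim.values, sim.values.T)
            assert np.all(sim.values >= -1.0) and np.all(sim.values <= 1.0)
            nonzero = np.linalg.norm(weight_matrix(t).to_numpy(), axis=1) > 0
            assert np.allclose(np.diag(sim.values)[nonzero], 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            t = random_table(rng, n_diseases=int(rng.integers(2, 6)),
                             n_microbes=int(rng.integers(2, 7)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny tables can yield zero-norm vectors
                sim = run_similarity(t)
            oracle = brute_force_similarity(t)
            for i, a in enumerate(sim.diseases):
                for j, b in enumerate(sim.diseases):
                    assert sim.values[i, j] == pytest.approx(oracle[a, b], abs=1e-12)

    def test_matches_sklearn_cosine(self):
        from sklearn.metrics.pairwise import cosine_similarity as sk_cosine

        rng = np.random.default_rng(13)
        t = random_table(rng, n_diseases=5, n_microbes=8)
        w = weight_matrix(t).to_numpy()
        if not (np.linalg.norm(w, axis=1) > 0).all():  # pragma: no cover
            pytest.skip("degenerate draw")
        assert np.allclose(run_similarity(t).values, sk_cosine(w), atol=1e-12)

    def test_log_base_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            t = random_table(rng)
            a = run_similarity(t, log_base=math.e)
            b = run_similarity(t, log_base=2.0)
            assert np.allclose(a.values, b.values, atol=1e-12)

    def test_zero_norm_disease_warns_and_reports_zero(self):
        # every microbe of disease "a" occurs in all diseases -> all idf weights 0
        rows = [("a", "m1", 1), ("b", "m1", 1), ("c", "m1", -1),
                ("b", "m2", 1), ("c", "m3", 1)]
        t = AssociationTable(AssociationRecord(*r) for r in rows)
        with pytest.warns(UserWarning, match="zero-norm"):
            sim = run_similarity(t)
        i = sim.diseases.index("a")
        assert np.all(sim.values[i] == 0.0)

    def test_long_format_lists_each_pair_once(self, small_table):
        sim = run_similarity(small_table)
        long = sim.to_long()
        n = small_table.n_diseases
        assert len(long) == n * (n - 1) // 2
        assert (long["disease_a"] < long["disease_b"]).all()
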