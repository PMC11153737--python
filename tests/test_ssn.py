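"""Reference correlations and per-sample ΔPCC networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sfrgsn as sf


def _world(ref_cols, disease_cols, genes=("x", "y")):
    """Build a matrix/labels pair from explicit per-gene columns."""
    data = np.array(ref_cols + disease_cols, dtype=float).T
    samples = [f"n{k}" for k in range(len(ref_cols))] + \
              [f"d{k}" for k in range(len(disease_cols))]
    m = sf.ExpressionMatrix(
        pd.DataFrame(data, index=list(genes), columns=samples), unit="normalized")
    labels = sf.GroupLabels(
        {s: ("Normal" if s.startswith("n") else "D") for s in samples}, "Normal")
    return m, labels


class TestReferenceNetwork:
    def test_perfect_positive_correlation(self):
        m, labels = _world([[1, 2], [2, 4], [3, 6], [4, 8]], [[5, 10]])
        ref = sf.build_reference_network(m, labels, {("x", "y")})
        assert ref.pcc[("x", "y")] == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        m, labels = _world([[1, 4], [2, 3], [3, 2], [4, 1]], [[5, 0]])
        ref = sf.build_reference_network(m, labels, {("x", "y")})
        assert ref.pcc[("x", "y")] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, reference_world):
        m, labels, ref = reference_world
        X = m.data[labels.reference_samples].to_numpy()
        genes = m.gene_ids
        for (a, b), got in ref.pcc.items():
            xa, xb = X[genes.index(a)], X[genes.index(b)]
            cov = np.mean((xa - xa.mean()) * (xb - xb.mean()))
            expected = cov / (xa.std() * xb.std())
            assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_reference_samples(self):
        m, labels = _world([[1, 2], [2, 3]], [[3, 4]])
        with pytest.raises(ValueError, match=">= 3"):
            sf.build_reference_network(m, labels, {("x", "y")})

    def test_zero_variance_pair_excluded(self):
        m, labels = _world([[1, 5], [2, 5], [3, 5]], [[4, 5]])
        ref = sf.build_reference_network(m, labels, {("x", "y")})
        assert ("x", "y") not in ref.pcc


class TestPerturbedPcc:
    def test_equals_from_scratch_pearson(self, reference_world):
        m, labels, ref = reference_world
        genes = m.gene_ids
        X = m.data[labels.reference_samples].to_numpy()
        for sample in ["d0", "d1", "d2"]:
            col = m.data[sample].to_numpy()
            for pair in list(ref.pcc)[:10]:
                ia, ib = genes.index(pair[0]), genes.index(pair[1])
                got = sf.perturbed_pcc(ref, m, labels, sample, pair)
                xa = np.append(X[ia], col[ia])
                xb = np.append(X[ib], col[ib])
                assert got == pytest.approx(np.corrcoef(xa, xb)[0, 1], abs=1e-10)

    def test_random_instances_match_naive_recomputation(self):
        """Incremental sufficient-statistic update vs np.corrcoef from scratch."""
        rng = np.random.default_rng(23)
        worst = 0.0
        for _ in range(200):
            n_ref = int(rng.integers(3, 12))
            ref_cols = rng.normal(size=(n_ref, 2)).tolist()
            disease = rng.normal(size=(1, 2)).tolist()
            m, labels = _world(ref_cols, disease)
            ref = sf.build_reference_network(m, labels, {("x", "y")})
            if ("x", "y") not in ref.pcc:
                continue
            got = sf.perturbed_pcc(ref, m, labels, "d0", ("x", "y"))
            arr = np.array(ref_cols + disease)
            expected = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
            worst = max(worst, abs(got - expected))
        assert worst < 1e-10

    def test_collinear_appended_sample_keeps_pcc_one(self):
        m, labels = _world([[1, 2], [2, 4], [3, 6], [4, 8]], [[5, 10]])
        ref = sf.build_reference_network(m, labels, {("x", "y")})
        p1 = sf.perturbed_pcc(ref, m, labels, "d0", ("x", "y"))
        assert p1 == pytest.approx(1.0)
        assert p1 - ref.pcc[("x", "y")] == pytest.approx(0.0, abs=1e-12)

    def test_reference_sample_rejected(self, reference_world):
        m, labels, ref = reference_world
        with pytest.raises(ValueError, match="reference sample"):
            sf.perturbed_pcc(ref, m, labels, "n0", list(ref.pcc)[0])


class TestBuildSsn:
    def test_alpha_zero_gives_empty_network(self, reference_world):
        m, labels, ref = reference_world
        # alpha must be in (0,1) for the config, but build_ssn takes it raw;
        # the smallest positive alpha keeps no edge on null data either
        ssn = sf.build_ssn(ref, m, labels, "d0", alpha=1e-300)
        assert ssn.edges == {}

    def test_all_deltas_bounded_by_two(self, reference_world):
        m, labels, ref = reference_world
        ssn = sf.build_ssn(ref, m, labels, "d0", alpha=0.99)
        assert ssn.edges  # near-1 alpha stores nearly everything
        for delta, p in ssn.edges.values():
            assert abs(delta) <= 2.0
            assert 0.0 <= p <= 1.0

    def test_stored_edges_all_significant(self, reference_world):
        m, labels, ref = reference_world
        ssn = sf.build_ssn(ref, m, labels, "d1", alpha=0.4)
        assert all(p < 0.4 for _, p in ssn.edges.values())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sign_flip_antisymmetry(self, seed):
        """Negating one gene's values negates PCC_n, PCC_{n+1} and ΔPCC."""
        rng = np.random.default_rng(seed)
        ref_cols = rng.normal(size=(6, 2)).tolist()
        disease = rng.normal(size=(1, 2)).tolist()
        m, labels = _world(ref_cols, disease)
        flipped_cols = [[-a, b] for a, b in ref_cols]
        mf, _ = _world(flipped_cols, [[-disease[0][0], disease[0][1]]])
        ref = sf.build_reference_network(m, labels, {("x", "y")})
        reff = sf.build_reference_network(mf, labels, {("x", "y")})
        if ("x", "y") not in ref.pcc:
            return
        assert reff.pcc[("x", "y")] == pytest.approx(-ref.pcc[("x", "y")], abs=1e-12)
        p1 = sf.perturbed_pcc(ref, m, labels, "d0", ("x", "y"))
        p1f = sf.perturbed_pcc(reff, mf, labels, "d0", ("x", "y"))
        assert p1f == pytest.approx(-p1, abs=1e-12)

    def test_batch_matches_single(self, reference_world):
        m, labels, ref = reference_world
        batch = sf.build_ssns(ref, m, labels, ["d0", "d1"], alpha=0.5)
        single = [sf.build_ssn(ref, m, labels, s, alpha=0.5) for s in ["d0", "d1"]]
        for b, s in zip(batch, single):
            assert b.sample_id == s.sample_id
            assert b.edges == s.edges
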