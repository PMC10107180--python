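import numpy as np
import pandas as pd
import pytest

from lakejsdm import evaluate
from lakejsdm.model import PosteriorChains


def _stub_chains(beta_draws, lam=None, gamma_draws=None, columns=None, level="site"):
    """Hand-built posterior container for the deterministic metric checks."""
    nd, p, S = beta_draws.shape
    chain = {
        "beta": beta_draws,
        "gamma": gamma_draws if gamma_draws is not None else np.zeros((nd, 1, p)),
        "V": np.repeat(np.eye(p)[None], nd, axis=0),
        "rho": np.zeros(nd),
        "sigma2": np.ones((nd, S)),
    }
    level_names = []
    if lam is not None:
        chain[f"lambda_{level}"] = lam
        level_names = [level]
    meta = {
        "columns": columns or ["intercept"] + [f"x{i}" for i in range(1, p)],
        "group_map": {},
        "species": [f"sp{j}" for j in range(S)],
        "trait_names": ["intercept"],
        "level_names": level_names,
        "level_units": {level: []} if lam is not None else {},
        "family": "probit",
        "constants": {},
    }
    return PosteriorChains(
        chains=[chain],
        schedule={"per_chain": nd, "total": nd, "n_chains": 1,
                  "n_iterations": nd, "burn_in": 0, "thin": 1, "seed": 0},
        meta=meta,
    )


class TestPsrf:
    def test_identical_chains_closed_form(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((200, 5))
        out = evaluate.compute_psrf(np.stack([chain, chain]))
        n = 200
        assert np.allclose(out["psrf"], np.sqrt((n - 1) / n))
        assert (out["psrf"] <= 1.0).all()

    def test_disjoint_chains_diverge(self):
        a = np.zeros((100, 1))
        b = np.ones((100, 1))
        out = evaluate.compute_psrf(np.stack([a, b]))
        assert out["psrf"][0] > 1.1

    def test_iid_normal_near_one(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 10_000, 20))
        out = evaluate.compute_psrf(draws)
        assert 0.99 <= out["mean"] <= 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            evaluate.compute_psrf(np.zeros((1, 50, 2)))

    def test_block_access_from_chains(self, desk_fit):
        out = evaluate.compute_psrf(desk_fit["chains"], "gamma")
        assert out["n_parameters"] == np.prod(desk_fit["chains"].chains[0]["gamma"].shape[1:])
        assert np.isfinite(out["mean"])


class TestTjurR2:
    @pytest.mark.parametrize(
        "y, p, expected",
        [
            ([1, 1, 0, 0], [0.9, 0.7, 0.4, 0.2], 0.5),
            ([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3], 0.0),
            ([1, 0, 0, 1], [1.0, 0.0, 0.0, 1.0], 1.0),
        ],
    )
    def test_examples(self, y, p, expected):
        assert evaluate.tjur_r2(np.array(y), np.array(p)) == pytest.approx(expected)

    def test_single_class_flagged_nan(self):
        assert np.isnan(evaluate.tjur_r2(np.ones(4), np.full(4, 0.5)))


class TestAuc:
    @pytest.mark.parametrize(
        "y, p, expected",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
            ([1, 0, 1, 0], [0.8, 0.7, 0.6, 0.5], 0.75),
        ],
    )
    def test_examples(self, y, p, expected):
        assert evaluate.auc(np.array(y), np.array(p)) == pytest.approx(expected)

    def test_single_class_flagged_nan(self):
        assert np.isnan(evaluate.auc(np.zeros(5), np.linspace(0, 1, 5)))

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = rng.choice(np.linspace(0, 1, 11), n)  # coarse grid -> many ties
            conc = 0.0
            pairs = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    pairs += 1
                    conc += 1.0 if p[i] > p[j] else (0.5 if p[i] == p[j] else 0.0)
            assert evaluate.auc(y, p) == pytest.approx(conc / pairs)

    def test_tjur_matches_mean_difference_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 150)
        p = rng.random(150)
        expected = p[y == 1].mean() - p[y == 0].mean()
        assert evaluate.tjur_r2(y, p) == pytest.approx(expected)


class TestGaussianR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert evaluate.gaussian_r2(y, y) == 1.0

    def test_mean_prediction_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert evaluate.gaussian_r2(y, np.full(3, 2.0)) == 0.0

    def test_ss_arithmetic(self):
        assert evaluate.gaussian_r2(np.array([0.0, 1, 2]), np.array([0.0, 1, 1])) == 0.5

    def test_constant_response_fails(self):
        with pytest.raises(ValueError):
            evaluate.gaussian_r2(np.ones(5), np.zeros(5))


class TestVariancePartition:
    def test_single_group_no_random(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        beta = rng.standard_normal((3, 2, 4))
        ch = _stub_chains(beta)
        ch.meta["group_map"] = {"x1": "physico_chemical"}
        vp = evaluate.variance_partition(ch, X=X)
        assert np.allclose(vp.to_numpy(), 1.0)

    def test_orthogonal_groups_split_evenly(self):
        n = 40
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = np.column_stack([np.ones(n), a, b])
        beta = np.ones((1, 3, 2))
        ch = _stub_chains(beta, columns=["intercept", "a", "b"])
        ch.meta["group_map"] = {"a": "g1", "b": "g2"}
        vp = evaluate.variance_partition(ch, X=X)
        assert np.allclose(vp.to_numpy(), 0.5, atol=1e-9)

    def test_pure_random_level(self):
        X = np.ones((10, 1))
        beta = np.zeros((1, 1, 3))
        lam = np.zeros((1, 2, 3))
        lam[0, 0, 0] = 1.0
        lam[0, :, 1] = [0.5, 0.5]
        lam[0, 0, 2] = 2.0
        ch = _stub_chains(beta, lam=lam, columns=["intercept"])
        ch.meta["group_map"] = {}
        vp = evaluate.variance_partition(ch, X=X)
        assert np.allclose(vp["random:site"], 1.0)

    def test_rows_sum_to_one_on_random_posteriors(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.standard_normal((30, 3))])
        beta = rng.standard_normal((4, 4, 6))
        lam = rng.standard_normal((4, 2, 6))
        ch = _stub_chains(beta, lam=lam, columns=["intercept", "a", "b", "c"])
        ch.meta["group_map"] = {"a": "g1", "b": "g1", "c": "g2"}
        vp = evaluate.variance_partition(ch, X=X)
        assert np.allclose(vp.sum(axis=1), 1.0, atol=1e-9)
        assert (vp.to_numpy() >= 0).all() and (vp.to_numpy() <= 1).all()

    def test_group_map_gap_fails(self):
        X = np.ones((10, 2))
        ch = _stub_chains(np.zeros((1, 2, 2)))
        ch.meta["group_map"] = {}
        with pytest.raises(KeyError):
            evaluate.variance_partition(ch, X=X)


class TestTraitVariance:
    def test_beta_equal_to_mean_gives_one(self):
        rng = np.random.default_rng(0)
        T = np.column_stack([np.ones(8), rng.standard_normal(8)])
        gamma = rng.standard_normal((1, 2, 3))
        mu = np.swapaxes(T @ gamma[0], 0, 1)  # p x S
        ch = _stub_chains(mu[None], gamma_draws=gamma, columns=["intercept", "x1", "x2"])
        out = evaluate.trait_variance_explained(ch, T)
        assert np.allclose(out["per_covariate"], 1.0)
        assert out["overall_weighted"] == pytest.approx(1.0)

    def test_zero_gamma_gives_zero(self):
        rng = np.random.default_rng(1)
        T = np.column_stack([np.ones(8), rng.standard_normal(8)])
        beta = rng.standard_normal((2, 3, 8))
        ch = _stub_chains(beta, gamma_draws=np.zeros((2, 2, 3)))
        out = evaluate.trait_variance_explained(ch, T)
        assert np.allclose(out["per_covariate"], 0.0)

    def test_matches_generator_ratio_at_the_truth(self, desk_bundle):
        # posterior concentrated at the generating parameters must reproduce
        # the generator-side analytic variance ratio exactly
        from lakejsdm.preprocess import build_trait_matrix

        truth = desk_bundle["truth"]
        T, _ = build_trait_matrix(desk_bundle["traits"])
        beta = truth.beta.to_numpy()[None]
        gamma = truth.gamma.to_numpy()[None]
        ch = _stub_chains(beta, gamma_draws=gamma,
                          columns=list(truth.beta.index))
        out = evaluate.trait_variance_explained(ch, T)
        expected = truth.trait_variance_fraction
        assert np.allclose(out["per_covariate"].to_numpy(), expected.to_numpy(),
                           atol=1e-10)

    def test_fitted_estimate_tracks_trait_signal(self, desk_fit):
        # the fitted posterior quantity is upward-biased at desk scale
        # (beta shrinks toward the trait mean; clumped traits absorb
        # phylogenetic structure) but must stay in [0, 1] and exceed the
        # no-signal floor where the generator planted signal
        out = evaluate.trait_variance_explained(desk_fit["chains"], desk_fit["data"].T)
        truth = desk_fit["bundle"]["truth"].trait_variance_fraction
        per = out["per_covariate"]
        assert ((per >= 0) & (per <= 1)).all()
        assert per["temperature"] > truth["temperature"] - 0.1
        assert 0.0 < out["overall_weighted"] < 1.0


class TestResidualAssociations:
    def test_single_positive_factor_full_support(self):
        lam = np.abs(np.random.default_rng(0).standard_normal((3, 1, 4))) + 0.1
        ch = _stub_chains(np.zeros((3, 1, 4)), lam=lam, columns=["intercept"])
        out = evaluate.residual_associations(ch, "site")
        assert np.allclose(out["correlation"].to_numpy(), 1.0)
        assert np.allclose(out["support"].to_numpy(), 1.0)

    def test_opposite_signs_negative_call(self):
        lam = np.zeros((5, 1, 2))
        lam[:, 0, 0] = 1.0
        lam[:, 0, 1] = -1.0
        ch = _stub_chains(np.zeros((5, 1, 2)), lam=lam)
        out = evaluate.residual_associations(ch, "site")
        assert out["support"].iloc[0, 1] == 0.0
        assert out["sign"].iloc[0, 1] == -1

    def test_matches_direct_matrix_arithmetic(self):
        lam = np.array([[[0.5, -0.2, 0.8], [0.1, 0.9, -0.4]]])  # 1 draw, 2 factors
        ch = _stub_chains(np.zeros((1, 1, 3)), lam=lam)
        out = evaluate.residual_associations(ch, "site")
        om = lam[0].T @ lam[0]
        dd = np.sqrt(np.diag(om))
        expected = om / np.outer(dd, dd)
        assert np.allclose(out["correlation"].to_numpy(), expected)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        lam = rng.standard_normal((4, 3, 6))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        lam_rot = np.einsum("hk,dks->dhs", Q, lam)
        ch1 = _stub_chains(np.zeros((4, 1, 6)), lam=lam)
        ch2 = _stub_chains(np.zeros((4, 1, 6)), lam=lam_rot)
        r1 = evaluate.residual_associations(ch1, "site")["correlation"]
        r2 = evaluate.residual_associations(ch2, "site")["correlation"]
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_missing_level_fails(self):
        ch = _stub_chains(np.zeros((1, 1, 2)))
        with pytest.raises(KeyError):
            evaluate.residual_associations(ch, "watershed")


class TestCoefficientSupport:
    def test_all_positive(self):
        beta = np.abs(np.random.default_rng(0).standard_normal((20, 2, 3))) + 0.01
        out = evaluate.coefficient_support(_stub_chains(beta))
        assert np.allclose(out["support"].to_numpy(), 1.0)
        assert (out["sign"].to_numpy() == 1).all()

    def test_symmetric_draws_no_call(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal((250, 1, 1))
        beta = np.concatenate([half, -half])
        out = evaluate.coefficient_support(_stub_chains(beta))
        assert out["support"].iloc[0, 0] == pytest.approx(0.5, abs=0.05)
        assert out["sign"].iloc[0, 0] == 0

    def test_counting(self):
        beta = np.ones((100, 1, 1))
        beta[:4] = -1.0
        out = evaluate.coefficient_support(_stub_chains(beta))
        assert out["support"].iloc[0, 0] == pytest.approx(0.96)
        assert out["sign"].iloc[0, 0] == 1


class TestLabelInvariance:
    def test_species_permutation_permutes_outputs(self, desk_fit):
        ch = desk_fit["chains"]
        X = desk_fit["dm"].X
        vp = evaluate.variance_partition(ch, X=X)
        perm = np.random.default_rng(0).permutation(len(vp))
        # permuting the posterior's species axis permutes the partition rows
        import copy

        ch2 = PosteriorChains(
            chains=[
                {k: (v[:, :, perm] if k == "beta" else
                     v[:, :, perm] if k.startswith("lambda_") else v)
                 for k, v in c.items()}
                for c in ch.chains
            ],
            schedule=ch.schedule,
            meta={**ch.meta, "species": [ch.meta["species"][i] for i in perm]},
        )
        vp2 = evaluate.variance_partition(ch2, X=X)
        assert np.allclose(vp2.to_numpy(), vp.to_numpy()[perm])
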