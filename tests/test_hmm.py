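"""HMM model types, likelihood/decoding oracles, training and domain calling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fourc import hmm, normalize
from fourc.fragmap import FragmentCounts, FragmentMap, PotentialFragment
from fourc.hmm import (
    HI,
    NI,
    CisModel,
    StatePath,
    TransModel,
    bootstrap_training_sample,
    call_domains,
    fit,
    init_params_cis,
    init_params_trans,
    loglik,
    n_parameters,
    sample_observations,
    viterbi,
)
from fourc.normalize import ObservationMatrix
from fourc.windows import Window, WindowSet


def make_cis(pi=(1 / 3, 1 / 3, 1 / 3), A=None,
             beta0=(0.5, 1.2, 2.0), beta1=(-0.1, -0.12, -0.15),
             sigma=(0.3, 0.3, 0.3)):
    A = A if A is not None else hmm._INIT_A
    return CisModel(np.array(pi), np.array(A), np.array(beta0),
                    np.array(beta1), np.array(sigma))


def make_trans(pi=(1 / 3, 1 / 3, 1 / 3), A=None,
               mu=(0.2, 0.8, 1.6), sigma=(0.25, 0.25, 0.25)):
    A = A if A is not None else hmm._INIT_A
    return TransModel(np.array(pi), np.array(A), np.array(mu), np.array(sigma))


# --------------------------------------------------------------------------- #
# exhaustive-path oracles
# --------------------------------------------------------------------------- #

def path_likelihoods(model, x, z):
    """Joint likelihood of every one of the 3^T state paths, by brute force."""
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    T = x.shape[0]
    if isinstance(model, CisModel):
        mu = model.beta0[None, :] + model.beta1[None, :] * np.asarray(z)[:, None]
    else:
        mu = np.broadcast_to(model.mu, (T, 3))
    out = {}
    for path in itertools.product(range(3), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t, s in enumerate(path):
            for m in range(x.shape[1]):
                p *= stats.norm.pdf(x[t, m], mu[t, s], model.sigma[s])
        out[path] = p
    return out


# --------------------------------------------------------------------------- #
# model types & parameter counting
# --------------------------------------------------------------------------- #

class TestModels:
    def test_parameter_counts(self):
        assert n_parameters(make_cis()) == 21
        assert n_parameters(make_trans()) == 18

    def test_constraint_validation(self):
        with pytest.raises(ValueError, match="beta0"):
            make_cis(beta0=(0.5, 0.55, 2.0))     # gap below eps 0.1
        with pytest.raises(ValueError, match="beta1"):
            make_cis(beta1=(-0.1, 0.01, -0.1))
        with pytest.raises(ValueError, match="mu"):
            make_trans(mu=(0.2, 0.22, 1.6))      # gap below eps 0.05
        with pytest.raises(ValueError, match="sigma"):
            make_cis(sigma=(0.3, 0.0, 0.3))
        with pytest.raises(ValueError, match="pi"):
            make_cis(pi=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="stochastic"):
            make_cis(A=np.full((3, 3), 0.5))

    def test_slack_boundary_allowed(self):
        m = make_cis(beta0=(0.5, 0.6, 0.7))      # gaps exactly eps
        assert m.beta0[1] - m.beta0[0] == pytest.approx(0.1)
        make_trans(mu=(0.2, 0.25, 0.30))

    def test_serialization_round_trip(self):
        d = make_cis().to_dict()
        assert d["kind"] == "cis" and len(d["beta0"]) == 3
        d2 = make_trans().to_dict()
        assert d2["kind"] == "trans" and d2["eps_mu"] == 0.05


# --------------------------------------------------------------------------- #
# likelihood
# --------------------------------------------------------------------------- #

class TestLoglik:
    def test_single_observation_closed_form(self):
        m = make_cis(pi=(1.0, 0.0, 0.0))
        x, z = np.array([[0.7]]), np.array([4.0])
        expected = stats.norm.logpdf(0.7, m.beta0[0] + m.beta1[0] * 4.0, m.sigma[0])
        assert loglik(m, x, z) == pytest.approx(float(expected))

    def test_duplicated_replicate_doubles_emission_term(self):
        m = make_trans(pi=(1.0, 0.0, 0.0))
        x1 = np.array([[0.4]])
        x2 = np.array([[0.4, 0.4]])
        assert loglik(m, x2) == pytest.approx(2 * loglik(m, x1))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            T = int(rng.integers(2, 7))
            m = make_cis()
            z = np.sort(rng.uniform(3, 6, T))[::-1].copy()
            x = rng.normal(1.0, 0.8, size=(T, 2))
            brute = np.log(sum(path_likelihoods(m, x, z).values()))
            assert loglik(m, x, z) == pytest.approx(brute, rel=1e-9)

    def test_chains_sum(self):
        m = make_trans()
        rng = np.random.default_rng(12)
        a = ObservationMatrix(rng.normal(0.8, 0.5, size=(5, 1)))
        b = ObservationMatrix(rng.normal(0.8, 0.5, size=(7, 1)))
        assert hmm.loglik_chains(m, [a, b]) == pytest.approx(
            loglik(m, a) + loglik(m, b))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            loglik(make_trans(), np.array([[np.inf]]))

    def test_cis_needs_covariate(self):
        with pytest.raises(ValueError, match="covariate"):
            loglik(make_cis(), np.array([[0.5]]))


# --------------------------------------------------------------------------- #
# Viterbi
# --------------------------------------------------------------------------- #

class TestViterbi:
    def test_well_separated_all_hi(self):
        m = make_trans(mu=(0.0, 1.0, 3.0), sigma=(0.1, 0.1, 0.1))
        x = np.full((20, 1), 3.0)
        (path,) = viterbi(m, x)
        assert (path.states == HI).all()

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            T = int(rng.integers(2, 7))
            m = make_trans()
            x = rng.normal(0.9, 0.7, size=(T, 1))
            brute = path_likelihoods(m, x, None)
            best = max(brute, key=brute.get)
            (path,) = viterbi(m, x)
            assert tuple(path.states - 1) == best
            assert path.logp == pytest.approx(np.log(brute[best]), rel=1e-9)

    def test_ties_break_to_lower_state(self):
        # x exactly midway between mu_1 and mu_2 with equal sigmas and a
        # symmetric chain: states 1 and 2 tie, state 1 must win
        m = make_trans(mu=(0.0, 1.0, 3.0), sigma=(0.2, 0.2, 0.2),
                       A=np.full((3, 3), 1 / 3))
        (path,) = viterbi(m, np.array([[0.5], [0.5]]))
        assert (path.states == NI).all()

    def test_replicates_decoded_independently(self):
        m = make_trans(mu=(0.0, 1.0, 3.0), sigma=(0.1, 0.1, 0.1))
        x = np.column_stack([np.full(10, 0.0), np.full(10, 3.0)])
        p1, p2 = viterbi(m, x)
        assert (p1.states == NI).all() and (p2.states == HI).all()


# --------------------------------------------------------------------------- #
# initial parameters
# --------------------------------------------------------------------------- #

class TestInit:
    def _sim_obs(self, seed=21, T=600):
        rng = np.random.default_rng(seed)
        true = make_cis(beta0=(0.8, 1.4, 2.1), beta1=(-0.15, -0.15, -0.15),
                        sigma=(0.2, 0.2, 0.2),
                        A=[[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        z = np.sort(rng.uniform(3, 6, T))
        _, obs = sample_observations(true, T, 1, rng, z=z)
        return true, obs

    def test_pi_and_A_exact(self):
        _, obs = self._sim_obs()
        m0 = init_params_cis(obs)
        assert np.array_equal(m0.pi, [1 / 3, 1 / 3, 1 / 3])
        assert np.array_equal(m0.A, [[0.50, 0.25, 0.25],
                                     [0.25, 0.50, 0.25],
                                     [0.25, 0.25, 0.50]])

    def test_intercept_scaling_exact(self):
        _, obs = self._sim_obs()
        m0 = init_params_cis(obs)
        # the 0.8/0.5 scaling holds unless the gap-repair had to kick in
        assert m0.beta0[1] == pytest.approx(0.8 * m0.beta0[2])
        assert m0.beta0[0] == pytest.approx(0.5 * m0.beta0[2])
        assert (m0.beta1 < 0).all()

    def test_slope_recovered_within_20pct(self):
        # pure linear decay: every observation on the line plus noise, so the
        # top-decile regression sees the true slope (selection is local in z)
        rng = np.random.default_rng(24)
        z = np.sort(rng.uniform(3, 6, 600))
        x = (2.1 - 0.15 * z + rng.normal(0, 0.2, 600))[:, None]
        m0 = init_params_cis(x, z=z)
        assert m0.beta1[2] == pytest.approx(-0.15, rel=0.20)

    def test_short_input_single_segment_warning(self):
        rng = np.random.default_rng(22)
        x = rng.normal(1.0, 0.5, size=(10, 1))
        with pytest.warns(UserWarning, match="fewer than 30"):
            init_params_trans(x)

    def test_trans_init_ordered(self):
        rng = np.random.default_rng(23)
        x = rng.normal(1.0, 0.6, size=(90, 2))
        m0 = init_params_trans(x)
        assert (np.diff(m0.mu) >= m0.eps_mu - 1e-9).all()
        assert (m0.sigma >= hmm.SIGMA_FLOOR).all()


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #

class TestFit:
    def test_loglik_never_decreases_and_constraints_hold(self):
        rng = np.random.default_rng(31)
        true = make_trans(mu=(0.2, 0.9, 1.8), sigma=(0.2, 0.2, 0.2),
                          A=[[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        _, obs = sample_observations(true, 400, 1, rng)
        m0 = init_params_trans(obs)
        fitted = fit(m0, obs)
        assert fitted.meta["loglik"] >= fitted.meta["loglik0"] - 1e-6
        hmm.validate_trans(fitted)          # would raise on violation
        assert (np.diff(fitted.mu) >= fitted.eps_mu - 1e-9).all()

    def test_diagonal_dominance_recovered(self):
        rng = np.random.default_rng(32)
        true = make_trans(mu=(0.1, 0.9, 2.0), sigma=(0.15, 0.15, 0.15),
                          A=[[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        _, obs = sample_observations(true, 800, 1, rng)
        fitted = fit(init_params_trans(obs), obs)
        for i in range(3):
            assert all(fitted.A[i, i] > fitted.A[i, j] for j in range(3) if j != i)

    def test_cis_fit_respects_sign_constraint(self):
        rng = np.random.default_rng(33)
        true = make_cis(beta0=(0.8, 1.4, 2.1), beta1=(-0.14,) * 3, sigma=(0.2,) * 3,
                        A=[[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        z = np.sort(rng.uniform(3, 6, 500))
        _, obs = sample_observations(true, 500, 1, rng, z=z)
        fitted = fit(init_params_cis(obs), obs)
        assert (fitted.beta1 < 0).all()
        assert (np.diff(fitted.beta0) >= fitted.eps_beta - 1e-9).all()
        assert fitted.meta["loglik"] >= fitted.meta["loglik0"] - 1e-6


# --------------------------------------------------------------------------- #
# bootstrap training sample
# --------------------------------------------------------------------------- #

def _lattice_dataset(n_frag=400, step=25, values=(3, 9)):
    """Dense fragment lattice plus two replicates with constant counts."""
    frags = [PotentialFragment("c", i * step, i * step + 10, "down", f"S{i}", True)
             for i in range(n_frag)]
    fmap = FragmentMap(frags)
    reps = [FragmentCounts(f"r{j+1}", fmap, np.full(n_frag, v), bait=("c", 0))
            for j, v in enumerate(values)]
    span = n_frag * step
    wins = [Window("c", s, s + 100, i, "right")
            for i, s in enumerate(range(0, span - 100, 50))]
    ws = WindowSet("c", wins, "nearbait", 5, bait_pos=0)
    return fmap, reps, ws


class TestBootstrap:
    def test_deterministic(self):
        _, reps, ws = _lattice_dataset()
        a = bootstrap_training_sample(reps, ws, "nearbait", seed=5, bait_pos=0)
        b = bootstrap_training_sample(reps, ws, "nearbait", seed=5, bait_pos=0)
        assert np.array_equal(a[0].x, b[0].x)
        c = bootstrap_training_sample(reps, ws, "nearbait", seed=6, bait_pos=0)
        assert not np.array_equal(a[0].x, c[0].x)

    def test_identical_replicates_invariance(self):
        _, reps, ws = _lattice_dataset(values=(7, 7))
        (chain,) = bootstrap_training_sample(reps, ws, "nearbait", seed=5, bait_pos=0)
        matrix = normalize.window_counts(reps, ws, bait_pos=0)
        normalize.size_factors(matrix)
        obs = normalize.make_observations(matrix)
        assert chain.x[:, 0] == pytest.approx(obs.x[:, 0])

    def test_replicate_choice_frequencies(self):
        # distinguishable replicates: block-level choices are Bernoulli(1/2)
        _, reps, ws = _lattice_dataset(n_frag=4000, values=(3, 9))
        (chain,) = bootstrap_training_sample(reps, ws, "nearbait", seed=7, bait_pos=0)
        x = chain.x[:, 0]
        lo, hi = x.min(), x.max()
        # pure windows take one of two constants; windows straddling a block
        # boundary mix the two replicates and land strictly in between
        n_lo = int((x == lo).sum())
        n_hi = int((x == hi).sum())
        n = n_lo + n_hi
        assert n >= 500
        assert abs(n_hi / n - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_single_replicate_refused(self):
        _, reps, ws = _lattice_dataset()
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_training_sample(reps[:1], ws, "nearbait", seed=1, bait_pos=0)


# --------------------------------------------------------------------------- #
# domain calling
# --------------------------------------------------------------------------- #

def _ws(intervals, side="right"):
    wins = [Window("c", s, e, i, side) for i, (s, e) in enumerate(intervals)]
    return WindowSet("c", wins, "nearbait", 5, bait_pos=0)


class TestCallDomains:
    def test_merge_both_hi(self):
        ws = _ws([(0, 100), (50, 150)])
        paths = {"r1": StatePath([3, 3], 0.0), "r2": StatePath([3, 3], 0.0)}
        d = call_domains(paths, ws)
        assert d.consensus == [(0, 150)]

    def test_trim_against_ni_neighbor(self):
        ws = _ws([(0, 100), (50, 150)])
        paths = {"r1": StatePath([3, 1], 0.0)}
        d = call_domains(paths, ws)
        assert d.replicate_domains["r1"] == [(0, 50)]

    def test_consensus_is_intersection(self):
        ws = _ws([(0, 100), (50, 150)])
        paths = {"rA": StatePath([3, 1], 0.0),   # domain [0,50)
                 "rB": StatePath([1, 3], 0.0)}   # domain [100,150)
        d = call_domains(paths, ws)
        assert d.replicate_domains["rA"] == [(0, 50)]
        assert d.replicate_domains["rB"] == [(100, 150)]
        assert d.consensus == []

    def test_replicate_intersection_example(self):
        # A calls [0,100), B calls [50,150): consensus [50,100)
        ws = _ws([(0, 100), (50, 150)])
        paths = {"rA": StatePath([3, 1], 0.0), "rB": StatePath([3, 3], 0.0)}
        d = call_domains(paths, ws)
        assert d.replicate_domains["rA"] == [(0, 50)]
        assert d.replicate_domains["rB"] == [(0, 150)]
        assert d.consensus == [(0, 50)]

    def test_hi_window_trimmed_away_entirely(self):
        # an HI window fully covered by conflicting neighbours disappears
        ws = _ws([(0, 100), (40, 80), (60, 160)])
        paths = {"r": StatePath([1, 3, 1], 0.0)}
        d = call_domains(paths, ws)
        assert d.replicate_domains["r"] == []

    def test_monotone_in_hi_calls(self):
        ws = _ws([(0, 100), (50, 150), (100, 200)])
        fewer = call_domains({"r": StatePath([1, 3, 1], 0.0)}, ws)
        more = call_domains({"r": StatePath([3, 3, 3], 0.0)}, ws)
        from fourc import intervals
        assert intervals.total_bp(more.replicate_domains["r"]) >= \
            intervals.total_bp(fewer.replicate_domains["r"])

    def test_length_mismatch_rejected(self):
        ws = _ws([(0, 100), (50, 150)])
        with pytest.raises(ValueError, match="length"):
            call_domains({"r": StatePath([3], 0.0)}, ws)

    def test_sides_trimmed_independently(self):
        wins = [Window("c", 0, 100, 0, "left"), Window("c", 100, 200, 1, "right")]
        ws = WindowSet("c", wins, "nearbait", 5, bait_pos=100)
        # the right HI window must not be trimmed by the left NI window
        d = call_domains({"r": StatePath([1, 3], 0.0)}, ws)
        assert d.replicate_domains["r"] == [(100, 200)]
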