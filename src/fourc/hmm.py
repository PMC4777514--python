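"""Three-state Gaussian hidden Markov models for 4C-Seq interaction calling.

The hidden states are NI (1, no interaction), LI (2, low interaction)
and HI (3, high interaction) with the bait.  Two model variants share
the chain structure but differ in emissions:

* cis (covariate-adjusted): in state i the log-normalized window count
  is Gaussian with mean ``beta0_i + beta1_i * z`` where z is the log10
  distance from the bait, capturing the contact-decay with distance.
  The free parameters are pi (3), A (9), three (beta0, beta1) pairs and
  three sigmas: 21 in total.
* trans: state means are constants mu_i (no covariate), 18 parameters.

Biological replicates are conditionally independent given the state and
share the emission parameters.  Training maximizes the forward
log-likelihood on a bootstrap synthetic sample under consistency
constraints that keep the states ordered and the distance decay
negative: beta0_1 + eps <= beta0_2, beta0_2 + eps <= beta0_3 (eps =
0.1), beta1_i < 0 in cis; mu_1 + eps <= mu_2 <= mu_3 - eps (eps = 0.05)
in trans.  Constraints are enforced by reparameterization (softmax for
pi and rows of A; log-gap offsets for the ordered means; log for
sigmas), so any fitted model is feasible by construction.  State
assignment uses the Viterbi algorithm per replicate; ties break toward
the lower state index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from fourc import intervals
from fourc.fragmap import FragmentCounts
from fourc.normalize import ObservationMatrix, WindowCountMatrix, size_factors, window_counts
from fourc.windows import WindowSet

NI, LI, HI = 1, 2, 3
EPS_BETA = 0.1
EPS_MU = 0.05
SIGMA_FLOOR = 0.05

_LOG_2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------- #
# model types
# --------------------------------------------------------------------------- #

@dataclass
class CisModel:
    """Covariate-adjusted cis HMM parameters."""

    pi: np.ndarray                  # (K,) simplex
    A: np.ndarray                   # (K,K) row-stochastic
    beta0: np.ndarray               # (K,) intercepts, strictly increasing with slack
    beta1: np.ndarray               # (K,) slopes, all < 0
    sigma: np.ndarray               # (K,) emission SDs > 0
    eps_beta: float = EPS_BETA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pi", "A", "beta0", "beta1", "sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        validate_cis(self)

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def means(self, z: np.ndarray) -> np.ndarray:
        """State means at covariate z: shape (T, K)."""
        z = np.asarray(z, dtype=float)
        return self.beta0[None, :] + self.beta1[None, :] * z[:, None]

    def to_dict(self) -> dict:
        return {
            "kind": "cis", "pi": self.pi.tolist(), "A": self.A.tolist(),
            "beta0": self.beta0.tolist(), "beta1": self.beta1.tolist(),
            "sigma": self.sigma.tolist(), "eps_beta": self.eps_beta,
            "meta": {k: v for k, v in self.meta.items()},
        }


@dataclass
class TransModel:
    """Constant-mean trans HMM parameters."""

    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray                  # (K,) ordered with slack
    sigma: np.ndarray
    eps_mu: float = EPS_MU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pi", "A", "mu", "sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        validate_trans(self)

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def means(self, z=None) -> np.ndarray:
        return self.mu[None, :]

    def to_dict(self) -> dict:
        return {
            "kind": "trans", "pi": self.pi.tolist(), "A": self.A.tolist(),
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "eps_mu": self.eps_mu, "meta": {k: v for k, v in self.meta.items()},
        }


def validate_cis(m: CisModel) -> None:
    _validate_chain(m.pi, m.A)
    if (m.sigma <= 0).any():
        raise ValueError("sigma must be positive")
    gaps = np.diff(m.beta0)
    if (gaps < m.eps_beta - 1e-9).any():
        raise ValueError(f"beta0 must increase by at least eps={m.eps_beta}: {m.beta0}")
    if (m.beta1 >= 0).any():
        raise ValueError(f"beta1 must be negative: {m.beta1}")


def validate_trans(m: TransModel) -> None:
    _validate_chain(m.pi, m.A)
    if (m.sigma <= 0).any():
        raise ValueError("sigma must be positive")
    if (np.diff(m.mu) < m.eps_mu - 1e-9).any():
        raise ValueError(f"mu must increase by at least eps={m.eps_mu}: {m.mu}")


def _validate_chain(pi, A) -> None:
    if not np.isclose(pi.sum(), 1.0) or (pi < -1e-12).any():
        raise ValueError(f"pi must be a probability vector: {pi}")
    if not np.allclose(A.sum(axis=1), 1.0) or (A < -1e-12).any():
        raise ValueError("A must be row-stochastic")


def n_parameters(model: CisModel | TransModel) -> int:
    """Free-parameter count by the convention that lists every entry of
    pi and A plus the emission parameters (21 cis, 18 trans for K=3)."""
    k = model.n_states
    emission = (2 * k + k) if isinstance(model, CisModel) else (k + k)
    return k + k * k + emission


@dataclass
class StatePath:
    """Viterbi decoding of one replicate."""

    states: np.ndarray              # (T,) values in {1, 2, 3}
    logp: float                     # joint log-probability of the best path

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if ((self.states < 1) | (self.states > 3)).any():
            raise ValueError("states must be in {1,2,3}")


@dataclass
class DomainSet:
    """High-interaction intervals per replicate plus the consensus."""

    chrom: str
    replicate_domains: dict[str, list[tuple[int, int]]]
    consensus: list[tuple[int, int]]
    mode: str = "cis"

    def to_bed(self, path, which: str = "consensus") -> None:
        ivs = self.consensus if which == "consensus" else self.replicate_domains[which]
        with open(path, "w") as fh:
            for s, e in ivs:
                fh.write(f"{self.chrom}\t{s}\t{e}\tHI\n")


# --------------------------------------------------------------------------- #
# numba kernels
# --------------------------------------------------------------------------- #

@njit(cache=True)
def _forward_logspace(log_pi, log_A, logB):
    # scaled linear-space forward recursion; emissions stay in log space and
    # are shifted by their per-step maximum before exponentiation
    T, K = logB.shape
    A = np.exp(log_A)
    rowmax = logB[0].max()
    alpha = np.exp(log_pi + logB[0] - rowmax)
    norm = alpha.sum()
    if norm <= 0.0 or not np.isfinite(norm):
        return -np.inf
    alpha /= norm
    total = rowmax + np.log(norm)
    new = np.empty(K)
    for t in range(1, T):
        rowmax = logB[t].max()
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[i] * A[i, j]
            new[j] = acc * np.exp(logB[t, j] - rowmax)
        norm = new.sum()
        if norm <= 0.0 or not np.isfinite(norm):
            return -np.inf
        for j in range(K):
            alpha[j] = new[j] / norm
        total += rowmax + np.log(norm)
    return total


@njit(cache=True)
def _viterbi_kernel(log_pi, log_A, logB):
    T, K = logB.shape
    delta = log_pi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best_i = 0
            best = delta[0] + log_A[0, j]
            for i in range(1, K):
                v = delta[i] + log_A[i, j]
                if v > best:        # strict: ties keep the lower state index
                    best, best_i = v, i
            new[j] = best + logB[t, j]
            back[t, j] = best_i
        delta = new
    path = np.zeros(T, dtype=np.int64)
    best_i = 0
    best = delta[0]
    for i in range(1, K):
        if delta[i] > best:
            best, best_i = delta[i], i
    path[T - 1] = best_i
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


# --------------------------------------------------------------------------- #
# likelihood, decoding
# --------------------------------------------------------------------------- #

def _as_columns(x) -> np.ndarray:
    """Coerce observations to (T, M); a 1-D vector is one replicate."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("observations must be (T, M)")
    return x


def _log_emissions(model, x: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    """(T, K) log emission densities, replicates conditionally independent."""
    x = _as_columns(x)
    if not np.isfinite(x).all():
        raise ValueError("non-finite observations")
    T, M = x.shape
    if isinstance(model, CisModel):
        if z is None:
            raise ValueError("cis model requires the distance covariate")
        mu = model.means(z)                         # (T, K)
    else:
        mu = np.broadcast_to(model.means(), (T, model.n_states))
    sig = model.sigma[None, :]
    # sum over replicates of N(x_m; mu, sigma^2) in log space
    resid = (x[:, :, None] - mu[:, None, :]) / sig[:, None, :]
    logB = -0.5 * (resid ** 2) - np.log(sig)[:, None, :] - 0.5 * _LOG_2PI
    return logB.sum(axis=1)


def _unpack_obs(obs):
    if isinstance(obs, ObservationMatrix):
        return obs.x, obs.z
    return np.asarray(obs, dtype=float), None


def loglik(model, obs, z=None) -> float:
    """Forward-algorithm log-likelihood of (possibly multi-replicate) observations."""
    x, z_obs = _unpack_obs(obs)
    z = z if z is not None else z_obs
    logB = _log_emissions(model, x, z)
    with np.errstate(divide="ignore"):
        return float(_forward_logspace(np.log(model.pi), np.log(model.A), logB))


def loglik_chains(model, chains) -> float:
    """Sum of independent-chain log-likelihoods (e.g. one per trans chromosome)."""
    return sum(loglik(model, c) for c in chains)


def viterbi(model, obs, z=None) -> list[StatePath]:
    """Decode each replicate column separately against the shared model."""
    x, z_obs = _unpack_obs(obs)
    z = z if z is not None else z_obs
    x = _as_columns(x)
    paths = []
    with np.errstate(divide="ignore"):
        log_pi, log_A = np.log(model.pi), np.log(model.A)
    for m in range(x.shape[1]):
        logB = _log_emissions(model, x[:, [m]], z)
        states, logp = _viterbi_kernel(log_pi, log_A, logB)
        paths.append(StatePath(states + 1, float(logp)))
    return paths


# --------------------------------------------------------------------------- #
# initial parameters
# --------------------------------------------------------------------------- #

_INIT_PI = np.array([1 / 3, 1 / 3, 1 / 3])
_INIT_A = np.array([[0.50, 0.25, 0.25],
                    [0.25, 0.50, 0.25],
                    [0.25, 0.25, 0.50]])
SEGMENT_WINDOWS = 30
_Q_SPLIT = (0.60, 0.90)


def _quantile_classes(x: np.ndarray, z: np.ndarray | None):
    """Split observations into NI/LI/HI classes by per-segment quantiles.

    The chromosome is divided into 30-window segments; within each,
    observations below the 60th quantile are NI, between the 60th and
    90th LI, above the 90th HI.
    """
    T, M = x.shape
    if T < SEGMENT_WINDOWS:
        import warnings
        warnings.warn("fewer than 30 windows: using a single segment", stacklevel=3)
    xs = [[] for _ in range(3)]
    zs = [[] for _ in range(3)]
    for seg_start in range(0, T, SEGMENT_WINDOWS):
        seg = slice(seg_start, min(T, seg_start + SEGMENT_WINDOWS))
        vals = x[seg].ravel()
        q60, q90 = np.quantile(vals, _Q_SPLIT)
        for t in range(seg.start, seg.stop):
            for m in range(M):
                v = x[t, m]
                i = 0 if v <= q60 else (1 if v <= q90 else 2)
                xs[i].append(v)
                if z is not None:
                    zs[i].append(z[t])
    return [np.array(a) for a in xs], [np.array(a) for a in zs]


def init_params_cis(obs, z=None, eps_beta: float = EPS_BETA) -> CisModel:
    """Quantile-based starting values for the cis model.

    An OLS fit to the top-decile (z, x) pairs gives (beta0_3, beta1_3);
    the lower intercepts are scaled as beta0_2 = 0.8*beta0_3 and
    beta0_1 = 0.5*beta0_3 to start well inside the constraint region,
    and all slopes start at the HI slope (clipped negative).
    """
    x, z_obs = _unpack_obs(obs)
    z = z if z is not None else z_obs
    if z is None:
        raise ValueError("cis initialization needs the distance covariate")
    x = _as_columns(x)
    z = np.asarray(z, dtype=float)
    xs, zs = _quantile_classes(x, z)

    zhi, xhi = zs[2], xs[2]
    if len(xhi) >= 2 and np.ptp(zhi) > 0:
        slope, intercept = np.polyfit(zhi, xhi, 1)
    else:
        slope, intercept = -0.1, float(np.mean(xhi) if len(xhi) else 1.0)
    beta1_3 = min(slope, -1e-3)
    beta0_3 = float(intercept)
    beta0 = np.array([0.5 * beta0_3, 0.8 * beta0_3, beta0_3])
    beta1 = np.full(3, beta1_3)

    sigma = np.empty(3)
    for i in range(3):
        if len(xs[i]) >= 2:
            resid = xs[i] - (beta0[i] + beta1[i] * zs[i])
            sigma[i] = max(resid.std(), SIGMA_FLOOR)
        else:
            sigma[i] = 0.2
    beta0 = _repair_gaps(beta0, eps_beta)
    return CisModel(_INIT_PI.copy(), _INIT_A.copy(), beta0, beta1, sigma,
                    eps_beta=eps_beta)


def init_params_trans(obs, eps_mu: float = EPS_MU) -> TransModel:
    """Quantile-based starting values for the trans model."""
    x, _ = _unpack_obs(obs)
    x = _as_columns(x)
    xs, _ = _quantile_classes(x, None)
    mu = np.array([np.mean(a) if len(a) else i * 0.5 for i, a in enumerate(xs)])
    sigma = np.array([max(a.std(), SIGMA_FLOOR) if len(a) >= 2 else 0.2 for a in xs])
    mu = _repair_gaps(mu, eps_mu)
    return TransModel(_INIT_PI.copy(), _INIT_A.copy(), mu, sigma, eps_mu=eps_mu)


def _repair_gaps(means: np.ndarray, eps: float) -> np.ndarray:
    """Push ordered means apart until consecutive gaps are at least eps."""
    out = means.astype(float).copy()
    for i in range(1, len(out)):
        if out[i] - out[i - 1] < eps:
            out[i] = out[i - 1] + eps * 1.01
    return out


# --------------------------------------------------------------------------- #
# constrained maximum-likelihood fitting
# --------------------------------------------------------------------------- #

def _softmax(u):
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def _pack_cis(m: CisModel) -> np.ndarray:
    g2 = np.log(max(m.beta0[1] - m.beta0[0] - m.eps_beta, 1e-8))
    g3 = np.log(max(m.beta0[2] - m.beta0[1] - m.eps_beta, 1e-8))
    with np.errstate(divide="ignore"):
        u_pi = np.log(np.maximum(m.pi, 1e-12))
        u_A = np.log(np.maximum(m.A, 1e-12)).ravel()
    return np.concatenate([
        u_pi, u_A, [m.beta0[0], g2, g3],
        np.log(-m.beta1), np.log(np.maximum(m.sigma - SIGMA_FLOOR, 1e-8)),
    ])


def _unpack_cis(theta: np.ndarray, eps_beta: float) -> CisModel:
    theta = np.clip(theta, -30.0, 30.0)
    pi = _softmax(theta[0:3])
    A = np.vstack([_softmax(theta[3 + 3 * i: 6 + 3 * i]) for i in range(3)])
    b01, g2, g3 = theta[12], theta[13], theta[14]
    beta0 = np.array([b01,
                      b01 + eps_beta + np.exp(g2),
                      b01 + 2 * eps_beta + np.exp(g2) + np.exp(g3)])
    beta1 = -np.exp(theta[15:18])
    sigma = SIGMA_FLOOR + np.exp(theta[18:21])
    return CisModel(pi, A, beta0, beta1, sigma, eps_beta=eps_beta)


def _pack_trans(m: TransModel) -> np.ndarray:
    g2 = np.log(max(m.mu[1] - m.mu[0] - m.eps_mu, 1e-8))
    g3 = np.log(max(m.mu[2] - m.mu[1] - m.eps_mu, 1e-8))
    with np.errstate(divide="ignore"):
        u_pi = np.log(np.maximum(m.pi, 1e-12))
        u_A = np.log(np.maximum(m.A, 1e-12)).ravel()
    return np.concatenate([
        u_pi, u_A, [m.mu[0], g2, g3],
        np.log(np.maximum(m.sigma - SIGMA_FLOOR, 1e-8)),
    ])


def _unpack_trans(theta: np.ndarray, eps_mu: float) -> TransModel:
    theta = np.clip(theta, -30.0, 30.0)
    pi = _softmax(theta[0:3])
    A = np.vstack([_softmax(theta[3 + 3 * i: 6 + 3 * i]) for i in range(3)])
    m1, g2, g3 = theta[12], theta[13], theta[14]
    mu = np.array([m1,
                   m1 + eps_mu + np.exp(g2),
                   m1 + 2 * eps_mu + np.exp(g2) + np.exp(g3)])
    sigma = SIGMA_FLOOR + np.exp(theta[15:18])
    return TransModel(pi, A, mu, sigma, eps_mu=eps_mu)


def fit(model0, chains, tol: float = 1e-6, maxiter: int = 500):
    """Constrained maximum-likelihood fit of an HMM to training chains.

    ``chains`` is a single ObservationMatrix or a list of them (one per
    chromosome for trans).  The forward log-likelihood is maximized with
    L-BFGS on the unconstrained reparameterization, so the returned
    model always satisfies the ordering, negativity and stochasticity
    constraints.  Optimizer diagnostics land in ``model.meta``.
    """
    if isinstance(chains, (ObservationMatrix, np.ndarray)):
        chains = [chains]
    chains = [(_as_columns(c.x), c.z) if isinstance(c, ObservationMatrix)
              else (_as_columns(c), None) for c in chains]

    is_cis = isinstance(model0, CisModel)
    if is_cis and any(z is None for _, z in chains):
        raise ValueError("cis fit requires the distance covariate on every chain")
    pack = _pack_cis if is_cis else _pack_trans
    unpack = ((lambda th: _unpack_cis(th, model0.eps_beta)) if is_cis
              else (lambda th: _unpack_trans(th, model0.eps_mu)))

    def nll(theta):
        try:
            m = unpack(theta)
        except (ValueError, FloatingPointError):
            return 1e12
        total = 0.0
        with np.errstate(divide="ignore"):
            log_pi, log_A = np.log(m.pi), np.log(m.A)
        for x, z in chains:
            logB = _log_emissions(m, x, z)
            total += _forward_logspace(log_pi, log_A, logB)
        if not np.isfinite(total):
            return 1e12
        return -total

    theta0 = pack(model0)
    ll0 = -nll(theta0)
    res = minimize(nll, theta0, method="L-BFGS-B", options={
        "maxiter": maxiter, "ftol": tol, "maxfun": maxiter * 60,
    })
    theta = res.x if -res.fun >= ll0 else theta0
    fitted = unpack(theta)
    fitted.meta.update({
        "converged": bool(res.success), "iterations": int(res.nit),
        "loglik": float(max(-res.fun, ll0)), "loglik0": float(ll0),
        "message": str(res.message),
    })
    if fitted.meta["loglik"] < ll0 - tol:
        raise RuntimeError(f"optimizer decreased the likelihood: {res.message}")
    return fitted


# --------------------------------------------------------------------------- #
# bootstrap training data
# --------------------------------------------------------------------------- #

def bootstrap_training_sample(
    samples: list[FragmentCounts],
    window_sets: WindowSet | list[WindowSet],
    mode: str,
    seed: int,
    bait_pos: int | None = None,
):
    """Draw one synthetic training sample from the biological replicates.

    cis: the chromosome is partitioned into non-overlapping blocks (every
    second window of the overlapping chain) and each block takes the
    fragment signal of one uniformly chosen replicate.  trans: each
    chromosome takes one uniformly chosen replicate wholesale.  The
    synthetic sample then runs through the same trim / size-factor / log
    pipeline as the real replicates (jointly normalized with them), which
    produces training chains with state transitions unseen in any single
    replicate.

    Returns a list of single-column ObservationMatrix chains (one for
    cis, one per chromosome for trans).
    """
    if len(samples) < 2:
        raise ValueError("bootstrap requires at least 2 replicates; "
                         "duplicate the sample explicitly if you must")
    rng = np.random.default_rng(seed)
    if isinstance(window_sets, WindowSet):
        window_sets = [window_sets]

    chains = []
    for ws in window_sets:
        fmap = samples[0].fmap
        chrom_idx = np.array([i for i, f in enumerate(fmap) if f.chrom == ws.chrom])
        synth = np.zeros(len(fmap), dtype=samples[0].counts.dtype)

        if mode in ("nearbait", "cis"):
            # non-overlapping blocks: starts of every second window define
            # breakpoints along the chromosome
            wins = sorted(ws.windows, key=lambda w: w.start)
            breaks = [w.start for w in wins[::2]] + [max(w.end for w in wins)]
            mids = np.array([fmap.fragments[i].mid for i in chrom_idx])
            for b in range(len(breaks) - 1):
                r = rng.integers(len(samples))
                in_block = (mids >= breaks[b]) & (mids < breaks[b + 1])
                sel = chrom_idx[in_block]
                synth[sel] = samples[r].counts[sel]
            # fragments outside the window span keep a random replicate too
            outside = (mids < breaks[0]) | (mids >= breaks[-1])
            sel = chrom_idx[outside]
            synth[sel] = samples[rng.integers(len(samples))].counts[sel]
        else:
            r = rng.integers(len(samples))
            synth[chrom_idx] = samples[r].counts[chrom_idx]

        synth_counts = FragmentCounts("bootstrap", fmap, synth,
                                      bait=samples[0].bait,
                                      enzyme_class=samples[0].enzyme_class)
        matrix = window_counts(samples + [synth_counts], ws, bait_pos=bait_pos)
        size_factors(matrix)
        norm = matrix.normalized(trimmed=True)
        x = np.log10(norm[:, [-1]] + 1.0)    # synthetic column only
        z = None
        if mode in ("nearbait", "cis"):
            z = np.log10(matrix.distances + 1.0)
        chains.append(ObservationMatrix(x, z))
    return chains


# --------------------------------------------------------------------------- #
# domains
# --------------------------------------------------------------------------- #

def call_domains(
    paths: dict[str, StatePath] | dict[str, list[StatePath]],
    window_set: WindowSet,
    mode: str | None = None,
) -> DomainSet:
    """Turn per-replicate Viterbi paths into consensus HI domains.

    Within each chain of overlapping windows, an HI window adjacent to a
    window in a different state is trimmed to the part outside the
    conflict; surviving HI intervals are merged per replicate, and the
    consensus is the base-pair intersection across replicates.
    """
    mode = mode or window_set.mode
    per_rep: dict[str, list[tuple[int, int]]] = {}
    for rep, path in paths.items():
        if isinstance(path, list):
            path = path[0]
        if len(path.states) != len(window_set):
            raise ValueError(f"path length {len(path.states)} != "
                             f"window count {len(window_set)}")
        ivs = []
        states = path.states
        # adjacency is within a side chain; windows arrive sorted by start
        idx_by_side: dict[str, list[int]] = {}
        for i, w in enumerate(window_set):
            idx_by_side.setdefault(w.side, []).append(i)
        for side_idx in idx_by_side.values():
            side_idx.sort(key=lambda i: window_set.windows[i].start)
            for pos, i in enumerate(side_idx):
                if states[i] != HI:
                    continue
                w = window_set.windows[i]
                s, e = w.start, w.end
                if pos > 0:
                    prev = side_idx[pos - 1]
                    if states[prev] != HI:
                        s = max(s, window_set.windows[prev].end)
                if pos < len(side_idx) - 1:
                    nxt = side_idx[pos + 1]
                    if states[nxt] != HI:
                        e = min(e, window_set.windows[nxt].start)
                if s < e:
                    ivs.append((s, e))
        per_rep[rep] = intervals.merge(ivs)
    consensus = intervals.intersect_many(per_rep.values()) if per_rep else []
    return DomainSet(window_set.chrom, per_rep, consensus, mode=mode)


# --------------------------------------------------------------------------- #
# sampling from a model (used for testing and benchmarking)
# --------------------------------------------------------------------------- #

def sample_states(model, T: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate a state path (values 1..K) from pi and A."""
    K = model.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(K, p=model.pi)
    for t in range(1, T):
        states[t] = rng.choice(K, p=model.A[states[t - 1]])
    return states + 1


def sample_observations(model, T: int, M: int, rng: np.random.Generator,
                        z: np.ndarray | None = None):
    """Simulate (states, observations) from the full generative model."""
    states = sample_states(model, T, rng)
    if isinstance(model, CisModel):
        if z is None:
            raise ValueError("cis sampling needs the covariate")
        mu = model.means(z)[np.arange(T), states - 1]
    else:
        mu = model.mu[states - 1]
    x = rng.normal(mu[:, None], model.sigma[states - 1][:, None], size=(T, M))
    return states, ObservationMatrix(x, z)
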