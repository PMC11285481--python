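"""Hidden Markov machinery shared by the hiding and behaviour analyses.

Observation streams are Gamma (parametrized by mean and standard
deviation, optionally with an explicit zero-mass mixture weight so that
exact zeros are legal) or Bernoulli. Transition probabilities follow a
multinomial logit with the diagonal as reference category and an
arbitrary covariate design (including animal-id dummies). Fitting is
direct numerical maximum likelihood on the scaled forward recursion;
decoding is Viterbi; model comparison is by AIC.

Missing values (NaN) in any stream contribute likelihood 1 for that
bin, so partially observed bins stay in the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

__all__ = [
    "GammaStream",
    "BernoulliStream",
    "HMMSpec",
    "HMMParams",
    "FittedHMM",
    "transition_matrices",
    "stationary_distribution",
    "forward_loglik",
    "viterbi",
    "fit_hmm",
    "moment_init",
    "rank_models",
    "permute_states",
]

_LOG_EPS = -1e12  # stand-in for log(0) that keeps arithmetic finite


@dataclass(frozen=True)
class GammaStream:
    """Gamma-distributed stream, mean/sd parametrized.

    ``zero_inflated`` adds a per-state point mass at exactly zero
    (weight pi0), needed for streams like step length or receiver count
    that can be identically zero where the Gamma density is undefined.
    """

    name: str
    zero_inflated: bool = False

    @property
    def family(self) -> str:
        return "gamma"

    def n_params(self, k: int) -> int:
        return (3 if self.zero_inflated else 2) * k


@dataclass(frozen=True)
class BernoulliStream:
    name: str

    @property
    def family(self) -> str:
        return "bernoulli"

    def n_params(self, k: int) -> int:
        return k


Stream = GammaStream | BernoulliStream


@dataclass(frozen=True)
class HMMSpec:
    """Model skeleton: state count, streams, transition covariates."""

    n_states: int
    streams: tuple[Stream, ...]
    covariates: tuple[str, ...] = ()

    def n_params(self) -> int:
        k = self.n_states
        n_em = sum(s.n_params(k) for s in self.streams)
        n_tr = k * (k - 1) * (1 + len(self.covariates))
        return n_em + n_tr


@dataclass
class HMMParams:
    """Natural-scale parameter values for an :class:`HMMSpec`.

    ``emission[name]`` maps to dicts: Gamma streams have ``mean``,
    ``sd`` (and ``zero_mass`` if inflated), Bernoulli streams have
    ``p`` — each an array of length K. ``beta`` has shape
    (K, K, 1 + n_cov) with the diagonal rows unused (logit reference).
    """

    emission: dict[str, dict[str, np.ndarray]]
    beta: np.ndarray

    def copy(self) -> "HMMParams":
        return HMMParams(
            {k: {p: v.copy() for p, v in d.items()} for k, d in self.emission.items()},
            self.beta.copy(),
        )


@dataclass
class FittedHMM:
    spec: HMMSpec
    params: HMMParams
    loglik: float
    n_params: int
    converged: bool
    n_obs: int
    message: str = ""
    n_starts: int = 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------- transitions


def _design(spec: HMMSpec, covariates: pd.DataFrame | None, t: int) -> np.ndarray:
    """Design matrix [T, 1 + n_cov] with intercept first."""
    if not spec.covariates:
        return np.ones((t, 1))
    if covariates is None:
        raise ValueError("model has covariates but none were supplied")
    X = covariates[list(spec.covariates)].to_numpy(float)
    return np.column_stack([np.ones(len(X)), X])


def transition_matrices(
    spec: HMMSpec, params: HMMParams, covariates: pd.DataFrame | None, t: int
) -> np.ndarray:
    """Row-stochastic transition matrices, shape (T, K, K).

    Entry (i, j != i) has logit ``beta[i, j] . x``; the diagonal is the
    reference category (logit 0). Without covariates the matrix is
    constant and broadcast.
    """
    k = spec.n_states
    X = _design(spec, covariates, t)
    eta = np.einsum("tc,ijc->tij", X, params.beta)
    eta[:, np.arange(k), np.arange(k)] = 0.0
    eta -= eta.max(axis=2, keepdims=True)
    num = np.exp(eta)
    return num / num.sum(axis=2, keepdims=True)


def stationary_distribution(tm: np.ndarray) -> np.ndarray:
    """Stationary distribution of one transition matrix (left eigvec)."""
    k = tm.shape[0]
    A = np.vstack([tm.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 1e-12, None)
    return pi / pi.sum()


# ------------------------------------------------------------------ emissions


def _gamma_logpdf(x, mean, sd):
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    return (shape - 1.0) * np.log(x) - x / scale - shape * np.log(scale) - gammaln(shape)


def emission_logprob(
    spec: HMMSpec, params: HMMParams, obs: dict[str, np.ndarray]
) -> np.ndarray:
    """Per-bin per-state log emission probability, shape (T, K).

    Missing values (NaN) contribute 0. Exact zeros in a zero-inflated
    Gamma stream take the state's zero-mass weight; in a plain Gamma
    stream they are a data error.
    """
    k = spec.n_states
    t = len(next(iter(obs.values())))
    logb = np.zeros((t, k))
    for stream in spec.streams:
        x = np.asarray(obs[stream.name], float)
        pars = params.emission[stream.name]
        miss = np.isnan(x)
        if stream.family == "bernoulli":
            p = np.clip(pars["p"], 1e-12, 1 - 1e-12)
            xs = np.where(miss, 0.0, x)
            contrib = xs[:, None] * np.log(p) + (1 - xs[:, None]) * np.log(1 - p)
        else:
            mean = pars["mean"]
            sd = pars["sd"]
            if np.any(mean <= 0) or np.any(sd <= 0):
                raise ValueError(f"non-positive Gamma parameters in {stream.name!r}")
            zero = ~miss & (x == 0.0)
            if zero.any() and not stream.zero_inflated:
                raise ValueError(
                    f"stream {stream.name!r} has zeros but no zero-mass weight"
                )
            xs = np.where(miss | zero, 1.0, x)
            contrib = _gamma_logpdf(xs[:, None], mean[None, :], sd[None, :])
            if stream.zero_inflated:
                pi0 = np.clip(pars["zero_mass"], 1e-12, 1 - 1e-12)
                contrib = contrib + np.log1p(-pi0)[None, :]
                contrib[zero] = np.log(pi0)[None, :]
        contrib = np.where(miss[:, None], 0.0, contrib)
        logb += contrib
    return np.maximum(logb, _LOG_EPS)


# ------------------------------------------------------------------- forward


@dataclass
class _PackedData:
    """Sequences padded to a common length for vectorized recursion.

    Padding bins carry NaN observations (emission likelihood 1) and the
    sequence-mean covariates, which leaves the scaled forward
    log-likelihood exactly unchanged.
    """

    obs: dict[str, np.ndarray]  # name -> (S, T)
    X: np.ndarray | None  # (S, T, 1 + n_cov) or None without covariates
    lengths: np.ndarray


def _pack_data(data: pd.DataFrame, spec: HMMSpec, seq_col: str | None) -> _PackedData:
    names = [s.name for s in spec.streams]
    covs = list(spec.covariates)
    groups = [g for _, g in data.groupby(seq_col, sort=True)] if seq_col else [data]
    groups = [g for g in groups if len(g)]
    lengths = np.array([len(g) for g in groups], int)
    t_max = int(lengths.max()) if len(lengths) else 0
    s = len(groups)
    obs = {n: np.full((s, t_max), np.nan) for n in names}
    X = None
    if covs:
        X = np.ones((s, t_max, 1 + len(covs)))
    for i, g in enumerate(groups):
        for n in names:
            obs[n][i, : len(g)] = g[n].to_numpy(float)
        if covs:
            xg = g[covs].to_numpy(float)
            X[i, : len(g), 1:] = xg
            X[i, len(g) :, 1:] = xg.mean(axis=0)
    return _PackedData(obs, X, lengths)


def _packed_tms(spec: HMMSpec, params: HMMParams, packed: _PackedData):
    """(tms, pi): per-bin transition matrices and per-sequence initial.

    Without covariates ``tms`` is a single (K, K) matrix.
    """
    k = spec.n_states
    if packed.X is None:
        eta = params.beta[..., 0].copy()
        eta[np.arange(k), np.arange(k)] = 0.0
        eta -= eta.max(axis=1, keepdims=True)
        num = np.exp(eta)
        tm = num / num.sum(axis=1, keepdims=True)
        pi = np.tile(stationary_distribution(tm), (len(packed.lengths), 1))
        return tm, pi
    eta = np.einsum("stc,ijc->stij", packed.X, params.beta)
    eta[:, :, np.arange(k), np.arange(k)] = 0.0
    eta -= eta.max(axis=3, keepdims=True)
    num = np.exp(eta)
    tms = num / num.sum(axis=3, keepdims=True)
    pi = np.stack([stationary_distribution(tms[i].mean(axis=0)) for i in range(len(tms))])
    return tms, pi


def _forward_packed(
    spec: HMMSpec,
    params: HMMParams,
    packed: _PackedData,
    initial: np.ndarray | None = None,
) -> float:
    s = len(packed.lengths)
    if s == 0:
        return 0.0
    t_max = next(iter(packed.obs.values())).shape[1]
    flat = {n: v.ravel() for n, v in packed.obs.items()}
    logb = emission_logprob(spec, params, flat).reshape(s, t_max, spec.n_states)
    tms, pi = _packed_tms(spec, params, packed)
    if initial is not None:
        pi = np.tile(initial, (s, 1))
    bmax = logb.max(axis=2)
    b = np.exp(logb - bmax[:, :, None])
    alpha = pi * b[:, 0]
    c = alpha.sum(axis=1)
    ll = np.log(c) + bmax[:, 0]
    alpha /= c[:, None]
    static = packed.X is None
    for i in range(1, t_max):
        prop = alpha @ tms if static else np.einsum("sk,skj->sj", alpha, tms[:, i - 1])
        alpha = prop * b[:, i]
        c = alpha.sum(axis=1)
        ll += np.log(c) + bmax[:, i]
        alpha /= c[:, None]
    return float(ll.sum())


def forward_loglik(
    spec: HMMSpec,
    params: HMMParams,
    data: pd.DataFrame,
    *,
    seq_col: str | None = None,
    initial: np.ndarray | None = None,
) -> float:
    """Total log-likelihood over all (independent) sequences.

    The initial distribution defaults to the stationary distribution of
    the transition matrix at the covariate means of each sequence.
    Missing stream values contribute likelihood 1 for their bin.
    """
    return _forward_packed(spec, params, _pack_data(data, spec, seq_col), initial)


def viterbi(
    spec: HMMSpec,
    params: HMMParams,
    data: pd.DataFrame,
    *,
    seq_col: str | None = None,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable state path (0-based), ties toward the lower index."""
    names = [s.name for s in spec.streams]
    covs = list(spec.covariates)
    groups = [g for _, g in data.groupby(seq_col, sort=True)] if seq_col else [data]
    paths = []
    for g in groups:
        t = len(g)
        if t == 0:
            continue
        obs = {n: g[n].to_numpy(float) for n in names}
        cov = g[covs] if covs else None
        tms = transition_matrices(spec, params, cov, t)
        pi = (
            stationary_distribution(tms.mean(axis=0)) if initial is None else initial
        )
        logb = emission_logprob(spec, params, obs)
        logtm = np.log(np.clip(tms, 1e-300, None))
        delta = np.log(np.clip(pi, 1e-300, None)) + logb[0]
        back = np.zeros((t, spec.n_states), dtype=int)
        for i in range(1, t):
            cand = delta[:, None] + logtm[i - 1]
            back[i] = np.argmax(cand, axis=0)  # first max -> lower index
            delta = cand[back[i], np.arange(spec.n_states)] + logb[i]
        path = np.empty(t, dtype=int)
        path[-1] = int(np.argmax(delta))
        for i in range(t - 2, -1, -1):
            path[i] = back[i + 1][path[i + 1]]
        paths.append(path)
    return np.concatenate(paths) if paths else np.array([], dtype=int)


# ------------------------------------------------------------------- fitting


def _pack_params(spec: HMMSpec, params: HMMParams) -> np.ndarray:
    k = spec.n_states
    parts = []
    for s in spec.streams:
        d = params.emission[s.name]
        if s.family == "bernoulli":
            parts.append(logit(np.clip(d["p"], 1e-9, 1 - 1e-9)))
        else:
            parts.append(np.log(d["mean"]))
            parts.append(np.log(d["sd"]))
            if s.zero_inflated:
                parts.append(logit(np.clip(d["zero_mass"], 1e-9, 1 - 1e-9)))
    off = ~np.eye(k, dtype=bool)
    parts.append(params.beta[off].ravel())
    return np.concatenate(parts)


def _unpack_params(spec: HMMSpec, theta: np.ndarray) -> HMMParams:
    k = spec.n_states
    pos = 0
    emission: dict[str, dict[str, np.ndarray]] = {}
    for s in spec.streams:
        if s.family == "bernoulli":
            emission[s.name] = {"p": expit(theta[pos : pos + k])}
            pos += k
        else:
            d = {
                "mean": np.exp(theta[pos : pos + k]),
                "sd": np.exp(theta[pos + k : pos + 2 * k]),
            }
            pos += 2 * k
            if s.zero_inflated:
                d["zero_mass"] = expit(theta[pos : pos + k])
                pos += k
            emission[s.name] = d
    n_c = 1 + len(spec.covariates)
    beta = np.zeros((k, k, n_c))
    off = ~np.eye(k, dtype=bool)
    beta[off] = theta[pos:].reshape(k * (k - 1), n_c)
    return HMMParams(emission, beta)


def moment_init(
    spec: HMMSpec, data: pd.DataFrame, seed: int = 0
) -> HMMParams:
    """Quantile-split moment estimates as default starting values.

    Each Gamma stream's non-zero values are split into K ordered groups
    whose sample mean/sd seed the state parameters; Bernoulli p is
    spread over (0.2, 0.8); transition logits start at -2 off-diagonal
    (sticky states) with zero covariate effects.
    """
    k = spec.n_states
    emission: dict[str, dict[str, np.ndarray]] = {}
    for s in spec.streams:
        x = data[s.name].to_numpy(float)
        x = x[~np.isnan(x)]
        if s.family == "bernoulli":
            emission[s.name] = {"p": np.linspace(0.2, 0.8, k)}
            continue
        nz = x[x > 0]
        if len(nz) < k:
            nz = np.abs(np.random.default_rng(seed).normal(1, 0.1, 10 * k))
        srt = np.sort(nz)
        groups = np.array_split(srt, k)
        mean = np.array([max(g.mean(), 1e-6) for g in groups])
        sd = np.array([max(g.std(), 0.1 * m) for g, m in zip(groups, mean)])
        d = {"mean": mean, "sd": sd}
        if s.zero_inflated:
            frac0 = float((x == 0).mean())
            d["zero_mass"] = np.full(k, np.clip(frac0, 0.01, 0.9))
        emission[s.name] = d
    beta = np.zeros((k, k, 1 + len(spec.covariates)))
    off = ~np.eye(k, dtype=bool)
    beta[..., 0][off] = -2.0
    return HMMParams(emission, beta)


def fit_hmm(
    spec: HMMSpec,
    data: pd.DataFrame,
    *,
    seq_col: str | None = None,
    init: HMMParams | None = None,
    n_starts: int = 5,
    jitter: float = 0.2,
    seed: int = 0,
    maxiter: int = 2000,
    tol: float = 1e-8,
) -> FittedHMM:
    """Direct numerical ML fit of the forward log-likelihood.

    Optimizes over unconstrained transforms (log mean/sd, logit p and
    zero-mass, free transition coefficients) with L-BFGS-B and
    ``n_starts`` jittered restarts; the best final log-likelihood wins.
    """
    if init is None:
        init = moment_init(spec, data, seed)
    theta0 = _pack_params(spec, init)
    packed = _pack_data(data, spec, seq_col)
    rng = np.random.default_rng(seed)

    def neg(theta: np.ndarray) -> float:
        try:
            ll = _forward_packed(spec, _unpack_params(spec, theta), packed)
        except (ValueError, FloatingPointError):
            return 1e15
        if not np.isfinite(ll):
            return 1e15
        return -ll

    best = None
    messages = []
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0, jitter, len(theta0))
        res = minimize(
            neg,
            start,
            method="L-BFGS-B",
            options={"maxfun": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e14:
        raise RuntimeError(f"HMM fit failed on all starts: {messages}")
    n_obs = sum(
        int(np.isfinite(data[s.name].to_numpy(float)).sum()) for s in spec.streams
    )
    return FittedHMM(
        spec=spec,
        params=_unpack_params(spec, best.x),
        loglik=-float(best.fun),
        n_params=spec.n_params(),
        converged=bool(best.success),
        n_obs=n_obs,
        message=str(best.message),
        n_starts=max(1, n_starts),
    )


def rank_models(models: list[FittedHMM]) -> pd.DataFrame:
    """Ascending-AIC table with delta-AIC; ties keep entry order.

    All candidates must have been fitted on the same observations.
    """
    if not models:
        raise ValueError("no models to rank")
    n_obs = {m.n_obs for m in models}
    if len(n_obs) != 1:
        raise ValueError("models were fitted on different observation sets")
    rows = [
        {"index": i, "n_params": m.n_params, "loglik": m.loglik, "aic": m.aic}
        for i, m in enumerate(models)
    ]
    tab = pd.DataFrame(rows).sort_values(["aic", "index"], kind="stable")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.reset_index(drop=True)


def permute_states(fitted: FittedHMM, perm: np.ndarray) -> FittedHMM:
    """Relabel states: new state s corresponds to old state perm[s]."""
    perm = np.asarray(perm, int)
    emission = {
        name: {p: v[perm] for p, v in d.items()}
        for name, d in fitted.params.emission.items()
    }
    beta = fitted.params.beta[np.ix_(perm, perm)]
    return replace(fitted, params=HMMParams(emission, beta))
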