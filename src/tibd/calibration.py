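"""Bayesian ensemble calibration of the TIBD model.

Thirty of the 36 model parameters are sampled in log10 space.  Twenty-five
are shared across tumor types; the five tumor-specific rate constants
(kTdiv, kTtgfb, kTdth, kTpthrp, kTB) get one copy per tumor type, so a
two-type calibration has 35 sampled dimensions.  Priors are log-normal,
centered on the literature defaults, except the carrying capacity ``M``,
which gets a log-uniform prior of total width 0.3 decades.

The likelihood is a product of independent Gaussians over every data point,
with standard deviation equal to the reported (or policy-adjusted) standard
error, evaluated on simulated observables from the protocol bound to each
dataset.  Sampling uses a multi-chain differential-evolution MCMC with
subspace crossover moves and proposals built from an archive of past states
(DREAM-style); convergence is monitored per dimension with the
Gelman-Rubin potential scale reduction factor, with sampling extended in
blocks until every dimension falls below the threshold (default 1.2).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import StudyDataset
from .model import SimulationError, simulate
from .params import ADJUSTABLE_PARAMS, TUMOR_PARAMS, ModelParameters
from .protocols import (
    Event,
    TrajectorySet,
    extract_observables,
    make_standard_protocols,
    pre_equilibrate,
)

__all__ = [
    "ParameterSpace",
    "PriorSpec",
    "CalibrationConfig",
    "MCMCResult",
    "PosteriorEnsemble",
    "build_parameter_space",
    "default_priors",
    "log_prior",
    "gaussian_loglik",
    "log_likelihood",
    "dream_sample",
    "run_mcmc",
    "gelman_rubin",
    "burn_in_and_filter",
    "retained_after_burn_in",
]

log = logging.getLogger(__name__)

#: shared sampled parameters, canonical order (25 of the 30 adjustable)
SHARED_PARAMS = tuple(n for n in ADJUSTABLE_PARAMS if n not in TUMOR_PARAMS)


@dataclass(frozen=True)
class ParameterSpace:
    """Mapping between the sampled log10 vector and per-type model parameters."""

    base: ModelParameters
    tumor_types: Tuple[str, ...]
    dims: Tuple[Tuple[str, Optional[str]], ...]  # (parameter name, tumor type or None)

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(
            name if ttype is None else f"{name}[{ttype}]" for name, ttype in self.dims
        )

    def index(self, name: str, tumor_type: Optional[str] = None) -> int:
        target = name if tumor_type is None else f"{name}[{tumor_type}]"
        try:
            return self.names.index(target)
        except ValueError:
            raise KeyError(f"no sampled dimension {target!r}") from None

    def center(self) -> np.ndarray:
        """log10 of the default values, one per sampled dimension."""
        return np.array(
            [math.log10(getattr(self.base, name)) for name, _ in self.dims]
        )

    def params_for(self, theta: np.ndarray) -> Dict[str, ModelParameters]:
        """Per-tumor-type ModelParameters from a sampled log10 vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.ndim,):
            raise ValueError(f"theta must have {self.ndim} components")
        values = 10.0**theta
        shared = {
            name: values[i] for i, (name, ttype) in enumerate(self.dims) if ttype is None
        }
        out = {}
        for tt in self.tumor_types:
            specific = {
                name: values[i]
                for i, (name, ttype) in enumerate(self.dims)
                if ttype == tt
            }
            out[tt] = self.base.replace(**shared, **specific)
        return out

    def theta_from_overrides(
        self, params: ModelParameters, overrides: Mapping[str, Mapping[str, float]]
    ) -> np.ndarray:
        """log10 vector for known parameter values (e.g., a ground truth)."""
        vals = []
        for name, ttype in self.dims:
            v = getattr(params, name) if ttype is None else overrides[ttype][name]
            vals.append(math.log10(v))
        return np.array(vals)


def build_parameter_space(
    params: ModelParameters, tumor_types: Sequence[str]
) -> ParameterSpace:
    """25 shared + 5 per-tumor-type sampled dimensions, in deterministic order."""
    tumor_types = tuple(tumor_types)
    if not tumor_types:
        raise ValueError("at least one tumor type is required")
    if len(set(tumor_types)) != len(tumor_types):
        raise ValueError("tumor type labels must be unique")
    dims: List[Tuple[str, Optional[str]]] = [(n, None) for n in SHARED_PARAMS]
    for tt in tumor_types:
        dims.extend((n, tt) for n in TUMOR_PARAMS)
    return ParameterSpace(base=params, tumor_types=tumor_types, dims=tuple(dims))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    name: str  # decorated dimension name, e.g. 'kTdiv[parental]'
    kind: str  # 'log-normal' | 'log-uniform'
    center: float  # log10 of the default value
    scale: float  # sd in decades (log-normal) or total width (log-uniform)

    def __post_init__(self) -> None:
        if self.kind not in ("log-normal", "log-uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")


def default_priors(
    space: ParameterSpace, sigma: float = 2.0, m_width: float = 0.3
) -> List[PriorSpec]:
    """Log-normal priors centered on the defaults; log-uniform for ``M``.

    ``sigma`` (in decades) is the weakly-informative spread used for every
    log-normal dimension; the carrying capacity gets a log-uniform prior of
    total width ``m_width`` decades centered on its default.
    """
    priors = []
    centers = space.center()
    for i, (name, ttype) in enumerate(space.dims):
        dim_name = space.names[i]
        if name == "M":
            priors.append(PriorSpec(dim_name, "log-uniform", centers[i], m_width))
        else:
            priors.append(PriorSpec(dim_name, "log-normal", centers[i], sigma))
    return priors


def log_prior(theta: np.ndarray, priors: Sequence[PriorSpec]) -> float:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(priors),):
        raise ValueError(
            f"theta has {theta.shape} components but {len(priors)} priors given"
        )
    total = 0.0
    for x, pr in zip(theta, priors):
        if pr.kind == "log-normal":
            z = (x - pr.center) / pr.scale
            total += -0.5 * z * z - math.log(pr.scale * math.sqrt(2.0 * math.pi))
        else:  # log-uniform
            half = 0.5 * pr.scale
            if not (pr.center - half <= x <= pr.center + half):
                return -math.inf
            total += -math.log(pr.scale)
    return total


def sample_prior(priors: Sequence[PriorSpec], rng: np.random.Generator, n: int = 1):
    out = np.empty((n, len(priors)))
    for j, pr in enumerate(priors):
        if pr.kind == "log-normal":
            out[:, j] = rng.normal(pr.center, pr.scale, size=n)
        else:
            half = 0.5 * pr.scale
            out[:, j] = rng.uniform(pr.center - half, pr.center + half, size=n)
    return out[0] if n == 1 else out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def gaussian_loglik(y_model, y_obs, sigma) -> float:
    """Sum of independent Gaussian log-densities over data points."""
    y_model = np.asarray(y_model, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z = (y_model - y_obs) / sigma
    return float(np.sum(-0.5 * z**2 - np.log(sigma * math.sqrt(2.0 * math.pi))))


def _protocol_events(proto_id: str) -> Tuple[Event, ...]:
    i, ii, iii = make_standard_protocols()
    return {"i": i.events, "ii": ii.events, "iii": iii.events}[proto_id]


def log_likelihood(
    theta: np.ndarray,
    datasets: Sequence[StudyDataset],
    space: ParameterSpace,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    max_steps: int = 20_000,
) -> float:
    """Gaussian log-likelihood of the sampled vector over all datasets.

    One simulation per (tumor type, protocol) pair, reused across every
    dataset bound to that pair; the tumor-free pre-equilibration is shared
    across tumor types (the tumor-specific parameters do not act while
    T = 0).  A solver failure rejects the sample with -inf.
    """
    try:
        params_by_type = space.params_for(theta)
    except (ValueError, KeyError):
        return -math.inf

    # group required output times per (tumor type, protocol)
    needs: Dict[Tuple[str, str], set] = {}
    for ds in datasets:
        if ds.tumor_type not in params_by_type:
            raise KeyError(
                f"dataset {ds.label!r} references unknown tumor type {ds.tumor_type!r}"
            )
        needs.setdefault((ds.tumor_type, ds.protocol), set()).update(ds.days.tolist())

    try:
        any_params = next(iter(params_by_type.values()))
        state0 = pre_equilibrate(any_params, rtol=rtol, atol=atol, max_steps=max_steps)
    except (SimulationError, ValueError) as exc:
        log.debug("pre-equilibration failed: %s", exc)
        return -math.inf
    if not np.all(np.isfinite(state0)):
        return -math.inf
    bone0 = state0[3]
    if bone0 <= 0:
        return -math.inf

    sims: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for (ttype, proto_id), days in needs.items():
        t_grid = np.unique(np.concatenate([[0.0], sorted(days)]))
        events = _protocol_events(proto_id)
        try:
            y = simulate(
                params_by_type[ttype],
                state0,
                t_grid,
                events=events,
                rtol=rtol,
                atol=atol,
                max_steps=max_steps,
            )
        except (SimulationError, ValueError) as exc:
            log.debug("simulation failed for %s/%s: %s", ttype, proto_id, exc)
            return -math.inf
        if not np.all(np.isfinite(y)):
            return -math.inf
        sims[(ttype, proto_id)] = (t_grid, y)

    total = 0.0
    for ds in datasets:
        t_grid, y = sims[(ds.tumor_type, ds.protocol)]
        traj = TrajectorySet(t=t_grid, y=y, initial_state=state0, label=ds.label)
        y_model = extract_observables(traj, ds.observable, ds.days)
        total += gaussian_loglik(y_model, ds.means, ds.ses)
    return total


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class CalibrationConfig:
    """Knobs of the multi-chain calibration.

    The defaults mirror the full-scale study (5 chains, 50,000-iteration
    blocks, Gelman-Rubin threshold 1.2); desk-scale runs shrink
    ``block_iters``/``max_blocks``/``descent_iters``.  ``init`` selects how
    chains are seeded: ``descent`` (default) runs one independent
    greedy-ish windowed descent per chain from the default-parameter point
    before sampling begins, ``center`` scatters chains around the prior
    modes, and ``prior`` draws them from the prior.
    """

    n_chains: int = 5
    block_iters: int = 50_000
    gr_threshold: float = 1.2
    max_blocks: int = 10
    seed: int = 0
    prior_sigma: float = 2.0
    m_width: float = 0.3
    rtol: float = 1e-6
    atol: float = 1e-8
    init: str = "descent"  # 'descent' | 'center' | 'prior'
    descent_iters: int = 4000
    descent_window: int = 400
    descent_eps: float = 0.01  # decades, jitter floor keeping descents mobile
    init_spread: float = 0.5  # decades, initial archive cloud around the centers
    init_jitter: float = 0.1  # decades, chain-start spread
    archive_append_every: int = 10
    gamma1_prob: float = 0.1
    snooker_prob: float = 0.0
    cr_values: Tuple[float, ...] = (1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass
class MCMCResult:
    chains: np.ndarray  # (n_chains, n_iters, ndim), log10 scale
    logpost: np.ndarray  # (n_chains, n_iters)
    loglik: np.ndarray  # (n_chains, n_iters)
    gr: np.ndarray  # per-dimension Gelman-Rubin at termination
    names: Tuple[str, ...] = ()
    gr_history: List[np.ndarray] = field(default_factory=list)


def _de_proposal(x, flat, lo, crng, cr_values, gamma1_prob, eps):
    """Subspace-crossover differential-evolution proposal from archive rows."""
    ndim = x.size
    ia, ib = lo + crng.choice(flat.shape[0] - lo, size=2, replace=False)
    cr = cr_values[crng.integers(len(cr_values))]
    mask = crng.random(ndim) < cr
    if not mask.any():
        mask[crng.integers(ndim)] = True
    d_eff = int(mask.sum())
    gamma = 1.0 if crng.random() < gamma1_prob else 2.38 / math.sqrt(2.0 * d_eff)
    prop = x.copy()
    prop[mask] = (
        x[mask]
        + (1.0 + crng.uniform(-0.1, 0.1)) * gamma * (flat[ia][mask] - flat[ib][mask])
        + crng.normal(0.0, eps, size=d_eff)
    )
    return prop


def dream_sample(
    logpost_fn: Callable[[np.ndarray], Tuple[float, float]],
    ndim: int,
    draw_init: Callable[[np.random.Generator, int], np.ndarray],
    n_chains: int,
    n_iters: int,
    rng: np.random.Generator,
    state: Optional[dict] = None,
    archive_append_every: int = 10,
    gamma1_prob: float = 0.1,
    snooker_prob: float = 0.0,
    proposal_eps: float = 1e-6,
    cr_values: Sequence[float] = (1.0 / 3.0, 2.0 / 3.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Differential-evolution MCMC with subspace crossover and a state archive.

    ``logpost_fn`` returns (log posterior, log likelihood).  Proposals for a
    random subset of dimensions follow the scaled difference of two archive
    members; the archive grows with thinned chain states, which supplies the
    adaptive cross-chain geometry that lets a handful of chains explore a
    high-dimensional target.  Optional snooker moves project archive
    differences onto the line through the current state.  Fully
    deterministic given ``rng``; pass the returned ``state`` back in to
    continue a run seamlessly.
    """
    cr_values = tuple(cr_values)
    if state is None:
        m0 = max(10 * ndim, 2 * n_chains)
        Z = np.atleast_2d(draw_init(rng, m0))
        X = np.atleast_2d(draw_init(rng, n_chains)).copy()
        chain_rngs = list(rng.spawn(n_chains))
        lp = np.empty(n_chains)
        ll = np.empty(n_chains)
        for j in range(n_chains):
            lp[j], ll[j] = logpost_fn(X[j])
        if not np.any(np.isfinite(lp)):
            raise RuntimeError("no finite log-posterior among the initial chain states")
        state = {"Z": Z, "X": X, "lp": lp, "ll": ll, "rngs": chain_rngs}
    flatZ = np.array(state["Z"], dtype=float)
    X = state["X"]
    lp = state["lp"]
    ll = state["ll"]
    chain_rngs = state["rngs"]

    samples = np.empty((n_chains, n_iters, ndim))
    logposts = np.empty((n_chains, n_iters))
    logliks = np.empty((n_chains, n_iters))

    for it in range(n_iters):
        for j in range(n_chains):
            crng = chain_rngs[j]
            log_metropolis_corr = 0.0
            if snooker_prob and crng.random() < snooker_prob:
                iz, ia, ib = crng.choice(flatZ.shape[0], size=3, replace=False)
                z, za, zb = flatZ[iz], flatZ[ia], flatZ[ib]
                F = X[j] - z
                norm2 = float(F @ F)
                if norm2 == 0.0:
                    continue
                gamma_s = crng.uniform(1.2, 2.2)
                proj = (float(za @ F) - float(zb @ F)) / norm2
                prop = X[j] + gamma_s * proj * F
                d_new2 = float((prop - z) @ (prop - z))
                if d_new2 == 0.0:
                    continue
                log_metropolis_corr = 0.5 * (ndim - 1) * math.log(d_new2 / norm2)
            else:
                prop = _de_proposal(
                    X[j], flatZ, 0, crng, cr_values, gamma1_prob, proposal_eps
                )
            lp_new, ll_new = logpost_fn(prop)
            if math.isfinite(lp_new) and (
                math.log(crng.random()) < lp_new - lp[j] + log_metropolis_corr
            ):
                X[j] = prop
                lp[j] = lp_new
                ll[j] = ll_new
        if (it + 1) % archive_append_every == 0:
            flatZ = np.concatenate([flatZ, X.copy()])
        samples[:, it, :] = X
        logposts[:, it] = lp
        logliks[:, it] = ll

    state = {"Z": flatZ, "X": X, "lp": lp, "ll": ll, "rngs": chain_rngs}
    return samples, logposts, logliks, state


def descent_init(
    logpost_fn: Callable[[np.ndarray], Tuple[float, float]],
    centers: np.ndarray,
    n_chains: int,
    rng: np.random.Generator,
    n_iters: int = 4000,
    window: int = 400,
    eps: float = 0.01,
    init_spread: float = 0.5,
    init_jitter: float = 0.1,
    archive_tail: int = 200,
    cr_values: Sequence[float] = (1.0 / 3.0, 2.0 / 3.0, 1.0),
    gamma1_prob: float = 0.1,
) -> dict:
    """Independent per-chain burn-in descents from the default-parameter point.

    Each chain runs its own Metropolis walk whose proposals are built from a
    sliding window over its own history (plus a small jitter floor so the
    walk never freezes), which lets it travel down the narrow likelihood
    valley quickly.  The chains land on diverse points of the
    high-likelihood region; their endpoint clouds are merged into the
    initial archive, so the sampling phase starts with cross-chain
    difference vectors that span the region -- the geometry differential-
    evolution moves need to mix along ridges.  Initialization only: the
    returned state feeds ``dream_sample`` and none of the descent states
    are reported as posterior samples.
    """
    ndim = centers.size
    cr_values = tuple(cr_values)
    chain_rngs = list(rng.spawn(n_chains))
    X = np.empty((n_chains, ndim))
    lp = np.empty(n_chains)
    ll = np.empty(n_chains)
    tails = []
    for j in range(n_chains):
        crng = chain_rngs[j]
        flat = centers[None, :] + crng.normal(0.0, init_spread, size=(3 * window // 10, ndim))
        x = centers + crng.normal(0.0, init_jitter, size=ndim)
        lp_j, ll_j = logpost_fn(x)
        for it in range(n_iters):
            lo = max(0, flat.shape[0] - window)
            prop = _de_proposal(x, flat, lo, crng, cr_values, gamma1_prob, eps)
            lp_n, ll_n = logpost_fn(prop)
            if math.isfinite(lp_n) and math.log(crng.random()) < lp_n - lp_j:
                x, lp_j, ll_j = prop, lp_n, ll_n
            if (it + 1) % 10 == 0:
                flat = np.concatenate([flat, x[None, :]])
        X[j], lp[j], ll[j] = x, lp_j, ll_j
        tails.append(flat[-archive_tail:])
        log.info("descent chain %d: log-likelihood %.1f", j, ll_j)
    if not np.any(np.isfinite(lp)):
        raise RuntimeError("no finite log-posterior among the descent endpoints")
    return {
        "Z": np.concatenate(tails),
        "X": X,
        "lp": lp,
        "ll": ll,
        "rngs": chain_rngs,
    }


def run_mcmc(
    space: ParameterSpace,
    priors: Sequence[PriorSpec],
    datasets: Sequence[StudyDataset],
    config: CalibrationConfig,
) -> MCMCResult:
    """Block-wise DREAM-style sampling with Gelman-Rubin-gated extension.

    Chains are initialized per ``config.init`` (by default via independent
    windowed descents from the default-parameter point), then run for
    ``block_iters`` iterations per block; after each block the potential
    scale reduction factor is computed per sampled dimension over the
    accumulated chains, and sampling stops once every dimension is below
    ``gr_threshold`` or ``max_blocks`` is reached.  Reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    def fn(theta: np.ndarray) -> Tuple[float, float]:
        lp = log_prior(theta, priors)
        if not math.isfinite(lp):
            return -math.inf, -math.inf
        ll = log_likelihood(theta, datasets, space, rtol=config.rtol, atol=config.atol)
        if not math.isfinite(ll):
            return -math.inf, -math.inf
        return lp + ll, ll

    centers = np.array([pr.center for pr in priors])

    def draw_init(r: np.random.Generator, n: int) -> np.ndarray:
        if config.init == "prior":
            return np.atleast_2d(sample_prior(priors, r, n))
        spread = config.init_jitter if n == config.n_chains else config.init_spread
        draws = centers[None, :] + r.normal(0.0, spread, size=(n, centers.size))
        for j, pr in enumerate(priors):
            if pr.kind == "log-uniform":
                half = 0.5 * pr.scale
                draws[:, j] = np.clip(draws[:, j], pr.center - half, pr.center + half)
        return draws

    if config.init == "descent":
        state = descent_init(
            fn,
            centers,
            config.n_chains,
            rng,
            n_iters=config.descent_iters,
            window=config.descent_window,
            eps=config.descent_eps,
            init_spread=config.init_spread,
            init_jitter=config.init_jitter,
            cr_values=config.cr_values,
            gamma1_prob=config.gamma1_prob,
        )
    elif config.init in ("center", "prior"):
        state = None
    else:
        raise ValueError(f"unknown init mode {config.init!r}")

    all_samples: List[np.ndarray] = []
    all_lp: List[np.ndarray] = []
    all_ll: List[np.ndarray] = []
    gr = np.full(space.ndim, np.inf)
    gr_history: List[np.ndarray] = []
    for block in range(config.max_blocks):
        samples, lps, lls, state = dream_sample(
            fn,
            space.ndim,
            draw_init,
            config.n_chains,
            config.block_iters,
            rng,
            state=state,
            archive_append_every=config.archive_append_every,
            gamma1_prob=config.gamma1_prob,
            snooker_prob=config.snooker_prob,
            cr_values=config.cr_values,
        )
        all_samples.append(samples)
        all_lp.append(lps)
        all_ll.append(lls)
        chains = np.concatenate(all_samples, axis=1)
        gr = gelman_rubin(chains)
        gr_history.append(gr)
        log.info(
            "block %d: %d iterations, max GR = %.3f",
            block + 1,
            chains.shape[1],
            float(np.nanmax(gr)),
        )
        if np.all(gr < config.gr_threshold):
            break
    return MCMCResult(
        chains=np.concatenate(all_samples, axis=1),
        logpost=np.concatenate(all_lp, axis=1),
        loglik=np.concatenate(all_ll, axis=1),
        gr=gr,
        names=space.names,
        gr_history=gr_history,
    )


# ---------------------------------------------------------------------------
# diagnostics and post-processing
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per dimension, on second-half chains.

    ``chains`` has shape (n_chains, n_iters, ndim).  Dimensions with zero
    within-chain variance are reported as +inf with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n_total, ndim = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    half = chains[:, n_total // 2 :, :]
    n = half.shape[1]
    if n < 5:
        raise ValueError("chains too short for a Gelman-Rubin estimate")
    means = half.mean(axis=1)  # (m, ndim)
    variances = half.var(axis=1, ddof=1)  # (m, ndim)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    out = np.empty(ndim)
    for d in range(ndim):
        if W[d] == 0.0:
            import warnings

            warnings.warn(
                f"zero within-chain variance in dimension {d}; GR reported as inf",
                RuntimeWarning,
                stacklevel=2,
            )
            out[d] = math.inf if B[d] > 0 else 1.0
        else:
            var_hat = (n - 1) / n * W[d] + B[d] / n
            out[d] = math.sqrt(var_hat / W[d])
    return out


@dataclass
class PosteriorEnsemble:
    """Post-burn-in samples with their log-likelihoods and provenance."""

    samples: np.ndarray  # (n_samples, ndim), log10 scale
    loglik: np.ndarray
    chain_id: np.ndarray
    iteration: np.ndarray
    mask: np.ndarray  # True where the likelihood filter retains the sample
    names: Tuple[str, ...] = ()

    @property
    def filtered(self) -> np.ndarray:
        return self.samples[self.mask]

    @property
    def n_filtered(self) -> int:
        return int(self.mask.sum())

    def marginal(self, name: str, tumor_type: Optional[str] = None) -> np.ndarray:
        """Filtered log10 samples of one sampled dimension."""
        target = name if tumor_type is None else f"{name}[{tumor_type}]"
        if target not in self.names:
            raise KeyError(f"no sampled dimension {target!r}")
        return self.filtered[:, self.names.index(target)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=list(self.names))
        df["loglik"] = self.loglik
        df["chain"] = self.chain_id
        df["iteration"] = self.iteration
        df["retained"] = self.mask
        return df


def retained_after_burn_in(n_chains: int, n_iters: int) -> Tuple[int, int]:
    """(total samples, samples retained after discarding the first half)."""
    return n_chains * n_iters, n_chains * (n_iters - n_iters // 2)


def burn_in_and_filter(result: MCMCResult) -> PosteriorEnsemble:
    """Discard the first half of each chain, then apply the likelihood filter.

    The filter keeps samples whose log-likelihood is at least the mean minus
    two standard deviations, both computed over the retained (post-burn-in)
    samples.
    """
    chains = result.chains
    lls = result.loglik
    m, n, ndim = chains.shape
    start = n // 2
    kept = chains[:, start:, :].reshape(-1, ndim)
    kept_ll = lls[:, start:].reshape(-1)
    chain_id = np.repeat(np.arange(m), n - start)
    iteration = np.tile(np.arange(start, n), m)
    sd = float(kept_ll.std(ddof=0))
    threshold = float(kept_ll.mean()) - 2.0 * sd
    mask = kept_ll >= threshold
    if not mask.any():
        raise ValueError("likelihood filter removed every sample")
    return PosteriorEnsemble(
        samples=kept,
        loglik=kept_ll,
        chain_id=chain_id,
        iteration=iteration,
        mask=mask,
        names=tuple(result.names),
    )
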