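"""Blocked Gibbs sampler for latent count reconstruction.

The sampler jointly explores (a) the latent true fine-unit case counts
consistent with every published, privacy-perturbed table — each areal level
plus the socioeconomic and remoteness margins — and (b) the parameters of
the geospatial prevalence model, by cycling three blocks:

1. ``update_counts``: single-cell Metropolis moves on each fine-unit count,
   scored against the exact perturbation likelihood of *every* published
   cell containing the unit (aggregates maintained incrementally) plus the
   binomial model term.
2. ``update_field``: elliptical slice sampling of the spatial field under
   its Gaussian-process prior and the binomial likelihood.
3. ``update_scalars``: adaptive random-walk Metropolis on the intercepts,
   covariate effects, field scale and mixing weight (coordinate-wise;
   adaptation during burn-in only), plus three moves along directions that
   centred samplers explore poorly when the data are weak: a location
   interweaving shift trading the intercepts against the field mean, a
   scale interweaving (non-centred) move rescaling the field with its
   scale, and a whitened range move deforming the field under a proposed
   correlation range.

Latent state is fine-level only; every coarser observed cell is a
deterministic sum of fine counts, so aggregation coherence is exact by
construction (and re-verified against a from-scratch recomputation at a
fixed cadence).
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit

from .hierarchy import AGE_GROUPS, Hierarchy
from .model import ModelParams, PriorSpec
from .perturbation import PerturbConfig

__all__ = [
    "MCMCConfig",
    "ChainState",
    "PosteriorSamples",
    "init_state",
    "update_counts",
    "update_field",
    "update_scalars",
    "run_chain",
    "diagnostics",
    "stated_denominators",
]

_BIG_NEG = -1e10  # feasibility penalty standing in for -inf inside kernels

SCALAR_NAMES = (
    "beta0_young",
    "beta0_old",
    "beta_ses",
    "gamma1",
    "gamma2",
    "gamma3",
    "gamma4",
    "gamma5",
    "log_sigma_u",
    "log_rho",
    "w",
)

# coordinates updated by random-walk Metropolis, in sweep order
_RW_COORDS = (
    "beta0_young",
    "beta0_old",
    "beta_ses",
    "g0",
    "g1",
    "g2",
    "g3",
    "log_sigma_u",
    "logit_w",
)

# all adapted proposal scales: the RW coordinates, the location shift, and
# the whitened (non-centred) range move
_ADAPT_COORDS = _RW_COORDS + ("shift", "rho_nc")


@dataclass
class MCMCConfig:
    """Sampler run settings.

    count_proposal_sd sets the mean jump size of the +/-k geometric
    random walk on latent counts; adaptation of the scalar proposal scales
    toward target_accept happens during burn-in only.
    """

    n_iter: int = 6000
    n_burn: int = 2000
    thin: int = 4
    count_proposal_sd: int = 1
    adapt_interval: int = 50
    target_accept: float = 0.44
    seed: int = 20210810
    n_chains: int = 2
    recompute_interval: int = 1000

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must be in (0, 1)")
        if self.count_proposal_sd < 1:
            raise ValueError("count_proposal_sd must be a positive integer")


# ---------------------------------------------------------------------------
# observed-table bookkeeping

class ObservedTables:
    """Published positive-count cells aligned to hierarchy partitions.

    Holds, for each partition present in the observed tables, the
    per-fine-unit group codes and the published positive counts, flattened
    so the count kernel can walk all partitions with one index per unit.
    """

    def __init__(self, observed: pd.DataFrame, h: Hierarchy):
        present = [
            lvl
            for lvl in ("L1", "L2", "L3", "L4", "STATE", "ses_decile", "remoteness")
            if lvl in set(observed["level"])
        ]
        if "L1" not in present:
            raise ValueError("observed tables must include level L1")
        pos = observed[observed["category"] == "positive"]
        codes_rows = []
        offsets = [0]
        o_blocks = []
        for lvl in present:
            labels, codes = h.partition_codes(lvl)
            sub = pos[pos["level"] == lvl].pivot(
                index="unit_id", columns="age_group", values="count"
            )
            missing = [u for u in labels if u not in sub.index]
            if missing:
                raise ValueError(f"missing published rows at {lvl}: {missing[:5]}")
            o_blocks.append(
                sub.loc[labels, list(AGE_GROUPS)].to_numpy(dtype=np.int64)
            )
            codes_rows.append(codes)
            offsets.append(offsets[-1] + len(labels))
        self.partitions = present
        self.codes = np.asarray(codes_rows, dtype=np.int64)  # (P, n)
        self.offsets = np.asarray(offsets, dtype=np.int64)  # (P+1,)
        self.o_flat = np.vstack(o_blocks)  # (G_total, 3)

    def aggregate(self, y: np.ndarray) -> np.ndarray:
        """From-scratch aggregates of fine counts, flattened like o_flat."""
        blocks = []
        for pi in range(len(self.partitions)):
            g = self.offsets[pi + 1] - self.offsets[pi]
            out = np.zeros((g, y.shape[1]), dtype=np.int64)
            np.add.at(out, self.codes[pi], y)
            blocks.append(out)
        return np.vstack(blocks)


def stated_denominators(observed: pd.DataFrame, h: Hierarchy) -> np.ndarray:
    """Denominators from published L1 positives + negatives.

    Used when the true stated-response denominators are not supplied; their
    relative perturbation is negligible at denominator scale.
    """
    sub = observed[(observed["level"] == "L1")]
    wide = sub.pivot_table(
        index="unit_id", columns=["category", "age_group"], values="count"
    )
    n = np.zeros((h.n_fine, len(AGE_GROUPS)), dtype=np.int64)
    for ai, age in enumerate(AGE_GROUPS):
        pos = wide[("positive", age)].loc[h.fine_ids].to_numpy()
        neg = wide[("negative", age)].loc[h.fine_ids].to_numpy()
        n[:, ai] = np.maximum(pos + neg, pos)
    return n


# ---------------------------------------------------------------------------
# chain state

@dataclass
class ChainState:
    """Mutable sampler state: latent counts, parameters, and caches."""

    y: np.ndarray  # (n, 3) int64
    params: ModelParams
    n_stated: np.ndarray  # (n, 3) int64
    obs: ObservedTables
    h: Hierarchy
    agg_flat: np.ndarray = None  # running aggregates aligned with obs.o_flat
    eta: np.ndarray = None  # (n, 3)
    chol_corr: np.ndarray = None  # lower Cholesky of exp(-d/rho) + jitter
    corr_logdet: float = 0.0
    quad: float = 0.0  # u' C^-1 u for current rho
    prop_log_sd: dict = field(default_factory=dict)
    _accept: dict = field(default_factory=dict)
    _dist: np.ndarray = None

    def _covariate_arrays(self):
        cached = self.__dict__.get("_cov_arrays")
        if cached is None:
            cached = (self.h.ses_decile - 5.5, self.h.remoteness_codes)
            self.__dict__["_cov_arrays"] = cached
        return cached

    def eta_at(self, u: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        """(n, 3) logit prevalences for the current scalars at field u."""
        p = self.params
        dec55, rem = self._covariate_arrays()
        if out is None:
            out = np.empty((self.h.n_fine, 3))
        base = p.beta_ses * dec55
        base += p.gamma[rem]
        base += u
        w = p.w
        np.add(base, p.beta0_young, out=out[:, 0])
        np.add(base, w * p.beta0_young + (1.0 - w) * p.beta0_old, out=out[:, 1])
        np.add(base, p.beta0_old, out=out[:, 2])
        return out

    def refresh_eta(self) -> None:
        self.eta = self.eta_at(self.params.u, out=self.eta)

    def refresh_corr(self) -> None:
        if self._dist is None:
            self._dist = self.h.distances()
        corr = np.exp(-self._dist / self.params.rho)
        corr[np.diag_indices_from(corr)] += 1e-8
        try:
            self.chol_corr = cholesky(corr, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "correlation Cholesky failed; increase the diagonal jitter"
            ) from exc
        self.corr_logdet = 2.0 * float(np.log(np.diag(self.chol_corr)).sum())
        self.refresh_quad()

    def refresh_quad(self) -> None:
        a = solve_triangular(self.chol_corr, self.params.u, lower=True)
        self.quad = float(a @ a)


def _binom_ll(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    """Binomial log likelihood up to y-independent constants."""
    return float((y * eta - n * np.logaddexp(0.0, eta)).sum())


def _gp_logprior(state: ChainState) -> float:
    n = state.h.n_fine
    s = state.params.sigma_u
    return -0.5 * (
        n * math.log(2 * math.pi)
        + 2 * n * math.log(s)
        + state.corr_logdet
        + state.quad / s**2
    )


def init_state(
    observed: pd.DataFrame,
    h: Hierarchy,
    seed: int,
    priors: PriorSpec | None = None,
    n_stated: np.ndarray | None = None,
) -> ChainState:
    """Deterministic initial state from the published fine-level table.

    Latent counts start at the published L1 positives clipped to
    [0, n_stated]; scalars at their prior means; the field at zero.
    """
    priors = priors or PriorSpec()
    obs = ObservedTables(observed, h)
    if n_stated is None:
        n_stated = stated_denominators(observed, h)
    n_stated = np.asarray(n_stated, dtype=np.int64)
    o_l1 = obs.o_flat[obs.offsets[0]: obs.offsets[1]]
    # L1 block rows follow partition label order == fine order
    y0 = np.clip(o_l1, 0, n_stated).astype(np.int64)
    pm = priors.prior_means()
    params = ModelParams(
        beta0_young=pm["beta0_young"],
        beta0_old=pm["beta0_old"],
        beta_ses=pm["beta_ses"],
        gamma_free=np.full(4, pm["gamma"]),
        u=np.zeros(h.n_fine),
        log_sigma_u=pm["log_sigma_u"],
        log_rho=pm["log_rho"],
        logit_w=0.0,
    )
    state = ChainState(y=y0, params=params, n_stated=n_stated, obs=obs, h=h)
    state.agg_flat = obs.aggregate(state.y)
    state.refresh_eta()
    state.refresh_corr()
    state.prop_log_sd = {c: math.log(0.1) for c in _ADAPT_COORDS}
    state._accept = {c: 0 for c in _ADAPT_COORDS}
    return state


# ---------------------------------------------------------------------------
# count block (numba kernel)

@njit(cache=True)
def _pert_ll(o, yv, pmf, cdf, d, tau, zero_fixed):
    if zero_fixed and yv == 0:
        return 0.0 if o == 0 else _BIG_NEG
    if o == 0:
        k = tau - yv
        if k < -d:
            return _BIG_NEG
        if k > d:
            k = d
        p = cdf[k + d]
        return math.log(p) if p > 0.0 else _BIG_NEG
    if o <= tau:
        return _BIG_NEG
    e = o - yv
    if e > d or e < -d:
        return _BIG_NEG
    p = pmf[e + d]
    return math.log(p) if p > 0.0 else _BIG_NEG


@njit(cache=True)
def _sweep_counts(
    y, n_stated, logp, log1mp, codes, offsets, o_flat, agg_flat,
    pmf, cdf, d, tau, zero_fixed, geo_p, seed,
):
    np.random.seed(seed)
    n, n_age = y.shape
    n_part = codes.shape[0]
    acc = 0
    for i in range(n):
        for a in range(n_age):
            ns = n_stated[i, a]
            if ns == 0:
                continue
            cur = y[i, a]
            if geo_p >= 1.0:
                k = 1
            else:
                k = 1 + int(math.floor(
                    math.log(1.0 - np.random.random()) / math.log(1.0 - geo_p)
                ))
            if np.random.random() < 0.5:
                k = -k
            prop = cur + k
            if prop < 0 or prop > ns:
                continue
            delta = prop - cur
            dll = (
                math.lgamma(cur + 1.0)
                + math.lgamma(ns - cur + 1.0)
                - math.lgamma(prop + 1.0)
                - math.lgamma(ns - prop + 1.0)
                + delta * (logp[i, a] - log1mp[i, a])
            )
            for pi in range(n_part):
                r = offsets[pi] + codes[pi, i]
                o = o_flat[r, a]
                old = agg_flat[r, a]
                dll += _pert_ll(o, old + delta, pmf, cdf, d, tau, zero_fixed)
                dll -= _pert_ll(o, old, pmf, cdf, d, tau, zero_fixed)
            if dll >= 0.0 or math.log(np.random.random()) < dll:
                y[i, a] = prop
                for pi in range(n_part):
                    r = offsets[pi] + codes[pi, i]
                    agg_flat[r, a] += delta
                acc += 1
    return acc


def update_counts(
    state: ChainState,
    pcfg: PerturbConfig,
    rng: np.random.Generator,
    count_proposal_sd: int = 1,
) -> int:
    """One Metropolis sweep over every fine unit x age latent count.

    Proposes y' = y +/- k with k geometric; the acceptance ratio combines
    the exact perturbation likelihood at every published cell containing
    the unit (aggregates adjusted incrementally) with the binomial model
    term.  Returns the number of accepted moves.
    """
    p = expit(state.eta)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    seed = int(rng.integers(2**31))
    return int(
        _sweep_counts(
            state.y,
            state.n_stated,
            logp,
            log1mp,
            state.obs.codes,
            state.obs.offsets,
            state.obs.o_flat,
            state.agg_flat,
            pcfg.pmf,
            pcfg.cdf,
            pcfg.d,
            pcfg.tau,
            pcfg.zero_fixed,
            1.0 / count_proposal_sd,
            seed,
        )
    )


# ---------------------------------------------------------------------------
# field block (elliptical slice sampling)

def _field_ll(state: ChainState, u: np.ndarray) -> float:
    return _binom_ll(state.eta_at(u), state.y, state.n_stated)


def update_field(state: ChainState, rng: np.random.Generator) -> None:
    """Elliptical slice sampling update of the spatial field u.

    Exact under the Gaussian-process prior (always terminates, no tuning);
    leaves every other block untouched.
    """
    p = state.params
    nu = p.sigma_u * (state.chol_corr @ rng.standard_normal(state.h.n_fine))
    u = p.u
    log_y = _field_ll(state, u) + math.log(rng.random())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    lo, hi = theta - 2.0 * math.pi, theta
    while True:
        u_prop = u * math.cos(theta) + nu * math.sin(theta)
        if _field_ll(state, u_prop) > log_y:
            break
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    p.u = u_prop
    state.refresh_eta()
    state.refresh_quad()


# ---------------------------------------------------------------------------
# scalar block (adaptive random-walk Metropolis + interweaving for the scale)

def _scalar_logpost(state: ChainState, priors: PriorSpec) -> float:
    """Log posterior terms that scalar moves can change (binomial + GP +
    priors + logit-w Jacobian)."""
    ll = _binom_ll(state.eta, state.y, state.n_stated)
    ll += _gp_logprior(state)
    ll += priors.log_prior_scalars(state.params)
    lw = state.params.logit_w
    ll += -lw - 2.0 * math.log1p(math.exp(-lw))  # uniform w on its logit scale
    return ll


def _get_coord(params: ModelParams, coord: str) -> float:
    if coord.startswith("g"):
        return float(params.gamma_free[int(coord[1])])
    return float(getattr(params, coord))


def _set_coord(params: ModelParams, coord: str, value: float) -> None:
    if coord.startswith("g"):
        params.gamma_free[int(coord[1])] = value
    else:
        setattr(params, coord, value)


def update_scalars(
    state: ChainState,
    priors: PriorSpec,
    rng: np.random.Generator,
    adapt: bool = False,
    adapt_interval: int = 50,
    adapt_step: float = 0.0,
    target_accept: float = 0.44,
) -> None:
    """Coordinate-wise random-walk Metropolis on all scalar parameters.

    Covers both intercepts, the socioeconomic slope, the four free
    remoteness coordinates, log field scale/range and the logit mixing
    weight.  When ``adapt`` (burn-in only) the per-coordinate proposal
    scales drift toward ``target_accept``.  The field scale additionally
    receives an interweaving move that proposes (sigma', u' = u sigma'/sigma)
    jointly.
    """
    p = state.params
    cur_lp = _scalar_logpost(state, priors)
    for coord in _RW_COORDS:
        sd = math.exp(state.prop_log_sd[coord])
        old = _get_coord(p, coord)
        _set_coord(p, coord, old + sd * rng.standard_normal())
        if coord != "log_sigma_u":  # a sigma move changes no predictor
            state.refresh_eta()
        new_lp = _scalar_logpost(state, priors)
        if new_lp - cur_lp > math.log(rng.random()):
            cur_lp = new_lp
            state._accept[coord] += 1
        else:
            _set_coord(p, coord, old)
            if coord != "log_sigma_u":
                state.refresh_eta()

    # location interweaving: the field has no sum constraint, so its mean
    # level trades off against the intercepts along a likelihood ridge;
    # shift both intercepts by delta and the field by -delta (eta invariant,
    # only the GP prior and intercept priors enter the ratio)
    sd = math.exp(state.prop_log_sd["shift"])
    delta = sd * rng.standard_normal()
    a = solve_triangular(
        state.chol_corr, p.u - delta, lower=True, check_finite=False
    )
    new_quad = float(a @ a)
    s2 = p.sigma_u**2
    dlp = -0.5 * (new_quad - state.quad) / s2
    m, s = priors.beta0_young
    dlp += (-((p.beta0_young + delta - m) ** 2) + (p.beta0_young - m) ** 2) / (
        2 * s**2
    )
    m, s = priors.beta0_old
    dlp += (-((p.beta0_old + delta - m) ** 2) + (p.beta0_old - m) ** 2) / (2 * s**2)
    if dlp > math.log(rng.random()):
        p.beta0_young += delta
        p.beta0_old += delta
        p.u = p.u - delta
        state.quad = new_quad
        state.refresh_eta()
        cur_lp = _scalar_logpost(state, priors)
        state._accept["shift"] += 1

    # the non-centred moves below target the weakly identified field
    # hyperparameters; they are cheap relative to the count sweep, so they
    # run several times per cycle to lift their effective sample size
    for _ in range(6):
        cur_lp = _move_sigma_interweave(state, priors, rng, cur_lp)
    cur_lp = _move_rho_whitened(state, priors, rng, cur_lp)

    if adapt:
        for coord in _ADAPT_COORDS:
            rate = state._accept[coord] / adapt_interval
            state.prop_log_sd[coord] += adapt_step * (rate - target_accept)
            state._accept[coord] = 0


def _move_sigma_interweave(
    state: ChainState, priors: PriorSpec, rng: np.random.Generator, cur_lp: float
) -> float:
    """Rescale the field jointly with its scale (non-centred move).

    Holding v = u/sigma fixed removes the centred GP prior term from the
    acceptance ratio, side-stepping the funnel between the field and its
    scale when the data are weak.
    """
    p = state.params
    sd = math.exp(state.prop_log_sd["log_sigma_u"])
    old_ls, old_u, old_quad = p.log_sigma_u, p.u, state.quad
    new_ls = old_ls + sd * rng.standard_normal()
    ratio = math.exp(new_ls - old_ls)
    p.log_sigma_u = new_ls
    p.u = old_u * ratio
    state.quad = old_quad * ratio**2
    state.refresh_eta()
    new_lp = _scalar_logpost(state, priors)
    corr_old = _gp_logprior_at(state, old_ls, old_quad)
    corr_new = _gp_logprior_at(state, new_ls, state.quad)
    if (new_lp - corr_new) - (cur_lp - corr_old) > math.log(rng.random()):
        return new_lp
    p.log_sigma_u, p.u, state.quad = old_ls, old_u, old_quad
    state.refresh_eta()
    return cur_lp


def _move_rho_whitened(
    state: ChainState, priors: PriorSpec, rng: np.random.Generator, cur_lp: float
) -> float:
    """Whitened range move: deform the field under a proposed range.

    The standardised innovations L(rho)^-1 u / sigma are held fixed — in
    centred form the high-dimensional field pins the range's conditional
    posterior and a plain random walk on log rho barely moves.
    """
    p = state.params
    sd = math.exp(state.prop_log_sd["rho_nc"])
    new_lr = p.log_rho + sd * rng.standard_normal()
    a = solve_triangular(state.chol_corr, p.u, lower=True, check_finite=False)
    dist = state._dist if state._dist is not None else state.h.distances()
    corr = np.exp(-dist / math.exp(new_lr))
    corr[np.diag_indices_from(corr)] += 1e-8
    try:
        new_chol = cholesky(corr, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return cur_lp
    u_new = new_chol @ a
    ll_old = _binom_ll(state.eta, state.y, state.n_stated)
    ll_new = _field_ll(state, u_new)
    m, s_lr = priors.log_rho
    dlp = (
        ll_new
        - ll_old
        - 0.5 * ((new_lr - m) / s_lr) ** 2
        + 0.5 * ((p.log_rho - m) / s_lr) ** 2
    )
    if dlp > math.log(rng.random()):
        p.log_rho = new_lr
        p.u = u_new
        state.chol_corr = new_chol
        state.corr_logdet = 2.0 * float(np.log(np.diag(new_chol)).sum())
        state.quad = float(a @ a)  # invariant under the deformation
        state.refresh_eta()
        state._accept["rho_nc"] += 1
        return _scalar_logpost(state, priors)
    return cur_lp


def _gp_logprior_at(state: ChainState, log_sigma: float, quad: float) -> float:
    n = state.h.n_fine
    return -0.5 * (
        n * math.log(2 * math.pi)
        + 2 * n * log_sigma
        + state.corr_logdet
        + quad / math.exp(2 * log_sigma)
    )


# ---------------------------------------------------------------------------
# samples container, chain driver, diagnostics

@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from one or more chains.

    y has shape (chains, draws, n_fine, n_ages); u (chains, draws, n_fine);
    each scalar (chains, draws).
    """

    y: np.ndarray
    u: np.ndarray
    scalars: dict[str, np.ndarray]
    fine_ids: list[str]
    age_groups: tuple[str, ...]
    n_stated: np.ndarray
    manifest: dict

    @property
    def n_chains(self) -> int:
        return self.y.shape[0]

    @property
    def n_draws(self) -> int:
        return self.y.shape[1]

    def stacked_y(self) -> np.ndarray:
        """Draws pooled over chains: (chains*draws, n_fine, n_ages)."""
        c, d, n, a = self.y.shape
        return self.y.reshape(c * d, n, a)

    def stacked_scalar(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalars.items():
            c, d = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "iter": np.tile(np.arange(d), c),
                        "name": name,
                        "index": "",
                        "value": arr.reshape(-1),
                    }
                )
            )
        c, d, n, a = self.y.shape
        for ai, age in enumerate(self.age_groups):
            flat = self.y[:, :, :, ai].reshape(c * d, n)
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d).repeat(n),
                        "iter": np.tile(np.repeat(np.arange(d), n), c),
                        "name": "y",
                        "index": np.tile(
                            [f"{u}:{age}" for u in self.fine_ids], c * d
                        ),
                        "value": flat.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_long_df().to_csv(out / "samples.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_chain(
    observed: pd.DataFrame,
    h: Hierarchy,
    pcfg: PerturbConfig,
    priors: PriorSpec,
    mcfg: MCMCConfig,
    n_stated: np.ndarray | None = None,
    progress: bool = False,
) -> PosteriorSamples:
    """Run the blocked Gibbs sampler and return thinned posterior draws.

    Cycles count, field and scalar blocks; stores thinned post-burn-in
    draws per chain.  Running aggregates are recomputed from scratch at a
    fixed cadence and checked for exact integer agreement.
    """
    t0 = time.time()
    ss = np.random.SeedSequence(mcfg.seed)
    chain_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(mcfg.n_chains)]

    n_keep = (mcfg.n_iter - mcfg.n_burn) // mcfg.thin
    accept_rates: list[dict] = []
    first = None
    y_draws = None
    u_draws = None
    scal_draws = {k: None for k in SCALAR_NAMES}

    for ci, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        state = init_state(observed, h, cseed, priors=priors, n_stated=n_stated)
        if first is None:
            first = state
            y_draws = np.zeros(
                (mcfg.n_chains, n_keep, h.n_fine, len(AGE_GROUPS)), dtype=np.int64
            )
            u_draws = np.zeros((mcfg.n_chains, n_keep, h.n_fine))
            scal_draws = {
                k: np.zeros((mcfg.n_chains, n_keep)) for k in SCALAR_NAMES
            }
        kept = 0
        n_batches = 0
        count_acc = 0
        for it in range(1, mcfg.n_iter + 1):
            acc = update_counts(state, pcfg, rng, mcfg.count_proposal_sd)
            update_field(state, rng)
            adapt = it <= mcfg.n_burn and it % mcfg.adapt_interval == 0
            if adapt:
                n_batches += 1
            update_scalars(
                state,
                priors,
                rng,
                adapt=adapt,
                adapt_interval=mcfg.adapt_interval,
                adapt_step=1.0 / math.sqrt(n_batches) if adapt else 0.0,
                target_accept=mcfg.target_accept,
            )
            if it == mcfg.n_burn:  # clean window for post-burn-in rates
                state._accept = {c: 0 for c in _ADAPT_COORDS}
            if it > mcfg.n_burn:
                count_acc += acc
            if it % mcfg.recompute_interval == 0:
                fresh = state.obs.aggregate(state.y)
                if not np.array_equal(fresh, state.agg_flat):  # pragma: no cover
                    raise RuntimeError("aggregate cache drifted from fine counts")
                state.agg_flat = fresh
            if it > mcfg.n_burn and (it - mcfg.n_burn) % mcfg.thin == 0:
                p = state.params
                y_draws[ci, kept] = state.y
                u_draws[ci, kept] = p.u
                g = p.gamma
                vals = (
                    p.beta0_young, p.beta0_old, p.beta_ses,
                    g[0], g[1], g[2], g[3], g[4],
                    p.log_sigma_u, p.log_rho, p.w,
                )
                for k, v in zip(SCALAR_NAMES, vals):
                    scal_draws[k][ci, kept] = v
                kept += 1
            if progress and it % 1000 == 0:
                print(f"chain {ci}: iteration {it}/{mcfg.n_iter}")
        post = mcfg.n_iter - mcfg.n_burn
        accept_rates.append(
            {
                "counts": count_acc / max(post * h.n_fine * len(AGE_GROUPS), 1),
                **{c: state._accept[c] / post for c in _ADAPT_COORDS},
            }
        )

    manifest = {
        "accept_rates": accept_rates,
        "n_stated": np.asarray(first.n_stated).tolist(),
        "mcmc_config": asdict(mcfg),
        "perturb_config": asdict(pcfg),
        "priors": asdict(priors),
        "chain_seeds": chain_seeds,
        "wall_clock_s": time.time() - t0,
        "input_hash": hashlib.sha256(
            observed.to_csv(index=False).encode()
            + first.h.units.to_csv(index=False).encode()
        ).hexdigest(),
    }
    return PosteriorSamples(
        y=y_draws,
        u=u_draws,
        scalars=scal_draws,
        fine_ids=h.fine_ids,
        age_groups=AGE_GROUPS,
        n_stated=np.asarray(first.n_stated),
        manifest=manifest,
    )


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Rank-normalised split R-hat and effective sample size per scalar.

    Requires at least 2 chains or 200 draws.  Degenerate (constant) chains
    are flagged rather than reported with a numeric value.
    """
    import warnings

    import arviz as az

    if samples.n_chains < 2 and samples.n_draws < 200:
        raise ValueError("need >= 2 chains or >= 200 draws for diagnostics")
    rows = []
    for name, arr in samples.scalars.items():
        if np.allclose(arr.std(), 0.0):
            rows.append((name, np.nan, np.nan, True))
            continue
        data = az.convert_to_dataset({name: arr})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(data)[name].values)
            ess = float(az.ess(data)[name].values)
        flagged = not np.isfinite(rhat) or not np.isfinite(ess)
        rows.append((name, rhat, ess, flagged))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
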