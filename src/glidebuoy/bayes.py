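"""Hierarchical Bayesian estimation of glide-model parameters.

The observation model treats each 5-s glide segment's measured
acceleration as Gaussian around the hydrodynamic prediction, with the
per-segment residual RMS as known observation error::

    a_i ~ Normal( f(theta_{group(i)}; v_i, p_i, d_i, rho_sw_i), sigma_i )

Tissue density, the combined drag term and the diving gas volume can be
global, per-group (individual or dive) or hierarchical — per-group values
drawn from a truncated normal around an estimated population mean with an
estimated between-group s.d.  Tissue compressibility r is always a single
global scalar when included.

Sampling uses a blocked adaptive Metropolis-within-Gibbs kernel: all
groups of a block are proposed jointly and accepted elementwise (valid
because, conditional on the remaining blocks, group values enter disjoint
likelihood factors), with per-element random-walk scales adapted toward a
0.44 acceptance rate during burn-in and frozen afterwards.  The default
protocol is 3 chains x 24,000 iterations, 12,000 burn-in, thinning by 36.
Model comparison uses the deviance information criterion
DIC = Dbar + pD with pD = Dbar - D(posterior mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import InsufficientDataError
from .hydro import ML_PER_KG_TO_M3_PER_KG

__all__ = [
    "ModelSpec",
    "Priors",
    "PosteriorResult",
    "GlideModel",
    "build_model",
    "run_mcmc",
    "gelman_rubin",
    "compute_dic",
    "fit_and_compare",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

DENSITY_LEVELS = ("global", "individual", "hierarchical")
DRAG_LEVELS = ("global", "individual", "hierarchical")
GAS_LEVELS = ("global", "individual", "dive", "hierarchical-dive")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters vary at which level."""

    density_level: str = "hierarchical"
    drag_level: str = "global"
    gas_level: str = "global"
    include_compressibility: bool = True
    error_scale: bool = False  # optional global multiplicative error scale

    def __post_init__(self) -> None:
        if self.density_level not in DENSITY_LEVELS:
            raise ValueError(f"density_level must be one of {DENSITY_LEVELS}")
        if self.drag_level not in DRAG_LEVELS:
            raise ValueError(f"drag_level must be one of {DRAG_LEVELS}")
        if self.gas_level not in GAS_LEVELS:
            raise ValueError(f"gas_level must be one of {GAS_LEVELS}")

    @property
    def label(self) -> str:
        parts = [
            f"density={self.density_level}",
            f"drag={self.drag_level}",
            f"gas={self.gas_level}",
            f"r={'on' if self.include_compressibility else 'off'}",
        ]
        return ",".join(parts)


@dataclass(frozen=True)
class Priors:
    """Prior specification for the glide model.

    Tissue density and the global gas mean carry uniform (non-informative)
    priors; the drag term carries an informative truncated normal built
    from drag-coefficient, surface-area and mass estimates for
    similar-sized cetaceans; compressibility r is uniform on a narrow
    physical band around seawater's value.  Between-group s.d. hyperpriors
    are uniform on zero-to-wide ranges spanning observed spreads.
    """

    r_bounds: Tuple[float, float] = (0.3e-9, 0.7e-9)
    density_bounds: Tuple[float, float] = (800.0, 1200.0)
    gas_global_bounds: Tuple[float, float] = (5.0, 50.0)
    gas_value_bounds: Tuple[float, float] = (0.0, 200.0)
    drag_mean: float = 10.0e-6
    drag_sd: float = 2.0e-6
    drag_bounds: Tuple[float, float] = (5.0e-6, 20.0e-6)
    density_group_sd_max: float = 20.0
    drag_group_sd_max: float = 10.0e-6
    gas_group_sd_max: float = 50.0
    error_scale_bounds: Tuple[float, float] = (0.1, 10.0)


def _trunc_norm_loglik(x: np.ndarray, mu: float, sd: float, lo: float, hi: float) -> float:
    """Sum of truncated-normal log densities (normalization included)."""
    if sd <= 0:
        return -np.inf
    x = np.atleast_1d(x)
    if np.any(x < lo) or np.any(x > hi):
        return -np.inf
    z = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    if z <= 0:
        return -np.inf
    return float(
        -0.5 * np.sum(((x - mu) / sd) ** 2)
        - x.size * (np.log(sd) + np.log(z) + 0.5 * _LOG_2PI)
    )


@dataclass
class _Block:
    """One vector of group-level parameters plus its prior bookkeeping."""

    name: str
    level: str
    size: int
    seg_group: np.ndarray  # segment -> group index
    bounds: Tuple[float, float]
    prior_kind: str  # "uniform" | "truncnorm" | "hier"
    prior_mu: float = 0.0
    prior_sd: float = 1.0
    hyper_mu_prior: Optional[Tuple[str, float, float, float, float]] = None
    hyper_sd_max: float = 1.0
    group_names: List[str] = field(default_factory=list)


class GlideModel:
    """Evaluable log-prior + log-likelihood for a glide-segment table."""

    def __init__(
        self,
        segments: pd.DataFrame,
        spec: ModelSpec,
        priors: Priors,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
        sigma_floor: float = 1.0e-3,
    ) -> None:
        if len(segments) == 0:
            raise InsufficientDataError("empty segment table")
        seg = segments.reset_index(drop=True)
        self.spec = spec
        self.priors = priors
        self.constants = constants
        self.n_seg = len(seg)

        self.a_obs = seg["a"].to_numpy(dtype=float)
        v = seg["v"].to_numpy(dtype=float)
        p = seg["p"].to_numpy(dtype=float)
        d = seg["d"].to_numpy(dtype=float)
        self.rho_sw = seg["rho_sw"].to_numpy(dtype=float)
        sigma = np.maximum(seg["sigma_a"].to_numpy(dtype=float), sigma_floor)
        self.sigma = sigma
        self.inv_var = 1.0 / sigma**2
        self.log_sigma_sum = float(np.sum(np.log(sigma)))

        self.v2 = v**2
        self.gsinp = constants.g * np.sin(p)
        self.P = constants.atm_pa * d / constants.m_per_atm
        q = 1.0 + d / constants.m_per_atm
        # gas factor: per ml/kg of surface air, buoyancy contribution
        self.gas_factor = (
            self.gsinp
            * (ML_PER_KG_TO_M3_PER_KG / q)
            * (self.rho_sw - constants.rho_air_surface * q)
        )

        ind_codes, ind_ids = pd.factorize(seg["individual_id"])
        dive_key = seg["individual_id"].astype(str) + ":" + seg["dive_id"].astype(str)
        dive_codes, dive_ids = pd.factorize(dive_key)
        self.individual_ids = [str(i) for i in ind_ids]
        self.dive_ids = [str(i) for i in dive_ids]
        self.n_individuals = len(ind_ids)
        self.n_dives = len(dive_ids)
        zeros = np.zeros(self.n_seg, dtype=np.intp)

        pr = priors
        # --- density block ---
        if spec.density_level == "global":
            self.density = _Block(
                "rho_tissue", "global", 1, zeros, pr.density_bounds, "uniform",
                group_names=["rho_tissue"],
            )
        else:
            kind = "hier" if spec.density_level == "hierarchical" else "uniform"
            self.density = _Block(
                "rho_tissue", spec.density_level, self.n_individuals,
                ind_codes.astype(np.intp), pr.density_bounds, kind,
                hyper_mu_prior=("uniform", *pr.density_bounds, 0.0, 0.0),
                hyper_sd_max=pr.density_group_sd_max,
                group_names=[f"rho_tissue[{i}]" for i in self.individual_ids],
            )
        # --- drag block (informative prior at every level) ---
        if spec.drag_level == "global":
            self.drag = _Block(
                "drag", "global", 1, zeros, pr.drag_bounds, "truncnorm",
                prior_mu=pr.drag_mean, prior_sd=pr.drag_sd, group_names=["drag"],
            )
        else:
            kind = "hier" if spec.drag_level == "hierarchical" else "truncnorm"
            self.drag = _Block(
                "drag", spec.drag_level, self.n_individuals,
                ind_codes.astype(np.intp), pr.drag_bounds, kind,
                prior_mu=pr.drag_mean, prior_sd=pr.drag_sd,
                hyper_mu_prior=("truncnorm", *pr.drag_bounds, pr.drag_mean, pr.drag_sd),
                hyper_sd_max=pr.drag_group_sd_max,
                group_names=[f"drag[{i}]" for i in self.individual_ids],
            )
        # --- gas block ---
        if spec.gas_level == "global":
            self.gas = _Block(
                "vair", "global", 1, zeros, pr.gas_global_bounds, "uniform",
                group_names=["vair"],
            )
        elif spec.gas_level == "individual":
            self.gas = _Block(
                "vair", "individual", self.n_individuals, ind_codes.astype(np.intp),
                pr.gas_value_bounds, "uniform",
                group_names=[f"vair[{i}]" for i in self.individual_ids],
            )
        else:
            kind = "hier" if spec.gas_level == "hierarchical-dive" else "uniform"
            self.gas = _Block(
                "vair", spec.gas_level, self.n_dives, dive_codes.astype(np.intp),
                pr.gas_value_bounds, kind,
                hyper_mu_prior=("uniform", *pr.gas_global_bounds, 0.0, 0.0),
                hyper_sd_max=pr.gas_group_sd_max,
                group_names=[f"vair[{i}]" for i in self.dive_ids],
            )
        self.blocks = [self.density, self.drag, self.gas]
        for blk in self.blocks:
            if np.bincount(blk.seg_group, minlength=blk.size).min() == 0:
                raise InsufficientDataError(
                    f"a {blk.name} group has zero segments under spec {spec.label}"
                )

    # ---- likelihood pieces -------------------------------------------------
    def contributions(self, density, drag, gas, r):
        """(drag, tissue, gas) contribution arrays for given block values."""
        dens_seg = np.asarray(density)[self.density.seg_group]
        drag_seg = np.asarray(drag)[self.drag.seg_group]
        gas_seg = np.asarray(gas)[self.gas.seg_group]
        dc = -0.5 * drag_seg * self.rho_sw * self.v2
        tc = self.gsinp * (self.rho_sw * (1.0 - r * self.P) / dens_seg - 1.0)
        gc = self.gas_factor * gas_seg
        return dc, tc, gc

    def log_likelihood(self, density, drag, gas, r, error_scale: float = 1.0):
        """Full Gaussian log-likelihood (constants included)."""
        dc, tc, gc = self.contributions(density, drag, gas, r)
        resid = self.a_obs - (dc + tc + gc)
        return float(
            -0.5 * np.sum(self.inv_var * resid**2) / error_scale**2
            - self.log_sigma_sum
            - self.n_seg * (np.log(error_scale) + 0.5 * _LOG_2PI)
        )

    def deviance(self, density, drag, gas, r, error_scale: float = 1.0) -> float:
        return -2.0 * self.log_likelihood(density, drag, gas, r, error_scale)


def build_model(
    segments,
    spec: ModelSpec,
    priors: Priors = Priors(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    sigma_floor: float = 1.0e-3,
) -> GlideModel:
    """Assemble the evaluable model object from a glide-segment table."""
    if not isinstance(segments, pd.DataFrame):
        segments = pd.DataFrame([s.__dict__ for s in segments])
    return GlideModel(segments, spec, priors, constants, sigma_floor)


@dataclass
class PosteriorResult:
    """MCMC output: per-parameter chains, summaries, diagnostics, DIC."""

    draws: Dict[str, np.ndarray]  # block name -> (n_chains, n_kept, size)
    param_names: Dict[str, List[str]]
    summaries: pd.DataFrame
    dic: float
    pd_eff: float
    spec: ModelSpec
    seed: int
    protocol: Dict[str, int]

    def chain_array(self, param: str) -> np.ndarray:
        """(n_chains, n_kept) draws for one named scalar parameter."""
        for block, names in self.param_names.items():
            if param in names:
                j = names.index(param)
                return self.draws[block][:, :, j]
        raise KeyError(param)

    def pooled(self, param: str) -> np.ndarray:
        return self.chain_array(param).reshape(-1)

    def to_netcdf(self, path) -> None:
        import xarray as xr

        data = {}
        for block, arr in self.draws.items():
            data[block] = xr.DataArray(
                arr,
                dims=("chain", "draw", f"{block}_group"),
                coords={f"{block}_group": self.param_names[block]},
            )
        ds = xr.Dataset(data, attrs={
            "dic": self.dic, "pD": self.pd_eff, "seed": self.seed,
            "spec": self.spec.label,
        })
        ds.to_netcdf(path, engine="scipy")


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor (between/within variance-ratio form).

    ``chains`` has shape (n_chains, n_draws); requires >= 2 chains with
    >= 2 draws each (short chains give a noisy diagnostic).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of >= 2 draws")
    m, n = chains.shape
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if w == 0:
        warnings.warn("degenerate chains: zero within-chain variance")
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


class _SamplerState:
    """Mutable per-chain state of the blocked Metropolis-within-Gibbs kernel."""

    def __init__(self, model: GlideModel, rng: np.random.Generator):
        self.model = model
        pr = model.priors

        def jit(x):
            return x * (1.0 + 0.01 * rng.standard_normal())

        self.values: Dict[str, np.ndarray] = {}
        self.hyper: Dict[str, Tuple[float, float]] = {}
        self.steps: Dict[str, np.ndarray] = {}
        self.hyper_steps: Dict[str, np.ndarray] = {}
        for blk, init, step in (
            (model.density, 0.5 * sum(pr.density_bounds), 1.0),
            (model.drag, pr.drag_mean, 0.1 * pr.drag_sd),
            (model.gas, 0.5 * sum(pr.gas_global_bounds), 2.0),
        ):
            v = np.clip(
                np.full(blk.size, init) * (1 + 0.01 * rng.standard_normal(blk.size)),
                blk.bounds[0], blk.bounds[1],
            )
            self.values[blk.name] = v
            self.steps[blk.name] = np.full(blk.size, step)
            if blk.prior_kind == "hier":
                mu0 = float(np.clip(jit(init), *blk.bounds))
                sd0 = float(max(blk.hyper_sd_max * 0.25 * (1 + 0.01 * rng.standard_normal()), 1e-6 * blk.hyper_sd_max))
                self.hyper[blk.name] = (mu0, sd0)
                self.hyper_steps[blk.name] = np.array(
                    [0.1 * (blk.bounds[1] - blk.bounds[0]) / 20, 0.05 * blk.hyper_sd_max]
                )
        if model.spec.include_compressibility:
            self.r = float(np.clip(jit(0.5 * sum(pr.r_bounds)), *pr.r_bounds))
        else:
            self.r = 0.0
        self.r_step = 0.02e-9
        self.error_scale = 1.0
        self.es_step = 0.05

        dc, tc, gc = model.contributions(
            self.values["rho_tissue"], self.values["drag"], self.values["vair"], self.r
        )
        self.dc, self.tc, self.gc = dc, tc, gc
        self.pred = dc + tc + gc

    # -- helpers -------------------------------------------------------------
    def _value_logprior_delta(self, blk: _Block, prop: np.ndarray, cur: np.ndarray):
        """Elementwise prior log-density difference (hyper terms constant)."""
        lo, hi = blk.bounds
        inb = (prop >= lo) & (prop <= hi)
        if blk.prior_kind == "uniform":
            d = np.zeros(blk.size)
        else:
            if blk.prior_kind == "hier":
                mu, sd = self.hyper[blk.name]
            else:
                mu, sd = blk.prior_mu, blk.prior_sd
            d = -0.5 * (((prop - mu) / sd) ** 2 - ((cur - mu) / sd) ** 2)
        return np.where(inb, d, -np.inf)

    def update_block(self, blk: _Block, rng, adapt_gamma: Optional[float]) -> None:
        model = self.model
        cur = self.values[blk.name]
        prop = cur + self.steps[blk.name] * rng.standard_normal(blk.size)
        dlp = self._value_logprior_delta(blk, prop, cur)
        prop_seg = prop[blk.seg_group]
        if blk.name == "rho_tissue":
            new_contrib = model.gsinp * (
                model.rho_sw * (1.0 - self.r * model.P) / prop_seg - 1.0
            )
            old_contrib = self.tc
        elif blk.name == "drag":
            new_contrib = -0.5 * prop_seg * model.rho_sw * model.v2
            old_contrib = self.dc
        else:
            new_contrib = model.gas_factor * prop_seg
            old_contrib = self.gc
        pred_new = self.pred + (new_contrib - old_contrib)
        dll_seg = (
            -0.5
            * model.inv_var
            * ((model.a_obs - pred_new) ** 2 - (model.a_obs - self.pred) ** 2)
            / self.error_scale**2
        )
        dll = np.bincount(blk.seg_group, weights=dll_seg, minlength=blk.size)
        accept = np.log(rng.uniform(size=blk.size)) < dll + dlp
        if np.any(accept):
            acc_seg = accept[blk.seg_group]
            merged = np.where(acc_seg, new_contrib, old_contrib)
            if blk.name == "rho_tissue":
                self.tc = merged
            elif blk.name == "drag":
                self.dc = merged
            else:
                self.gc = merged
            self.pred = np.where(acc_seg, pred_new, self.pred)
            self.values[blk.name] = np.where(accept, prop, cur)
        if adapt_gamma is not None:
            self.steps[blk.name] *= np.exp(adapt_gamma * (accept.astype(float) - 0.44))

    def update_r(self, rng, adapt_gamma: Optional[float]) -> None:
        model = self.model
        lo, hi = model.priors.r_bounds
        prop = self.r + self.r_step * rng.standard_normal()
        accept = False
        if lo <= prop <= hi:
            dens_seg = self.values["rho_tissue"][model.density.seg_group]
            tc_new = model.gsinp * (
                model.rho_sw * (1.0 - prop * model.P) / dens_seg - 1.0
            )
            pred_new = self.pred + (tc_new - self.tc)
            dll = float(
                -0.5
                * np.sum(
                    model.inv_var
                    * ((model.a_obs - pred_new) ** 2 - (model.a_obs - self.pred) ** 2)
                )
                / self.error_scale**2
            )
            if np.log(rng.uniform()) < dll:
                self.r = float(prop)
                self.tc = tc_new
                self.pred = pred_new
                accept = True
        if adapt_gamma is not None:
            self.r_step *= np.exp(adapt_gamma * (float(accept) - 0.44))

    def update_error_scale(self, rng, adapt_gamma: Optional[float]) -> None:
        model = self.model
        lo, hi = model.priors.error_scale_bounds
        prop = self.error_scale + self.es_step * rng.standard_normal()
        accept = False
        if lo <= prop <= hi:
            ssq = float(np.sum(model.inv_var * (model.a_obs - self.pred) ** 2))
            dll = (
                -0.5 * ssq * (1.0 / prop**2 - 1.0 / self.error_scale**2)
                - model.n_seg * (np.log(prop) - np.log(self.error_scale))
            )
            if np.log(rng.uniform()) < dll:
                self.error_scale = float(prop)
                accept = True
        if adapt_gamma is not None:
            self.es_step *= np.exp(adapt_gamma * (float(accept) - 0.44))

    def _hyper_logpost(self, blk: _Block, mu: float, sd: float) -> float:
        if not (blk.bounds[0] <= mu <= blk.bounds[1]) or not (0 < sd <= blk.hyper_sd_max):
            return -np.inf
        ll = _trunc_norm_loglik(self.values[blk.name], mu, sd, *blk.bounds)
        kind, lo, hi, pm, ps = blk.hyper_mu_prior
        if kind == "truncnorm":
            ll += _trunc_norm_loglik(np.array([mu]), pm, ps, lo, hi)
        return ll

    def update_hypers(self, blk: _Block, rng, adapt_gamma: Optional[float]) -> None:
        mu, sd = self.hyper[blk.name]
        steps = self.hyper_steps[blk.name]
        cur_lp = self._hyper_logpost(blk, mu, sd)
        for j, name in enumerate(("mu", "sd")):
            if name == "mu":
                cand = (mu + steps[0] * rng.standard_normal(), sd)
            else:
                cand = (mu, sd + steps[1] * rng.standard_normal())
            lp = self._hyper_logpost(blk, *cand)
            accept = np.log(rng.uniform()) < lp - cur_lp
            if accept:
                mu, sd = cand
                cur_lp = lp
            if adapt_gamma is not None:
                steps[j] *= np.exp(adapt_gamma * (float(accept) - 0.44))
        self.hyper[blk.name] = (mu, sd)


_HYPER_LABEL = {"rho_tissue": ("mu_rho_tissue", "sd_rho_tissue"),
                "drag": ("mu_drag", "sd_drag"),
                "vair": ("mu_vair", "sd_vair")}


def run_mcmc(
    model: GlideModel,
    n_chains: int = 3,
    n_iter: int = 24000,
    n_burn: int = 12000,
    thin: int = 36,
    seed: int = 0,
) -> PosteriorResult:
    """Sample the posterior with the blocked adaptive MH-within-Gibbs kernel.

    Identical seeds give bit-identical output.  Step sizes adapt only
    during burn-in.  Retained draws per chain: ceil((n_iter-n_burn)/thin).
    """
    if n_burn >= n_iter:
        raise ValueError("n_burn must be < n_iter")
    keep_iters = range(n_burn, n_iter, thin)
    n_kept = len(keep_iters)
    keep_set = set(keep_iters)

    block_names = [b.name for b in model.blocks]
    hyper_blocks = [b for b in model.blocks if b.prior_kind == "hier"]
    draws: Dict[str, np.ndarray] = {
        b.name: np.empty((n_chains, n_kept, b.size)) for b in model.blocks
    }
    for b in hyper_blocks:
        mu_name, sd_name = _HYPER_LABEL[b.name]
        draws[mu_name] = np.empty((n_chains, n_kept, 1))
        draws[sd_name] = np.empty((n_chains, n_kept, 1))
    if model.spec.include_compressibility:
        draws["r"] = np.empty((n_chains, n_kept, 1))
    if model.spec.error_scale:
        draws["error_scale"] = np.empty((n_chains, n_kept, 1))

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(chain,)))
        state = None
        for attempt in range(5):
            state = _SamplerState(model, rng)
            if np.all(np.isfinite(state.pred)):
                break
        else:
            raise RuntimeError("non-finite log-posterior at initialization")
        k = 0
        for it in range(n_iter):
            gamma = min(0.2, (it + 10.0) ** -0.6) if it < n_burn else None
            for blk in model.blocks:
                state.update_block(blk, rng, gamma)
            if model.spec.include_compressibility:
                state.update_r(rng, gamma)
            if model.spec.error_scale:
                state.update_error_scale(rng, gamma)
            for blk in hyper_blocks:
                state.update_hypers(blk, rng, gamma)
            if it in keep_set:
                for b in model.blocks:
                    draws[b.name][chain, k] = state.values[b.name]
                for b in hyper_blocks:
                    mu_name, sd_name = _HYPER_LABEL[b.name]
                    draws[mu_name][chain, k, 0] = state.hyper[b.name][0]
                    draws[sd_name][chain, k, 0] = state.hyper[b.name][1]
                if model.spec.include_compressibility:
                    draws["r"][chain, k, 0] = state.r
                if model.spec.error_scale:
                    draws["error_scale"][chain, k, 0] = state.error_scale
                k += 1

    param_names: Dict[str, List[str]] = {
        b.name: list(b.group_names) for b in model.blocks
    }
    for b in hyper_blocks:
        mu_name, sd_name = _HYPER_LABEL[b.name]
        param_names[mu_name] = [mu_name]
        param_names[sd_name] = [sd_name]
    if model.spec.include_compressibility:
        param_names["r"] = ["r"]
    if model.spec.error_scale:
        param_names["error_scale"] = ["error_scale"]

    rows = []
    for block, names in param_names.items():
        arr = draws[block]
        for j, name in enumerate(names):
            pooled = arr[:, :, j].reshape(-1)
            rows.append({
                "parameter": name,
                "mean": float(np.mean(pooled)),
                "ci_2.5": float(np.quantile(pooled, 0.025)),
                "ci_97.5": float(np.quantile(pooled, 0.975)),
                "rhat": gelman_rubin(arr[:, :, j]) if n_kept >= 10 else np.nan,
            })
    summaries = pd.DataFrame(rows).set_index("parameter")

    result = PosteriorResult(
        draws=draws,
        param_names=param_names,
        summaries=summaries,
        dic=np.nan,
        pd_eff=np.nan,
        spec=model.spec,
        seed=int(seed),
        protocol={"n_chains": n_chains, "n_iter": n_iter, "n_burn": n_burn, "thin": thin},
    )
    dic, pd_eff = compute_dic(result, model)
    result.dic, result.pd_eff = dic, pd_eff
    summaries.attrs["dic"] = dic
    return result


def compute_dic(result: PosteriorResult, model: GlideModel) -> Tuple[float, float]:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean).

    Non-finite deviance draws are dropped (with a warning giving the
    count).
    """
    dens = result.draws["rho_tissue"]
    drag = result.draws["drag"]
    gas = result.draws["vair"]
    n_chains, n_kept, _ = dens.shape
    r_draws = result.draws.get("r")
    es_draws = result.draws.get("error_scale")
    devs = np.empty(n_chains * n_kept)
    idx = 0
    for c in range(n_chains):
        for k in range(n_kept):
            r = float(r_draws[c, k, 0]) if r_draws is not None else 0.0
            es = float(es_draws[c, k, 0]) if es_draws is not None else 1.0
            devs[idx] = model.deviance(dens[c, k], drag[c, k], gas[c, k], r, es)
            idx += 1
    finite = np.isfinite(devs)
    if not np.all(finite):
        warnings.warn(f"dropped {int(np.sum(~finite))} non-finite deviance draws")
        devs = devs[finite]
    d_bar = float(np.mean(devs))
    d_at_mean = model.deviance(
        dens.mean(axis=(0, 1)),
        drag.mean(axis=(0, 1)),
        gas.mean(axis=(0, 1)),
        float(r_draws.mean()) if r_draws is not None else 0.0,
        float(es_draws.mean()) if es_draws is not None else 1.0,
    )
    pd_eff = d_bar - d_at_mean
    return d_bar + pd_eff, pd_eff


def _global_mean(result: PosteriorResult, block: str, hyper: str) -> float:
    if hyper in result.param_names:
        return float(result.draws[hyper].mean())
    return float(result.draws[block].mean())


def fit_and_compare(
    segments,
    specs: Sequence[ModelSpec],
    priors: Priors = Priors(),
    seed: int = 0,
    **mcmc_kwargs,
) -> Tuple[pd.DataFrame, List[PosteriorResult]]:
    """Fit each candidate spec and tabulate DIC with key posterior means.

    Returns the comparison table sorted by DIC (best first) and the
    corresponding PosteriorResult objects in spec order.
    """
    if len(specs) < 1:
        raise ValueError("need at least one spec")
    results = []
    rows = []
    for spec in specs:
        model = build_model(segments, spec, priors)
        res = run_mcmc(model, seed=seed, **mcmc_kwargs)
        results.append(res)
        rows.append({
            "spec": spec.label,
            "dic": res.dic,
            "pD": res.pd_eff,
            "rho_tissue_global": _global_mean(res, "rho_tissue", "mu_rho_tissue"),
            "vair_global": _global_mean(res, "vair", "mu_vair"),
            "drag_global": _global_mean(res, "drag", "mu_drag"),
            "r": float(res.draws["r"].mean()) if "r" in res.draws else 0.0,
        })
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    return table, results
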