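"""Hierarchical multispecies occupancy model (MSOM) with data augmentation.

Model hierarchy, for taxon k, visit i, replicate j:

    w_k   ~ Bernoulli(Omega)                      (metacommunity membership)
    z_ik  ~ Bernoulli(w_k * psi_ik)               (occupancy state)
    y_ijk | z_ik ~ Bernoulli(z_ik * p_ijk)        (detection)
    logit(psi_ik) = lpsi_k + betalpsi_k . x_i
    logit(p_ijk)  = lp_k   + betalp_k  . v_ij

Taxon intercepts and slopes are normal random effects governed by community
hyperparameters (mu, sigma). The observed taxon list is augmented to a
superpopulation of M potential taxa; regional richness (gamma) is the
posterior of sum(w_k). Covariate selection uses Kuo-Mallick binary
indicators V_x ~ Bernoulli(0.5) multiplying each covariate's contribution.

Inference is adaptive random-walk Metropolis-within-Gibbs, fully vectorized
across taxa: latent z and w have exact full conditionals (z marginalized out
when updating w for never-detected taxa), Omega and the hyper-means are
conjugate, and taxon-level logit parameters and hyper-SDs use random-walk
proposals whose scales adapt toward a target acceptance rate during burn-in
only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit

from .dataset import DetectionDataset
from .diagnostics import gelman_rubin

__all__ = [
    "PriorSpec",
    "MSOMConfig",
    "PosteriorSamples",
    "marginal_loglik_site_taxon",
    "update_z",
    "w_conditional_prob",
    "omega_conditional",
    "fit_msom",
    "estimate_gamma",
]


def _log_expit(x):
    """log(expit(x)), stable for large |x|."""
    return -np.logaddexp(0.0, -x)


def _log_expit_pair(eta):
    """(log expit(eta), log expit(-eta)) via one expit; clipped at 1e-15.

    Much faster than two logaddexp calls on large arrays; the clip bounds
    log-probabilities at ~-34.5, ample for Metropolis ratios.
    """
    p = expit(eta)
    np.clip(p, 1e-15, 1.0 - 1e-15, out=p)
    return np.log(p), np.log1p(-p)


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for the community hyperparameters.

    Hyper-means are Normal(mu_mean, mu_sd^2) on the logit scale; hyper-SDs
    Uniform(0, sigma_upper); the inclusion probability Omega is
    Beta(omega_a, omega_b).
    """

    mu_mean: float = 0.0
    mu_sd: float = 1.5
    sigma_upper: float = 5.0
    omega_a: float = 1.0
    omega_b: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_sd <= 0 or self.sigma_upper <= 0:
            raise ValueError("prior scales must be > 0")
        if self.omega_a <= 0 or self.omega_b <= 0:
            raise ValueError("Beta prior parameters must be > 0")


@dataclasses.dataclass
class MSOMConfig:
    """Model and MCMC settings for :func:`fit_msom`."""

    n_chains: int = 3
    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 10
    M: int | None = None  # superpopulation size; default 2x observed richness
    augment: bool = True
    select_occ_covariates: bool = False
    select_det_covariates: bool = False
    fit_hypers: bool = True
    # fixed hyperparameters when fit_hypers=False:
    fixed_mu_lpsi: float = 0.0
    fixed_sigma_lpsi: float = 1.5
    fixed_mu_lp: float = 0.0
    fixed_sigma_lp: float = 1.5
    store_z: bool = False
    store_taxon_params: bool = True
    adapt_target: float = 0.35
    progress_every: int = 0
    # permit visits with no replicate samples (prior-propagation studies)
    allow_empty_visits: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


# ---------------------------------------------------------------------------
# Reference full-conditional operations (scalar/1D; the fit vectorizes these)
# ---------------------------------------------------------------------------

def _check_probs(psi, p_vec):
    p_vec = np.asarray(p_vec, dtype=float)
    if p_vec.ndim != 1 or p_vec.size == 0:
        raise ValueError("p_vec must be a nonempty 1-D vector")
    if not (0.0 <= psi <= 1.0) or ((p_vec < 0) | (p_vec > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return p_vec


def marginal_loglik_site_taxon(y_vec, psi, p_vec) -> float:
    """Log-likelihood of one taxon's replicate history at one visit, z summed out.

    Returns log[ psi * prod_j p_j^y_j (1-p_j)^(1-y_j) + (1-psi) * 1{all y=0} ].
    """
    p_vec = _check_probs(psi, p_vec)
    y_vec = np.asarray(y_vec)
    if y_vec.shape != p_vec.shape:
        raise ValueError("y_vec and p_vec must have equal length")
    with np.errstate(divide="ignore"):
        ll_det = np.where(y_vec > 0, np.log(p_vec), np.log1p(-p_vec)).sum()
    present = psi * np.exp(ll_det)
    absent = (1.0 - psi) if not (y_vec > 0).any() else 0.0
    with np.errstate(divide="ignore"):
        return float(np.log(present + absent))


def update_z(y_vec, psi, p_vec, rng) -> int:
    """Draw the latent occupancy state from its full conditional (w=1 assumed)."""
    p_vec = _check_probs(psi, p_vec)
    y_vec = np.asarray(y_vec)
    if (y_vec > 0).any():
        return 1
    q0 = np.prod(1.0 - p_vec)
    num = psi * q0
    prob = num / (num + (1.0 - psi)) if num + (1.0 - psi) > 0 else 0.0
    return int(rng.random() < prob)


def w_conditional_prob(omega, psi_by_visit, p_by_visit) -> float:
    """P(w=1 | all y = 0) for a never-detected taxon, z marginalized out.

    ``psi_by_visit`` is the occupancy probability per visit; ``p_by_visit``
    a list of per-replicate detection probability vectors, one per visit.
    """
    L = 1.0
    for psi, p_vec in zip(psi_by_visit, p_by_visit):
        p_vec = _check_probs(psi, p_vec)
        L *= psi * np.prod(1.0 - p_vec) + (1.0 - psi)
    num = omega * L
    return float(num / (num + (1.0 - omega)))


def omega_conditional(prior: PriorSpec, w) -> tuple:
    """Beta full-conditional parameters for Omega given membership indicators."""
    w = np.asarray(w)
    return (prior.omega_a + w.sum(), prior.omega_b + (w.size - w.sum()))


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws, per chain, plus fitted-probability summaries."""

    samples: dict  # name -> array (n_chains, n_draws, ...)
    n_chains: int
    n_iter: int
    burn_in: int
    thin: int
    seed: object
    acceptance: dict
    mean_psi: np.ndarray | None = None  # (I, M) posterior mean occupancy prob
    mean_p: np.ndarray | None = None  # (I, J, M) posterior mean detection prob
    mean_zp: np.ndarray | None = None  # (I, J, M) posterior mean of z*p
    mean_z: np.ndarray | None = None  # (I, M) posterior occupancy prob of z
    taxon_ids: list | None = None
    n_observed: int = 0
    M: int = 0

    def get(self, name) -> np.ndarray:
        """Draws pooled across chains: shape (n_chains * n_draws, ...)."""
        arr = self.samples[name]
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def summary(self, name):
        """Posterior mean and central 95% interval for one parameter."""
        x = self.get(name).astype(float)
        return {
            "mean": x.mean(axis=0),
            "lo95": np.quantile(x, 0.025, axis=0),
            "hi95": np.quantile(x, 0.975, axis=0),
        }

    def detection_residuals(self, data, rng=None, mode: str = "randomized"):
        """Dunn-Smyth residuals of the observations against the fitted model.

        Marginally y_ijk ~ Bernoulli(E[z_ik p_ijk]); the randomized quantile
        residuals of the observed detections against the posterior-mean
        fitted probabilities are ~N(0,1) when the model is adequate.
        Returns (residuals, fitted_probabilities) over existing replicates
        of the listed taxa.
        """
        from .diagnostics import dunn_smyth_residuals

        if self.mean_zp is None:
            raise ValueError("fitted probabilities unavailable on this fit")
        K = len(self.taxon_ids)
        cells = data.mask[:, :, None] & np.ones((1, 1, K), dtype=bool)
        q = self.mean_zp[:, :, :K][cells]
        y = np.asarray(data.y)[cells]
        return dunn_smyth_residuals(y, q, rng=rng, mode=mode), q

    def inclusion_probabilities(self) -> dict:
        out = {}
        for key in ("V_occ", "V_det"):
            if key in self.samples:
                out[key] = self.get(key).mean(axis=0)
        return out

    def diagnostics(self, threshold: float = 1.1) -> dict:
        """Gelman-Rubin statistics for scalar traces, with a >=threshold flag."""
        rhats = {}
        for name, arr in self.samples.items():
            if arr.ndim == 2:  # scalar parameter
                rhats[name] = gelman_rubin(arr)
            elif arr.ndim == 3 and arr.shape[2] <= 50:
                for c in range(arr.shape[2]):
                    rhats[f"{name}[{c}]"] = gelman_rubin(arr[:, :, c])
        flagged = [
            k for k, v in rhats.items() if np.isfinite(v) and v >= threshold
        ]
        return {
            "rhat": rhats,
            "flagged": flagged,
            "undefined": [k for k, v in rhats.items() if not np.isfinite(v)],
            "acceptance": self.acceptance,
            "inclusion_probabilities": {
                k: v.tolist() for k, v in self.inclusion_probabilities().items()
            },
        }

    def to_dataframe(self):
        """Long-format draws: chain, iteration, parameter, value (scalars only)."""
        import pandas as pd

        rows = []
        for name, arr in self.samples.items():
            if arr.ndim == 2:
                for c in range(arr.shape[0]):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(arr.shape[1]),
                                "parameter": name,
                                "value": arr[c],
                            }
                        )
                    )
            elif arr.ndim == 3:
                for idx in range(arr.shape[2]):
                    for c in range(arr.shape[0]):
                        rows.append(
                            pd.DataFrame(
                                {
                                    "chain": c,
                                    "iteration": np.arange(arr.shape[1]),
                                    "parameter": f"{name}[{idx}]",
                                    "value": arr[c, :, idx],
                                }
                            )
                        )
        return pd.concat(rows, ignore_index=True)


def estimate_gamma(fit: PosteriorSamples) -> dict:
    """Posterior of regional richness gamma = sum_k w_k.

    Without augmentation every membership indicator is 1, so gamma equals
    the observed richness in every draw.
    """
    gamma = fit.get("gamma")
    return {
        "draws": gamma,
        "mean": float(gamma.mean()),
        "lo95": float(np.quantile(gamma, 0.025)),
        "hi95": float(np.quantile(gamma, 0.975)),
    }


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class _ChainState:
    """Mutable per-chain state; arrays sized to the augmented taxon set M."""

    def __init__(self, I, J, M, Ppsi, Pp):
        self.lpsi = np.zeros(M)
        self.bpsi = np.zeros((M, Ppsi))
        self.lp = np.zeros(M)
        self.bp = np.zeros((M, Pp))
        self.z = np.zeros((I, M), dtype=np.int8)
        self.w = np.ones(M, dtype=np.int8)
        self.omega = 0.5
        self.V_occ = np.ones(Ppsi)
        self.V_det = np.ones(Pp)
        # hypers: [mu_lpsi, sig_lpsi], per-cov [mu, sig] ...
        self.hyp = {
            "lpsi": np.array([0.0, 1.0]),
            "lp": np.array([0.0, 1.0]),
            "bpsi": np.tile([0.0, 0.5], (Ppsi, 1)),
            "bp": np.tile([0.0, 0.5], (Pp, 1)),
        }


def _normal_logpdf_sum_terms(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)


def fit_msom(
    data: DetectionDataset,
    config: MSOMConfig | None = None,
    prior: PriorSpec | None = None,
    seed=None,
) -> PosteriorSamples:
    """Fit the MSOM by Metropolis-within-Gibbs MCMC.

    Runs ``config.n_chains`` independent chains (seeds spawned from ``seed``)
    and returns post-burn-in, thinned draws together with acceptance rates
    and running posterior means of psi, p and z*p used for residual checks.
    Convergence is advisory: inspect ``result.diagnostics()``.
    """
    config = config or MSOMConfig()
    prior = prior or PriorSpec()
    if data.mode != "presence_absence":
        raise ValueError("fit_msom requires presence_absence data")
    if not config.allow_empty_visits and not data.mask.any(axis=1).all():
        raise ValueError("every visit must have at least one replicate sample")

    y = np.asarray(data.y, dtype=np.int8)
    mask = data.mask
    X = np.asarray(data.occ_covariates, dtype=float)
    V = np.asarray(data.det_covariates, dtype=float)
    I, J, Kobs = y.shape
    Ppsi, Pp = X.shape[1], V.shape[2]

    detected = data.detected_any()  # (I, Kobs)
    everdet = detected.any(axis=0)
    n_observed = int(everdet.sum())
    # order: observed taxa first, then all-zero observed taxa, then augmented
    if config.augment:
        M = config.M if config.M is not None else max(2 * n_observed, Kobs)
        if M < Kobs:
            raise ValueError(
                f"superpopulation M={M} smaller than the {Kobs} listed taxa"
            )
    else:
        M = Kobs

    y_ext = np.zeros((I, J, M), dtype=np.int8)
    y_ext[:, :, :Kobs] = y
    det_ext = np.zeros((I, M), dtype=bool)
    det_ext[:, :Kobs] = detected
    everdet_ext = det_ext.any(axis=0)

    maskf = mask.astype(float)
    w_mask = maskf[:, :, None]  # (I, J, 1)
    nreps = mask.sum(axis=1).astype(float)  # replicates per visit
    y_maskf = (y_ext * mask[:, :, None]).astype(float)
    n_kept = -((config.n_iter - config.burn_in) // -config.thin)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.n_chains)

    store = {
        k: np.empty((config.n_chains, n_kept))
        for k in (
            "Omega",
            "gamma",
            "mu_lpsi",
            "sigma_lpsi",
            "mu_lp",
            "sigma_lp",
        )
    }
    if Ppsi:
        store["mu_betalpsi"] = np.empty((config.n_chains, n_kept, Ppsi))
        store["sigma_betalpsi"] = np.empty((config.n_chains, n_kept, Ppsi))
        store["V_occ"] = np.empty((config.n_chains, n_kept, Ppsi))
    if Pp:
        store["mu_betalp"] = np.empty((config.n_chains, n_kept, Pp))
        store["sigma_betalp"] = np.empty((config.n_chains, n_kept, Pp))
        store["V_det"] = np.empty((config.n_chains, n_kept, Pp))
    if config.store_taxon_params:
        store["lpsi"] = np.empty((config.n_chains, n_kept, M))
        store["lp"] = np.empty((config.n_chains, n_kept, M))
        if Ppsi:
            store["betalpsi"] = np.empty((config.n_chains, n_kept, M, Ppsi))
        if Pp:
            store["betalp"] = np.empty((config.n_chains, n_kept, M, Pp))
    if config.store_z:
        store["z"] = np.empty((config.n_chains, n_kept, I, M), dtype=np.uint8)
        store["w"] = np.empty((config.n_chains, n_kept, M), dtype=np.uint8)

    sum_psi = np.zeros((I, M))
    sum_p = np.zeros((I, J, M))
    sum_zp = np.zeros((I, J, M))
    sum_z = np.zeros((I, M))
    n_acc_total = {}
    n_prop_total = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        st = _ChainState(I, J, M, Ppsi, Pp)
        if config.fit_hypers:
            st.hyp["lpsi"] = np.array([rng.normal(0, 0.5), 1.0])
            st.hyp["lp"] = np.array([rng.normal(0, 0.5), 1.0])
        else:
            st.hyp["lpsi"] = np.array([config.fixed_mu_lpsi, config.fixed_sigma_lpsi])
            st.hyp["lp"] = np.array([config.fixed_mu_lp, config.fixed_sigma_lp])
        st.lpsi = rng.normal(st.hyp["lpsi"][0], st.hyp["lpsi"][1], M)
        st.lp = rng.normal(st.hyp["lp"][0], st.hyp["lp"][1], M)
        st.z[:, :] = 0
        st.z[det_ext] = 1
        st.w[:] = 1
        if not config.select_occ_covariates:
            st.V_occ[:] = 1.0
        if not config.select_det_covariates:
            st.V_det[:] = 1.0

        # adaptive log step sizes, one per taxon per block
        ls = {
            "lpsi": np.full(M, -0.3),
            "lp": np.full(M, -0.3),
            "bpsi": np.full((M, Ppsi), -0.3),
            "bp": np.full((M, Pp), -0.3),
            "sig": {k: 0.0 for k in ("lpsi", "lp")},
        }
        ls["sig"].update({f"bpsi{x}": 0.0 for x in range(Ppsi)})
        ls["sig"].update({f"bp{x}": 0.0 for x in range(Pp)})
        acc_counts = {}
        prop_counts = {}

        def _eta_psi(lpsi, bpsi):
            if Ppsi:
                return lpsi[None, :] + X @ (bpsi * st.V_occ).T
            return np.broadcast_to(lpsi[None, :], (I, M)).copy()

        def _eta_p(lp, bp):
            if Pp:
                return lp[None, None, :] + np.einsum("ijc,kc->ijk", V, bp * st.V_det)
            return np.broadcast_to(lp[None, None, :], (I, J, M)).copy()

        def _occ_ll(eta, z, active):
            # per-taxon Bernoulli(z | expit(eta)) log-likelihood, 0 if inactive
            lp1, lp0 = _log_expit_pair(eta)
            ll = np.where(z > 0, lp1, lp0).sum(axis=0)
            return np.where(active, ll, 0.0)

        def _det_ll(eta, z, active):
            wgt = w_mask * (st.z[:, None, :] if z is None else z[:, None, :])
            lp1, lp0 = _log_expit_pair(eta)
            ll = (np.where(y_ext > 0, lp1, lp0) * wgt).sum(axis=(0, 1))
            return np.where(active, ll, 0.0)

        def _track(name, accepted, proposed):
            acc_counts[name] = acc_counts.get(name, 0.0) + accepted
            prop_counts[name] = prop_counts.get(name, 0) + proposed

        kept = 0
        for it in range(config.n_iter):
            adapting = it < config.burn_in
            gamma_t = 1.0 / (1.0 + it) ** 0.6

            # --- latent w (z marginalized for never-detected taxa), then z ---
            # without covariates the visit dimension enters only through the
            # replicate count, so log-probabilities are outer products
            if Ppsi == 0:
                k1, k0 = _log_expit_pair(st.lpsi)
                log_psi1 = np.broadcast_to(k1[None, :], (I, M))
                log_psi0 = np.broadcast_to(k0[None, :], (I, M))
            else:
                log_psi1, log_psi0 = _log_expit_pair(_eta_psi(st.lpsi, st.bpsi))
            if Pp == 0:
                log_q0 = np.outer(nreps, _log_expit_pair(st.lp)[1])
            else:
                log_1mp = _log_expit_pair(_eta_p(st.lp, st.bp))[1]
                log_q0 = (log_1mp * w_mask).sum(axis=1)  # (I, M)
            log_site_absent = np.logaddexp(log_psi1 + log_q0, log_psi0)

            if config.augment:
                cand = ~everdet_ext
                logL = log_site_absent[:, cand].sum(axis=0)
                lo = np.log(st.omega) + logL
                prob_w = np.exp(lo - np.logaddexp(lo, np.log1p(-st.omega)))
                st.w[:] = 1
                st.w[cand] = (rng.random(cand.sum()) < prob_w).astype(np.int8)
                a_post, b_post = omega_conditional(prior, st.w)
                st.omega = rng.beta(a_post, b_post)
            # z | w, params
            log_num = log_psi1 + log_q0
            prob_z = np.exp(log_num - log_site_absent)
            st.z = (rng.random((I, M)) < prob_z).astype(np.int8)
            st.z[det_ext] = 1
            st.z[:, st.w == 0] = 0

            active_occ = st.w == 1
            # for w=0 taxa all parameters are prior draws (no likelihood)
            inactive = ~active_occ
            if inactive.any():
                st.lpsi[inactive] = rng.normal(
                    st.hyp["lpsi"][0], st.hyp["lpsi"][1], inactive.sum()
                )
                st.lp[inactive] = rng.normal(
                    st.hyp["lp"][0], st.hyp["lp"][1], inactive.sum()
                )
                for x in range(Ppsi):
                    st.bpsi[inactive, x] = rng.normal(
                        st.hyp["bpsi"][x, 0], st.hyp["bpsi"][x, 1], inactive.sum()
                    )
                for x in range(Pp):
                    st.bp[inactive, x] = rng.normal(
                        st.hyp["bp"][x, 0], st.hyp["bp"][x, 1], inactive.sum()
                    )

            # --- occupancy intercepts ---
            step = np.exp(ls["lpsi"])
            prop = st.lpsi + step * rng.standard_normal(M)
            if Ppsi == 0:
                # sufficient statistic: number of occupied visits per taxon
                s_k = st.z.sum(axis=0)
                c1, c0 = _log_expit_pair(st.lpsi)
                q1, q0 = _log_expit_pair(prop)
                ll_cur = s_k * c1 + (I - s_k) * c0
                ll_prop = s_k * q1 + (I - s_k) * q0
            else:
                eta = _eta_psi(st.lpsi, st.bpsi)
                ll_cur = _occ_ll(eta, st.z, active_occ)
                eta_prop = eta + (prop - st.lpsi)[None, :]
                ll_prop = _occ_ll(eta_prop, st.z, active_occ)
            mu, sig = st.hyp["lpsi"]
            log_r = (
                ll_prop
                - ll_cur
                + _normal_logpdf_sum_terms(prop, mu, sig)
                - _normal_logpdf_sum_terms(st.lpsi, mu, sig)
            )
            acc = (np.log(rng.random(M)) < log_r) & active_occ
            st.lpsi = np.where(acc, prop, st.lpsi)
            if adapting:
                pr = np.exp(np.minimum(0.0, log_r))
                ls["lpsi"][active_occ] += gamma_t * (
                    pr[active_occ] - config.adapt_target
                )
            _track("lpsi", acc[active_occ].sum(), active_occ.sum())

            # --- occupancy slopes ---
            for x in range(Ppsi):
                mu, sig = st.hyp["bpsi"][x]
                if st.V_occ[x] == 0:
                    st.bpsi[:, x] = rng.normal(mu, sig, M)
                    continue
                eta = _eta_psi(st.lpsi, st.bpsi)
                ll_cur = _occ_ll(eta, st.z, active_occ)
                step = np.exp(ls["bpsi"][:, x])
                prop = st.bpsi[:, x] + step * rng.standard_normal(M)
                eta_prop = eta + np.outer(X[:, x], prop - st.bpsi[:, x])
                ll_prop = _occ_ll(eta_prop, st.z, active_occ)
                log_r = (
                    ll_prop
                    - ll_cur
                    + _normal_logpdf_sum_terms(prop, mu, sig)
                    - _normal_logpdf_sum_terms(st.bpsi[:, x], mu, sig)
                )
                acc = (np.log(rng.random(M)) < log_r) & active_occ
                st.bpsi[:, x] = np.where(acc, prop, st.bpsi[:, x])
                if adapting:
                    pr = np.exp(np.minimum(0.0, log_r))
                    ls["bpsi"][active_occ, x] += gamma_t * (
                        pr[active_occ] - config.adapt_target
                    )
                _track(f"bpsi{x}", acc[active_occ].sum(), active_occ.sum())

            # --- detection intercepts ---
            act_det = active_occ & (st.z.sum(axis=0) > 0)
            step = np.exp(ls["lp"])
            prop = st.lp + step * rng.standard_normal(M)
            if Pp == 0:
                # sufficient statistics among occupied cells: detections, trials
                zf = st.z.astype(float)
                yz = np.einsum("ijk,ik->k", y_maskf, zf)
                ntr = zf.T @ nreps
                c1, c0 = _log_expit_pair(st.lp)
                q1, q0 = _log_expit_pair(prop)
                ll_cur = yz * c1 + (ntr - yz) * c0
                ll_prop = yz * q1 + (ntr - yz) * q0
            else:
                eta = _eta_p(st.lp, st.bp)
                ll_cur = _det_ll(eta, None, act_det)
                eta_prop = eta + (prop - st.lp)[None, None, :]
                ll_prop = _det_ll(eta_prop, None, act_det)
            mu, sig = st.hyp["lp"]
            log_r = (
                ll_prop
                - ll_cur
                + _normal_logpdf_sum_terms(prop, mu, sig)
                - _normal_logpdf_sum_terms(st.lp, mu, sig)
            )
            upd = active_occ  # taxa with z==0 everywhere: prior-only MH is valid
            acc = (np.log(rng.random(M)) < log_r) & upd
            st.lp = np.where(acc, prop, st.lp)
            if adapting:
                pr = np.exp(np.minimum(0.0, log_r))
                ls["lp"][upd] += gamma_t * (pr[upd] - config.adapt_target)
            _track("lp", acc[upd].sum(), upd.sum())

            # --- detection slopes ---
            for x in range(Pp):
                mu, sig = st.hyp["bp"][x]
                if st.V_det[x] == 0:
                    st.bp[:, x] = rng.normal(mu, sig, M)
                    continue
                eta = _eta_p(st.lp, st.bp)
                ll_cur = _det_ll(eta, None, act_det)
                step = np.exp(ls["bp"][:, x])
                prop = st.bp[:, x] + step * rng.standard_normal(M)
                eta_prop = eta + V[:, :, x, None] * (prop - st.bp[:, x])[None, None, :]
                ll_prop = _det_ll(eta_prop, None, act_det)
                log_r = (
                    ll_prop
                    - ll_cur
                    + _normal_logpdf_sum_terms(prop, mu, sig)
                    - _normal_logpdf_sum_terms(st.bp[:, x], mu, sig)
                )
                acc = (np.log(rng.random(M)) < log_r) & upd
                st.bp[:, x] = np.where(acc, prop, st.bp[:, x])
                if adapting:
                    pr = np.exp(np.minimum(0.0, log_r))
                    ls["bp"][upd, x] += gamma_t * (pr[upd] - config.adapt_target)
                _track(f"bp{x}", acc[upd].sum(), upd.sum())

            # --- hyperparameters ---
            if config.fit_hypers:
                for key, theta in (
                    ("lpsi", st.lpsi),
                    ("lp", st.lp),
                ):
                    st.hyp[key] = _update_hyper(
                        theta, st.hyp[key], prior, rng, ls["sig"], key,
                        gamma_t if adapting else 0.0, config.adapt_target,
                    )
                for x in range(Ppsi):
                    st.hyp["bpsi"][x] = _update_hyper(
                        st.bpsi[:, x], st.hyp["bpsi"][x], prior, rng,
                        ls["sig"], f"bpsi{x}",
                        gamma_t if adapting else 0.0, config.adapt_target,
                    )
                for x in range(Pp):
                    st.hyp["bp"][x] = _update_hyper(
                        st.bp[:, x], st.hyp["bp"][x], prior, rng,
                        ls["sig"], f"bp{x}",
                        gamma_t if adapting else 0.0, config.adapt_target,
                    )

            # --- Kuo-Mallick covariate indicators ---
            if config.select_occ_covariates and Ppsi:
                for x in range(Ppsi):
                    st.V_occ[x] = 1.0
                    ll1 = _occ_ll(_eta_psi(st.lpsi, st.bpsi), st.z, active_occ).sum()
                    st.V_occ[x] = 0.0
                    ll0 = _occ_ll(_eta_psi(st.lpsi, st.bpsi), st.z, active_occ).sum()
                    p1 = expit(ll1 - ll0)  # Bernoulli(0.5) prior cancels
                    st.V_occ[x] = float(rng.random() < p1)
            if config.select_det_covariates and Pp:
                for x in range(Pp):
                    st.V_det[x] = 1.0
                    ll1 = _det_ll(_eta_p(st.lp, st.bp), None, act_det).sum()
                    st.V_det[x] = 0.0
                    ll0 = _det_ll(_eta_p(st.lp, st.bp), None, act_det).sum()
                    p1 = expit(ll1 - ll0)
                    st.V_det[x] = float(rng.random() < p1)

            # --- store ---
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                store["Omega"][c, kept] = st.omega
                store["gamma"][c, kept] = st.w.sum()
                store["mu_lpsi"][c, kept] = st.hyp["lpsi"][0]
                store["sigma_lpsi"][c, kept] = st.hyp["lpsi"][1]
                store["mu_lp"][c, kept] = st.hyp["lp"][0]
                store["sigma_lp"][c, kept] = st.hyp["lp"][1]
                if Ppsi:
                    store["mu_betalpsi"][c, kept] = st.hyp["bpsi"][:, 0]
                    store["sigma_betalpsi"][c, kept] = st.hyp["bpsi"][:, 1]
                    store["V_occ"][c, kept] = st.V_occ
                if Pp:
                    store["mu_betalp"][c, kept] = st.hyp["bp"][:, 0]
                    store["sigma_betalp"][c, kept] = st.hyp["bp"][:, 1]
                    store["V_det"][c, kept] = st.V_det
                if config.store_taxon_params:
                    store["lpsi"][c, kept] = st.lpsi
                    store["lp"][c, kept] = st.lp
                    if Ppsi:
                        store["betalpsi"][c, kept] = st.bpsi
                    if Pp:
                        store["betalp"][c, kept] = st.bp
                if config.store_z:
                    store["z"][c, kept] = st.z
                    store["w"][c, kept] = st.w
                psi_now = expit(_eta_psi(st.lpsi, st.bpsi))
                p_now = expit(_eta_p(st.lp, st.bp))
                sum_psi += psi_now
                sum_p += p_now
                sum_zp += st.z[:, None, :] * p_now
                sum_z += st.z
                kept += 1

        for k, v in acc_counts.items():
            n_acc_total[k] = n_acc_total.get(k, 0.0) + v
            n_prop_total[k] = n_prop_total.get(k, 0) + prop_counts[k]

    total_kept = config.n_chains * n_kept
    acceptance = {
        k: float(n_acc_total[k] / max(n_prop_total[k], 1)) for k in n_acc_total
    }
    return PosteriorSamples(
        samples=store,
        n_chains=config.n_chains,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=seed,
        acceptance=acceptance,
        mean_psi=sum_psi / total_kept,
        mean_p=sum_p / total_kept,
        mean_zp=sum_zp / total_kept,
        mean_z=sum_z / total_kept,
        taxon_ids=list(data.taxon_ids),
        n_observed=n_observed,
        M=M,
    )


def _update_hyper(theta, hyp, prior, rng, sig_ls, key, gamma_t, target):
    """Conjugate normal update of the hyper-mean; RW Metropolis on log sigma."""
    mu, sig = hyp
    n = theta.size
    prec = n / sig**2 + 1.0 / prior.mu_sd**2
    mean = (theta.sum() / sig**2 + prior.mu_mean / prior.mu_sd**2) / prec
    mu = rng.normal(mean, 1.0 / np.sqrt(prec))

    log_sig = np.log(sig)
    prop = log_sig + np.exp(sig_ls[key]) * rng.standard_normal()
    sig_prop = np.exp(prop)
    if sig_prop < prior.sigma_upper:
        ss = ((theta - mu) ** 2).sum()
        log_r = (
            (-n * prop - ss / (2 * sig_prop**2))
            - (-n * log_sig - ss / (2 * sig**2))
            + (prop - log_sig)  # Jacobian of the log transform
        )
        if np.log(rng.random()) < log_r:
            sig = sig_prop
        if gamma_t > 0:
            sig_ls[key] += gamma_t * (min(1.0, np.exp(log_r)) - target)
    elif gamma_t > 0:
        sig_ls[key] += gamma_t * (0.0 - target)
    return np.array([mu, sig])
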