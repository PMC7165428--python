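"""Community N-mixture model for replicated count data.

State and observation processes, sharing the membership/augmentation
machinery of the occupancy model:

    w_k  ~ Bernoulli(Omega)
    N_ik ~ Poisson(w_k * lambda_ik),   log(lambda_ik) = llam_k + betallam_k . x_i
    y_ijk | N_ik ~ Binomial(N_ik, p_ijk), logit(p_ijk) = lp_k + betalp_k . v_ij

Latent abundances N are updated by a discrete random walk (+-1, +-2) with an
exact Poisson-surplus draw wherever a visit has a single replicate; the
standalone :func:`update_N` draws from the exact truncated-enumeration full
conditional and serves as the oracle for the sampler's kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

from .dataset import DetectionDataset
from .msom import (
    MSOMConfig,
    PosteriorSamples,
    PriorSpec,
    _log_expit,
    _log_expit_pair,
    _update_hyper,
    omega_conditional,
)

__all__ = [
    "full_conditional_N",
    "update_N",
    "fit_nmixture",
    "expected_richness",
    "expected_richness_under_count_model",
]


def full_conditional_N(y_vec, lam, p_vec, cap: int = 500, tail_tol: float = 1e-10):
    """Support and pmf of N | y, lambda, p by truncated enumeration.

    p(N) is proportional to Poisson(N; lambda) * prod_j Binomial(y_j; N, p_j)
    on N >= max(y). Enumeration stops when the accumulated tail mass beyond
    the last support point is below ``tail_tol``; exceeding ``cap`` raises.
    """
    y = np.asarray(y_vec, dtype=int)
    p = np.asarray(p_vec, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("detection probabilities must lie in [0, 1]")
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    m = int(y.max()) if y.size else 0
    support = np.arange(m, m + cap + 1)
    N = support[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_binom = (
            gammaln(N + 1)
            - gammaln(y[None, :] + 1)
            - gammaln(N - y[None, :] + 1)
            + y[None, :] * np.log(np.where(p > 0, p, 1.0))
            + (N - y[None, :]) * np.log1p(-np.where(p < 1, p, 0.0))
        )
        # p == 0 with y > 0 or p == 1 with y < N are impossible outcomes
        log_binom = np.where((p[None, :] == 0) & (y[None, :] > 0), -np.inf, log_binom)
        log_binom = np.where(
            (p[None, :] == 1) & (N != y[None, :]), -np.inf, log_binom
        )
    log_pois = support * np.log(lam) - lam - gammaln(support + 1)
    logw = log_pois + log_binom.sum(axis=1)
    logw -= logw.max()
    wgt = np.exp(logw)
    total = wgt.sum()
    pmf = wgt / total
    # find truncation point with tail below tolerance
    cum = np.cumsum(pmf)
    idx = np.searchsorted(cum, 1.0 - tail_tol)
    if idx >= cap:
        raise RuntimeError(
            f"full conditional of N not covered within cap={cap}; raise cap"
        )
    last = min(idx + 1, len(support) - 1)
    return support[: last + 1], pmf[: last + 1] / pmf[: last + 1].sum()


def update_N(y_vec, lam, p_vec, rng, cap: int = 500) -> int:
    """Exact draw from the full conditional of latent abundance N.

    Single-replicate visits use the closed form
    N = y + Poisson(lambda * (1 - p)); otherwise truncated enumeration.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = np.asarray(y_vec, dtype=int)
    p = np.asarray(p_vec, dtype=float)
    if y.size == 1:
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        if not 0 <= p[0] <= 1:
            raise ValueError("p must lie in [0, 1]")
        if p[0] == 1.0:
            return int(y[0])
        return int(y[0] + rng.poisson(lam * (1.0 - p[0])))
    support, pmf = full_conditional_N(y, lam, p, cap=cap)
    return int(rng.choice(support, p=pmf))


def fit_nmixture(
    data: DetectionDataset,
    config: MSOMConfig | None = None,
    prior: PriorSpec | None = None,
    seed=None,
    n_latent_steps: int = 3,
) -> PosteriorSamples:
    """Fit the community N-mixture model by Metropolis-within-Gibbs MCMC.

    Shares :class:`MSOMConfig`/:class:`PriorSpec` with the occupancy model;
    ``fixed_mu_lpsi``-style fields are interpreted on the log-lambda scale.
    Covariate selection indicators apply to the abundance covariates
    (``select_occ_covariates``) and detection covariates
    (``select_det_covariates``) exactly as in the occupancy fit.
    """
    config = config or MSOMConfig()
    prior = prior or PriorSpec()
    if data.mode != "count":
        raise ValueError("fit_nmixture requires count-mode data")
    y = np.asarray(data.y)
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("counts must be integers")
    mask = data.mask
    X = np.asarray(data.occ_covariates, dtype=float)
    V = np.asarray(data.det_covariates, dtype=float)
    I, J, Kobs = y.shape
    Ppsi, Pp = X.shape[1], V.shape[2]

    detected = ((y > 0) & mask[:, :, None]).any(axis=1)
    everdet = detected.any(axis=0)
    n_observed = int(everdet.sum())
    if config.augment:
        M = config.M if config.M is not None else max(2 * n_observed, Kobs)
        if M < Kobs:
            raise ValueError("superpopulation M smaller than the listed taxa")
    else:
        M = Kobs
    y_ext = np.zeros((I, J, M), dtype=np.int64)
    y_ext[:, :, :Kobs] = y
    everdet_ext = np.zeros(M, dtype=bool)
    everdet_ext[:Kobs] = everdet
    maskf = mask.astype(float)[:, :, None]
    ymax = (y_ext * mask[:, :, None]).max(axis=1)  # (I, M)
    n_reps = mask.sum(axis=1)  # replicates per visit
    single = n_reps == 1
    single_j = np.argmax(mask, axis=1)  # replicate index where single

    n_kept = -((config.n_iter - config.burn_in) // -config.thin)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.n_chains)

    store = {
        k: np.empty((config.n_chains, n_kept))
        for k in ("Omega", "gamma", "mu_llam", "sigma_llam", "mu_lp", "sigma_lp")
    }
    if Ppsi:
        store["mu_betallam"] = np.empty((config.n_chains, n_kept, Ppsi))
        store["sigma_betallam"] = np.empty((config.n_chains, n_kept, Ppsi))
        store["V_occ"] = np.empty((config.n_chains, n_kept, Ppsi))
    if Pp:
        store["mu_betalp"] = np.empty((config.n_chains, n_kept, Pp))
        store["sigma_betalp"] = np.empty((config.n_chains, n_kept, Pp))
        store["V_det"] = np.empty((config.n_chains, n_kept, Pp))
    if config.store_taxon_params:
        store["llam"] = np.empty((config.n_chains, n_kept, M))
        store["lp"] = np.empty((config.n_chains, n_kept, M))
    sum_N = np.zeros((I, M))
    acc_tot: dict = {}
    prop_tot: dict = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        llam = rng.normal(0.0, 0.5, M)
        blam = np.zeros((M, Ppsi))
        lp = rng.normal(0.0, 0.5, M)
        bp = np.zeros((M, Pp))
        hyp = {
            "llam": np.array([0.0, 1.0]),
            "lp": np.array([0.0, 1.0]),
            "blam": np.tile([0.0, 0.5], (Ppsi, 1)),
            "bp": np.tile([0.0, 0.5], (Pp, 1)),
        }
        if not config.fit_hypers:
            hyp["llam"] = np.array([config.fixed_mu_lpsi, config.fixed_sigma_lpsi])
            hyp["lp"] = np.array([config.fixed_mu_lp, config.fixed_sigma_lp])
        V_occ = np.ones(Ppsi)
        V_det = np.ones(Pp)
        w = np.ones(M, dtype=np.int8)
        omega = 0.5
        N = ymax.copy()
        ls = {
            "llam": np.full(M, -0.5),
            "lp": np.full(M, -0.5),
            "blam": np.full((M, Ppsi), -0.5),
            "bp": np.full((M, Pp), -0.5),
            "sig": {"llam": 0.0, "lp": 0.0},
        }
        ls["sig"].update({f"blam{x}": 0.0 for x in range(Ppsi)})
        ls["sig"].update({f"bp{x}": 0.0 for x in range(Pp)})
        acc: dict = {}
        prop_n: dict = {}

        def _lam(llam_v, blam_m):
            if Ppsi:
                eta = llam_v[None, :] + X @ (blam_m * V_occ).T
            else:
                eta = np.broadcast_to(llam_v[None, :], (I, M)).copy()
            return np.exp(np.clip(eta, -30, 30))

        def _p(lp_v, bp_m):
            # logit scale
            if Pp:
                return lp_v[None, None, :] + np.einsum("ijc,kc->ijk", V, bp_m * V_det)
            return np.broadcast_to(lp_v[None, None, :], (I, J, M)).copy()

        def _pois_ll(lam, active):
            ll = (N * np.log(lam) - lam).sum(axis=0)
            return np.where(active, ll, 0.0)

        def _binom_ll(eta_p, active):
            lp1, lp0 = _log_expit_pair(eta_p)
            ll = (
                maskf * (y_ext * lp1 + (N[:, None, :] - y_ext) * lp0)
            ).sum(axis=(0, 1))
            return np.where(active, ll, 0.0)

        def _track(name, a, n):
            acc[name] = acc.get(name, 0.0) + a
            prop_n[name] = prop_n.get(name, 0) + n

        kept = 0
        for it in range(config.n_iter):
            adapting = it < config.burn_in
            gamma_t = 1.0 / (1.0 + it) ** 0.6

            lam = _lam(llam, blam)
            eta_p = _p(lp, bp)
            pdet = expit(eta_p)

            # --- membership w and Omega (z... here N marginalized) ---
            if config.augment:
                cand = ~everdet_ext
                s = np.exp((np.log1p(-np.clip(pdet, 0, 1 - 1e-12)) * maskf).sum(axis=1))
                logL = (lam[:, cand] * (s[:, cand] - 1.0)).sum(axis=0)
                lo = np.log(omega) + logL
                pw = np.exp(lo - np.logaddexp(lo, np.log1p(-omega)))
                w[:] = 1
                w[cand] = (rng.random(cand.sum()) < pw).astype(np.int8)
                a_post, b_post = omega_conditional(prior, w)
                omega = rng.beta(a_post, b_post)
                # exact N draw for never-detected members; zero for w=0
                mem = cand & (w == 1)
                if mem.any():
                    N[:, mem] = rng.poisson(lam[:, mem] * s[:, mem])
                N[:, w == 0] = 0

            active = w == 1
            inactive = ~active
            if inactive.any():
                llam[inactive] = rng.normal(hyp["llam"][0], hyp["llam"][1], inactive.sum())
                lp[inactive] = rng.normal(hyp["lp"][0], hyp["lp"][1], inactive.sum())
                for x in range(Ppsi):
                    blam[inactive, x] = rng.normal(hyp["blam"][x, 0], hyp["blam"][x, 1], inactive.sum())
                for x in range(Pp):
                    bp[inactive, x] = rng.normal(hyp["bp"][x, 0], hyp["bp"][x, 1], inactive.sum())

            # --- latent N for detected taxa ---
            det_cols = everdet_ext & active
            if det_cols.any():
                lam_d = lam[:, det_cols]
                # exact Poisson-surplus draw where a visit has one replicate
                if single.any():
                    p1 = np.take_along_axis(
                        pdet[:, :, det_cols][single],
                        single_j[single][:, None, None],
                        axis=1,
                    )[:, 0, :]
                    N_single = y_ext[single][
                        np.arange(single.sum())[:, None],
                        single_j[single][:, None],
                        np.nonzero(det_cols)[0][None, :],
                    ] + rng.poisson(lam_d[single] * (1.0 - p1))
                    Nd = N[:, det_cols]
                    Nd[single] = N_single
                    N[:, det_cols] = Nd
                multi = ~single
                if multi.any():
                    idx_cols = np.nonzero(det_cols)[0]
                    Nsub = N[np.ix_(multi, idx_cols)]
                    ysub = y_ext[multi][:, :, idx_cols]
                    msub = maskf[multi][:, :, 0][:, :, None]
                    lamsub = lam_d[multi]
                    lpd = _log_expit(eta_p[multi][:, :, idx_cols])
                    lqd = _log_expit(-eta_p[multi][:, :, idx_cols])
                    ymaxsub = ymax[np.ix_(multi, idx_cols)]

                    def _logtarget(Nv):
                        lc = (
                            gammaln(Nv[:, None, :] + 1)
                            - gammaln(Nv[:, None, :] - ysub + 1)
                        )
                        return (
                            Nv * np.log(lamsub)
                            - gammaln(Nv + 1)
                            + (msub * (lc + (Nv[:, None, :] - ysub) * lqd)).sum(axis=1)
                        )

                    cur_lt = _logtarget(Nsub)
                    for _ in range(n_latent_steps):
                        delta = rng.choice((-2, -1, 1, 2), size=Nsub.shape)
                        propN = Nsub + delta
                        ok = propN >= ymaxsub
                        propN = np.where(ok, propN, Nsub)
                        new_lt = _logtarget(propN)
                        accept = ok & (np.log(rng.random(Nsub.shape)) < new_lt - cur_lt)
                        Nsub = np.where(accept, propN, Nsub)
                        cur_lt = np.where(accept, new_lt, cur_lt)
                    N[np.ix_(multi, idx_cols)] = Nsub

            # --- abundance parameters ---
            lam = _lam(llam, blam)
            ll_cur = _pois_ll(lam, active)
            prop = llam + np.exp(ls["llam"]) * rng.standard_normal(M)
            lam_prop = lam * np.exp(prop - llam)[None, :]
            ll_prop = _pois_ll(lam_prop, active)
            mu, sig = hyp["llam"]
            log_r = ll_prop - ll_cur - 0.5 * (((prop - mu) ** 2 - (llam - mu) ** 2) / sig**2)
            a = (np.log(rng.random(M)) < log_r) & active
            llam = np.where(a, prop, llam)
            if adapting:
                pr = np.exp(np.minimum(0.0, log_r))
                ls["llam"][active] += gamma_t * (pr[active] - config.adapt_target)
            _track("llam", a[active].sum(), active.sum())

            for x in range(Ppsi):
                mu, sig = hyp["blam"][x]
                if V_occ[x] == 0:
                    blam[:, x] = rng.normal(mu, sig, M)
                    continue
                lam = _lam(llam, blam)
                ll_cur = _pois_ll(lam, active)
                prop = blam[:, x] + np.exp(ls["blam"][:, x]) * rng.standard_normal(M)
                blam_p = blam.copy()
                blam_p[:, x] = prop
                ll_prop = _pois_ll(_lam(llam, blam_p), active)
                log_r = ll_prop - ll_cur - 0.5 * (
                    ((prop - mu) ** 2 - (blam[:, x] - mu) ** 2) / sig**2
                )
                a = (np.log(rng.random(M)) < log_r) & active
                blam[:, x] = np.where(a, prop, blam[:, x])
                if adapting:
                    pr = np.exp(np.minimum(0.0, log_r))
                    ls["blam"][active, x] += gamma_t * (pr[active] - config.adapt_target)
                _track(f"blam{x}", a[active].sum(), active.sum())

            # --- detection parameters ---
            eta_p = _p(lp, bp)
            ll_cur = _binom_ll(eta_p, active)
            prop = lp + np.exp(ls["lp"]) * rng.standard_normal(M)
            ll_prop = _binom_ll(eta_p + (prop - lp)[None, None, :], active)
            mu, sig = hyp["lp"]
            log_r = ll_prop - ll_cur - 0.5 * (((prop - mu) ** 2 - (lp - mu) ** 2) / sig**2)
            a = (np.log(rng.random(M)) < log_r) & active
            lp = np.where(a, prop, lp)
            if adapting:
                pr = np.exp(np.minimum(0.0, log_r))
                ls["lp"][active] += gamma_t * (pr[active] - config.adapt_target)
            _track("lp", a[active].sum(), active.sum())

            for x in range(Pp):
                mu, sig = hyp["bp"][x]
                if V_det[x] == 0:
                    bp[:, x] = rng.normal(mu, sig, M)
                    continue
                eta_p = _p(lp, bp)
                ll_cur = _binom_ll(eta_p, active)
                prop = bp[:, x] + np.exp(ls["bp"][:, x]) * rng.standard_normal(M)
                ll_prop = _binom_ll(
                    eta_p + V[:, :, x, None] * (prop - bp[:, x])[None, None, :], active
                )
                log_r = ll_prop - ll_cur - 0.5 * (
                    ((prop - mu) ** 2 - (bp[:, x] - mu) ** 2) / sig**2
                )
                a = (np.log(rng.random(M)) < log_r) & active
                bp[:, x] = np.where(a, prop, bp[:, x])
                if adapting:
                    pr = np.exp(np.minimum(0.0, log_r))
                    ls["bp"][active, x] += gamma_t * (pr[active] - config.adapt_target)
                _track(f"bp{x}", a[active].sum(), active.sum())

            # --- hyperparameters ---
            if config.fit_hypers:
                hyp["llam"] = _update_hyper(
                    llam, hyp["llam"], prior, rng, ls["sig"], "llam",
                    gamma_t if adapting else 0.0, config.adapt_target,
                )
                hyp["lp"] = _update_hyper(
                    lp, hyp["lp"], prior, rng, ls["sig"], "lp",
                    gamma_t if adapting else 0.0, config.adapt_target,
                )
                for x in range(Ppsi):
                    hyp["blam"][x] = _update_hyper(
                        blam[:, x], hyp["blam"][x], prior, rng, ls["sig"], f"blam{x}",
                        gamma_t if adapting else 0.0, config.adapt_target,
                    )
                for x in range(Pp):
                    hyp["bp"][x] = _update_hyper(
                        bp[:, x], hyp["bp"][x], prior, rng, ls["sig"], f"bp{x}",
                        gamma_t if adapting else 0.0, config.adapt_target,
                    )

            # --- covariate indicators ---
            if config.select_occ_covariates and Ppsi:
                for x in range(Ppsi):
                    V_occ[x] = 1.0
                    ll1 = _pois_ll(_lam(llam, blam), active).sum()
                    V_occ[x] = 0.0
                    ll0 = _pois_ll(_lam(llam, blam), active).sum()
                    V_occ[x] = float(rng.random() < expit(ll1 - ll0))
            if config.select_det_covariates and Pp:
                for x in range(Pp):
                    V_det[x] = 1.0
                    ll1 = _binom_ll(_p(lp, bp), active).sum()
                    V_det[x] = 0.0
                    ll0 = _binom_ll(_p(lp, bp), active).sum()
                    V_det[x] = float(rng.random() < expit(ll1 - ll0))

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                store["Omega"][c, kept] = omega
                store["gamma"][c, kept] = w.sum()
                store["mu_llam"][c, kept] = hyp["llam"][0]
                store["sigma_llam"][c, kept] = hyp["llam"][1]
                store["mu_lp"][c, kept] = hyp["lp"][0]
                store["sigma_lp"][c, kept] = hyp["lp"][1]
                if Ppsi:
                    store["mu_betallam"][c, kept] = hyp["blam"][:, 0]
                    store["sigma_betallam"][c, kept] = hyp["blam"][:, 1]
                    store["V_occ"][c, kept] = V_occ
                if Pp:
                    store["mu_betalp"][c, kept] = hyp["bp"][:, 0]
                    store["sigma_betalp"][c, kept] = hyp["bp"][:, 1]
                    store["V_det"][c, kept] = V_det
                if config.store_taxon_params:
                    store["llam"][c, kept] = llam
                    store["lp"][c, kept] = lp
                sum_N += N
                kept += 1

        for k, v in acc.items():
            acc_tot[k] = acc_tot.get(k, 0.0) + v
            prop_tot[k] = prop_tot.get(k, 0) + prop_n[k]

    total_kept = config.n_chains * n_kept
    return PosteriorSamples(
        samples=store,
        n_chains=config.n_chains,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=seed,
        acceptance={k: float(acc_tot[k] / max(prop_tot[k], 1)) for k in acc_tot},
        mean_z=sum_N / total_kept,  # posterior mean abundance, reused slot
        taxon_ids=list(data.taxon_ids),
        n_observed=n_observed,
        M=M,
    )


def expected_richness(lambdas, n_individuals: int) -> float:
    """Expected observed richness when n individuals are drawn at random.

    Relative abundances pi_k = lambda_k / sum(lambda); the expected number
    of taxa appearing at least once in a random sample of ``n_individuals``
    individuals is sum_k [1 - (1 - pi_k)^n].
    """
    lam = np.asarray(lambdas, dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all lambdas are zero")
    pi = lam / total
    return float((1.0 - (1.0 - pi) ** n_individuals).sum())


def expected_richness_under_count_model(fit: PosteriorSamples, n_individuals: int) -> dict:
    """Posterior summary of expected observed richness at a given survey effort.

    The misspecification check behind comparing model-implied richness with
    what the survey actually recorded: per posterior draw, convert the
    fitted Poisson means to relative abundances and compute the expected
    number of taxa represented among ``n_individuals`` randomly sampled
    individuals (observed taxa only).
    """
    llam = fit.get("llam")[:, : fit.n_observed]
    vals = np.array(
        [expected_richness(np.exp(row), n_individuals) for row in llam]
    )
    return {
        "mean": float(vals.mean()),
        "lo95": float(np.quantile(vals, 0.025)),
        "hi95": float(np.quantile(vals, 0.975)),
        "draws": vals,
    }
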