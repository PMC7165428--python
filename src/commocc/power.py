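"""Metacommunity simulation and biomonitoring power analysis.

Workflow: build a baseline site x taxon presence matrix from an occupancy
distribution (fitted draws or a parametric logit-normal), inject stochastic
year-to-year turnover with fixed-margin (curveball) permutations, degrade
the community by removing occurrences of stress-intolerant taxa, observe it
through imperfect replicated detection, and test reference vs impacted
composition with a sum-of-likelihood-ratios multivariate test whose null
distribution comes from permuting site labels (an mvabund-style manyglm
analogue). Sweeping designs and stressor severities yields power curves and
the minimum detectable reduction in community occupancy.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from scipy.stats import norm, spearmanr

from .dataset import DetectionDataset
from .diversity import CommunityMatrix, mean_pairwise_dissimilarity

__all__ = [
    "MetacommunitySim",
    "ToleranceProfile",
    "DesignPoint",
    "PowerResult",
    "DETECTION_PRESETS",
    "build_baseline",
    "yearly_baselines",
    "permute_fixed_margins",
    "calibrate_turnover",
    "make_tolerances",
    "apply_stressor",
    "sample_detection",
    "manyglm_test",
    "power_curve",
]


@dataclasses.dataclass
class MetacommunitySim:
    """Baseline presence matrix plus the occupancy probabilities behind it."""

    matrix: np.ndarray  # (n_sites, gamma) binary
    psi: np.ndarray  # (gamma,) per-taxon occupancy used to build it
    seed: object = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("baseline matrix must be binary")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def gamma(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass
class ToleranceProfile:
    """Per-taxon stress tolerance in [0, 1], rank-correlated with occupancy."""

    tolerance: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.tolerance = np.asarray(self.tolerance, dtype=float)
        if ((self.tolerance < 0) | (self.tolerance > 1)).any():
            raise ValueError("tolerances must lie in [0, 1]")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclasses.dataclass(frozen=True)
class DesignPoint:
    """One monitoring design: sites per year, replicates, sampling approach."""

    n_sites: int
    replicates: int = 1
    detection_preset: str = "dna_genus"
    years_post_impact: int = 2

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.replicates < 1:
            raise ValueError("need >= 2 sites and >= 1 replicate")


@dataclasses.dataclass
class PowerResult:
    """Rejection rates per (design, severity) and minimum detectable severity."""

    designs: list
    severities: np.ndarray
    power: np.ndarray  # (n_designs, n_severities)
    n_sim: int
    alpha: float

    def minimum_detectable_severity(self, threshold: float = 0.5) -> np.ndarray:
        """Smallest severity with power > threshold, linearly interpolated.

        NaN when no severity on the grid reaches the threshold.
        """
        out = np.full(len(self.designs), np.nan)
        s = self.severities
        for d in range(len(self.designs)):
            pw = self.power[d]
            above = np.nonzero(pw > threshold)[0]
            if len(above) == 0:
                continue
            i = above[0]
            if i == 0:
                out[d] = s[0]
            else:
                frac = (threshold - pw[i - 1]) / (pw[i] - pw[i - 1])
                out[d] = s[i - 1] + frac * (s[i] - s[i - 1])
        return out


# logit-normal per-replicate detectability by sampling approach; the DNA
# presets sit above the morphology-based one, genus slightly below family
DETECTION_PRESETS = {
    "cabin_family": {"mu": -1.0, "sigma": 0.8},
    "dna_family": {"mu": 1.2, "sigma": 0.9},
    "dna_genus": {"mu": 0.8, "sigma": 0.9},
}


def build_baseline(occupancy_source, gamma: int, n_sites: int, seed=None) -> MetacommunitySim:
    """Draw a baseline presence matrix cell-wise Bernoulli(psi_k).

    ``occupancy_source`` is either an array of per-taxon occupancy
    probabilities (length gamma) or a dict {"mu": ., "sigma": .} describing
    a logit-normal community distribution to draw them from.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    rng = np.random.default_rng(seed)
    if isinstance(occupancy_source, dict):
        psi = expit(rng.normal(occupancy_source["mu"], occupancy_source["sigma"], gamma))
    else:
        psi = np.asarray(occupancy_source, dtype=float)
        if psi.shape != (gamma,):
            raise ValueError("occupancy_source length must equal gamma")
        if ((psi < 0) | (psi > 1)).any():
            raise ValueError("occupancy probabilities must lie in [0, 1]")
    m = (rng.random((n_sites, gamma)) < psi[None, :]).astype(np.int8)
    return MetacommunitySim(matrix=m, psi=psi, seed=seed)


def yearly_baselines(
    occupancy_source,
    gamma: int,
    n_sites: int,
    n_years: int,
    year_effect_sd: float = 0.0,
    seed=None,
) -> list:
    """Per-year baseline matrices with covariate-driven occupancy shifts.

    Each year applies an independent Normal(0, year_effect_sd) shift to
    every taxon's logit-occupancy before drawing presences — the
    deterministic (environment-driven) component of temporal turnover.
    With sd = 0 the years are independent draws from identical psi.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    base = build_baseline(occupancy_source, gamma, n_sites, rng.integers(2**31))
    psi = np.clip(base.psi, 1e-12, 1 - 1e-12)
    logit_psi = np.log(psi) - np.log1p(-psi)
    years = []
    for _ in range(n_years):
        shift = rng.normal(0.0, year_effect_sd, gamma) if year_effect_sd > 0 else 0.0
        psi_y = expit(logit_psi + shift)
        m = (rng.random((n_sites, gamma)) < psi_y[None, :]).astype(np.int8)
        years.append(MetacommunitySim(matrix=m, psi=psi_y, seed=seed))
    return years


def permute_fixed_margins(matrix, n_swaps: int, seed=None) -> np.ndarray:
    """Curveball permutation: n_swaps trades preserving row and column sums.

    Each trade picks two rows and randomly reallocates the columns where
    exactly one of them is present; row and column totals are invariant by
    construction. Roughly 5 x n_rows trades reach the uniform distribution
    on the fixed-margin class for typical matrices.
    """
    m = np.array(matrix, dtype=np.int8, copy=True)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix must be binary")
    n_rows = m.shape[0]
    if n_rows < 2 or n_swaps == 0:
        return m
    rng = np.random.default_rng(seed)
    pairs = rng.integers(0, n_rows, size=(n_swaps, 2))
    for a, b in pairs:
        if a == b:
            continue
        ra, rb = m[a], m[b]
        only_a = np.nonzero((ra == 1) & (rb == 0))[0]
        only_b = np.nonzero((ra == 0) & (rb == 1))[0]
        na = len(only_a)
        if na == 0 or len(only_b) == 0:
            continue
        pool = np.concatenate([only_a, only_b])
        rng.shuffle(pool)
        m[a, pool] = 0
        m[b, pool] = 0
        m[a, pool[:na]] = 1
        m[b, pool[na:]] = 1
    return m


def _within_site_turnover(m0: np.ndarray, m1: np.ndarray) -> float:
    """Mean per-site Jaccard dissimilarity between two years' matrices."""
    inter = (m0 & m1).sum(axis=1)
    union = (m0 | m1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    return float(np.nanmean(np.where(union > 0, d, np.nan)))


def calibrate_turnover(
    sim: MetacommunitySim,
    target_dissimilarity: float,
    seed=None,
    n_rep: int = 5,
    grid: tuple = (0, 1, 2, 4, 8, 16, 32, 64, 128),
):
    """Trade count whose mean year-to-year within-site turnover matches target.

    Evaluates mean turnover between the baseline and its permutation over a
    grid of trade counts (units of n_sites trades) and returns the count
    with turnover closest to the target, with the achieved value. If even
    full randomization cannot reach the target a warning flag is set.
    """
    if not 0.0 <= target_dissimilarity < 1.0:
        raise ValueError("target must lie in [0, 1)")
    if target_dissimilarity == 0.0:
        return {"n_swaps": 0, "achieved": 0.0, "attainable": True}
    rng = np.random.default_rng(seed)
    counts = [int(g * sim.n_sites) for g in grid]
    achieved = []
    for c in counts:
        vals = [
            _within_site_turnover(
                sim.matrix.astype(bool),
                permute_fixed_margins(sim.matrix, c, rng.integers(2**31)).astype(bool),
            )
            for _ in range(n_rep)
        ]
        achieved.append(float(np.mean(vals)))
    achieved = np.asarray(achieved)
    best = int(np.argmin(np.abs(achieved - target_dissimilarity)))
    return {
        "n_swaps": counts[best],
        "achieved": achieved[best],
        "attainable": bool(abs(achieved[best] - target_dissimilarity) < 0.05),
        "grid": dict(zip(counts, achieved.tolist())),
    }


def make_tolerances(occupancy, rho: float, seed=None) -> ToleranceProfile:
    """Tolerances on [0, 1] with Spearman correlation ~rho to occupancy.

    Gaussian copula: a standard-normal score correlated with the normal
    score of the occupancy ranks is mapped through the normal CDF. rho=+-1
    reproduces/reverses the occupancy rank order exactly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    psi = np.asarray(occupancy, dtype=float)
    rng = np.random.default_rng(seed)
    n = psi.size
    # normal scores of the occupancy ranks (ties broken by position)
    ranks = np.argsort(np.argsort(psi, kind="stable"), kind="stable")
    zpsi = norm.ppf((ranks + 1) / (n + 1))
    # copula correlation reproducing the target Spearman correlation
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    ztol = r * zpsi + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    return ToleranceProfile(tolerance=norm.cdf(ztol), rho=rho)


def apply_stressor(
    sim: MetacommunitySim, tolerances: ToleranceProfile, severity: float, seed=None
) -> MetacommunitySim:
    """Remove a fraction ``severity`` of all occurrences, sparing tolerant taxa.

    Exactly round(severity * total occurrences) occurrences are removed;
    each occurrence's removal probability is proportional to
    (1 - tolerance) of its taxon (weighted sampling without replacement).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    m = sim.matrix.copy()
    if severity == 0.0:
        return MetacommunitySim(matrix=m, psi=sim.psi, seed=sim.seed)
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(m)
    total = len(rows)
    n_remove = int(round(severity * total))
    if n_remove == 0:
        return MetacommunitySim(matrix=m, psi=sim.psi, seed=sim.seed)
    wgt = 1.0 - tolerances.tolerance[cols]
    if wgt.sum() == 0:
        wgt = np.ones_like(wgt)  # all fully tolerant: removals hit uniformly
    # sequential weighted sampling without replacement via exponential keys
    keys = rng.exponential(size=total) / np.where(wgt > 0, wgt, 1e-300)
    keys[wgt == 0] = np.inf  # fully tolerant taxa removed only if unavoidable
    order = np.argsort(keys)
    sel = order[:n_remove]
    m[rows[sel], cols[sel]] = 0
    return MetacommunitySim(matrix=m, psi=sim.psi, seed=sim.seed)


def sample_detection(
    sim: MetacommunitySim, detection_probs, replicates: int, seed=None
) -> np.ndarray:
    """Observe the metacommunity: y_sjk ~ Bernoulli(presence * p_k) per replicate.

    Returns a binary (n_sites, replicates, gamma) detection array.
    """
    p = np.asarray(detection_probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("detection probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pres = sim.matrix[:, None, :].astype(bool)
    return ((rng.random((sim.n_sites, replicates, sim.gamma)) < p[None, None, :]) & pres).astype(np.int8)


def detection_dataset_from_sample(y: np.ndarray, sim: MetacommunitySim) -> DetectionDataset:
    """Wrap a sampled detection array in a DetectionDataset (plumbing helper)."""
    import pandas as pd

    n_sites, J, K = y.shape
    taxa = [f"t{k:03d}" for k in range(K)]
    tax = pd.DataFrame({"genus": taxa, "family": taxa}, index=pd.Index(taxa, name="taxon_id"))
    info = pd.DataFrame(
        {"site_id": [f"s{i:02d}" for i in range(n_sites)], "year": 0, "visit_id": range(n_sites)}
    )
    return DetectionDataset(
        y=y.astype(np.int64),
        mask=np.ones((n_sites, J), dtype=bool),
        occ_covariates=np.zeros((n_sites, 0)),
        det_covariates=np.zeros((n_sites, J, 0)),
        taxonomy=tax,
        visit_info=info,
        taxon_ids=taxa,
        mode="presence_absence",
    )


def _collapse(y: np.ndarray) -> np.ndarray:
    """Any-detection collapse of (sites, replicates, taxa) to (sites, taxa)."""
    return y.max(axis=1)


def _binom_ll(x, n):
    """Maximized Bernoulli log-likelihood of x successes in n trials."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = x / n
        ll = x * np.log(ph) + (n - x) * np.log1p(-ph)
    return np.where((x == 0) | (x == n), 0.0, ll)


def manyglm_test(baseline, impacted, n_resamples: int = 499, seed=None) -> dict:
    """Community composition test: summed per-taxon binomial LR statistics.

    Per taxon, the likelihood-ratio statistic compares an intercept-only
    Bernoulli GLM with a two-group model across sites; the community
    statistic is the sum over taxa. Significance comes from permuting group
    labels over sites: p = (1 + #{perm >= obs}) / (1 + n_resamples).
    Accepts collapsed binary matrices or (sites, replicates, taxa) arrays.
    """
    A = np.asarray(baseline)
    B = np.asarray(impacted)
    if A.ndim == 3:
        A = _collapse(A)
    if B.ndim == 3:
        B = _collapse(B)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs >= 2 sites")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the taxon set")
    X = np.vstack([A, B]).astype(np.int64)
    n, K = X.shape
    nA = A.shape[0]
    tot = X.sum(axis=0)
    keep = (tot > 0) & (tot < n)  # invariant taxa carry no information
    X = X[:, keep]

    def stat(xA):
        xB = X.sum(axis=0) - xA
        lr = 2.0 * (
            _binom_ll(xA, nA) + _binom_ll(xB, n - nA) - _binom_ll(xA + xB, n)
        )
        return lr

    lr_obs = stat(X[:nA].sum(axis=0))
    obs = float(lr_obs.sum())

    rng = np.random.default_rng(seed)
    perms = np.empty((n_resamples, nA), dtype=np.int64)
    for r in range(n_resamples):
        perms[r] = rng.choice(n, nA, replace=False)
    # selection matrix (n_resamples, n) @ X -> per-perm group-A counts
    sel = np.zeros((n_resamples, n))
    np.put_along_axis(sel, perms, 1.0, axis=1)
    xA_perm = sel @ X  # (n_resamples, K_kept)
    xB_perm = X.sum(axis=0)[None, :] - xA_perm
    lr_perm = 2.0 * (
        _binom_ll(xA_perm, nA)
        + _binom_ll(xB_perm, n - nA)
        - _binom_ll(xA_perm + xB_perm, n)
    ).sum(axis=1)
    p = (1.0 + (lr_perm >= obs - 1e-12).sum()) / (1.0 + n_resamples)
    return {
        "statistic": obs,
        "p_value": float(p),
        "per_taxon_lr": lr_obs,
        "taxa_kept": int(keep.sum()),
    }


def power_curve(
    design_grid,
    severities,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed=None,
    gamma: int = 120,
    occupancy_source=None,
    tolerance_rho: float = 0.0,
    n_resamples: int = 199,
    turnover_swaps_per_site: int = 10,
    require_both_years: bool = False,
) -> PowerResult:
    """Monte Carlo power over a design x severity grid.

    Each simulation builds a baseline metacommunity; every simulated year
    (the reference year included) is an independent fixed-margin shuffle of
    it, emulating the near-random year-to-year turnover of the system, so
    that with no stressor the reference and impacted years are exchangeable.
    Post-impact years additionally lose a ``severity`` fraction of
    occurrences, weighted against intolerant taxa. Each year is observed
    through imperfect replicated detection and tested against the reference
    sample. Success means rejection at ``alpha`` in at least one post-impact
    year (or both, when ``require_both_years``); power is the success
    fraction over ``n_sim``.
    """
    designs = list(design_grid)
    if not designs:
        raise ValueError("empty design grid")
    severities = np.asarray(sorted(severities), dtype=float)
    root = np.random.SeedSequence(seed)
    power = np.zeros((len(designs), len(severities)))

    for di, design in enumerate(designs):
        preset = DETECTION_PRESETS[design.detection_preset]
        for si, sev in enumerate(severities):
            streams = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(di, si)
            ).spawn(n_sim)
            hits = 0
            for s in range(n_sim):
                rng = np.random.default_rng(streams[s])
                if occupancy_source is None:
                    src = {"mu": -1.1, "sigma": 1.3}
                else:
                    src = occupancy_source
                base = build_baseline(src, gamma, design.n_sites, rng.integers(2**31))
                p_k = expit(rng.normal(preset["mu"], preset["sigma"], gamma))
                ref_year = MetacommunitySim(
                    matrix=permute_fixed_margins(
                        base.matrix,
                        turnover_swaps_per_site * design.n_sites,
                        rng.integers(2**31),
                    ),
                    psi=base.psi,
                )
                ref = sample_detection(
                    ref_year, p_k, design.replicates, rng.integers(2**31)
                )
                tol = make_tolerances(base.psi, tolerance_rho, rng.integers(2**31))
                rejections = 0
                for _year in range(design.years_post_impact):
                    shuffled = MetacommunitySim(
                        matrix=permute_fixed_margins(
                            base.matrix,
                            turnover_swaps_per_site * design.n_sites,
                            rng.integers(2**31),
                        ),
                        psi=base.psi,
                    )
                    impacted = apply_stressor(shuffled, tol, sev, rng.integers(2**31))
                    obs = sample_detection(
                        impacted, p_k, design.replicates, rng.integers(2**31)
                    )
                    res = manyglm_test(ref, obs, n_resamples, rng.integers(2**31))
                    rejections += res["p_value"] <= alpha
                success = (
                    rejections == design.years_post_impact
                    if require_both_years
                    else rejections >= 1
                )
                hits += success
            power[di, si] = hits / n_sim
    return PowerResult(
        designs=designs, severities=severities, power=power, n_sim=n_sim, alpha=alpha
    )
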