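"""Detection-corrected alpha, beta and gamma diversity.

Observed diversity collapses replicate detections; corrected diversity uses
the posterior latent occupancy states z (which include detections the survey
missed), so corrected alpha >= observed alpha per site and gamma >= observed
richness in every draw. Beta diversity is pairwise Jaccard or Sorensen
dissimilarity on presence-absence, ignoring shared absences.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import DetectionDataset
from .msom import PosteriorSamples

__all__ = [
    "CommunityMatrix",
    "observed_matrix",
    "corrected_matrices",
    "beta_correction_summary",
    "pairwise_dissimilarity",
    "aggregate_taxa",
    "resolution_dissimilarity_contrast",
    "percent_increase",
]


@dataclasses.dataclass
class CommunityMatrix:
    """Binary site(-visit) x taxon presence-absence matrix with labels."""

    values: np.ndarray
    site_labels: list
    taxon_labels: list
    year: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("community matrix entries must be 0/1")
        if self.values.shape != (len(self.site_labels), len(self.taxon_labels)):
            raise ValueError("labels do not match matrix shape")

    @property
    def alpha(self) -> np.ndarray:
        """Per-site richness (row sums)."""
        return self.values.sum(axis=1)

    @property
    def gamma(self) -> int:
        """Number of taxa present anywhere."""
        return int((self.values.any(axis=0)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_labels, columns=self.taxon_labels)


def observed_matrix(data: DetectionDataset) -> CommunityMatrix:
    """Collapse replicates by any-detection into a visit x taxon matrix.

    Visits whose replicates are all missing are excluded.
    """
    if data.mode != "presence_absence":
        raise ValueError("observed_matrix requires presence_absence data")
    has_rep = data.mask.any(axis=1)
    vals = data.detected_any()[has_rep].astype(np.int64)
    info = data.visit_info.loc[has_rep].reset_index(drop=True)
    labels = [f"{r.site_id}@{r.year}" for r in info.itertuples(index=False)]
    return CommunityMatrix(
        values=vals,
        site_labels=labels,
        taxon_labels=list(data.taxon_ids),
        year=info["year"].to_numpy(),
    )


def corrected_matrices(fit: PosteriorSamples, data: DetectionDataset):
    """Yield the latent-state (z) community matrix of each stored draw.

    Columns are restricted to the listed taxa (augmented never-observed taxa
    contribute to gamma, not to site x taxon composition). Requires the fit
    to have been run with ``store_z=True``.
    """
    if "z" not in fit.samples:
        raise ValueError(
            "latent z draws were not stored; refit with MSOMConfig(store_z=True)"
        )
    z = fit.get("z")  # (draws, I, M)
    labels = [f"{r.site_id}@{r.year}" for r in data.visit_info.itertuples(index=False)]
    year = data.visit_info["year"].to_numpy()
    K = len(data.taxon_ids)
    for d in range(z.shape[0]):
        yield CommunityMatrix(
            values=z[d, :, :K].astype(np.int64),
            site_labels=labels,
            taxon_labels=list(data.taxon_ids),
            year=year,
        )


def beta_correction_summary(
    fit: PosteriorSamples, data: DetectionDataset, metric: str = "jaccard"
) -> dict:
    """Observed vs detection-corrected beta diversity, per posterior draw.

    For each stored latent-state draw, computes the mean pairwise
    dissimilarity of the corrected (z) matrix and the paired difference
    (observed - corrected) averaged over site pairs. A positive difference
    means imperfect detection inflates apparent turnover.
    """
    obs = observed_matrix(data)
    d_obs = mean_pairwise_dissimilarity(obs, metric)
    corrected = np.array(
        [mean_pairwise_dissimilarity(m, metric) for m in corrected_matrices(fit, data)]
    )
    diff = d_obs - corrected
    return {
        "observed": d_obs,
        "corrected_mean": float(corrected.mean()),
        "corrected_lo95": float(np.quantile(corrected, 0.025)),
        "corrected_hi95": float(np.quantile(corrected, 0.975)),
        "difference_mean": float(diff.mean()),
        "difference_lo95": float(np.quantile(diff, 0.025)),
        "difference_hi95": float(np.quantile(diff, 0.975)),
    }


def _pair_counts(m: np.ndarray):
    a = m.sum(axis=1)
    inter = m @ m.T
    union = a[:, None] + a[None, :] - inter
    return a, inter, union


def pairwise_dissimilarity(m: CommunityMatrix, metric: str = "jaccard"):
    """Site x site dissimilarity matrix; shared absences carry no weight.

    Jaccard: 1 - |A&B| / |A|B|; Sorensen: 1 - 2|A&B| / (|A| + |B|).
    An empty site is maximally dissimilar (1) to any non-empty site; a pair
    of empty sites is set to 0. Returns (matrix, empty_site_flags).
    """
    vals = m.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    a, inter, union = _pair_counts(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "jaccard":
            d = 1.0 - inter / union
        elif metric == "sorensen":
            d = 1.0 - 2.0 * inter / (a[:, None] + a[None, :])
        else:
            raise ValueError(f"unknown metric {metric!r}")
    both_empty = (a[:, None] == 0) & (a[None, :] == 0)
    d = np.where(both_empty, 0.0, d)
    np.fill_diagonal(d, 0.0)
    return d, a == 0


def mean_pairwise_dissimilarity(m: CommunityMatrix, metric: str = "jaccard") -> float:
    d, _ = pairwise_dissimilarity(m, metric)
    iu = np.triu_indices_from(d, k=1)
    return float(d[iu].mean())


def aggregate_taxa(m, taxonomy: pd.DataFrame, rank: str):
    """Aggregate a community matrix or dataset to genus or family rank.

    Presence at the coarser rank is the logical OR over member taxa; counts
    are summed. Raises if any taxon lacks a mapping at the requested rank.
    """
    if rank not in ("genus", "family"):
        raise ValueError("rank must be 'genus' or 'family'")
    if isinstance(m, CommunityMatrix):
        labels = m.taxon_labels
        missing = [t for t in labels if t not in taxonomy.index]
        if missing:
            raise ValueError(f"taxa unmapped in taxonomy: {missing[:5]}")
        groups = taxonomy.loc[labels, rank].to_numpy()
        uniq = sorted(set(groups))
        out = np.zeros((m.values.shape[0], len(uniq)), dtype=np.int64)
        for g, name in enumerate(uniq):
            out[:, g] = m.values[:, groups == name].max(axis=1)
        return CommunityMatrix(out, m.site_labels, uniq, year=m.year)
    if isinstance(m, DetectionDataset):
        labels = m.taxon_ids
        missing = [t for t in labels if t not in taxonomy.index]
        if missing:
            raise ValueError(f"taxa unmapped in taxonomy: {missing[:5]}")
        groups = taxonomy.loc[labels, rank].to_numpy()
        uniq = sorted(set(groups))
        y = np.zeros(m.y.shape[:2] + (len(uniq),), dtype=np.int64)
        for g, name in enumerate(uniq):
            sub = m.y[:, :, groups == name]
            y[:, :, g] = sub.sum(axis=2) if m.mode == "count" else sub.max(axis=2)
        if rank == "genus":
            g2f = taxonomy.drop_duplicates("genus").set_index("genus")["family"]
            fams = [g2f[u] for u in uniq]
        else:
            fams = uniq
        tax = pd.DataFrame(
            {"genus": uniq, "family": fams}, index=pd.Index(uniq, name="taxon_id")
        )
        return dataclasses.replace(m, y=y, taxon_ids=uniq, taxonomy=tax)
    raise TypeError("m must be a CommunityMatrix or DetectionDataset")


def resolution_dissimilarity_contrast(
    genus_m: CommunityMatrix, family_m: CommunityMatrix, metric: str = "jaccard"
) -> float:
    """Percent by which mean genus-rank dissimilarity exceeds family rank.

    Returns 100 * (mean_d_genus - mean_d_family) / mean_d_family; positive
    when the finer rank looks more heterogeneous, the expected direction
    since OR-aggregation can only create shared presences.
    """
    if genus_m.values.shape[0] != family_m.values.shape[0]:
        raise ValueError("matrices must share sites")
    if genus_m.values.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    dg = mean_pairwise_dissimilarity(genus_m, metric)
    df = mean_pairwise_dissimilarity(family_m, metric)
    if df == 0:
        return 0.0 if dg == 0 else float("inf")
    return 100.0 * (dg - df) / df


def percent_increase(estimated_richness: float, observed_richness: float) -> int:
    """Integer percent increase of a corrected richness over the observed one."""
    if observed_richness <= 0:
        raise ValueError("observed richness must be > 0")
    frac = 100.0 * (estimated_richness - observed_richness) / observed_richness
    # round half away from zero, the convention used when reporting percents
    return int(np.sign(frac) * np.floor(abs(frac) + 0.5))
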