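"""Survey data containers and plain-text readers/writers.

The central object is :class:`DetectionDataset`: a dense (visit, replicate,
taxon) observation array with a replicate mask for irregular sampling,
standardized covariates at the visit and replicate level, and a genus/family
taxonomy map. The same container holds binary detections (presence–absence
mode) and integer counts (count mode).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDesign",
    "DetectionDataset",
    "read_detection_table",
    "read_taxonomy",
    "write_dataset",
]

OBS_COLUMNS = ["site_id", "year", "visit_id", "replicate_id", "taxon_id", "value"]


@dataclasses.dataclass(frozen=True)
class SurveyDesign:
    """Shape of a multi-year replicated survey.

    A "visit" is one site in one year; occupancy is defined per visit.
    ``n_taxa_true`` is the regional richness (gamma) of the simulated
    metacommunity.
    """

    n_sites: int = 12
    n_years: int = 6
    visits_per_site_year: int = 1
    replicates_per_visit: int = 2
    n_taxa_true: int = 360
    n_occ_covariates: int = 3
    n_det_covariates: int = 1
    primer_levels: int = 2

    def __post_init__(self) -> None:
        for name in (
            "n_sites",
            "n_years",
            "visits_per_site_year",
            "replicates_per_visit",
            "n_taxa_true",
            "primer_levels",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_occ_covariates < 0 or self.n_det_covariates < 0:
            raise ValueError("covariate counts must be >= 0")
        if not 1 <= self.replicates_per_visit <= 3:
            raise ValueError("replicates_per_visit must be in 1..3")

    @property
    def n_visits(self) -> int:
        return self.n_sites * self.n_years * self.visits_per_site_year


@dataclasses.dataclass
class DetectionDataset:
    """Replicated detection/count observations with covariates.

    Attributes
    ----------
    y : int array, shape (n_visits, max_replicates, n_taxa)
        Binary detections (presence_absence mode) or counts (count mode).
        Entries where ``mask`` is False carry no information.
    mask : bool array, shape (n_visits, max_replicates)
        True where the replicate sample exists.
    occ_covariates : float array, shape (n_visits, n_occ_covariates)
        Standardized visit-level covariates (flood frequency, days since
        ice melt, water temperature, ...).
    det_covariates : float array, shape (n_visits, max_replicates, n_det_cov)
        Standardized replicate-level covariates; categorical primer is
        expanded to treatment contrasts and included here.
    taxonomy : DataFrame indexed by taxon_id with columns genus, family.
    visit_info : DataFrame with site_id, year, visit_id per visit row.
    mode : {"presence_absence", "count"}
    """

    y: np.ndarray
    mask: np.ndarray
    occ_covariates: np.ndarray
    det_covariates: np.ndarray
    taxonomy: pd.DataFrame
    visit_info: pd.DataFrame
    taxon_ids: list
    mode: str = "presence_absence"
    occ_covariate_names: list = dataclasses.field(default_factory=list)
    det_covariate_names: list = dataclasses.field(default_factory=list)
    primer: np.ndarray | None = None  # per (visit, replicate) primer label

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.ndim != 3:
            raise ValueError("y must be 3-dimensional (visit, replicate, taxon)")
        if self.mask.shape != self.y.shape[:2]:
            raise ValueError("mask shape must match y's first two axes")
        vals = self.y[self.mask]
        if self.mode == "presence_absence":
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("presence_absence mode requires y in {0, 1}")
        elif self.mode == "count":
            if (vals < 0).any() or not np.issubdtype(self.y.dtype, np.integer):
                raise ValueError("count mode requires nonnegative integer y")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = set(self.taxon_ids) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa missing from taxonomy: {sorted(missing)[:5]}")

    @property
    def n_visits(self) -> int:
        return self.y.shape[0]

    @property
    def max_replicates(self) -> int:
        return self.y.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.y.shape[2]

    @property
    def observed_richness(self) -> int:
        """Number of taxa with at least one detection."""
        detected = (self.y * self.mask[:, :, None]).sum(axis=(0, 1)) > 0
        return int(detected.sum())

    def detected_any(self) -> np.ndarray:
        """(n_visits, n_taxa) bool: any detection across existing replicates."""
        return ((self.y > 0) & self.mask[:, :, None]).any(axis=1)

    def to_long(self) -> pd.DataFrame:
        """Long-format observation table, one row per (visit, replicate, taxon)."""
        ii, jj = np.nonzero(self.mask)
        rows = []
        for i, j in zip(ii, jj):
            info = self.visit_info.iloc[i]
            for k, taxon in enumerate(self.taxon_ids):
                rows.append(
                    {
                        "site_id": info["site_id"],
                        "year": info["year"],
                        "visit_id": info["visit_id"],
                        "replicate_id": j,
                        "taxon_id": taxon,
                        "value": int(self.y[i, j, k]),
                        "primer": None if self.primer is None else self.primer[i, j],
                    }
                )
        df = pd.DataFrame(rows)
        if self.primer is None:
            df = df.drop(columns=["primer"])
        return df


def _standardize_columns(df: pd.DataFrame, cols: list) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        sd = out[c].std(ddof=0)
        out[c] = (out[c] - out[c].mean()) / (sd if sd > 0 else 1.0)
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxon_id → genus → family map from TSV.

    Raises on duplicate taxon ids and on genera assigned to more than one
    family (an internally inconsistent classification).
    """
    tax = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "genus", "family"}
    if not required.issubset(tax.columns):
        raise ValueError(f"taxonomy must have columns {sorted(required)}")
    if tax["taxon_id"].duplicated().any():
        dup = tax.loc[tax["taxon_id"].duplicated(), "taxon_id"].iloc[0]
        raise ValueError(f"duplicate taxon_id in taxonomy: {dup}")
    fam_per_genus = tax.groupby("genus")["family"].nunique()
    bad = fam_per_genus[fam_per_genus > 1]
    if len(bad):
        raise ValueError(f"genus mapped to multiple families: {bad.index[0]}")
    return tax.set_index("taxon_id")


def read_detection_table(
    obs_path,
    covariates_path=None,
    taxonomy_path=None,
    mode: str = "presence_absence",
) -> DetectionDataset:
    """Assemble a :class:`DetectionDataset` from the package's CSV/TSV schema.

    ``obs_path`` columns: site_id, year, visit_id, replicate_id, taxon_id,
    value and optionally primer. ``covariates_path`` columns: site_id, year,
    visit_id plus covariate columns (standardized on read).
    """
    obs = pd.read_csv(obs_path)
    missing = set(OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    dups = obs.duplicated(subset=["visit_id", "replicate_id", "taxon_id"])
    if dups.any():
        raise ValueError("duplicate (visit_id, replicate_id, taxon_id) rows")
    if mode == "presence_absence" and not obs["value"].isin((0, 1)).all():
        raise ValueError("non-binary value in presence_absence mode")
    if mode == "count" and ((obs["value"] < 0).any() or (obs["value"] % 1 != 0).any()):
        raise ValueError("count mode requires nonnegative integer values")

    visit_info = (
        obs[["site_id", "year", "visit_id"]]
        .drop_duplicates()
        .sort_values(["year", "site_id", "visit_id"])
        .reset_index(drop=True)
    )
    visit_index = {v: i for i, v in enumerate(visit_info["visit_id"])}
    taxa = sorted(obs["taxon_id"].unique())
    taxon_index = {t: k for k, t in enumerate(taxa)}
    n_rep = int(obs["replicate_id"].max()) + 1

    y = np.zeros((len(visit_info), n_rep, len(taxa)), dtype=np.int64)
    mask = np.zeros((len(visit_info), n_rep), dtype=bool)
    primer = None
    if "primer" in obs.columns:
        primer = np.full((len(visit_info), n_rep), "", dtype=object)
    for row in obs.itertuples(index=False):
        i = visit_index[row.visit_id]
        j = int(row.replicate_id)
        y[i, j, taxon_index[row.taxon_id]] = int(row.value)
        mask[i, j] = True
        if primer is not None:
            primer[i, j] = row.primer

    occ_names: list = []
    det_names: list = []
    X = np.zeros((len(visit_info), 0))
    V = np.zeros((len(visit_info), n_rep, 0))
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        occ_names = [c for c in cov.columns if c not in ("site_id", "year", "visit_id")]
        cov = _standardize_columns(cov, occ_names)
        cov = cov.set_index("visit_id").loc[visit_info["visit_id"]]
        X = cov[occ_names].to_numpy(dtype=float)
    if primer is not None:
        levels = sorted({p for p in primer[mask] if p != ""})
        # treatment contrasts against the first primer level
        det_names = [f"primer_{lv}" for lv in levels[1:]]
        V = np.zeros((len(visit_info), n_rep, len(levels) - 1))
        for c, lv in enumerate(levels[1:]):
            V[:, :, c] = (primer == lv).astype(float)

    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
        absent = set(taxa) - set(taxonomy.index)
        if absent:
            raise ValueError(f"taxa absent from taxonomy: {sorted(absent)[:5]}")
    else:
        taxonomy = pd.DataFrame(
            {"genus": taxa, "family": taxa}, index=pd.Index(taxa, name="taxon_id")
        )

    return DetectionDataset(
        y=y,
        mask=mask,
        occ_covariates=X,
        det_covariates=V,
        taxonomy=taxonomy,
        visit_info=visit_info,
        taxon_ids=taxa,
        mode=mode,
        occ_covariate_names=occ_names,
        det_covariate_names=det_names,
        primer=primer,
    )


def write_dataset(data: DetectionDataset, outdir, params: dict | None = None) -> dict:
    """Write observations.csv, covariates.csv, taxonomy.tsv and a JSON sidecar.

    Returns the mapping of logical name → written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    obs = data.to_long()
    paths["observations"] = outdir / "observations.csv"
    obs.to_csv(paths["observations"], index=False)

    cov = data.visit_info.copy()
    for c, name in enumerate(data.occ_covariate_names):
        cov[name] = data.occ_covariates[:, c]
    paths["covariates"] = outdir / "covariates.csv"
    cov.to_csv(paths["covariates"], index=False)

    paths["taxonomy"] = outdir / "taxonomy.tsv"
    data.taxonomy.reset_index().to_csv(paths["taxonomy"], sep="\t", index=False)

    if params is not None:
        paths["params"] = outdir / "generation_params.json"
        with open(paths["params"], "w") as fh:
            json.dump(params, fh, indent=2, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
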