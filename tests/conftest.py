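import numpy as np
import pandas as pd
import pytest

from commocc.dataset import DetectionDataset


def make_dataset(y, mask=None, mode="presence_absence", occ_cov=None, det_cov=None):
    """Build a DetectionDataset from a (visits, replicates, taxa) array."""
    y = np.asarray(y, dtype=np.int64)
    I, J, K = y.shape
    if mask is None:
        mask = np.ones((I, J), dtype=bool)
    taxa = [f"t{k:03d}" for k in range(K)]
    tax = pd.DataFrame(
        {"genus": taxa, "family": taxa}, index=pd.Index(taxa, name="taxon_id")
    )
    info = pd.DataFrame(
        {"site_id": [f"s{i:02d}" for i in range(I)], "year": 0, "visit_id": range(I)}
    )
    return DetectionDataset(
        y=y,
        mask=np.asarray(mask, dtype=bool),
        occ_covariates=np.zeros((I, 0)) if occ_cov is None else np.asarray(occ_cov),
        det_covariates=np.zeros((I, J, 0)) if det_cov is None else np.asarray(det_cov),
        taxonomy=tax,
        visit_info=info,
        taxon_ids=taxa,
        mode=mode,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
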