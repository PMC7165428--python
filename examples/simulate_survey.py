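"""Generate a synthetic multi-year wetland survey and write it to CSV.

Builds the default survey preset (12 sites x 6 years, 2 replicate bulk
samples per visit, 360 genera in 130 families, two primer pairs) and
prints the survey's observed summary statistics.
"""

from pathlib import Path

from commocc import (
    CovariateSpec,
    draw_community_params,
    boreal_wetland_design,
    boreal_wetland_hyperparams,
    random_taxonomy,
    simulate_dataset,
    write_dataset,
)

design = boreal_wetland_design()
hyp = boreal_wetland_hyperparams()
n_det = design.n_det_covariates + design.primer_levels - 1
params = draw_community_params(hyp, design.n_taxa_true, design.n_occ_covariates, n_det, seed=1)
taxonomy = random_taxonomy(design.n_taxa_true, 130, seed=1)
data = simulate_dataset(params, design, CovariateSpec(), seed=2, taxonomy=taxonomy)

outdir = Path("example_output/survey")
paths = write_dataset(data, outdir, params={"seed": 1})

print(f"site visits:        {data.n_visits}")
print(f"replicates/visit:   {data.max_replicates}")
print(f"true richness:      {data.n_taxa} genera")
print(f"observed richness:  {data.observed_richness} genera detected at least once")
print(f"written to:         {outdir}/")
# The gap between true and observed richness is the imperfect-detection
# shortfall the occupancy model is built to estimate.
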