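"""Metabolite quality control on the simulated cohort's raw intensities.

Reads results/cohort/metabolites_raw.tsv, applies outlier masking (>5 SD),
probabilistic quotient normalization, the >=300-observation filter, builds
pairwise ratios within the amino-acid / peptide / lipid-fatty-acid
super-pathways, and inverse-normal transforms both.  Writes the transformed
matrices under results/preprocessed/ and reports what each step changed.
"""

from pathlib import Path

import pandas as pd

from uromet.preprocess import (
    build_ratio_matrix,
    filter_min_observations,
    mask_outliers,
    pqn_normalize,
    read_metabolite_tsv,
    transform_matrix,
    write_metabolite_tsv,
)

COHORT = Path("results/cohort")
OUT = Path("results/preprocessed")
OUT.mkdir(parents=True, exist_ok=True)

truth = pd.read_csv(COHORT / "truth.tsv", sep="\t")
pathways = {m: "amino acid" for m in truth["metabolite"]}
raw = read_metabolite_tsv(COHORT / "metabolites_raw.tsv", pathways)
for col in raw.values.columns:
    pathways.setdefault(col, "amino acid")

masked = mask_outliers(raw)
n_masked = int(raw.values.notna().sum().sum() - masked.values.notna().sum().sum())
print(f"outlier masking: {n_masked} values (>5 SD) set to missing")

normalized = pqn_normalize(masked)
print("PQN: per-sample dilution quotients divided out "
      f"(reference spectrum from metabolites with <1% missing)")

filtered = filter_min_observations(normalized, 300)
print(f"observation filter: {normalized.values.shape[1]} -> "
      f"{filtered.values.shape[1]} metabolites with >= 300 observations")

ratios = filter_min_observations(build_ratio_matrix(filtered), 300)
print(f"ratios: {ratios.values.shape[1]} pairwise ratios retained")

transformed = transform_matrix(filtered)
write_metabolite_tsv(transformed, OUT / "metabolites_int.tsv")
ratios.pairs.to_csv(OUT / "ratio_pairs.tsv", sep="\t", index=False)
# the full ratio matrix is large and cheap to rebuild; only the pair table
# is persisted, plus the INT ratios that involve a causal-gene metabolite
involved = ratios.pairs["ratio_id"][
    ratios.pairs["numerator"].isin(truth["metabolite"])
    | ratios.pairs["denominator"].isin(truth["metabolite"])
]
ratio_subset = transform_matrix(ratios).values[list(involved)]
ratio_subset.to_csv(OUT / "ratios_int_causal.tsv", sep="\t",
                    index_label="sample_id", na_rep="")
print(f"wrote INT metabolite matrix and {ratio_subset.shape[1]} "
      f"causal-gene ratios -> {OUT}/")
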