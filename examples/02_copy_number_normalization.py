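"""Copy-number normalization of 16S and 18S tables.

18S route: fit the genome-size -> 18S copy-number power law on a reference
table, impute missing genome sizes from taxonomic relatives, divide by the
predicted copies and rescale to hits per million.  16S route: average
rrnDB-style strain records per species, propagate through the taxonomy,
divide and rescale.
"""

import poleward as pw

data = pw.simulate_transect(
    pw.TransectConfig(seed=1, n_cold_taxa=70, n_warm_taxa=70, n_shared_taxa=60)
)

# --- 18S: the genome-size regression --------------------------------------
ref = data.copy_reference_18S.dropna()
model = pw.fit_copy_number_model(ref["genome_size_Mbp"], ref["copy_number"])
print(f"copy-number law: log10(copies) = {model.slope:.2f} * log10(Mbp) + "
      f"{model.intercept:.2f}   (R^2 = {model.r_squared:.2f}, n = {model.n_points})")
print(f"a 100 Mbp genome is predicted to carry {model.predict(100):.0f} 18S copies")

sizes = pw.impute_missing_attribute(
    data.taxonomy,
    {r["name"]: r["genome_size_Mbp"] for _, r in ref.iterrows()},
    list(data.table_18S.columns),
)
copies18 = {sp: model.predict(g) for sp, g in sizes.items()}
t18 = pw.hits_per_million(pw.normalize_by_copy_number(data.table_18S, copies18))
print(f"normalized 18S table: every station row sums to {t18.sum(axis=1).iloc[0]:,.0f}")

# --- 16S: rrnDB-style strain -> species -> lineage averaging ----------------
species_means = pw.average_copy_numbers_by_species(
    list(zip(data.rrndb_like_16S["species"], data.rrndb_like_16S["copy_number"]))
)
print(f"{len(data.rrndb_like_16S)} strain records collapse to "
      f"{len(species_means)} species-mean copy numbers")
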