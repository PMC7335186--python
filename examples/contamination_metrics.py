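"""Estimate ambient contamination from spliced/unspliced fractions.

Ambient RNA is mostly mature (spliced) mRNA while nuclear RNA is mostly
unspliced pre-mRNA, so the per-droplet percent spliced is bimodal: a
nuclear mode low and a background mode high. A two-Gaussian mixture fitted
to the distribution gives a midpoint (equal-density point) that classifies
droplets as background or nuclear.
"""

import debrisem as dm

matrix, truth = dm.simulate_droplets(seed=7)
splice_tab = dm.simulate_splice(
    truth, p_spliced_ambient=0.8, p_spliced_nuclear=0.25, seed=7
)

records = dm.percent_spliced(splice_tab)
defined = records["pct_spliced"].notna()
print(f"{defined.sum()} of {len(records)} droplets have a defined percent spliced")

model = dm.fit_midpoint(records["pct_spliced"].to_numpy(), seed=7)
print(f"mixture means {model.means.round(3)}, weights {model.weights.round(3)}")
print(f"equal-density midpoint: {model.midpoint:.3f}")

labels = dm.classify_droplets(records, model.midpoint)
print(labels.value_counts().to_string())

# agreement with the simulated origin, on droplets with enough molecules
# for the ratio to be well measured
big = (records["spliced"] + records["unspliced"] >= 100).to_numpy()
origin = truth.droplets.set_index("barcode").loc[records["barcode"], "origin"]
expected = origin.map({"empty": "background", "nucleus": "nuclear"}).to_numpy()
agree = (labels.to_numpy() == expected)[big].mean()
print(f"agreement with true origin (droplets with >= 100 molecules): {agree:.4f}")
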