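"""Generate a synthetic BTL-like dataset and run the descriptor filters.

The generator plants a known structure–activity signal (5 informative
descriptors of 40) plus blocks of near-duplicate columns; the preprocessing
chain removes zero-variance and intercorrelated (|r| > 0.9) columns, and a
Kohonen map can squeeze the pool further by descriptor similarity.
"""

import btlqsar as bq

spec = bq.SyntheticSpec(n_compounds=120, n_descriptors=40, n_informative=5,
                        noise_sd=0.2, seed=7)
ds = bq.generate_btl_like_dataset(spec)
print(f"dataset: {ds.descriptors.n_compounds} compounds, "
      f"{ds.descriptors.n_descriptors} descriptors, "
      f"{ds.activities.n_active} active / {ds.activities.n_inactive} inactive "
      f"at pKi > {spec.activity_threshold}")
print(f"planted signal on: {ds.true_support}")

X = bq.drop_zero_variance(ds.descriptors)
print(f"after zero-variance filter: {X.n_descriptors} columns")
X = bq.drop_intercorrelated(X, threshold=0.9)
print(f"after intercorrelation filter (|r| > 0.9): {X.n_descriptors} columns "
      f"(one survivor per correlated block)")

pool = bq.kohonen_reduce(X, target_pool=16, seed=0)
print(f"Kohonen similarity reduction toward 16: kept {len(pool)} descriptors")
print("informative descriptors surviving every filter:",
      sorted(set(pool) & set(ds.true_support)))
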