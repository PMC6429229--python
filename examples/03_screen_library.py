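"""Screen an untested 300-compound library with a trained battery.

Each screened compound gets a transporter-activity profile: the call and
applicability-domain flag of every classification model, the consensus
calls (strict A, majority A+B, pairwise), and — for compounds called active
by at least one model — a consensus pKi estimate from the regression
battery.  Stricter consensus covers fewer compounds; that trade-off is the
point of the profile.
"""

import btlqsar as bq

ds = bq.generate_btl_like_dataset(
    bq.SyntheticSpec(n_compounds=120, n_descriptors=40, n_informative=5,
                     noise_sd=0.2, seed=7)
)
battery, _ = bq.run_modeling_pipeline(ds.descriptors, ds.activities, seed=7)

library = bq.generate_screening_set(300, ds, seed=8)
profiles, summary = bq.run_screening(battery, library)

print(f"screened {summary['n_compounds']} compounds")
print("in-domain compounds per model:  ", summary["in_ad_per_model"])
print("actives called per model:       ", summary["actives_per_model"])
print("compounds predicted / actives per consensus:")
for mode in summary["actives_per_consensus"]:
    print(f"  {mode:>10}: {summary['predicted_per_consensus'][mode]:>3} predicted, "
          f"{summary['actives_per_consensus'][mode]:>3} active")
print(f"compounds with a consensus pKi estimate: {summary['n_with_pki_estimate']}")

print("\nfirst active calls with a consensus pKi estimate "
      "(needs an in-domain regression model):")
hits = profiles[profiles["pKi_consensus"].notna()]
print(hits[["NN-C_label", "NN-D_label", "Q-D_label",
            "consensus_A+B", "pKi_consensus"]].head())
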