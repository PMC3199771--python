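"""Generate a synthetic 250-species radiation and run the full pipeline.

The generator emulates an island radiation: a 44 Ma crown, right-skewed body
and range sizes, a positive log-log body-range association, and range
centroids diffusing over a 1600 x 600 km domain.
"""

import sisterrange as sr

ds = sr.generate_dataset(sr.SynthConfig(seed=42))
print(f"tips: {ds.tree_time.n_tips}, crown age: {ds.tree_time.height:.1f} Ma, "
      f"localities: {len(ds.localities)}")

summary = sr.run_analysis(ds)
rsa = summary["policies"]["RSA"]
print(f"sister pairs          : {summary['pairs']['n_included']}")
print(f"mean pair age (Ma)    : {summary['pairs']['mean_age_ma']:.2f}")
print(f"% allopatric (RSA)    : {rsa['classification']['pct_allopatric']:.1f}")
print(f"sympatric mean overlap: {rsa['mean_overlap_pct_sympatric']:.1f}%")
print(f"sign test             : Z={rsa['sign_test']['Z']:.2f}, "
      f"p={rsa['sign_test']['p']:.2g}")
print()
print("Sister species overlap more than random non-sister species (positive "
      "Z): shared ancestry keeps ranges close even when speciation leaves "
      "most pairs allopatric.")
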