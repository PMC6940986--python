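"""Generate the fixed benchmark fixture set.

Writes six ground-truth particles with noiseless and noisy curves plus a
TSV manifest of their true parameters. Regenerating with the same seed is
byte-identical, so the fixtures can serve as frozen regression inputs.
"""

import saxshybrid as sx

manifest = sx.make_benchmark_suite("benchmark_fixtures", seed=0, n_q=256)
cols = ["fixture", "Rg", "Dmax", "seed"]
print(manifest[cols].to_string(index=False))
print()
print("Each row lists a truth model (PDB), its curves (.dat) and the true")
print("parameters an analysis should recover; see manifest.tsv alongside.")
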