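"""Generate a synthetic dimorphic craniometric dataset and inspect it.

The generator draws two classes of six correlated skull measurements
(sagittal arcs and chords) from multivariate normals with a shared
within-class covariance; males sit `effect_scale` within-class SDs above
females on every variable.
"""


from cranioclass import default_spec, generate, write_measurements

spec = default_spec(effect_scale=2.0, seed=42)
dataset = generate(spec)

print(f"rows: {len(dataset)} ({dataset.n_female} female / {dataset.n_male} male)")
print(f"Mahalanobis separation between class means: {spec.mahalanobis_separation():.2f}")
print("per-class sample means (mm):")
for label, name in ((1, "female"), (0, "male")):
    means = dataset.X[dataset.sex == label].mean(axis=0)
    print(f"  {name:>6}: " + "  ".join(f"{m:7.1f}" for m in means))

write_measurements(dataset, "skulls_synthetic.csv")
print("wrote skulls_synthetic.csv")
# The separation (~2.6 SD units) puts the optimal accuracy near 90%,
# the range classical craniometric discriminant studies report.
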