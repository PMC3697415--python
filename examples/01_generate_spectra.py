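"""Generate the synthetic study design and look at what it contains.

Builds the default data set — 60 pure yogurt spectra in three batches and
197 adulterated spectra across three adulterants at increasing doping
levels — plus the pure-water reference spectrum, and prints the design
table.  The printed counts are the study's sample-size design; the truth
sidecar records the latent nuisance draws behind every spectrum.
"""

from ocplsnir import GeneratorConfig, generate_study

pure, adulterated, reference, truth = generate_study(GeneratorConfig(seed=7))

print(f"pure spectra:        {pure.n_samples} "
      f"({pure.grid.n_points} wavenumbers, "
      f"{pure.grid.values[0]:.0f}-{pure.grid.values[-1]:.1f} cm^-1)")
print(f"adulterated spectra: {adulterated.n_samples}")
print(f"water reference norm: {float((reference.absorbance**2).sum())**0.5:.3f}\n")

design = {}
for m in adulterated.meta:
    design.setdefault((m.adulterant, m.doping_level), 0)
    design[(m.adulterant, m.doping_level)] += 1
print("adulterant  level(w/w)  n")
for (adulterant, level), n in sorted(design.items()):
    print(f"{adulterant:>10}  {level:>9.3f}  {n}")

print("\nfirst truth records (latent draws the tests can recover):")
print(truth.records.head(3).to_string(index=False))
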