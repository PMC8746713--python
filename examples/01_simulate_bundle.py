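"""Generate a synthetic multi-study cross bundle and write it to disk.

The default bundle emulates a nine-dataset compilation: benthic x
limnetic and marine x freshwater stickleback crosses raised in lab
aquaria or field ponds, genotyped on microsatellites, SNP arrays or GBS.
"""

from ancestryhet import generate_study_bundle, study_bundle_config, write_bundle

config = study_bundle_config(seed=1, scale=0.25)   # quarter-size for speed
bundle = generate_study_bundle(config)
paths = write_bundle(bundle, "scratch/example_bundle")

print(bundle.manifest.to_string(index=False))
print(f"\nwrote {len(bundle.datasets)} genotype TSVs next to "
      f"{paths['manifest']}")
print("Each row is one dataset: its environment, cross type, platform and "
      "the number of fish and markers simulated.")
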