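"""Generate a synthetic allo-octoploid discovery panel.

Builds a 100 kb two-chromosome reference with four collapsed subgenomes,
plants fixed homoeologous variants (HSVs), segregating marker SNPs/indels
and the three haploSNP constructs, and writes one VCF per panel file plus
a ground-truth table.
"""

from polyarray import SimConfig, generate_panel

config = SimConfig(seed=42, ref_length=100_000, n_chromosomes=2)
panel = generate_panel(config, "scratch/example_panel")

print(f"reference: {panel.reference_fasta}")
print(f"panel files: {len(panel.vcf_paths)} VCFs "
      f"({len(panel.accession_ids)} accessions, one sequenced twice)")
print("\nplanted features by kind:")
print(panel.truth["kind"].value_counts().to_string())
print("\nplanted marker candidates by target pipeline:")
print(panel.truth[panel.truth.satisfies]["category"]
      .value_counts().to_string())
print("\nEach 'satisfies' row is a marker that meets every filter of its "
      "pipeline by construction, so discovery should recover it exactly; "
      "'none' rows are HSVs and decoys that must NOT be recovered.")
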