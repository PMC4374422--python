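# polyarray

SNP-array design toolkit for allo-octoploid genomes: marker discovery
from per-accession variant calls, ploidy-reducing haploSNP mining, probe
tiling and accounting, two-channel genotype-cluster QC, and
pedigree/sequence-based genotype validation — plus a synthetic
allo-octoploid panel generator that makes every stage testable without
any external data.

## The problem

In an allo-octoploid such as cultivated strawberry (2n = 8x = 56, modelled
as four diverged subgenomes AABBCCDD), short reads from all eight
homoeologous copies collapse onto one diploid reference. Two kinds of
variants then look identical in a VCF:

* **homoeologous sequence variants (HSVs)** — fixed differences between a
  subgenome and the reference, present in *every* accession; useless as
  markers and poisonous inside probe flanks;
* **marker variants** — polymorphisms segregating within one subgenome
  among accessions (present in ≥ 2, absent in ≥ 2 members).

Even a clean marker is hard to genotype on a two-channel array at 8x:
a probe hybridizes to all eight copies, so the non-segregating copies add
constant signal and compress the genotype clusters. In the
contrast/size plane (contrast = log2(A/B), size = (log2 A + log2 B)/2)
the cluster centers follow the linear dosage model

    A = nA · I_A + bg,    B = nB · I_B + bg

and the **HomRO** statistic — min(contrast_AA, −contrast_BB), the signed
displacement from zero contrast of the homozygous cluster nearest it —
separates diploid-like (HomRO ≥ 0.3) from polyploid-like patterns.

The toolkit's central trick is the **haploSNP**: couple a marker SNP to a
closely adjacent HSV (the "destabilization site") and target the probe at
the HSV form carried by the marker's subgenome. Homoeologs lacking that
form fail to hybridize, achieving technical ploidy reduction. Three
constructions are mined: an HSV SNP within 6 bp of the marker, a 4–6 bp
HSV indel within 14 bp, and a marker SNP residing inside a 3–6 bp
subgenome-specific insertion.

## Worked example

```bash
python examples/cluster_genotyping.py
```

prints (one segregating locus simulated at three effective ploidies,
300 samples, 5% multiplicative intensity noise):

```
2x (diploid-like)  class=PHR  call accuracy=1.000  HomRO=+1.59 (diploid_like)
4x                 class=PHR  call accuracy=1.000  HomRO=+0.00 (polyploid_like)
8x B-fixed         class=PHR  call accuracy=1.000  HomRO=-1.22 (polyploid_like)
```

The caller resolves all three genotype clusters at every ploidy, but the
fixed B-allele background pushes the homozygous clusters toward negative
contrast: HomRO falls from +1.59 to −1.22, flagging the 4x and 8x loci as
polyploid-like. The other example scripts cover panel simulation
(`simulate_panel.py`), marker discovery with truth-table recovery
(`discover_markers.py`), probe tiling/accounting (`design_probes.py`) and
pedigree/sequence validation (`validate_genotypes.py`).

A thin CLI wires the stages for shell use:

```bash
polyarray simulate --seed 1 --out panel/
polyarray discover --panel panel/ --pipeline all --out candidates/
polyarray design --candidates candidates/candidates.tsv --out design/
polyarray classify --intensities intensities.tsv --out quality/
polyarray validate concordance --genotypes gt.tsv \
    --parent1 P1 --parent2 P2 --out report/
```

## Layout

| path                | contents                                              |
|---------------------|-------------------------------------------------------|
| `src/polyarray/synthetic.py` | synthetic panel, pedigree and intensity generator |
| `src/polyarray/panel_io.py`  | VCF/FASTA/GFF3 readers, panel table, depth profiles |
| `src/polyarray/pipelines.py` | filter primitives and the eight discovery pipelines |
| `src/polyarray/probes.py`    | screens, tiling geometry, probe/probeset accounting |
| `src/polyarray/clusters.py`  | contrast/size model, mixture caller, quality classes, HomRO, OTV |
| `src/polyarray/validation.py`| concordance, binomial genotyping, MAF, gap analysis |
| `src/polyarray/cli.py`       | thin `polyarray` command                     |
| `docs/methods.md`   | model assumptions, parameter defaults, limitations    |
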