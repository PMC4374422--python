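"""Synthetic allo-octoploid discovery panel generator.

The generator emulates the data situation of SNP-array design in an
allo-octoploid crop: four diverged subgenomes (AABBCCDD model) whose short
reads all collapse onto a single diploid reference coordinate system.
Variation comes in two fundamentally different flavours:

* **HSVs** (homoeologous sequence variants): differences between a
  subgenome and the reference that are fixed in every panel member.  They
  are nuisance variation for marker discovery but the raw material for
  "destabilization sites" in the haploSNP strategies.
* **Marker variants**: SNPs/indels segregating within one subgenome among
  panel members (carried by >= 2 accessions and absent from >= 2).

Every planted feature is recorded in a truth table so the discovery
pipelines can be tested for exact recovery.  Planted features are placed
on an exclusive slot grid so that, by construction, their probe-flank
windows contain no unrelated variants; a configuration too dense for the
grid is rejected.

Outputs are plain text: a reference FASTA, a two-exon gene-model GFF3, one
VCF v4.2 per panel *file* (an accession may contribute two files, as in
real multi-run sequencing), a diploid-parent VCF, and TSV truth tables.
All outputs are byte-identical for identical configurations.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seq import BASES, TRANSITION, random_sequence
from .clusters import ClusterCenterModel, contrast_size

# Per-file mean fold-coverages of the 20-file / 19-accession octoploid
# discovery panel (one accession sequenced twice).  These defaults define
# the study conditions: 10 files reach >=16x (the HD-16 subpanel, which
# includes both files of the twice-sequenced accession) and 8 reach >=20x
# (HD-20, which excludes its lower-coverage file).
DEFAULT_FILE_COVERAGES: tuple[float, ...] = (
    48.7, 37.0, 34.9, 32.3, 31.2, 30.0, 26.0, 24.9, 19.7, 16.7,
    15.1, 14.2, 5.7, 4.6, 4.3, 2.7, 2.0, 5.6, 4.1, 4.0,
)
# file index -> accession index; files 5 and 9 are the same accession.
_DEFAULT_FILE_ACCESSION: tuple[int, ...] = (
    0, 1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
)

GENOTYPE_ALPHABET = frozenset({"AA", "AB", "BB", "A0", "B0", "00"})


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised."""


@dataclass
class SimConfig:
    """Configuration of the synthetic panel.

    Rates are features per kb of reference.  The inter-subgenome
    divergence (``hsv_rate``) is a free parameter of the simulation, not
    an empirical value; the default of 0.8/kb merely gives the pipelines
    a realistic excess of HSVs over marker variants.
    """

    seed: int = 1
    ref_length: int = 200_000
    n_chromosomes: int = 2
    n_subgenomes: int = 4
    n_accessions: int = 19
    duplicate_first_low_coverage: bool = True  # 20 files from 19 accessions
    file_coverages: tuple[float, ...] = DEFAULT_FILE_COVERAGES

    hsv_rate: float = 0.8
    hsv_indel_rate: float = 0.1
    marker_rate: float = 0.2
    indel_marker_rate: float = 0.06
    msnp_rate: float = 0.04
    snpsnp_rate: float = 0.08
    indelsnp_rate: float = 0.05
    insertion_marker_rate: float = 0.05
    diploid_snp_rate: float = 0.08
    decoy_at_rate: float = 0.02
    decoy_bigindel_rate: float = 0.02

    deletion_block_count: int = 2
    deletion_block_length: int = 10_000

    # gene models: uniformly spaced two-exon genes
    exon_length: int = 300  # multiple of 3 so frames stay complete
    intron_length: int = 150
    gene_spacing: int = 1_500

    slot_spacing: int = 80
    edge_margin: int = 60

    include_unanchored: bool = True
    unanchored_length: int = 4_000

    diploid_coverage: float = 36.0

    intensity_model: "ClusterCenterModel" = field(
        default_factory=lambda: ClusterCenterModel()
    )
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subgenomes < 2:
            raise SimulationError("n_subgenomes must be >= 2")
        for name in (
            "hsv_rate", "hsv_indel_rate", "marker_rate", "indel_marker_rate",
            "msnp_rate", "snpsnp_rate", "indelsnp_rate",
            "insertion_marker_rate", "diploid_snp_rate",
            "decoy_at_rate", "decoy_bigindel_rate",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.duplicate_first_low_coverage:
            if len(self.file_coverages) != self.n_accessions + 1:
                raise SimulationError(
                    "need n_accessions + 1 file coverages when one "
                    "accession is sequenced twice"
                )
        elif len(self.file_coverages) != self.n_accessions:
            raise SimulationError("need one coverage per accession")

    @property
    def file_accession_map(self) -> tuple[int, ...]:
        if not self.duplicate_first_low_coverage:
            return tuple(range(self.n_accessions))
        if (
            self.n_accessions == 19
            and self.file_coverages == DEFAULT_FILE_COVERAGES
        ):
            return _DEFAULT_FILE_ACCESSION
        # generic layout: last file re-sequences accession 0
        return tuple(range(self.n_accessions)) + (0,)


@dataclass(frozen=True)
class PlantedAllele:
    """One alternate allele segregating (or fixed) in the panel.

    ``carriers`` is None for an HSV (all accessions carry it).
    ``copies_in_carriers``/``copies_in_others`` give the number of
    homoeologous copies bearing the allele per accession class.
    """

    chrom: str
    pos: int  # 0-based anchor coordinate
    ref: str
    alt: str
    vtype: str  # snp | ins | del
    subgenome: int
    carriers: frozenset | None
    copies_in_carriers: int = 1
    copies_in_others: int = 0

    def copies(self, accession: int) -> int:
        if self.carriers is None or accession in self.carriers:
            return self.copies_in_carriers
        return self.copies_in_others


@dataclass
class SyntheticPanel:
    """Paths plus in-memory truth for one generated panel."""

    out_dir: Path
    reference_fasta: Path
    gff3: Path
    vcf_paths: list[Path]
    diploid_vcf: Path
    panel_yaml: Path
    truth: pd.DataFrame
    deletions: pd.DataFrame
    chrom_lengths: dict[str, int]
    file_ids: list[str]
    accession_ids: list[str]
    file_coverages: list[float]


# ---------------------------------------------------------------------------
# layout helpers


def _chrom_layout(config: SimConfig) -> dict[str, int]:
    per = config.ref_length // config.n_chromosomes
    lengths = {f"chr{i + 1}": per for i in range(config.n_chromosomes)}
    if config.include_unanchored:
        lengths["chrUn"] = config.unanchored_length
    return lengths


def _make_slots(config: SimConfig, lengths: Mapping[str, int],
                rng: np.random.Generator) -> list[tuple[str, int]]:
    slots: list[tuple[str, int]] = []
    for chrom, length in lengths.items():
        lo, hi = config.edge_margin, length - config.edge_margin
        slots.extend(
            (chrom, int(p)) for p in range(lo, hi, config.slot_spacing)
        )
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def _deletion_blocks(config: SimConfig, lengths: Mapping[str, int],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Species-wide deletion blocks, each removing one or two subgenomes."""
    rows = []
    chroms = [c for c in lengths if c != "chrUn"]
    for i in range(config.deletion_block_count):
        chrom = chroms[i % len(chroms)]
        length = lengths[chrom]
        span = min(config.deletion_block_length, length // 3)
        start = int(rng.integers(0, max(1, length - span)))
        n_del = 1 + (i % 2)  # alternate 1- and 2-subgenome deletions
        subs = tuple(
            sorted(rng.choice(np.arange(1, config.n_subgenomes),
                              size=n_del, replace=False).tolist())
        )
        rows.append({
            "chrom": chrom, "start": start, "end": start + span,
            "subgenomes": ",".join(map(str, subs)),
        })
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "subgenomes"]
    )


def _deleted_subgenomes(deletions: pd.DataFrame, chrom: str,
                        pos: int) -> set[int]:
    out: set[int] = set()
    for row in deletions.itertuples():
        if row.chrom == chrom and row.start <= pos < row.end:
            out.update(int(s) for s in row.subgenomes.split(","))
    return out


# ---------------------------------------------------------------------------
# feature planting


def _choose_carriers(rng: np.random.Generator, n_acc: int) -> frozenset:
    n = int(rng.integers(2, n_acc - 1))  # 2 .. n_acc-2 carriers
    return frozenset(rng.choice(n_acc, size=n, replace=False).tolist())


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def _plant_features(config: SimConfig, seqs: dict[str, str],
                    deletions: pd.DataFrame,
                    rng: np.random.Generator):
    lengths = {c: len(s) for c, s in seqs.items()}
    slots = _make_slots(config, lengths, rng)
    # the unanchored contig only hosts decoys
    anchored = [s for s in slots if s[0] != "chrUn"]
    unanchored = [s for s in slots if s[0] == "chrUn"]

    kb = sum(length for c, length in lengths.items() if c != "chrUn") / 1000.0
    counts = {
        "hsv_snp": round(config.hsv_rate * kb),
        "hsv_indel": round(config.hsv_indel_rate * kb),
        "diallelic": round(config.marker_rate * kb),
        "indel": round(config.indel_marker_rate * kb),
        "msnp": round(config.msnp_rate * kb),
        "snp_snp": round(config.snpsnp_rate * kb),
        "indel_snp": round(config.indelsnp_rate * kb),
        "snp_in_insertion": round(config.insertion_marker_rate * kb),
        "diploid": round(config.diploid_snp_rate * kb),
        "decoy_at": round(config.decoy_at_rate * kb),
        "decoy_bigindel": round(config.decoy_bigindel_rate * kb),
    }
    total = sum(counts.values())
    if total > len(anchored):
        raise SimulationError(
            f"cannot place {total} features on {len(anchored)} safe slots "
            f"(slot spacing {config.slot_spacing} bp over {kb:.0f} kb); "
            "reduce rates or enlarge the reference"
        )

    n_acc = config.n_accessions
    alleles: list[PlantedAllele] = []
    dip_alleles: list[PlantedAllele] = []
    truth_rows: list[dict] = []
    slot_iter = iter(anchored)

    def live_subgenome(chrom: str, pos: int) -> int:
        dead = _deleted_subgenomes(deletions, chrom, pos)
        live = [s for s in range(1, config.n_subgenomes) if s not in dead]
        if not live:
            raise SimulationError(
                f"all non-reference subgenomes deleted at {chrom}:{pos}"
            )
        return live[int(rng.integers(0, len(live)))]

    def record(chrom, pos, kind, category, subgenome, carriers,
               partner_pos, alleles_str, satisfies):
        truth_rows.append({
            "chrom": chrom, "pos": pos, "kind": kind, "category": category,
            "subgenome": subgenome,
            "carriers": ",".join(map(str, sorted(carriers)))
            if carriers is not None else "all",
            "partner_pos": partner_pos if partner_pos is not None else -1,
            "alleles": alleles_str, "satisfies": satisfies,
        })

    for kind, n in counts.items():
        for _ in range(n):
            chrom, pos = next(slot_iter)
            seq = seqs[chrom]
            ref = seq[pos]
            sub = live_subgenome(chrom, pos)

            if kind == "hsv_snp":
                alt = _other_base(rng, ref)
                alleles.append(PlantedAllele(
                    chrom, pos, ref, alt, "snp", sub, None, 2))
                record(chrom, pos, "hsv_snp", "none", sub, None, None,
                       f"{ref}/{alt}", False)

            elif kind == "hsv_indel":
                k = int(rng.integers(3, 7))
                vref = seq[pos:pos + k + 1]
                alleles.append(PlantedAllele(
                    chrom, pos, vref, ref, "del", sub, None, 2))
                record(chrom, pos, "hsv_indel", "none", sub, None, None,
                       f"{vref}/{ref}", False)

            elif kind in ("diallelic", "diploid", "decoy_at"):
                if kind == "decoy_at":
                    alt = {"A": "T", "T": "A", "G": "C", "C": "G"}[ref]
                else:
                    alt = TRANSITION[ref]
                if kind == "diploid":
                    dip_alleles.append(PlantedAllele(
                        chrom, pos, ref, alt, "snp", 0, frozenset({0}), 1))
                    record(chrom, pos, "marker_snp", "diploid", 0, None,
                           None, f"{ref}/{alt}", True)
                else:
                    carriers = _choose_carriers(rng, n_acc)
                    alleles.append(PlantedAllele(
                        chrom, pos, ref, alt, "snp", sub, carriers, 2))
                    record(chrom, pos, "marker_snp",
                           "diallelic" if kind == "diallelic" else "none",
                           sub, carriers, None, f"{ref}/{alt}",
                           kind == "diallelic")

            elif kind == "indel":
                carriers = _choose_carriers(rng, n_acc)
                k = int(rng.integers(3, 7))
                vref = seq[pos:pos + k + 1]
                alleles.append(PlantedAllele(
                    chrom, pos, vref, ref, "del", sub, carriers, 2))
                record(chrom, pos, "marker_indel", "indel", sub, carriers,
                       None, f"{vref}/{ref}", True)

            elif kind == "decoy_bigindel":
                carriers = _choose_carriers(rng, n_acc)
                k = 8  # outside the 3-6 bp candidate size range
                vref = seq[pos:pos + k + 1]
                alleles.append(PlantedAllele(
                    chrom, pos, vref, ref, "del", sub, carriers, 1))
                record(chrom, pos, "marker_indel", "none", sub, carriers,
                       None, f"{vref}/{ref}", False)

            elif kind == "msnp":
                # needs a fixed HSV on a second live subgenome at the site
                live = [s for s in range(1, config.n_subgenomes)
                        if s not in _deleted_subgenomes(deletions, chrom, pos)]
                while len(live) < 2:
                    chrom, pos = next(slot_iter)
                    seq = seqs[chrom]
                    ref = seq[pos]
                    live = [
                        s for s in range(1, config.n_subgenomes)
                        if s not in _deleted_subgenomes(deletions, chrom, pos)
                    ]
                picked = rng.choice(live, size=2, replace=False)
                sub, sub2 = int(picked[0]), int(picked[1])
                carriers = _choose_carriers(rng, n_acc)
                marker_alt = TRANSITION[ref]
                hsv_alt = _other_base(rng, ref, marker_alt)
                alleles.append(PlantedAllele(
                    chrom, pos, ref, marker_alt, "snp", sub, carriers, 2))
                alleles.append(PlantedAllele(
                    chrom, pos, ref, hsv_alt, "snp", sub2, None, 2))
                inventory = f"{ref}/{marker_alt}/{hsv_alt}"
                remaining = [s for s in live if s not in (sub, sub2)]
                if remaining and rng.random() < 0.2:
                    # tetra-allelic: a second fixed HSV on a third subgenome
                    last = _other_base(rng, ref, marker_alt, hsv_alt)
                    alleles.append(PlantedAllele(
                        chrom, pos, ref, last, "snp", remaining[0], None, 2))
                    inventory += f"/{last}"
                record(chrom, pos, "marker_snp", "msnp", sub, carriers,
                       None, inventory, True)

            elif kind == "snp_snp":
                carriers = _choose_carriers(rng, n_acc)
                alt = TRANSITION[ref]
                offset = int(rng.integers(1, 7)) * (
                    1 if rng.random() < 0.5 else -1)
                dpos = pos + offset
                dref = seq[dpos]
                dalt = _other_base(rng, dref)
                alleles.append(PlantedAllele(
                    chrom, pos, ref, alt, "snp", sub, carriers, 2))
                alleles.append(PlantedAllele(
                    chrom, dpos, dref, dalt, "snp", sub, None, 2))
                record(chrom, pos, "marker_snp", "snp_snp", sub, carriers,
                       dpos, f"{ref}/{alt}", True)
                record(chrom, dpos, "hsv_snp", "none", sub, None, pos,
                       f"{dref}/{dalt}", False)

            elif kind == "indel_snp":
                carriers = _choose_carriers(rng, n_acc)
                alt = TRANSITION[ref]
                k = int(rng.integers(4, 7))
                dist = int(rng.integers(2, 15))  # to nearest edited base
                if rng.random() < 0.5:  # destabilizing deletion downstream
                    dpos = pos + dist - 1
                else:  # upstream: deleted bases end at pos - dist
                    dpos = pos - dist - k
                dref = seq[dpos:dpos + k + 1]
                alleles.append(PlantedAllele(
                    chrom, pos, ref, alt, "snp", sub, carriers, 2))
                alleles.append(PlantedAllele(
                    chrom, dpos, dref, seq[dpos], "del", sub, None, 2))
                record(chrom, pos, "marker_snp", "indel_snp", sub, carriers,
                       dpos, f"{ref}/{alt}", True)
                record(chrom, dpos, "hsv_indel", "none", sub, None, pos,
                       f"{dref}/{seq[dpos]}", False)

            elif kind == "snp_in_insertion":
                carriers = _choose_carriers(rng, n_acc)
                k = int(rng.integers(3, 7))
                ins = random_sequence(rng, k)
                j = int(rng.integers(0, k))
                base_bg = ins[j]
                base_marker = TRANSITION[base_bg]
                form_bg = ref + ins
                form_marker = ref + ins[:j] + base_marker + ins[j + 1:]
                alleles.append(PlantedAllele(
                    chrom, pos, ref, form_bg, "ins", sub, carriers,
                    copies_in_carriers=0, copies_in_others=2))
                alleles.append(PlantedAllele(
                    chrom, pos, ref, form_marker, "ins", sub, carriers, 2))
                record(chrom, pos, "marker_in_insertion",
                       "snp_in_insertion", sub, carriers, pos,
                       f"{form_bg}/{form_marker}", True)

    # decoy markers on the unanchored contig (excluded by the LG0 rule)
    for chrom, pos in unanchored[:2]:
        ref = seqs[chrom][pos]
        alt = TRANSITION[ref]
        carriers = _choose_carriers(rng, n_acc)
        alleles.append(PlantedAllele(
            chrom, pos, ref, alt, "snp", 1, carriers, 1))
        record(chrom, pos, "marker_snp", "none", 1, carriers, None,
               f"{ref}/{alt}", False)

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "kind", "category", "subgenome",
                 "carriers", "partner_pos", "alleles", "satisfies"],
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return alleles, dip_alleles, truth


# ---------------------------------------------------------------------------
# read-count model and VCF emission


def _copy_reads(rng: np.random.Generator, rate: float, n_copies: int) -> int:
    """Reads supporting one allele carried by ``n_copies`` homoeologs.

    Clipped Poisson: every surviving copy contributes at least one read, so
    a carried allele is always observed (the generator's contract with the
    recovery tests); the clipping inflates per-copy depth identically
    everywhere, preserving deletion-block depth proportionality.
    """
    if n_copies <= 0:
        return 0
    draws = rng.poisson(rate, size=n_copies)
    return int(np.maximum(draws, 1).sum())


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=polyarray-synthetic
{contigs}\
##INFO=<ID=TYPE,Number=A,Type=String,Description="Allele type: snp, ins or del">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observations">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _write_vcf(path: Path, sample: str, lengths: Mapping[str, int],
               records: Sequence[tuple]) -> None:
    contigs = "".join(
        f"##contig=<ID={c},length={n}>\n" for c, n in lengths.items()
    )
    lines = [_VCF_HEADER.format(contigs=contigs, sample=sample)]
    for chrom, pos, ref, alts, types, ro, aos, dp in records:
        info = f"TYPE={','.join(types)};DP={dp}"
        fmt = f"./.:{dp}:{ro}:{','.join(str(a) for a in aos)}"
        lines.append(
            f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t100\tPASS\t"
            f"{info}\tGT:DP:RO:AO\t{fmt}\n"
        )
    path.write_text("".join(lines))


def _emit_accession_records(
    config: SimConfig,
    alleles: Sequence[PlantedAllele],
    deletions: pd.DataFrame,
    accession: int,
    total_copies: int,
    coverage: float,
    rng: np.random.Generator,
) -> list[tuple]:
    """VCF record tuples for one accession at one coverage."""
    per_copy = coverage / total_copies
    by_site: dict[tuple[str, int], list[PlantedAllele]] = {}
    for al in alleles:
        by_site.setdefault((al.chrom, al.pos), []).append(al)

    records = []
    for (chrom, pos) in sorted(by_site):
        site_alleles = by_site[(chrom, pos)]
        carried = [al for al in site_alleles if al.copies(accession) > 0]
        if not carried:
            continue
        refs = {al.ref for al in carried}
        assert len(refs) == 1, "co-located planted alleles must share REF"
        ref = carried[0].ref
        dead = _deleted_subgenomes(deletions, chrom, pos)
        copies_here = total_copies - 2 * len(dead)
        alt_copies = sum(al.copies(accession) for al in carried)
        ref_copies = max(copies_here - alt_copies, 0)
        aos = [_copy_reads(rng, per_copy, al.copies(accession))
               for al in carried]
        ro = _copy_reads(rng, per_copy, ref_copies)
        dp = ro + sum(aos)
        records.append((
            chrom, pos, ref,
            [al.alt for al in carried], [al.vtype for al in carried],
            ro, aos, dp,
        ))
    return records


# ---------------------------------------------------------------------------
# gene models


def _gene_rows(config: SimConfig, lengths: Mapping[str, int]):
    """Uniformly spaced two-exon genes; CDS spans both exons, frame 0."""
    rows = []
    i = 0
    for chrom, length in lengths.items():
        if chrom == "chrUn":
            continue
        start = config.edge_margin
        span = 2 * config.exon_length + config.intron_length
        while start + span < length - config.edge_margin:
            i += 1
            strand = "+" if i % 2 else "-"
            e1 = (start, start + config.exon_length)
            e2 = (start + config.exon_length + config.intron_length,
                  start + span)
            rows.append({
                "gene_id": f"gene{i:04d}", "chrom": chrom, "strand": strand,
                "start": start, "end": start + span, "exons": (e1, e2),
            })
            start += config.gene_spacing
    return rows


def _write_gff3(path: Path, rows, lengths: Mapping[str, int]) -> None:
    out = ["##gff-version 3\n"]
    for chrom, length in lengths.items():
        out.append(f"##sequence-region {chrom} 1 {length}\n")
    for g in rows:
        c, s = g["chrom"], g["strand"]
        gid = g["gene_id"]
        out.append(f"{c}\t.\tgene\t{g['start'] + 1}\t{g['end']}\t.\t{s}\t.\t"
                   f"ID={gid}\n")
        out.append(f"{c}\t.\tmRNA\t{g['start'] + 1}\t{g['end']}\t.\t{s}\t.\t"
                   f"ID={gid}.t1;Parent={gid}\n")
        exons = g["exons"] if s == "+" else g["exons"]
        phase_order = exons if s == "+" else exons[::-1]
        phase = 0
        phases = {}
        for (a, b) in phase_order:
            phases[(a, b)] = phase
            phase = (3 - ((b - a) - phase) % 3) % 3
        for j, (a, b) in enumerate(exons, 1):
            out.append(f"{c}\t.\texon\t{a + 1}\t{b}\t.\t{s}\t.\t"
                       f"ID={gid}.e{j};Parent={gid}.t1\n")
            out.append(f"{c}\t.\tCDS\t{a + 1}\t{b}\t.\t{s}\t{phases[(a, b)]}\t"
                       f"ID={gid}.c{j};Parent={gid}.t1\n")
    path.write_text("".join(out))


# ---------------------------------------------------------------------------
# public API


def generate_panel(config: SimConfig, out_dir: str | Path) -> SyntheticPanel:
    """Generate reference, gene models, per-accession VCFs and truth tables.

    Fully deterministic under ``config.seed``: layout and read-count draws
    use separate child generators keyed on the seed, so the same
    configuration always yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "vcf").mkdir(exist_ok=True)

    layout_rng = np.random.default_rng([config.seed, 0])
    lengths = _chrom_layout(config)
    seqs = {c: random_sequence(layout_rng, n) for c, n in lengths.items()}
    deletions = _deletion_blocks(config, lengths, layout_rng)
    alleles, dip_alleles, truth = _plant_features(
        config, seqs, deletions, layout_rng)

    ref_path = out_dir / "reference.fa"
    with ref_path.open("w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
    for suffix in (".fai",):  # stale indexes would shadow a regenerated fasta
        idx = ref_path.with_suffix(ref_path.suffix + suffix)
        if idx.exists():
            idx.unlink()

    gff_path = out_dir / "genes.gff3"
    _write_gff3(gff_path, _gene_rows(config, lengths), lengths)

    acc_ids = [f"A{i + 1:02d}" for i in range(config.n_accessions)]
    fmap = config.file_accession_map
    file_ids = []
    seen: dict[int, int] = {}
    for acc in fmap:
        seen[acc] = seen.get(acc, 0) + 1
        fid = acc_ids[acc] if seen[acc] == 1 else f"{acc_ids[acc]}_r{seen[acc]}"
        file_ids.append(fid)

    total_copies = 2 * config.n_subgenomes
    vcf_paths = []
    for i, (fid, acc) in enumerate(zip(file_ids, fmap)):
        rng = np.random.default_rng([config.seed, 1, i])
        records = _emit_accession_records(
            config, alleles, deletions, acc, total_copies,
            config.file_coverages[i], rng)
        path = out_dir / "vcf" / f"{fid}.vcf"
        _write_vcf(path, fid, lengths, records)
        vcf_paths.append(path)

    dip_rng = np.random.default_rng([config.seed, 2])
    dip_records = []
    for al in sorted(dip_alleles, key=lambda a: (a.chrom, a.pos)):
        per_copy = config.diploid_coverage / 2
        ao = _copy_reads(dip_rng, per_copy, 1)
        ro = _copy_reads(dip_rng, per_copy, 1)
        dip_records.append((al.chrom, al.pos, al.ref, [al.alt], [al.vtype],
                            ro, [ao], ro + ao))
    dip_path = out_dir / "vcf" / "F1D.vcf"
    _write_vcf(dip_path, "F1D", lengths, dip_records)

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    del_path = out_dir / "deletions.tsv"
    deletions.to_csv(del_path, sep="\t", index=False)

    panel_yaml = out_dir / "panel.yaml"
    panel_yaml.write_text(yaml.safe_dump({
        "files": [
            {"id": fid, "accession": acc_ids[acc],
             "coverage": float(config.file_coverages[i]),
             "path": f"vcf/{fid}.vcf"}
            for i, (fid, acc) in enumerate(zip(file_ids, fmap))
        ],
        "diploid": {"id": "F1D", "coverage": float(config.diploid_coverage),
                    "path": "vcf/F1D.vcf"},
        "seed": config.seed,
    }, sort_keys=False))

    return SyntheticPanel(
        out_dir=out_dir, reference_fasta=ref_path, gff3=gff_path,
        vcf_paths=vcf_paths, diploid_vcf=dip_path, panel_yaml=panel_yaml,
        truth=truth, deletions=deletions, chrom_lengths=lengths,
        file_ids=file_ids, accession_ids=acc_ids,
        file_coverages=list(config.file_coverages),
    )


def simulate_depth(config: SimConfig, chrom_length: int,
                   deletions: pd.DataFrame, chrom: str,
                   coverage: float, seed_key: int = 3) -> np.ndarray:
    """Per-base depth for one accession on one chromosome.

    Sum over surviving homoeologous copies of clipped-Poisson per-copy
    depth, i.e. the same model that generates VCF read counts.
    """
    rng = np.random.default_rng([config.seed, seed_key])
    total = 2 * config.n_subgenomes
    per_copy = coverage / total
    copies = np.full(chrom_length, total)
    for row in deletions.itertuples():
        if row.chrom == chrom:
            n_del = len(row.subgenomes.split(","))
            copies[row.start:row.end] -= 2 * n_del
    max_c = int(copies.max())
    draws = np.maximum(rng.poisson(per_copy, size=(max_c, chrom_length)), 1)
    mask = np.arange(max_c)[:, None] < copies[None, :]
    return (draws * mask).sum(axis=0)


# ---------------------------------------------------------------------------
# pedigrees


@dataclass
class PedigreePanel:
    """Parents plus progeny genotypes under disomic inheritance."""

    markers: list[str]
    parent1: dict[str, str]
    parent2: dict[str, str]
    progeny: pd.DataFrame  # rows: progeny, columns: markers


def _draw_allele(rng: np.random.Generator, genotype: str) -> str:
    return genotype[int(rng.integers(0, 2))]


def _canonical(a: str, b: str) -> str:
    # allele order A < B < 0(null); nulls sort last
    order = {"A": 0, "B": 1, "0": 2}
    return a + b if order[a] <= order[b] else b + a


def generate_pedigree(parent1: Sequence[str], parent2: Sequence[str],
                      n_progeny: int, seed: int = 1,
                      markers: Sequence[str] | None = None) -> PedigreePanel:
    """Simulate progeny genotypes: one allele per parent per marker.

    Each marker segregates in a single subgenome with bivalent pairing, so
    transmission is exactly diploid Mendelian; the null allele (``0``) is
    transmissible like any other.
    """
    if len(parent1) != len(parent2):
        raise ValueError("parents must cover the same markers")
    for gt in list(parent1) + list(parent2):
        if gt not in GENOTYPE_ALPHABET:
            raise ValueError(f"unknown genotype symbol: {gt!r}")
    if markers is None:
        markers = [f"m{i + 1:04d}" for i in range(len(parent1))]
    markers = list(markers)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_progeny):
        rows.append({
            m: _canonical(_draw_allele(rng, g1), _draw_allele(rng, g2))
            for m, g1, g2 in zip(markers, parent1, parent2)
        })
    progeny = pd.DataFrame(rows, columns=markers)
    progeny.index = [f"p{i + 1:03d}" for i in range(n_progeny)]
    return PedigreePanel(
        markers=markers,
        parent1=dict(zip(markers, parent1)),
        parent2=dict(zip(markers, parent2)),
        progeny=progeny,
    )


# ---------------------------------------------------------------------------
# two-channel intensities


def genotype_allele_counts(genotype: str,
                           background: tuple[int, int] = (0, 0)
                           ) -> tuple[int, int]:
    """Hybridizing (#A, #B) allele counts for a genotype.

    ``background`` holds fixed A/B counts contributed by non-segregating
    subgenomes that the probe also hybridizes to.  Null-null samples give
    no signal at all (their probe site is absent), regardless of
    background.
    """
    if genotype not in GENOTYPE_ALPHABET:
        raise ValueError(f"unknown genotype symbol: {genotype!r}")
    if genotype == "00":
        return (0, 0)
    n_a = genotype.count("A") + background[0]
    n_b = genotype.count("B") + background[1]
    return (n_a, n_b)


def generate_intensities(genotypes: pd.DataFrame,
                         model: ClusterCenterModel,
                         noise_sd: float, seed: int = 1,
                         background: Mapping[str, tuple[int, int]]
                         | None = None) -> pd.DataFrame:
    """Two-channel intensities for a sample x marker genotype table.

    ``genotypes`` has columns ``marker``, ``sample``, ``genotype``.  Each
    channel equals the deterministic cluster center for the sample's
    hybridizing allele counts, multiplied by lognormal noise
    ``exp(N(0, noise_sd))`` so intensities stay positive.
    """
    if model.background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for row in genotypes.itertuples():
        bg = background.get(row.marker, (0, 0)) if background else (0, 0)
        n_a, n_b = genotype_allele_counts(row.genotype, bg)
        a, b = model.center(n_a, n_b)
        if noise_sd > 0:
            a *= float(np.exp(rng.normal(0.0, noise_sd)))
            b *= float(np.exp(rng.normal(0.0, noise_sd)))
        c, s = contrast_size(a, b)
        rows.append({
            "marker": row.marker, "sample": row.sample,
            "genotype": row.genotype, "A": a, "B": b,
            "contrast": c, "size": s,
        })
    return pd.DataFrame(
        rows, columns=["marker", "sample", "genotype", "A", "B",
                       "contrast", "size"])
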