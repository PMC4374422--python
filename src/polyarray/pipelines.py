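"""Marker-candidate discovery pipelines and their shared filter primitives.

Eight candidate categories are mined from the panel variant table:

* di-allelic SNPs, multi-allelic SNPs (3-4 alleles) and short di-allelic
  indels (3-6 bp) — the standard categories;
* three classes of ploidy-reducing haploSNPs, each coupling a segregating
  marker SNP to an adjacent fixed homoeologous variant (the
  "destabilization site") so the probe hybridizes to a single subgenome:
  SNP-SNP (HSV SNP within 6 bp), indel-SNP (4-6 bp HSV indel within
  14 bp) and SNP-in-insertion (marker inside a 3-6 bp subgenome-specific
  insertion);
* heterozygous SNPs of a diploid relative's VCF, flank-screened against
  the full octoploid panel;
* speculative codon-based sites: third positions of proline codons in
  CDS, with no variant evidence required.

Filter semantics: presence of an allele in a panel member means at least
one supporting read in that member's file; read-count thresholds sum
supporting reads across all panel files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


from ._seq import TRANSITION, is_at_or_gc
from .panel_io import (
    GeneModelSet,
    PanelVariantTable,
    SiteRecord,
    extract_flanks,
)

CATEGORY_PRECEDENCE = (
    "msnp", "haplosnp_snpsnp", "haplosnp_indelsnp", "snp_in_insertion",
    "diallelic_snp", "indel", "diploid_parent_snp", "codon_based",
)

_RAW_FLANK = 60  # raw reference context extracted around each candidate


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All numeric thresholds of the discovery pipelines."""

    min_reads_snp: int = 3
    min_reads_indel: int = 2
    min_present: int = 2
    min_absent: int = 2
    subpanel: str = "GDP"  # GDP | HD-16 | HD-20
    snp_up: int = 24
    snp_down: int = 24
    indel_up: int = 24
    indel_down: int = 30
    snpsnp_max_offset: int = 6
    indelsnp_max_offset: int = 14
    indelsnp_size_range: tuple[int, int] = (4, 6)
    insertion_size_range: tuple[int, int] = (3, 6)
    indel_size_range: tuple[int, int] = (3, 6)
    haplosnp_clean_window: int = 24
    genic_mode: str = "none"  # CDS | genic | none
    exclude_unanchored: bool = True
    unanchored_contigs: tuple[str, ...] = ("chrUn",)

    def __post_init__(self) -> None:
        for name in ("snp_up", "snp_down", "indel_up", "indel_down",
                     "snpsnp_max_offset", "indelsnp_max_offset",
                     "haplosnp_clean_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("indelsnp_size_range", "insertion_size_range",
                     "indel_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be ordered")
        if self.genic_mode not in ("CDS", "genic", "none"):
            raise ConfigError(f"unknown genic_mode {self.genic_mode!r}")


@dataclass(frozen=True)
class DestabRecord:
    """The critical destabilization form coupled to a haploSNP marker."""

    kind: str  # snp | del | ins | insertion
    pos: int
    ref: str
    alt: str  # the critical form targeted by the probe
    offset: int  # signed distance marker -> nearest edited base


@dataclass
class MarkerCandidate:
    category: str
    chrom: str
    pos: int  # 0-based
    alleles: tuple[str, ...]  # 2-4 alleles; [0] is the reference allele
    vtype: str = "snp"
    marker_allele: str | None = None  # the segregating allele
    destab: DestabRecord | None = None
    flank_up: str = ""
    flank_down: str = ""
    flank_status: str = "BothSafe"
    provenance: tuple[str, ...] = ()
    subpanel: str = "GDP"

    def __post_init__(self) -> None:
        if self.category in ("diallelic_snp", "indel",
                             "diploid_parent_snp", "codon_based"):
            if len(self.alleles) != 2:
                raise ValueError(
                    f"{self.category} candidates are di-allelic")
        if self.category.startswith("haplosnp") or \
                self.category == "snp_in_insertion":
            if self.destab is None:
                raise ValueError("haploSNP candidates need a destab record")


# ---------------------------------------------------------------------------
# filter primitives


def read_count_filter(site: SiteRecord, alt_key: str, vtype: str,
                      config: PipelineConfig) -> bool:
    """Keep iff supporting reads summed across all panel files reach the
    per-type minimum (3 for SNPs, 2 for indels by default)."""
    minimum = config.min_reads_snp if vtype == "snp" else \
        config.min_reads_indel
    return site.alts[alt_key].total_reads() >= minimum


def presence_absence_filter(table: PanelVariantTable, chrom: str, pos: int,
                            alt_key: str, config: PipelineConfig
                            ) -> tuple[bool, str]:
    """Minimum Presence and Minimum Absence on the selected subpanel."""
    subpanel = table.config.subpanel(config.subpanel)
    n_members = len(table._members(subpanel))
    if n_members < config.min_present + config.min_absent:
        raise ConfigError(
            f"subpanel {config.subpanel} has {n_members} members; "
            f"cannot require presence {config.min_present} + absence "
            f"{config.min_absent}")
    present = table.presence_count(chrom, pos, alt_key, subpanel)
    absent = n_members - present
    if present < config.min_present:
        return False, "insufficient presence"
    if absent < config.min_absent:
        reason = "HSV-like" if absent == 0 else "insufficient absence"
        return False, reason
    return True, "ok"


def at_gc_filter(ref_allele: str, alt_allele: str) -> bool:
    """Keep iff the pair is not {A,T} or {G,C} (single-probe designable)."""
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise ValueError("A/T-G/C filter applies to SNP alleles only")
    return not is_at_or_gc(ref_allele, alt_allele)


def genic_filter(chrom: str, pos: int, gene_models: GeneModelSet | None,
                 config: PipelineConfig) -> bool:
    if config.exclude_unanchored and chrom in config.unanchored_contigs:
        return False
    if config.genic_mode == "none" or gene_models is None:
        return True
    if config.genic_mode == "CDS":
        return gene_models.in_cds(chrom, pos)
    return gene_models.in_gene(chrom, pos)


def flank_safety(table: PanelVariantTable, chrom: str, pos: int,
                 up_window: int, down_window: int,
                 allowed_exception: int | None = None) -> str:
    """UpSafe/DownSafe status of the candidate's probe windows.

    A window is safe iff no panel variant other than the candidate itself
    (and the single allowed destabilization-site exception) falls in it.
    Returns one of BothSafe, UpSafe-only, DownSafe-only, Unsafe.
    """
    def clean(lo: int, hi: int) -> bool:
        for (vpos, _ref, _alt) in table.variants_in_window(chrom, lo, hi):
            if vpos == pos or vpos == allowed_exception:
                continue
            return False
        return True

    up_ok = clean(pos - up_window, pos - 1)
    down_ok = clean(pos + 1, pos + down_window)
    if up_ok and down_ok:
        return "BothSafe"
    if up_ok:
        return "UpSafe-only"
    if down_ok:
        return "DownSafe-only"
    return "Unsafe"


# ---------------------------------------------------------------------------
# flank construction


def _raw_flanks(reference, chrom: str, pos: int) -> tuple[str, str]:
    if reference is None:
        return "", ""
    f = extract_flanks(reference, chrom, pos, _RAW_FLANK, _RAW_FLANK)
    return f.upstream, f.downstream


def _apply_destab(up: str, down: str, pos: int,
                  destab: DestabRecord) -> tuple[str, str]:
    """Substitute the critical destabilization form into reference flanks."""
    if not up and not down:
        return up, down
    if destab.kind == "snp":
        if destab.pos < pos:
            i = len(up) - (pos - destab.pos)
            up = up[:i] + destab.alt + up[i + 1:]
        else:
            i = destab.pos - pos - 1
            down = down[:i] + destab.alt + down[i + 1:]
    elif destab.kind == "del":
        k = len(destab.ref) - len(destab.alt)
        if destab.pos < pos:  # deleted bases destab.pos+1 .. destab.pos+k
            i = len(up) - (pos - destab.pos) + 1
            up = up[:i] + up[i + k:]
        else:
            i = destab.pos - pos  # anchor index in down flank + 1
            down = down[:i] + down[i + k:]
    elif destab.kind == "ins":
        inserted = destab.alt[1:]
        if destab.pos < pos:
            i = len(up) - (pos - destab.pos) + 1
            up = up[:i] + inserted + up[i:]
        else:
            i = destab.pos - pos
            down = down[:i] + inserted + down[i:]
    return up, down


# ---------------------------------------------------------------------------
# standard pipelines


def _snp_alts(site: SiteRecord) -> list[str]:
    return [k for k, a in site.alts.items() if a.vtype == "snp"]


def _indel_size(site: SiteRecord, alt_key: str) -> int:
    a = site.alts[alt_key]
    ref = site.ref if ">" not in alt_key else alt_key.split(">", 1)[0]
    return abs(len(ref) - len(a.alt))


def discover_diallelic_snps(table: PanelVariantTable, config: PipelineConfig,
                            reference=None,
                            gene_models: GeneModelSet | None = None
                            ) -> list[MarkerCandidate]:
    """Sites with exactly two observed alleles (reference plus one SNP)
    passing read-count, presence/absence, A/T-G/C, genic and BothSafe
    filters."""
    out = []
    for (chrom, pos) in sorted(table.sites):
        site = table.sites[(chrom, pos)]
        if len(site.alts) != 1:
            continue
        (alt_key, alt_rec), = site.alts.items()
        if alt_rec.vtype != "snp":
            continue
        if not read_count_filter(site, alt_key, "snp", config):
            continue
        keep, _ = presence_absence_filter(table, chrom, pos, alt_key, config)
        if not keep:
            continue
        if not at_gc_filter(site.ref, alt_rec.alt):
            continue
        if not genic_filter(chrom, pos, gene_models, config):
            continue
        status = flank_safety(table, chrom, pos, config.snp_up,
                              config.snp_down)
        if status != "BothSafe":
            continue
        up, down = _raw_flanks(reference, chrom, pos)
        out.append(MarkerCandidate(
            category="diallelic_snp", chrom=chrom, pos=pos,
            alleles=(site.ref, alt_rec.alt), marker_allele=alt_rec.alt,
            flank_up=up, flank_down=down, flank_status=status,
            provenance=("read_count", "presence_absence", "at_gc",
                        "genic", "flank_safety"),
            subpanel=config.subpanel,
        ))
    return out


def discover_msnps(table: PanelVariantTable, config: PipelineConfig,
                   reference=None,
                   gene_models: GeneModelSet | None = None
                   ) -> list[MarkerCandidate]:
    """Tri- and tetra-allelic SNP sites.

    Every allele must pass the read-count filter; at least one must
    behave as a segregating marker (presence/absence per allele); flanks
    must be at least single-safe.
    """
    out = []
    for (chrom, pos) in sorted(table.sites):
        site = table.sites[(chrom, pos)]
        snp_keys = _snp_alts(site)
        if len(snp_keys) != len(site.alts):
            continue  # indel allele present: not a pure mSNP site
        if len(snp_keys) not in (2, 3):  # 3 or 4 alleles with the reference
            continue
        if not all(read_count_filter(site, k, "snp", config)
                   for k in snp_keys):
            continue
        marker_keys = [
            k for k in snp_keys
            if presence_absence_filter(table, chrom, pos, k, config)[0]
        ]
        if not marker_keys:
            continue
        if not genic_filter(chrom, pos, gene_models, config):
            continue
        status = flank_safety(table, chrom, pos, config.snp_up,
                              config.snp_down)
        if status == "Unsafe":
            continue
        up, down = _raw_flanks(reference, chrom, pos)
        out.append(MarkerCandidate(
            category="msnp", chrom=chrom, pos=pos,
            alleles=tuple([site.ref] + sorted(
                site.alts[k].alt for k in snp_keys)),
            marker_allele=site.alts[marker_keys[0]].alt,
            flank_up=up, flank_down=down, flank_status=status,
            provenance=("read_count", "presence_absence:per_allele",
                        "genic", "flank_safety"),
            subpanel=config.subpanel,
        ))
    return out


def discover_indels(table: PanelVariantTable, config: PipelineConfig,
                    reference=None,
                    gene_models: GeneModelSet | None = None
                    ) -> list[MarkerCandidate]:
    """Di-allelic 3-6 bp indel sites with 24/30 bp clean windows."""
    lo, hi = config.indel_size_range
    out = []
    for (chrom, pos) in sorted(table.sites):
        site = table.sites[(chrom, pos)]
        if len(site.alts) != 1:
            continue
        (alt_key, alt_rec), = site.alts.items()
        if alt_rec.vtype not in ("ins", "del"):
            continue
        if not lo <= _indel_size(site, alt_key) <= hi:
            continue
        if not read_count_filter(site, alt_key, alt_rec.vtype, config):
            continue
        subpanel = table.config.subpanel(config.subpanel)
        absent = table.absence_count(chrom, pos, alt_key, subpanel)
        if absent < config.min_absent:
            continue
        if not genic_filter(chrom, pos, gene_models, config):
            continue
        status = flank_safety(table, chrom, pos, config.indel_up,
                              config.indel_down)
        if status != "BothSafe":
            continue
        up, down = _raw_flanks(reference, chrom, pos)
        out.append(MarkerCandidate(
            category="indel", chrom=chrom, pos=pos,
            alleles=(site.ref, alt_rec.alt), vtype=alt_rec.vtype,
            marker_allele=alt_rec.alt,
            flank_up=up, flank_down=down, flank_status=status,
            provenance=("read_count", "size", "absence", "genic",
                        "flank_safety"),
            subpanel=config.subpanel,
        ))
    return out


# ---------------------------------------------------------------------------
# haploSNP pipelines


def _edited_span(pos: int, ref: str, alt: str, vtype: str
                 ) -> tuple[int, int]:
    """Inclusive range of reference bases altered by a variant."""
    if vtype == "snp":
        return pos, pos
    if vtype == "del":
        k = len(ref) - len(alt)
        return pos + 1, pos + k
    return pos, pos + 1  # insertion sits between pos and pos+1


def _destab_offset(marker_pos: int, span: tuple[int, int]) -> int | None:
    lo, hi = span
    if lo <= marker_pos <= hi:
        return None  # marker inside the edited span
    return lo - marker_pos if lo > marker_pos else hi - marker_pos


def _fixed_in_all(table: PanelVariantTable, chrom: str, pos: int,
                  alt_key: str, subpanel: Sequence[str]) -> bool:
    return table.absence_count(chrom, pos, alt_key, subpanel) == 0


def discover_haplosnps(table: PanelVariantTable, config: PipelineConfig,
                       strategy: str, reference=None
                       ) -> list[MarkerCandidate]:
    """Two-phase haploSNP search.

    Phase 1 mines destabilization candidates (variants present in every
    panel member, i.e. HSV-like); phase 2 mines marker SNP candidates
    (present in >= 2 and absent in >= 2 members); they are then paired
    under the strategy's distance/containment rule, checked for a clean
    24 bp window (no third variant between marker and destabilization
    site), and for coupling (every file carrying the marker allele also
    carries the critical form).
    """
    if strategy not in ("snp_snp", "indel_snp", "snp_in_insertion"):
        raise ValueError(f"unknown haploSNP strategy {strategy!r}")
    if strategy == "snp_in_insertion":
        return _discover_snp_in_insertion(table, config, reference)

    subpanel = table.config.subpanel(config.subpanel)
    size_lo, size_hi = config.indelsnp_size_range
    max_offset = (config.snpsnp_max_offset if strategy == "snp_snp"
                  else config.indelsnp_max_offset)

    # phase 1: destabilization candidates per chromosome
    destabs: dict[str, list[tuple[int, str, str, str]]] = {}
    for (chrom, pos), site in table.sites.items():
        for key, rec in site.alts.items():
            if strategy == "snp_snp" and rec.vtype != "snp":
                continue
            if strategy == "indel_snp":
                if rec.vtype not in ("ins", "del"):
                    continue
                if not size_lo <= _indel_size(site, key) <= size_hi:
                    continue
            if _fixed_in_all(table, chrom, pos, key, subpanel):
                destabs.setdefault(chrom, []).append(
                    (pos, site.ref, rec.alt, rec.vtype))
    for lst in destabs.values():
        lst.sort()

    out = []
    for (chrom, pos) in sorted(table.sites):
        site = table.sites[(chrom, pos)]
        for key, rec in site.alts.items():
            if rec.vtype != "snp":
                continue
            if not read_count_filter(site, key, "snp", config):
                continue
            keep, _ = presence_absence_filter(table, chrom, pos, key, config)
            if not keep:
                continue
            # phase 3: pair with the nearest qualifying destabilization site
            best = None
            for (dpos, dref, dalt, dtype) in destabs.get(chrom, []):
                if dpos == pos:
                    continue
                span = _edited_span(dpos, dref, dalt, dtype)
                off = _destab_offset(pos, span)
                if off is None or abs(off) > max_offset:
                    continue
                if best is None or abs(off) < abs(best.offset):
                    best = DestabRecord(dtype, dpos, dref, dalt, off)
            if best is None:
                continue
            # phase 4: 24 bp clean window around the marker, destab excepted
            status = flank_safety(
                table, chrom, pos, config.haplosnp_clean_window,
                config.haplosnp_clean_window, allowed_exception=best.pos)
            if status != "BothSafe":
                continue
            # phase 5: accession-level coupling of marker and critical form
            marker_files = site.alts[key].present_files()
            destab_site = table.sites[(chrom, best.pos)]
            destab_key = next(
                k for k, a in destab_site.alts.items() if a.alt == best.alt)
            destab_files = destab_site.alts[destab_key].present_files()
            if not marker_files <= destab_files:
                continue
            up, down = _raw_flanks(reference, chrom, pos)
            up, down = _apply_destab(up, down, pos, best)
            out.append(MarkerCandidate(
                category=("haplosnp_snpsnp" if strategy == "snp_snp"
                          else "haplosnp_indelsnp"),
                chrom=chrom, pos=pos, alleles=(site.ref, rec.alt),
                marker_allele=rec.alt, destab=best,
                flank_up=up, flank_down=down, flank_status=status,
                provenance=("read_count", "presence_absence", "pairing",
                            "clean_window", "coupling"),
                subpanel=config.subpanel,
            ))
    return out


def _discover_snp_in_insertion(table: PanelVariantTable,
                               config: PipelineConfig,
                               reference=None) -> list[MarkerCandidate]:
    """Marker SNPs residing inside 3-6 bp subgenome-specific insertions.

    Against the reference such a site shows two (or more) insertion
    alleles of equal length that differ at a single internal position:
    the insertion itself is the destabilization site (present in every
    member across forms) while one form segregates as the marker.
    """
    size_lo, size_hi = config.insertion_size_range
    subpanel = table.config.subpanel(config.subpanel)
    n_members = len(table._members(subpanel))
    out = []
    for (chrom, pos) in sorted(table.sites):
        site = table.sites[(chrom, pos)]
        ins_keys = [k for k, a in site.alts.items() if a.vtype == "ins"]
        if len(ins_keys) < 2:
            continue
        by_len: dict[int, list[str]] = {}
        for k in ins_keys:
            by_len.setdefault(len(site.alts[k].alt), []).append(k)
        for length, keys in sorted(by_len.items()):
            size = length - len(site.ref)
            if not size_lo <= size <= size_hi or len(keys) < 2:
                continue
            covered = set()
            for k in keys:
                covered |= site.alts[k].present_files() & set(subpanel)
            if len(covered) < n_members:
                continue  # insertion not fixed across the panel
            # the marker form: present >=2, absent >=2, one-base difference
            for k in sorted(keys):
                present = len(site.alts[k].present_files() & set(subpanel))
                absent = n_members - present
                if present < config.min_present or \
                        absent < config.min_absent:
                    continue
                other = next(
                    (o for o in keys if o != k and
                     _hamming1(site.alts[o].alt, site.alts[k].alt)
                     is not None), None)
                if other is None:
                    continue
                j = _hamming1(site.alts[other].alt, site.alts[k].alt)
                status = flank_safety(
                    table, chrom, pos, config.haplosnp_clean_window,
                    config.haplosnp_clean_window, allowed_exception=pos)
                if status != "BothSafe":
                    continue
                marker_alt = site.alts[k].alt
                bg_alt = site.alts[other].alt
                destab = DestabRecord("insertion", pos, site.ref,
                                      marker_alt, 0)
                up, down = _raw_flanks(reference, chrom, pos)
                if up or down:
                    # flanks across the insertional (critical) form
                    inserted = marker_alt[1:]
                    jj = j - 1  # index within the inserted sequence
                    up = up + site.ref + inserted[:jj]
                    down = inserted[jj + 1:] + down
                out.append(MarkerCandidate(
                    category="snp_in_insertion", chrom=chrom, pos=pos,
                    alleles=(bg_alt[j], marker_alt[j]),
                    marker_allele=marker_alt[j], destab=destab,
                    flank_up=up, flank_down=down, flank_status=status,
                    provenance=("insertion_fixed", "presence_absence",
                                "containment", "clean_window"),
                    subpanel=config.subpanel,
                ))
                break
    return out


def _hamming1(a: str, b: str) -> int | None:
    """Index of the single differing position, or None."""
    if len(a) != len(b):
        return None
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return diff[0] if len(diff) == 1 else None


# ---------------------------------------------------------------------------
# diploid-parent and codon-based pipelines


def discover_diploid_parent_snps(diploid_table: PanelVariantTable,
                                 panel_table: PanelVariantTable,
                                 config: PipelineConfig,
                                 reference=None) -> list[MarkerCandidate]:
    """Heterozygous SNPs of the diploid parent with flanks clean against
    the union of the octoploid panel and the diploid's own variants."""
    out = []
    for (chrom, pos) in sorted(diploid_table.sites):
        site = diploid_table.sites[(chrom, pos)]
        if len(site.alts) != 1:
            continue
        (alt_key, alt_rec), = site.alts.items()
        if alt_rec.vtype != "snp":
            continue
        alt_reads = alt_rec.total_reads()
        depth = max(site.depth.values(), default=0)
        ref_reads = depth - alt_reads
        # heterozygous: both alleles read-supported
        if alt_reads < config.min_reads_snp or \
                ref_reads < config.min_reads_snp:
            continue
        if not at_gc_filter(site.ref, alt_rec.alt):
            continue
        if config.exclude_unanchored and chrom in config.unanchored_contigs:
            continue
        status_oct = flank_safety(panel_table, chrom, pos, config.snp_up,
                                  config.snp_down)
        status_dip = flank_safety(diploid_table, chrom, pos, config.snp_up,
                                  config.snp_down)
        if status_oct != "BothSafe" or status_dip != "BothSafe":
            continue
        up, down = _raw_flanks(reference, chrom, pos)
        out.append(MarkerCandidate(
            category="diploid_parent_snp", chrom=chrom, pos=pos,
            alleles=(site.ref, alt_rec.alt), marker_allele=alt_rec.alt,
            flank_up=up, flank_down=down, flank_status="BothSafe",
            provenance=("heterozygous", "read_count", "at_gc",
                        "joint_flank_safety"),
            subpanel=config.subpanel,
        ))
    return out


def _cds_coding_order(gene) -> list[int]:
    """Genome coordinates of CDS bases in coding (5'->3' mRNA) order."""
    coords: list[int] = []
    intervals = gene.cds if gene.strand == "+" else gene.cds[::-1]
    phases = gene.phases if gene.strand == "+" else gene.phases[::-1]
    for a, b in intervals:
        block = list(range(a, b))
        if gene.strand == "-":
            block.reverse()
        coords.extend(block)
    # drop incomplete leading codon bases per the first segment's phase
    skip = phases[0] if phases else 0
    return coords[skip:]


def find_codon_sites(reference, gene_models: GeneModelSet,
                     panel_table: PanelVariantTable,
                     config: PipelineConfig) -> list[MarkerCandidate]:
    """Speculative candidates at third positions of proline codons.

    Proline codons are CCN on the coding strand, 4-fold degenerate at the
    third position, so a probe there can interrogate a polymorphism that
    was never observed in sequencing.  Candidates require BothSafe flanks
    against the panel; the speculative alternate allele is taken as the
    transition partner of the reference base (a transition pair is never
    A/T or G/C, so the A/T-G/C filter passes by construction, but it is
    still applied).
    """
    out = []
    seq_cache: dict[str, str] = {}
    for gene in gene_models.genes:
        if config.exclude_unanchored and \
                gene.chrom in config.unanchored_contigs:
            continue
        coords = _cds_coding_order(gene)
        if gene.chrom not in seq_cache:
            seq_cache[gene.chrom] = str(reference[gene.chrom][:])
        seq = seq_cache[gene.chrom]
        for i in range(0, len(coords) - 2, 3):
            c1, c2, c3 = coords[i], coords[i + 1], coords[i + 2]
            b1, b2 = seq[c1].upper(), seq[c2].upper()
            if gene.strand == "-":
                b1 = {"A": "T", "T": "A", "G": "C", "C": "G"}[b1]
                b2 = {"A": "T", "T": "A", "G": "C", "C": "G"}[b2]
            if b1 != "C" or b2 != "C":
                continue
            pos = c3  # genome coordinate of the codon's third base
            ref_base = seq[pos].upper()
            alt_base = TRANSITION[ref_base]
            if not at_gc_filter(ref_base, alt_base):
                continue
            status = flank_safety(panel_table, gene.chrom, pos,
                                  config.snp_up, config.snp_down)
            if status != "BothSafe":
                continue
            f = extract_flanks(reference, gene.chrom, pos,
                               _RAW_FLANK, _RAW_FLANK)
            out.append(MarkerCandidate(
                category="codon_based", chrom=gene.chrom, pos=pos,
                alleles=(ref_base, alt_base), marker_allele=alt_base,
                flank_up=f.upstream, flank_down=f.downstream,
                flank_status=status,
                provenance=("proline_codon", "at_gc", "flank_safety"),
                subpanel=config.subpanel,
            ))
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


# ---------------------------------------------------------------------------
# spread selection


def spread_selection(candidates: Sequence[MarkerCandidate],
                     chrom_lengths: Mapping[str, int], n_target: int,
                     precedence: Sequence[str] = CATEGORY_PRECEDENCE
                     ) -> list[MarkerCandidate]:
    """Widely spaced subset via greedy max-min spacing per chromosome.

    Coordinate duplicates across categories are removed first, keeping
    the highest-precedence category (ploidy-reducing categories first).
    Ties in the greedy step break toward the lower coordinate, so the
    selection is deterministic.
    """
    rank = {c: i for i, c in enumerate(precedence)}
    dedup: dict[tuple[str, int], MarkerCandidate] = {}
    for cand in candidates:
        key = (cand.chrom, cand.pos)
        old = dedup.get(key)
        if old is None or rank.get(cand.category, 99) < \
                rank.get(old.category, 99):
            dedup[key] = cand
    by_chrom: dict[str, list[MarkerCandidate]] = {}
    for cand in dedup.values():
        by_chrom.setdefault(cand.chrom, []).append(cand)
    for lst in by_chrom.values():
        lst.sort(key=lambda c: c.pos)

    total = sum(len(v) for v in by_chrom.values())
    if n_target >= total:
        return sorted(dedup.values(), key=lambda c: (c.chrom, c.pos))

    # largest-remainder allocation proportional to candidate counts
    chroms = sorted(by_chrom)
    quotas = {c: n_target * len(by_chrom[c]) / total for c in chroms}
    alloc = {c: int(quotas[c]) for c in chroms}
    leftovers = sorted(
        chroms, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in leftovers:
        if sum(alloc.values()) >= n_target:
            break
        if alloc[c] < len(by_chrom[c]):
            alloc[c] += 1

    selected: list[MarkerCandidate] = []
    for chrom in chroms:
        cands = by_chrom[chrom]
        k = min(alloc[chrom], len(cands))
        if k <= 0:
            continue
        chosen = [0]  # start from the lowest coordinate
        while len(chosen) < k:
            best_i, best_d = None, -1
            for i in range(len(cands)):
                if i in chosen:
                    continue
                d = min(abs(cands[i].pos - cands[j].pos) for j in chosen)
                if d > best_d:
                    best_i, best_d = i, d
            chosen.append(best_i)
        selected.extend(cands[i] for i in sorted(chosen))
    return selected


# ---------------------------------------------------------------------------
# candidate serialization


def candidates_to_dataframe(candidates: Sequence[MarkerCandidate]):
    """Tabular form of a candidate list (positions 1-based for export)."""
    import pandas as pd

    rows = []
    for c in candidates:
        d = c.destab
        rows.append({
            "category": c.category, "chrom": c.chrom, "pos": c.pos + 1,
            "alleles": "/".join(c.alleles),
            "marker_allele": c.marker_allele or "",
            "vtype": c.vtype,
            "destab_kind": d.kind if d else "",
            "destab_pos": d.pos + 1 if d else "",
            "destab_critical_form": d.alt if d else "",
            "destab_offset": d.offset if d else "",
            "flank_up": c.flank_up, "flank_down": c.flank_down,
            "flank_status": c.flank_status,
            "provenance": ";".join(c.provenance),
            "subpanel": c.subpanel,
        })
    return pd.DataFrame(rows, columns=[
        "category", "chrom", "pos", "alleles", "marker_allele", "vtype",
        "destab_kind", "destab_pos", "destab_critical_form", "destab_offset",
        "flank_up", "flank_down", "flank_status", "provenance", "subpanel",
    ])


def write_candidates(candidates: Sequence[MarkerCandidate], tsv_path,
                     bed_path=None) -> None:
    """Write candidates as TSV and, optionally, BED for browser inspection."""
    df = candidates_to_dataframe(candidates)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in candidates:
                name = f"{c.category}|{'/'.join(c.alleles)}"
                fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{name}\n")
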