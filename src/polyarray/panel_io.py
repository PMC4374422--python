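"""Reading reference, gene models and per-accession VCFs into a panel table.

All external coordinates (VCF, GFF3) are 1-based; internally everything
is 0-based half-open, with the conversion confined to this module.
Multi-allelic VCF records are decomposed into one (coordinate, alt)
variant each, and each alt is reduced to its minimal representation
(shared leading/trailing reference bases trimmed) so that variant and
site counts are stable across VCF dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)


class VcfFormatError(ValueError):
    pass


@dataclass(frozen=True)
class VariantObservation:
    """One allele observation in one panel file."""

    file_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vtype: str  # snp | ins | del
    count: int  # supporting reads
    depth: int  # total site depth in that file

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VcfFormatError("alleles must be non-empty")
        if self.count > self.depth:
            raise VcfFormatError("supporting count exceeds depth")
        expect = _variant_type(self.ref, self.alt)
        if expect != self.vtype:
            raise VcfFormatError(
                f"type {self.vtype!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {expect!r})"
            )


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "snp"
    return "ins" if len(alt) > len(ref) else "del"


def _normalize(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared trailing then leading bases."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class PanelConfig:
    """Panel membership: file ids, coverages, subpanels.

    Presence/absence is counted per *file* by default (an accession may
    contribute two files); set ``per_accession`` to collapse the files of
    one accession into a single member.
    """

    file_ids: list[str]
    coverages: list[float]
    accessions: list[str] | None = None  # parallel to file_ids
    diploid_id: str | None = None
    hd16_min_coverage: float = 16.0
    hd20_min_coverage: float = 20.0
    per_accession: bool = False

    def __post_init__(self) -> None:
        if len(self.file_ids) != len(self.coverages):
            raise ValueError("one coverage per file required")
        if len(set(self.file_ids)) != len(self.file_ids):
            raise ValueError("file ids must be unique")

    def subpanel(self, name: str) -> list[str]:
        name = name.upper().replace("_", "-")
        if name == "GDP":
            return list(self.file_ids)
        if name == "HD-16":
            cut = self.hd16_min_coverage
        elif name == "HD-20":
            cut = self.hd20_min_coverage
        else:
            raise ValueError(f"unknown subpanel {name!r}")
        return [f for f, c in zip(self.file_ids, self.coverages) if c >= cut]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        meta = yaml.safe_load(Path(path).read_text())
        files = meta["files"]
        return cls(
            file_ids=[f["id"] for f in files],
            coverages=[float(f["coverage"]) for f in files],
            accessions=[f.get("accession", f["id"]) for f in files],
            diploid_id=(meta.get("diploid") or {}).get("id"),
        )


@dataclass
class AltRecord:
    alt: str
    vtype: str
    counts: dict[str, int] = field(default_factory=dict)  # file -> reads

    def total_reads(self) -> int:
        return sum(self.counts.values())

    def present_files(self) -> set[str]:
        return {f for f, c in self.counts.items() if c >= 1}


@dataclass
class SiteRecord:
    chrom: str
    pos: int
    ref: str
    alts: dict[str, AltRecord] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)

    def alleles(self) -> list[str]:
        """Allele inventory: reference plus distinct alts."""
        return [self.ref] + sorted(self.alts)


class PanelVariantTable:
    """Union of variant observations across the discovery panel."""

    def __init__(self, config: PanelConfig):
        self.config = config
        self.sites: dict[tuple[str, int], SiteRecord] = {}
        self._index: dict[str, tuple[np.ndarray, list]] | None = None

    # -- construction -----------------------------------------------------

    def add(self, obs: VariantObservation) -> None:
        if obs.file_id not in self.config.file_ids:
            raise ValueError(f"observation from unknown file {obs.file_id!r}")
        key = (obs.chrom, obs.pos)
        site = self.sites.get(key)
        if site is None:
            site = self.sites[key] = SiteRecord(obs.chrom, obs.pos, obs.ref)
        # alleles at one anchor normally share REF; a longer REF context
        # (e.g. a deletion anchored at a SNP coordinate) keeps its own key
        alt_key = obs.alt if obs.ref == site.ref else f"{obs.ref}>{obs.alt}"
        alt = site.alts.get(alt_key)
        if alt is None:
            alt = site.alts[alt_key] = AltRecord(obs.alt, obs.vtype)
        if obs.file_id in alt.counts:
            raise VcfFormatError(
                f"duplicate observation: {obs.file_id} "
                f"{obs.chrom}:{obs.pos + 1} {obs.alt}"
            )
        alt.counts[obs.file_id] = obs.count
        site.depth[obs.file_id] = max(site.depth.get(obs.file_id, 0),
                                      obs.depth)
        self._index = None

    # -- counting ---------------------------------------------------------

    def _members(self, subpanel: Sequence[str]) -> list[str]:
        if self.config.per_accession and self.config.accessions:
            acc_of = dict(zip(self.config.file_ids, self.config.accessions))
            seen, out = set(), []
            for f in subpanel:
                if acc_of[f] not in seen:
                    seen.add(acc_of[f])
                    out.append(acc_of[f])
            return out
        return list(subpanel)

    def presence_count(self, chrom: str, pos: int, alt: str,
                       subpanel: Sequence[str]) -> int:
        site = self.sites.get((chrom, pos))
        if site is None or alt not in site.alts:
            return 0
        present = site.alts[alt].present_files() & set(subpanel)
        if self.config.per_accession and self.config.accessions:
            acc_of = dict(zip(self.config.file_ids, self.config.accessions))
            return len({acc_of[f] for f in present})
        return len(present)

    def absence_count(self, chrom: str, pos: int, alt: str,
                      subpanel: Sequence[str]) -> int:
        return len(self._members(subpanel)) - self.presence_count(
            chrom, pos, alt, subpanel)

    def n_sites(self) -> int:
        return len(self.sites)

    def n_variants(self) -> int:
        return sum(len(s.alts) for s in self.sites.values())

    # -- window queries ---------------------------------------------------

    def _build_index(self) -> None:
        idx: dict[str, tuple[np.ndarray, list]] = {}
        per_chrom: dict[str, list] = {}
        for (chrom, pos), site in self.sites.items():
            for alt in site.alts.values():
                per_chrom.setdefault(chrom, []).append(
                    (pos, site.ref, alt.alt))
        for chrom, entries in per_chrom.items():
            entries.sort()
            idx[chrom] = (np.array([e[0] for e in entries]), entries)
        self._index = idx

    def variants_in_window(self, chrom: str, lo: int, hi: int
                           ) -> list[tuple[int, str, str]]:
        """All (pos, ref, alt) with lo <= pos <= hi (0-based inclusive)."""
        if self._index is None:
            self._build_index()
        if chrom not in self._index:
            return []
        positions, entries = self._index[chrom]
        i = int(np.searchsorted(positions, lo, side="left"))
        j = int(np.searchsorted(positions, hi, side="right"))
        return entries[i:j]


def load_panel(vcf_paths: Mapping[str, str | Path] | Sequence[str | Path],
               panel_config: PanelConfig) -> PanelVariantTable:
    """Load per-accession VCFs into a unified panel table.

    ``vcf_paths`` maps file id -> path (or is a sequence parallel to
    ``panel_config.file_ids``).  Presence of an allele in a file means at
    least one supporting read there; absence means the file has no record
    for that allele at the coordinate.
    """
    if not isinstance(vcf_paths, Mapping):
        vcf_paths = dict(zip(panel_config.file_ids, vcf_paths))
    table = PanelVariantTable(panel_config)
    n_records = 0
    for file_id, path in vcf_paths.items():
        for obs in _read_vcf(file_id, path):
            table.add(obs)
            n_records += 1
    if n_records == 0:
        logger.warning("panel table is empty: no variant records in %d files",
                       len(vcf_paths))
    return table


def _read_vcf(file_id: str, path: str | Path) -> Iterable[VariantObservation]:
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"{path}: cannot parse VCF: {exc}") from exc
    with vf:
        for rec in vf:
            if not rec.alts:
                continue
            depth = _record_depth(rec)
            counts = _alt_counts(rec)
            for i, alt in enumerate(rec.alts):
                pos, ref, alt_n = _normalize(rec.pos - 1, rec.ref, alt)
                count = counts[i] if i < len(counts) else depth
                try:
                    yield VariantObservation(
                        file_id=file_id, chrom=rec.chrom, pos=pos,
                        ref=ref, alt=alt_n,
                        vtype=_variant_type(ref, alt_n),
                        count=count, depth=max(depth, count),
                    )
                except VcfFormatError as exc:
                    raise VcfFormatError(
                        f"{path} line at {rec.chrom}:{rec.pos}: {exc}"
                    ) from exc


def _record_depth(rec) -> int:
    for sample in rec.samples.values():
        dp = sample.get("DP")
        if dp is not None:
            return int(dp)
    dp = rec.info.get("DP")
    return int(dp) if dp is not None else 0


def _alt_counts(rec) -> list[int]:
    for sample in rec.samples.values():
        ao = sample.get("AO")
        if ao is not None:
            if isinstance(ao, (tuple, list)):
                return [int(a) for a in ao]
            return [int(ao)]
    return [_record_depth(rec)] * len(rec.alts)


def write_panel(table: PanelVariantTable, out_dir: str | Path,
                chrom_lengths: Mapping[str, int]) -> dict[str, Path]:
    """Write the table back to one VCF per panel file (round-trip form)."""
    from .synthetic import _write_vcf  # text writer shared with the simulator

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for file_id in table.config.file_ids:
        records = []
        for (chrom, pos) in sorted(table.sites):
            site = table.sites[(chrom, pos)]
            alts = [a for a in sorted(site.alts)
                    if file_id in site.alts[a].counts]
            if not alts:
                continue
            aos = [site.alts[a].counts[file_id] for a in alts]
            dp = site.depth.get(file_id, sum(aos))
            ro = max(dp - sum(aos), 0)
            records.append((chrom, pos, site.ref, alts,
                            [site.alts[a].vtype for a in alts],
                            ro, aos, ro + sum(aos)))
        path = out_dir / f"{file_id}.vcf"
        _write_vcf(path, file_id, chrom_lengths, records)
        paths[file_id] = path
    return paths


# ---------------------------------------------------------------------------
# reference flanks


@dataclass(frozen=True)
class Flanks:
    upstream: str
    downstream: str
    truncated_up: bool = False
    truncated_down: bool = False


def extract_flanks(reference, chrom: str, pos: int,
                   up_len: int, down_len: int) -> Flanks:
    """Reference flanks around a 0-based coordinate.

    ``reference`` is a pyfaidx.Fasta (or any mapping of chrom -> sequence
    supporting slicing).  Flanks are truncated (and flagged) at contig
    edges.
    """
    if up_len < 0 or down_len < 0:
        raise ValueError("flank lengths must be >= 0")
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise KeyError(f"unknown contig {chrom!r}") from exc
    length = len(seq)
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside contig {chrom}")
    lo = max(pos - up_len, 0)
    hi = min(pos + 1 + down_len, length)
    up = str(seq[lo:pos])
    down = str(seq[pos + 1:hi])
    return Flanks(up.upper(), down.upper(),
                  truncated_up=len(up) < up_len,
                  truncated_down=len(down) < down_len)


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    cds: tuple[tuple[int, int], ...]  # sorted 0-based half-open intervals
    phases: tuple[int, ...]


class GeneModelSet:
    """Gene/CDS intervals with reading frames, loaded from GFF3."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModelSet":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True)
        genes = []
        for g in db.features_of_type("gene"):
            cds = sorted(
                (c.start - 1, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(g, featuretype="CDS")
            )
            genes.append(Gene(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start - 1, end=g.end,
                cds=tuple((a, b) for a, b, _ in cds),
                phases=tuple(p for _, _, p in cds),
            ))
        return cls(genes)

    def in_cds(self, chrom: str, pos: int) -> bool:
        return any(
            a <= pos < b
            for g in self._by_chrom.get(chrom, [])
            for (a, b) in g.cds
        )

    def in_gene(self, chrom: str, pos: int) -> bool:
        return any(
            g.start <= pos < g.end for g in self._by_chrom.get(chrom, [])
        )

    def anchored_chroms(self) -> set[str]:
        return set(self._by_chrom)


# ---------------------------------------------------------------------------
# read-depth summaries


def gene_read_depth_profile(depths: Mapping[str, np.ndarray],
                            gene_models: GeneModelSet,
                            max_bin: int = 150
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean read depth per gene plus a unit-increment histogram.

    The mean is over every nucleotide coordinate in the gene extent.
    Histogram bins run in unit increments from 0 to ``max_bin``; gene
    means beyond the last bin are clipped into it.
    """
    rows = []
    for g in gene_models.genes:
        if g.chrom not in depths:
            raise KeyError(f"no depth track for contig {g.chrom!r}")
        track = depths[g.chrom]
        if g.end > len(track):
            raise ValueError(f"gene {g.gene_id} outside reference bounds")
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom,
            "mean_depth": float(track[g.start:g.end].mean()),
        })
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "mean_depth"])
    hist = np.zeros(max_bin + 1, dtype=int)
    if not df.empty:
        binned = np.clip(df["mean_depth"].to_numpy(), 0, max_bin)
        for b in np.floor(binned).astype(int):
            hist[min(b, max_bin)] += 1
    return df, hist
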