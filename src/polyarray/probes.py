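"""Probe tiling, array-vendor screens, and probe/probeset accounting.

A marker site can be tiled on the forward strand, the reverse strand, or
both.  Per tiled strand, a standard non-A/T-G/C polymorphism needs a
single probe; an A/T or C/G polymorphism needs two allele-specific
probes (which still form one probeset); a multi-allelic SNP is tiled
with four allele-specific probes, one per base, which combine into six
pairwise di-allelic probesets (C(4,2)).  SNP-SNP and indel-SNP haploSNPs
can be tiled on one strand only — the strand facing their destabilization
site.  Every probe is replicated twice on the chip, so features = 2 x
distinct probes.

Probe geometry: a probe is 30 bases of the tiled strand ending
immediately 5' of the interrogated position; allele-specific probes are
31 bases with the allele base at the 3' terminus.  The flank sequences
used already carry the critical destabilization form for haploSNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import is_at_or_gc, revcomp
from .pipelines import MarkerCandidate

PROBE_LEN = 30


@dataclass(frozen=True)
class ProbeSpec:
    candidate_id: str
    strand: str  # forward | reverse
    sequence: str
    allele_specific: bool
    allele: str | None
    probeset_id: str


@dataclass(frozen=True)
class ScreenResult:
    flank_class: str  # recommended | neutral | not_recommended
    kmer_matches: int
    kmer_pass: bool
    external_score: float | None = None
    score_class: str = "unscored"


# ---------------------------------------------------------------------------
# screens


def screen_flanks(candidate: MarkerCandidate, table,
                  strand: str = "forward",
                  allowed_exception: int | None = None) -> str:
    """Classify the tiled-strand flank by nearby panel polymorphisms.

    not_recommended: any polymorphism within 20 bases, or more than two
    within 24 bases; neutral: one or two polymorphisms between 20 and 24
    bases (none closer); recommended: none within 24 bases.
    """
    pos = candidate.pos
    if strand == "forward":
        lo, hi = pos - 24, pos - 1
    else:
        lo, hi = pos + 1, pos + 24
    if allowed_exception is None and candidate.destab is not None:
        allowed_exception = candidate.destab.pos
    near = 0   # within 20 bases
    far = 0    # between 20 and 24 bases
    for (vpos, _r, _a) in table.variants_in_window(candidate.chrom, lo, hi):
        if vpos == pos or vpos == allowed_exception:
            continue
        if abs(vpos - pos) <= 20:
            near += 1
        else:
            far += 1
    if near >= 1 or (near + far) > 2:
        return "not_recommended"
    if far >= 1:
        return "neutral"
    return "recommended"


def kmer_uniqueness(probe: str, reference: Mapping[str, str] | Sequence[str],
                    max_matches: int = 300) -> tuple[int, bool]:
    """Genome-wide 16-mer content of a probe.

    Counts every occurrence (both strands, overlapping) of each of the
    probe's (L-15) 16-mer substrings in the reference and sums them; the
    probe fails when the total exceeds ``max_matches``.
    """
    probe = probe.upper()
    if len(probe) < 16:
        raise ValueError("probe must be at least 16 bases")
    if hasattr(reference, "values"):
        seqs = [str(s[:]).upper() if not isinstance(s, str) else s.upper()
                for s in reference.values()]
    else:
        seqs = [str(s).upper() for s in reference]
    total = 0
    for i in range(len(probe) - 15):
        kmer = probe[i:i + 16]
        rc = revcomp(kmer)
        for seq in seqs:
            total += _count_overlapping(seq, kmer)
            if rc != kmer:
                total += _count_overlapping(seq, rc)
    return total, total <= max_matches


def _count_overlapping(seq: str, sub: str) -> int:
    n, start = 0, seq.find(sub)
    while start != -1:
        n += 1
        start = seq.find(sub, start + 1)
    return n


def classify_score(external_score: float | None) -> str:
    """Classify a vendor in-silico reproducibility score.

    Scores come from an external predictive model (a pluggable input, not
    re-trained here); below 0.4 is not_recommended, 0.4-0.7 neutral,
    above 0.7 recommended; a missing score is 'unscored'.
    """
    if external_score is None:
        return "unscored"
    if not 0.0 <= external_score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    if external_score < 0.4:
        return "not_recommended"
    if external_score > 0.7:
        return "recommended"
    return "neutral"


_STANDARD = ("diallelic_snp", "indel", "diploid_parent_snp", "codon_based")
_PLOIDY_REDUCING = ("msnp", "haplosnp_snpsnp", "haplosnp_indelsnp",
                    "snp_in_insertion")

#: array-fill priority: ploidy-reducing first, then remaining octoploid
#: discovery categories, then diploid-parent, then speculative codon sites
CATEGORY_PRIORITY = _PLOIDY_REDUCING + ("diallelic_snp", "indel",
                                        "diploid_parent_snp", "codon_based")


def eligibility(candidate: MarkerCandidate, screens: ScreenResult) -> bool:
    """Admission rule: standard categories require every screen
    recommended; ploidy-reducing categories (mSNPs, haploSNPs) also admit
    neutral screens.  'unscored' external scores count as neutral."""
    classes = [screens.flank_class]
    if not screens.kmer_pass:
        return False
    score = screens.score_class
    classes.append("neutral" if score == "unscored" else score)
    if "not_recommended" in classes:
        return False
    if candidate.category in _STANDARD:
        return all(c == "recommended" for c in classes)
    return True


# ---------------------------------------------------------------------------
# tiling


def _marker_is_atgc(candidate: MarkerCandidate) -> bool:
    if candidate.category == "msnp" or candidate.vtype != "snp":
        return False
    a, b = candidate.alleles[0], candidate.alleles[1]
    if len(a) == len(b) == 1:
        return is_at_or_gc(a, b)
    return False


def build_tiling(candidate: MarkerCandidate,
                 strands: Sequence[str] = ("forward",),
                 probe_len: int = PROBE_LEN) -> list[ProbeSpec]:
    """Probe specifications for one candidate on the requested strands."""
    single_strand_only = candidate.category in ("haplosnp_snpsnp",
                                                "haplosnp_indelsnp")
    if single_strand_only:
        allowed = ("forward",) if (candidate.destab and
                                   candidate.destab.offset < 0) \
            else ("reverse",)
        for s in strands:
            if s not in allowed:
                raise ValueError(
                    f"{candidate.category} sites can only be tiled on the "
                    f"strand facing their destabilization site ({allowed[0]})"
                )
    probes = []
    cid = f"{candidate.chrom}:{candidate.pos + 1}"
    for strand in strands:
        if strand == "forward":
            context = candidate.flank_up[-probe_len:]
        elif strand == "reverse":
            context = revcomp(candidate.flank_down[:probe_len])
        else:
            raise ValueError(f"unknown strand {strand!r}")
        if candidate.category == "msnp":
            pset_base = f"{cid}:{strand}"
            for base in "ACGT":
                allele = base if strand == "forward" else revcomp(base)
                probes.append(ProbeSpec(
                    cid, strand, context + allele, True, base,
                    probeset_id=pset_base))
        elif _marker_is_atgc(candidate):
            for allele in candidate.alleles[:2]:
                a = allele if strand == "forward" else revcomp(allele)
                probes.append(ProbeSpec(
                    cid, strand, context + a, True, allele,
                    probeset_id=f"{cid}:{strand}"))
        else:
            probes.append(ProbeSpec(
                cid, strand, context, False, None,
                probeset_id=f"{cid}:{strand}"))
    return probes


# ---------------------------------------------------------------------------
# accounting


@dataclass(frozen=True)
class CategoryPlan:
    """Summary tiling plan for one marker category.

    ``n_atgc_single``/``n_atgc_both`` count the sites whose polymorphism
    needs an allele-specific probe pair per strand.  The probeset
    convention is 'per_strand' (a probe pair collapses into one
    probeset), 'pairwise' (mSNPs: six pairwise di-allelic sets over the
    four tiled bases per strand) or 'pair_as_two' (each allele-specific
    pair counts as two probesets — used by the indel-SNP category).
    """

    category: str
    n_sites: int
    n_both_strand: int = 0
    n_atgc_single: int = 0
    n_atgc_both: int = 0
    probeset_convention: str = "per_strand"

    def __post_init__(self) -> None:
        if self.n_both_strand > self.n_sites:
            raise ValueError("both-strand sites exceed total sites")
        if self.n_atgc_single > self.n_sites - self.n_both_strand:
            raise ValueError("A/T-G/C single-strand sites exceed singles")

    @property
    def n_single_strand(self) -> int:
        return self.n_sites - self.n_both_strand

    @property
    def n_tiled_strands(self) -> int:
        return self.n_single_strand + 2 * self.n_both_strand

    @property
    def n_probes(self) -> int:
        if self.probeset_convention == "pairwise":  # mSNP: 4 per strand
            return 4 * self.n_tiled_strands
        plain_single = self.n_single_strand - self.n_atgc_single
        plain_both = self.n_both_strand - self.n_atgc_both
        return (plain_single + 2 * self.n_atgc_single
                + 2 * plain_both + 4 * self.n_atgc_both)

    @property
    def n_probesets(self) -> int:
        if self.probeset_convention == "pairwise":
            return 6 * self.n_tiled_strands
        if self.probeset_convention == "pair_as_two":
            return (self.n_tiled_strands + self.n_atgc_single
                    + 2 * self.n_atgc_both)
        return self.n_tiled_strands

    @property
    def n_features(self) -> int:
        return 2 * self.n_probes  # two replicates of every probe


@dataclass
class DesignSummary:
    per_category: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        keys = ("n_target_sites", "n_probes", "n_probesets", "n_features")
        return {k: sum(c[k] for c in self.per_category.values())
                for k in keys}


def account_design(plans: Sequence[CategoryPlan]) -> DesignSummary:
    """Exact probe/probeset/feature accounting for a set of tiling plans."""
    summary = DesignSummary()
    for plan in plans:
        summary.per_category[plan.category] = {
            "n_target_sites": plan.n_sites,
            "n_sites_single_strand": plan.n_single_strand,
            "n_sites_both_strands": plan.n_both_strand,
            "n_probes": plan.n_probes,
            "n_probesets": plan.n_probesets,
            "n_features": plan.n_features,
        }
    return summary


def summarize_tiling(category: str,
                     tilings: Mapping[str, Sequence[ProbeSpec]]
                     ) -> CategoryPlan:
    """Condense per-candidate probe lists into a CategoryPlan."""
    n_sites = len(tilings)
    n_both = n_atgc_single = n_atgc_both = 0
    convention = "pairwise" if category == "msnp" else "per_strand"
    for specs in tilings.values():
        strands = {s.strand for s in specs}
        both = len(strands) == 2
        n_both += both
        if category != "msnp":
            per_strand = len(specs) // len(strands)
            if per_strand == 2:
                if both:
                    n_atgc_both += 1
                else:
                    n_atgc_single += 1
    return CategoryPlan(category, n_sites, n_both, n_atgc_single,
                        n_atgc_both, probeset_convention=convention)
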