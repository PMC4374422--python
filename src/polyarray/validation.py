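"""Inheritance- and sequence-based genotype validation plus diversity stats.

Genotype symbols are two-character strings over the alleles ``A``, ``B``
and ``0`` (the null allele: a deletion or probe-site mutation that gives
no hybridization signal), e.g. ``AA``, ``AB``, ``A0``, ``00``; missing
calls are ``NoCall``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

_ALLELES = {"A", "B", "0"}
_VALID = {a + b for a in "AB0" for b in "AB0"}


def _alleles_of(genotype: str) -> tuple[str, str]:
    if genotype not in _VALID:
        raise ValueError(f"invalid genotype {genotype!r}")
    return genotype[0], genotype[1]


def _canonical(a: str, b: str) -> str:
    order = {"A": 0, "B": 1, "0": 2}
    return a + b if order[a] <= order[b] else b + a


def possible_progeny(parent1: str, parent2: str) -> set[str]:
    """Genotypes producible by one allele from each parent under disomic
    inheritance; the null allele is transmissible like any other."""
    return {
        _canonical(a, b)
        for a, b in product(_alleles_of(parent1), _alleles_of(parent2))
    }


# ---------------------------------------------------------------------------
# pedigree concordance


@dataclass
class MarkerConcordance:
    marker: str
    n_informative: int
    n_nonconcordant: int
    concordant: bool
    discarded: bool
    discard_reason: str | None
    offending: dict[str, str] = field(default_factory=dict)
    cleaned_calls: dict[str, str] = field(default_factory=dict)


@dataclass
class ConcordanceReport:
    markers: list[MarkerConcordance]

    @property
    def n_discarded(self) -> int:
        return sum(m.discarded for m in self.markers)

    @property
    def n_with_any_nonconcordant(self) -> int:
        return sum(m.n_nonconcordant > 0 for m in self.markers)


def check_concordance(parent1: Mapping[str, str], parent2: Mapping[str, str],
                      progeny: pd.DataFrame,
                      max_nonconcordant_fraction: float = 0.05
                      ) -> ConcordanceReport:
    """Parent-offspring concordance per marker, with the discard rule.

    A progeny call is concordant iff it can be formed from one allele of
    each parent.  Markers with a parental NoCall are discarded outright.
    Markers whose non-concordant fraction exceeds the threshold (default
    5% of informative progeny) are discarded; below or at the threshold
    the offending progeny calls are converted to missing (assumed to be
    individual-sample miscalls rather than a bad marker) and the marker
    is retained.
    """
    if set(parent1) != set(parent2):
        raise ValueError("parents must cover identical marker sets")
    missing = set(parent1) - set(progeny.columns)
    if missing:
        raise ValueError(f"progeny table lacks markers: {sorted(missing)}")
    results = []
    for marker in progeny.columns:
        p1, p2 = parent1[marker], parent2[marker]
        calls = progeny[marker]
        if p1 == "NoCall" or p2 == "NoCall":
            results.append(MarkerConcordance(
                marker, 0, 0, concordant=False, discarded=True,
                discard_reason="parental NoCall"))
            continue
        allowed = possible_progeny(p1, p2)
        informative = calls[calls != "NoCall"]
        bad = {s: g for s, g in informative.items() if g not in allowed}
        n_inf, n_bad = len(informative), len(bad)
        frac = n_bad / n_inf if n_inf else 0.0
        discarded = n_bad > 0 and frac > max_nonconcordant_fraction
        cleaned = {}
        if n_bad and not discarded:
            cleaned = {s: "NoCall" for s in bad}
        results.append(MarkerConcordance(
            marker, n_inf, n_bad,
            concordant=(n_bad == 0), discarded=discarded,
            discard_reason="nonconcordant > threshold" if discarded else None,
            offending=bad, cleaned_calls=cleaned))
    return ConcordanceReport(results)


def concordance_rate(n_flagged: int, n_total: int) -> float:
    """Percentage of markers flagged (or retained) out of those testable."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_flagged / n_total


# ---------------------------------------------------------------------------
# sequence-based validation


@dataclass(frozen=True)
class BinomialTestConfig:
    min_reads: int = 20
    null_minor_freq: float = 1.0 / 8.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.null_minor_freq < 0.5:
            raise ValueError("null minor-allele frequency must be in (0, .5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def binomial_genotype(ref_reads: int, alt_reads: int,
                      config: BinomialTestConfig | None = None
                      ) -> tuple[str, float | None]:
    """Sequence-derived genotype from read counts via a binomial test.

    Null hypothesis: the site is heterozygous in one subgenome of eight
    homoeologous copies, so the minor allele is expected at frequency
    >= 1/8.  The one-sided lower-tail p-value P(X <= k_minor | n, 1/8)
    is evaluated at the least-favourable point of the composite null;
    p < alpha rejects heterozygosity and calls the major-allele
    homozygote.  Fewer than ``min_reads`` total reads gives no call.
    """
    cfg = config or BinomialTestConfig()
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    n = ref_reads + alt_reads
    if n < cfg.min_reads:
        return "no_call", None
    k_minor = min(ref_reads, alt_reads)
    p = float(binom.cdf(k_minor, n, cfg.null_minor_freq))
    return ("hom_major" if p < cfg.alpha else "het"), p


@dataclass
class SeqArrayComparison:
    records: pd.DataFrame  # marker, sample, seq_genotype, array_call, category

    def summary(self) -> dict[str, float | int]:
        cat = self.records["category"]
        comparable = cat[~cat.str.startswith("not_comparable")]
        n = len(comparable)
        n_match = int((comparable == "match").sum())
        return {
            "n_attempted": len(cat),
            "n_comparable": n,
            "n_match": n_match,
            "match_pct": 100.0 * n_match / n if n else float("nan"),
            "het_seq_hom_array": int(
                (comparable == "het_seq_hom_array").sum()),
            "hom_seq_het_array": int(
                (comparable == "hom_seq_het_array").sum()),
            "opposite_homozygotes": int(
                (comparable == "opposite_homozygotes").sum()),
        }


def compare_seq_array(read_counts: pd.DataFrame, array_calls: pd.DataFrame,
                      config: BinomialTestConfig | None = None
                      ) -> SeqArrayComparison:
    """Compare sequence-derived to array-derived genotypes.

    ``read_counts`` columns: marker, sample, ref_reads, alt_reads,
    n_alleles (optional, default 2).  ``array_calls`` columns: marker,
    sample, call.  A comparison is not possible when the array call is
    NoCall (or null), the site has more than two alleles, or read depth
    is insufficient.
    """
    cfg = config or BinomialTestConfig()
    calls = array_calls.set_index(["marker", "sample"])["call"]
    rows = []
    for rec in read_counts.itertuples():
        key = (rec.marker, rec.sample)
        array = calls.get(key, "NoCall")
        n_alleles = getattr(rec, "n_alleles", 2)
        if array == "NoCall" or "0" in array:
            category = "not_comparable(no array call)"
            seq = None
        elif n_alleles > 2:
            category = "not_comparable(more than two alleles)"
            seq = None
        else:
            seq, _p = binomial_genotype(rec.ref_reads, rec.alt_reads, cfg)
            if seq == "no_call":
                category = "not_comparable(insufficient reads)"
            else:
                array_het = array == "AB"
                if seq == "het":
                    category = "match" if array_het else "het_seq_hom_array"
                else:
                    major = "A" if rec.ref_reads >= rec.alt_reads else "B"
                    if array_het:
                        category = "hom_seq_het_array"
                    elif array == major * 2:
                        category = "match"
                    else:
                        category = "opposite_homozygotes"
        rows.append({
            "marker": rec.marker, "sample": rec.sample,
            "seq_genotype": seq, "array_call": array, "category": category,
        })
    return SeqArrayComparison(pd.DataFrame(
        rows, columns=["marker", "sample", "seq_genotype", "array_call",
                       "category"]))


# ---------------------------------------------------------------------------
# diversity statistics


def maf(genotypes: Sequence[str]) -> tuple[float, str]:
    """Minor allele frequency from dosage-collapsed genotype calls.

    Each genotype contributes two allele observations (null alleles count
    as their own allele class when present); NoCalls are skipped.  The
    MAF is the frequency of the rarer allele, 0 for a monomorphic
    marker.  Classes: monomorphic (0), low (< 0.10), polymorphic
    (>= 0.10), highly_polymorphic (>= 0.35).
    """
    counts: dict[str, int] = {}
    for gt in genotypes:
        if gt == "NoCall":
            continue
        for allele in _alleles_of(gt):
            counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no called genotypes")
    if len(counts) <= 1:
        return 0.0, "monomorphic"
    freqs = sorted(c / total for c in counts.values())
    value = min(freqs[0], 0.5)  # frequency of the rarest allele class
    if value == 0.0:
        cls = "monomorphic"
    elif value >= 0.35:
        cls = "highly_polymorphic"
    elif value >= 0.10:
        cls = "polymorphic"
    else:
        cls = "low"
    return value, cls


def largest_gap(positions: Sequence[int], chrom_length: int | None = None,
                include_ends: bool = True) -> int:
    """Largest gap (bp) between adjacent polymorphic marker positions.

    With ``include_ends`` the chromosome boundaries count as gap edges,
    so an empty position list yields the chromosome length.
    """
    pos = sorted(positions)
    if not pos:
        if chrom_length is None:
            raise ValueError("need chrom_length for an empty marker list")
        return chrom_length
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    if include_ends and chrom_length is not None:
        gaps.append(pos[0] - 0)
        gaps.append(chrom_length - pos[-1])
    return max(gaps) if gaps else 0
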