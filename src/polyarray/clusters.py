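"""Two-channel genotype-cluster geometry, calling and quality classes.

The intensity model is linear in allele dosage: each channel equals the
number of hybridizing alleles times a per-allele brightness plus a
background term.  Clusters are delineated in (contrast, size) space,
where contrast = log2(A/B) and size = (log2 A + log2 B)/2 — the standard
MvA-style transform, chosen because it reproduces the qualitative cluster
geometry across effective ploidy levels: a diploid heterozygote and a
tetraploid AABB genotype both sit at contrast 0, while clusters with a
fixed B background are pushed to negative contrast.

The simplified caller here is a 1-D Gaussian mixture on contrast with a
separate low-size (null-allele / off-target) component; it stands in for
a proprietary production clustering algorithm and is documented as the
package's own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

_CALL_LABELS = ("AA", "AB", "BB")


@dataclass(frozen=True)
class ClusterCenterModel:
    """Linear dosage model for cluster centers (arbitrary intensity units)."""

    intensity_per_A_allele: float = 100.0
    intensity_per_B_allele: float = 100.0
    background_intensity: float = 100.0

    def __post_init__(self) -> None:
        if min(self.intensity_per_A_allele, self.intensity_per_B_allele,
               self.background_intensity) <= 0:
            raise ValueError("all model intensities must be positive")

    def center(self, n_a: int, n_b: int) -> tuple[float, float]:
        a = n_a * self.intensity_per_A_allele + self.background_intensity
        b = n_b * self.intensity_per_B_allele + self.background_intensity
        return (a, b)


def center(n_a: int, n_b: int,
           model: ClusterCenterModel | None = None) -> tuple[float, float]:
    """Deterministic (A, B) cluster center for an allele-count pair."""
    return (model or ClusterCenterModel()).center(n_a, n_b)


def contrast_size(a: float, b: float) -> tuple[float, float]:
    """(contrast, size) = (log2(A/B), mean of log2 A and log2 B)."""
    if a <= 0 or b <= 0:
        raise ValueError("channel intensities must be positive")
    la, lb = np.log2(a), np.log2(b)
    return (float(la - lb), float((la + lb) / 2.0))


@dataclass
class QualityThresholds:
    """Tunable thresholds of the quality classifier."""

    call_rate: float = 0.97
    n_minor_hom: int = 3
    variance_ratio: float = 4.0  # flag clusters > this x median variance
    homro_diploid: float = 0.3
    otv_size_offset: float = 0.2  # min size gap isolating a null cluster
    confidence: float = 0.01  # max confidence score (1 - posterior) to call


@dataclass
class SnpQuality:
    marker: str
    snp_class: str  # PHR | NMH | OTV | MHR | CRBT | Other
    call_rate: float
    n_clusters: int
    minor_hom_count: int
    homro: float | None
    ploidy_pattern: str | None  # diploid_like | polyploid_like
    failed_filters: tuple[str, ...] = ()
    filtered_phr: bool = False


# ---------------------------------------------------------------------------
# calling


def _quantile_means(x: np.ndarray, k: int) -> np.ndarray:
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(x, qs)


def _fit_mixture(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k,
        means_init=_quantile_means(x, k).reshape(-1, 1),
        reg_covar=1e-4,
        random_state=seed,
        max_iter=200,
    )
    gm.fit(x.reshape(-1, 1))
    return gm


def _detect_null_cluster(contrast: np.ndarray, size: np.ndarray,
                         min_gap: float) -> np.ndarray:
    """Mask of samples forming a low-size null-allele (off-target) cluster.

    A null-null sample has background-only signal in both channels, so it
    sits below every hybridizing cluster in size *and* near zero
    contrast.  The low-size group is split off at the largest size gap in
    the lower half of the distribution; it only counts as a null cluster
    when that gap exceeds ``min_gap`` and the group is contrast-neutral
    relative to the remaining samples (a genuinely homozygous cluster of
    a high-ploidy locus can also sit low in size, but is pushed to an
    extreme contrast, not to zero).
    """
    n = len(size)
    if n < 4:
        return np.zeros(n, bool)
    order = np.argsort(size)
    sorted_size = size[order]
    half = max(1, n // 2)
    gaps = np.diff(sorted_size[:half + 1])
    if len(gaps) == 0 or gaps.max() < min_gap:
        return np.zeros(n, bool)
    cut = int(gaps.argmax()) + 1
    mask = np.zeros(n, bool)
    mask[order[:cut]] = True
    rest_spread = np.quantile(np.abs(contrast[~mask]), 0.9)
    if np.abs(contrast[mask]).mean() > rest_spread:
        return np.zeros(n, bool)  # extreme-contrast homozygotes, not nulls
    return mask


def call_genotypes(dataset: pd.DataFrame, n_expected_clusters: int = 3,
                   confidence_threshold: float = 0.01, seed: int = 0,
                   detect_otv: bool = True,
                   otv_size_offset: float = 0.2) -> pd.DataFrame:
    """Call genotypes per marker from (contrast, size) values.

    A 1-D Gaussian mixture (at most ``n_expected_clusters`` components,
    chosen by BIC, EM initialized from quantiles for determinism) is fit
    on contrast after setting aside an optional low-size, contrast-neutral
    null-allele cluster whose samples are called homozygous null (``00``);
    ``otv_size_offset`` is the minimum size gap that separates such a
    cluster from the hybridizing ones.  The confidence score of a call is
    one minus the posterior of its assigned component; calls with
    confidence above the threshold become ``NoCall``.

    Returns a copy of ``dataset`` with ``call`` and ``confidence`` columns.
    """
    if dataset.empty:
        raise ValueError("dataset has no samples")
    out = []
    for marker, grp in dataset.groupby("marker", sort=True):
        grp = grp.copy()
        contrast = grp["contrast"].to_numpy(float)
        size = grp["size"].to_numpy(float)
        is_otv = np.zeros(len(grp), bool)
        if detect_otv:
            is_otv = _detect_null_cluster(contrast, size, otv_size_offset)
        x = contrast[~is_otv]
        calls = np.empty(len(grp), dtype=object)
        conf = np.zeros(len(grp))
        calls[is_otv] = "00"

        uniq = np.unique(np.round(x, 9))
        k_max = min(n_expected_clusters, len(uniq))
        if k_max < n_expected_clusters:
            logger.debug("marker %s: only %d distinct contrast values",
                         marker, len(uniq))
        if len(uniq) <= n_expected_clusters:
            # noise-free data: unique contrast values are the clusters
            order = np.argsort(uniq)[::-1]
            labels = {uniq[j]: _CALL_LABELS[i % 3]
                      for i, j in enumerate(order)}
            calls[~is_otv] = [labels[v] for v in np.round(x, 9)]
        else:
            best, best_bic = None, np.inf
            for k in range(1, k_max + 1):
                gm = _fit_mixture(x, k, seed)
                bic = gm.bic(x.reshape(-1, 1))
                if bic < best_bic - 1e-9:
                    best, best_bic = gm, bic
            post = best.predict_proba(x.reshape(-1, 1))
            comp = post.argmax(axis=1)
            order = np.argsort(best.means_.ravel())[::-1]
            label_of = {c: _CALL_LABELS[i % 3] for i, c in enumerate(order)}
            sub_calls = np.array([label_of[c] for c in comp], dtype=object)
            sub_conf = 1.0 - post.max(axis=1)
            nocall = sub_conf > confidence_threshold
            sub_calls[nocall] = "NoCall"
            calls[~is_otv] = sub_calls
            conf[~is_otv] = sub_conf
        grp["call"] = calls
        grp["confidence"] = conf
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# HomRO and quality classification


def homro(centers: Mapping[str, float],
          diploid_threshold: float = 0.3) -> tuple[float, str]:
    """Homozygous Ratio Offset from per-genotype contrast centers.

    The displacement from zero contrast of the homozygous cluster closest
    to it, signed so that homozygous clusters flanking zero give positive
    values and same-side clusters give negative values:
    ``min(contrast_AA, -contrast_BB)`` over the homozygous clusters
    present.  Values >= the threshold classify the locus as clustering
    like a diploid.
    """
    vals = []
    if "AA" in centers:
        vals.append(centers["AA"])
    if "BB" in centers:
        vals.append(-centers["BB"])
    if not vals:
        raise ValueError("need at least one homozygous cluster center")
    value = float(min(vals))
    pattern = "diploid_like" if value >= diploid_threshold \
        else "polyploid_like"
    return value, pattern


def _cluster_stats(grp: pd.DataFrame) -> dict[str, dict[str, float]]:
    stats: dict[str, dict[str, float]] = {}
    for call, sub in grp.groupby("call"):
        if call in ("NoCall",):
            continue
        stats[call] = {
            "n": len(sub),
            "contrast_mean": float(sub["contrast"].mean()),
            "size_mean": float(sub["size"].mean()),
            "contrast_var": float(sub["contrast"].var(ddof=0)),
            "size_var": float(sub["size"].var(ddof=0)),
        }
    return stats


def classify_quality(called: pd.DataFrame,
                     replicate_map: Sequence[tuple[str, str]] = (),
                     thresholds: QualityThresholds | None = None
                     ) -> list[SnpQuality]:
    """Assign each marker one of the six quality classes.

    Decision order: call rate below threshold -> CRBT; one genotype
    cluster -> MHR; an extra low-intensity (null) cluster -> OTV; two
    clusters -> NMH; three clusters -> PHR, then the post-filters
    (replicate reproducibility, cluster variances, minimum minor-homozygote
    count) decide whether the marker survives into the filtered PHR set;
    anything else -> Other.  Every marker lands in exactly one class.
    """
    th = thresholds or QualityThresholds()
    samples = set(called["sample"])
    for a, b in replicate_map:
        if a not in samples or b not in samples:
            raise ValueError(f"replicate pair ({a}, {b}) not in dataset")

    results = []
    for marker, grp in called.groupby("marker", sort=True):
        n = len(grp)
        n_called = int((grp["call"] != "NoCall").sum())
        call_rate = n_called / n if n else 0.0
        stats = _cluster_stats(grp)
        main = {c: s for c, s in stats.items() if c in _CALL_LABELS}
        has_null = "00" in stats
        n_clusters = len(main) + (1 if has_null else 0)

        hom_centers = {c: s["contrast_mean"] for c, s in main.items()
                       if c in ("AA", "BB")}
        h_value, pattern = (None, None)
        if hom_centers:
            h_value, pattern = homro(hom_centers, th.homro_diploid)

        def make(cls, failed=(), filtered=False):
            minor_hom = min(
                (s["n"] for c, s in main.items() if c in ("AA", "BB")),
                default=0,
            )
            return SnpQuality(
                marker=str(marker), snp_class=cls, call_rate=call_rate,
                n_clusters=n_clusters, minor_hom_count=int(minor_hom),
                homro=h_value, ploidy_pattern=pattern,
                failed_filters=tuple(failed), filtered_phr=filtered,
            )

        if call_rate < th.call_rate:
            results.append(make("CRBT"))
            continue
        if len(main) <= 1 and not has_null:
            results.append(make("MHR"))
            continue
        if has_null:
            results.append(make("OTV"))
            continue
        if len(main) == 2:
            results.append(make("NMH"))
            continue
        if len(main) == 3:
            failed = _phr_post_filters(grp, main, replicate_map, th)
            results.append(make("PHR", failed, filtered=not failed))
            continue
        results.append(make("Other"))
    return results


def _phr_post_filters(grp: pd.DataFrame, main: dict,
                      replicate_map: Sequence[tuple[str, str]],
                      th: QualityThresholds) -> list[str]:
    failed = []
    by_sample = grp.set_index("sample")["call"]
    for a, b in replicate_map:
        if a in by_sample.index and b in by_sample.index:
            if by_sample[a] != by_sample[b]:
                failed.append("reproducibility")
                break
    # variance filters: flag any genotype cluster whose spread greatly
    # exceeds the median same-marker cluster spread, per dimension
    for dim, tag in (("size_var", "varY"), ("contrast_var", "varX")):
        med = float(np.median([s[dim] for s in main.values()]))
        if med > 1e-9:  # ignore numerically-zero spreads of exact data
            for c, s in main.items():
                if s[dim] > th.variance_ratio * med:
                    failed.append(f"{c}.{tag}")
    minor_hom = min(s["n"] for c, s in main.items() if c in ("AA", "BB"))
    if minor_hom < th.n_minor_hom:
        failed.append("nMinorHom")
    return failed


# ---------------------------------------------------------------------------
# OTV recalling


def otv_recall(called: pd.DataFrame) -> pd.DataFrame:
    """Recode markers with a null-allele cluster to null-aware genotypes.

    Samples in the low-size cluster are already ``00``; where a null
    allele segregates, homozygote calls become allele+null (``A0``/``B0``)
    because a cluster at homozygous contrast may hide one hybridizing and
    one null copy — a four-cluster AA x BB family is thereby recoded to
    A0 x B0 semantics with progeny classes {A0, AB, B0, 00}.  Markers
    without a null cluster are returned unchanged.
    """
    out = []
    for marker, grp in called.groupby("marker", sort=True):
        grp = grp.copy()
        has_null = (grp["call"] == "00").any()
        all_null = (grp["call"] == "00").all()
        if all_null:
            grp["otv_degenerate"] = True
            out.append(grp)
            continue
        if has_null:
            grp["call"] = grp["call"].replace({"AA": "A0", "BB": "B0"})
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# depth vs clustering


def depth_vs_clustering(marker_depths: Mapping[str, float],
                        ploidy_patterns: Mapping[str, str],
                        bin_width: float = 10.0) -> pd.DataFrame:
    """Join per-marker read depth with cluster ploidy pattern.

    Returns one row per depth bin: the number of markers and the fraction
    classified diploid-like.  On panels with biological deletion blocks,
    di-allelic markers inside the blocks show depressed depth and an
    elevated diploid-like fraction; haploSNPs concentrate their
    diploid-like clustering at full depth instead.
    """
    rows = []
    markers = [m for m in marker_depths if m in ploidy_patterns]
    if not markers:
        return pd.DataFrame(columns=["depth_bin", "n", "frac_diploid_like"])
    depths = np.array([marker_depths[m] for m in markers])
    dip = np.array([ploidy_patterns[m] == "diploid_like" for m in markers])
    bins = np.floor(depths / bin_width).astype(int)
    for b in sorted(set(bins)):
        mask = bins == b
        rows.append({
            "depth_bin": b * bin_width,
            "n": int(mask.sum()),
            "frac_diploid_like": float(dip[mask].mean()),
        })
    return pd.DataFrame(rows, columns=["depth_bin", "n", "frac_diploid_like"])
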