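"""Scoring reconstructed networks against validation sets and enrichment tests.

Covers precision-recall evaluation of predicted links against eQTL- or
pcHi-C-style truth sets (with closest-promoter, maximum-correlation and
random baselines), the odds-ratio enrichment of QTL variants in regulatory
elements with MAF-matched control draws, interval-overlap enrichment with a
hypergeometric test, and Fisher's exact test for gene-set overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, PromoterAnnotation, ActivityMatrix
from .reconstruct import MAX_LINK_DISTANCE, spearman_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationLinkSet:
    """Truth pairs (enhancer_id, gene_id) from an external validation source."""

    pairs: frozenset
    source: str = "synthetic"

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str | None = None) -> "ValidationLinkSet":
        pairs = frozenset(zip(df["enhancer_id"], df["gene_id"]))
        if source is None:
            source = df["source"].iloc[0] if "source" in df.columns and len(df) else "unknown"
        return cls(pairs=pairs, source=source)


@dataclass
class EnrichmentCounts:
    """The a, b, c, d of the ratio-of-ratios odds score OR = (a/b)/(c/d).

    a: query hits in the target regions; b: control hits in the target
    regions; c: query hits in the baseline; d: control hits in the baseline.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")


def enrichment_or(counts: EnrichmentCounts) -> float:
    """OR = (a/b) / (c/d); undefined when b or c is zero."""
    for name in ("b", "c"):
        if getattr(counts, name) == 0:
            raise ZeroDivisionError(f"odds ratio undefined: count {name} is zero")
    if counts.d == 0:
        return 0.0
    return (counts.a / counts.b) / (counts.c / counts.d)


# ---------------------------------------------------------------------------
# precision-recall evaluation
# ---------------------------------------------------------------------------


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise average precision with tied scores grouped into one block.

    AP = sum over descending score blocks of (delta recall) * (precision at
    the end of the block); ties therefore contribute their block-level
    precision regardless of input order, which makes the value deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("undefined recall: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # block boundaries where the score changes
    boundaries = np.flatnonzero(np.diff(s)) + 1
    ends = np.append(boundaries, s.size)
    tp = np.cumsum(y)
    ap = 0.0
    prev_tp = 0
    for end in ends:
        tp_end = int(tp[end - 1])
        if tp_end > prev_tp:
            precision = tp_end / end
            ap += (tp_end - prev_tp) / n_pos * precision
        prev_tp = tp_end
    return float(ap)


def aupr_against(
    predicted: Mapping[tuple[str, str], float],
    truth: ValidationLinkSet | set,
    universe: Sequence[tuple[str, str]],
) -> float:
    """AUPR of scored pairs against a truth set over a restricted universe.

    Universe pairs without a prediction rank last with score 0.  Raises when
    the truth does not intersect the universe (recall undefined).
    """
    if not universe:
        raise ValueError("empty evaluation universe")
    truth_pairs = truth.pairs if isinstance(truth, ValidationLinkSet) else set(truth)
    universe = sorted(set(universe))
    labels = np.array([pair in truth_pairs for pair in universe])
    if not labels.any():
        raise ValueError("undefined recall: no true pair in the universe")
    scores = np.array([float(predicted.get(pair, 0.0)) for pair in universe])
    return average_precision(scores, labels)


def restricted_universe(
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[PromoterAnnotation],
    validated_enhancers: set | None = None,
    max_distance: int = MAX_LINK_DISTANCE,
) -> list[tuple[str, str]]:
    """Candidate pairs within 1 Mb, optionally restricted to enhancers that
    appear in a validation set at least once."""
    pairs = []
    for p in promoters:
        for e in enhancers:
            if validated_enhancers is not None and e.id not in validated_enhancers:
                continue
            if e.chrom == p.chrom and abs(e.midpoint - p.tss) <= max_distance:
                pairs.append((e.id, p.gene_id))
    return pairs


def baseline_links(
    method: str,
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[PromoterAnnotation],
    activity: tuple[ActivityMatrix, ActivityMatrix] | None = None,
    seed: int = 0,
    max_distance: int = MAX_LINK_DISTANCE,
) -> dict[tuple[str, str], float]:
    """One link per enhancer by a naive rule, as comparison baselines.

    ``closest`` links each enhancer to the nearest TSS within 1 Mb (scored by
    1/(1+distance)); ``max_corr`` to the promoter with the highest Spearman
    correlation (scored by (rho+1)/2); ``random`` to a uniformly drawn
    promoter within 1 Mb (seeded; uniform scores).  Enhancers with no
    promoter within 1 Mb are skipped and counted in the log.
    """
    if method not in {"closest", "max_corr", "random"}:
        raise ValueError(f"unknown baseline method {method!r}")
    if method == "max_corr" and activity is None:
        raise ValueError("max_corr baseline requires the activity matrices")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    proms_by_chrom: dict[str, list[PromoterAnnotation]] = {}
    for p in promoters:
        proms_by_chrom.setdefault(p.chrom, []).append(p)

    out: dict[tuple[str, str], float] = {}
    skipped = 0
    for e in sorted(enhancers, key=lambda x: x.id):
        nearby = [
            p for p in proms_by_chrom.get(e.chrom, [])
            if abs(e.midpoint - p.tss) <= max_distance
        ]
        if not nearby:
            skipped += 1
            continue
        nearby.sort(key=lambda p: (abs(e.midpoint - p.tss), p.gene_id))
        if method == "closest":
            target = nearby[0]
            out[(e.id, target.gene_id)] = 1.0 / (1.0 + abs(e.midpoint - target.tss))
        elif method == "random":
            target = nearby[int(rng.integers(len(nearby)))]
            out[(e.id, target.gene_id)] = float(rng.random())
        else:
            enh_act, prom_act = activity
            x = enh_act.row(e.id)
            Y = prom_act.data.loc[[p.gene_id for p in nearby]].to_numpy()
            rhos = spearman_many(x, Y)
            rhos = np.where(np.isfinite(rhos), rhos, -np.inf)
            best = int(np.argmax(rhos))
            out[(e.id, nearby[best].gene_id)] = (float(rhos[best]) + 1.0) / 2.0
    if skipped:
        logger.info("%s baseline: %d enhancers had no promoter within 1 Mb", method, skipped)
    return out


# ---------------------------------------------------------------------------
# interval machinery (numpy sweeps; inputs are modest-sized)
# ---------------------------------------------------------------------------


def _merged_edges(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome flattened edges of the merged interval union."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    edges = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for start, end in spans[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        edges[chrom] = np.array(merged).ravel()
    return edges


def points_in_intervals(
    chroms: Sequence[str], positions: Sequence[int], intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: does each (chrom, pos) fall inside the interval union?"""
    edges = _merged_edges(intervals)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    hit = np.zeros(len(positions), dtype=bool)
    for chrom, e in edges.items():
        mask = chroms == chrom
        if mask.any():
            hit[mask] = np.searchsorted(e, positions[mask], side="right") % 2 == 1
    return hit


def intervals_overlap_any(
    query: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask over ``query``: >= 1 bp overlap with any target interval."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        grouped.setdefault(t.chrom, []).append((t.start, t.end))
    for chrom, spans in grouped.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        ends = np.maximum.accumulate(np.array([e for _, e in spans]))
        by_chrom[chrom] = (starts, ends)
    out = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        if q.chrom not in by_chrom:
            continue
        starts, prefix_max_end = by_chrom[q.chrom]
        idx = np.searchsorted(starts, q.end, side="left")
        out[i] = idx > 0 and prefix_max_end[idx - 1] > q.start
    return out


# ---------------------------------------------------------------------------
# QTL and overlap enrichment
# ---------------------------------------------------------------------------


def qtl_enrichment(
    variants: pd.DataFrame,
    cre_regions: Sequence[GenomicInterval],
    baseline_regions: Sequence[GenomicInterval],
    control_pool: pd.DataFrame,
    n_repeats: int = 30,
    n_maf_bins: int = 50,
    seed: int = 0,
    pp_threshold: float | None = None,
) -> tuple[float, float]:
    """Enrichment OR of QTL variants in regulatory elements vs baseline regions.

    For each of ``n_repeats`` repeats a control set with the same size and
    MAF distribution as the real variants is drawn from ``control_pool``
    (matching on ``n_maf_bins`` equal-width bins over (0, 0.5]), the
    OR = (a/b)/(c/d) is computed, and the mean and standard deviation over
    the repeats are returned.  ``pp_threshold`` optionally keeps only
    fine-mapped variants with posterior probability above the threshold
    (requires a ``pp`` column).
    """
    if len(cre_regions) == 0 or len(baseline_regions) == 0:
        raise ValueError("region sets must be non-empty")
    if pp_threshold is not None:
        if "pp" not in variants.columns:
            raise ValueError("pp_threshold given but variants lack a 'pp' column")
        variants = variants.loc[variants["pp"] > pp_threshold]
    if variants.empty:
        raise ValueError("no variants to test")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    bins = np.linspace(0.0, 0.5, n_maf_bins + 1)
    real_bin = np.clip(np.digitize(variants["maf"].to_numpy(), bins) - 1, 0, n_maf_bins - 1)
    pool_bin = np.clip(np.digitize(control_pool["maf"].to_numpy(), bins) - 1, 0, n_maf_bins - 1)

    a = int(points_in_intervals(variants["chrom"], variants["pos"], cre_regions).sum())
    c = int(points_in_intervals(variants["chrom"], variants["pos"], baseline_regions).sum())
    if c == 0:
        raise ZeroDivisionError("no real variants in the baseline regions (count c is zero)")

    pool_in_cre = points_in_intervals(control_pool["chrom"], control_pool["pos"], cre_regions)
    pool_in_base = points_in_intervals(
        control_pool["chrom"], control_pool["pos"], baseline_regions
    )
    pool_by_bin = {b: np.flatnonzero(pool_bin == b) for b in np.unique(pool_bin)}

    need = {b: int(n) for b, n in zip(*np.unique(real_bin, return_counts=True))}
    missing = [b for b in need if b not in pool_by_bin]
    if missing:
        raise ValueError(
            "MAF bins with real variants but no candidate controls: "
            + ", ".join(f"({bins[b]:.3f}, {bins[b + 1]:.3f}]" for b in missing)
        )

    ors = []
    for _ in range(n_repeats):
        chosen = []
        for b, n in sorted(need.items()):
            pool_idx = pool_by_bin[b]
            chosen.append(rng.choice(pool_idx, size=n, replace=pool_idx.size < n))
        idx = np.concatenate(chosen)
        b_count = int(pool_in_cre[idx].sum())
        d_count = int(pool_in_base[idx].sum())
        if b_count == 0:
            raise ZeroDivisionError("control draw has zero variants in the CREs (count b)")
        ors.append(enrichment_or(EnrichmentCounts(a, b_count, c, d_count)))
    ors = np.asarray(ors)
    return float(ors.mean()), float(ors.std(ddof=1))


def overlap_enrichment(
    query: Sequence[GenomicInterval],
    active: Sequence[GenomicInterval],
    query_background: Sequence[GenomicInterval],
    active_background: Sequence[GenomicInterval],
) -> tuple[float, float]:
    """Enrichment of a query interval set in an 'active' interval set.

    The population is the query background annotated by whether each
    interval hits the active set; the query is the draw; the overlap count
    is the number of successes.  Returns the ratio-of-ratios OR
    (|query hits| / |query background|) / (|active| / |active background|)
    and the upper-tail hypergeometric p-value.
    """
    if not query_background or not active_background:
        raise ValueError("background sets must be non-empty")
    N = len(query_background)
    K = int(intervals_overlap_any(query_background, active).sum())
    n = len(query)
    k = int(intervals_overlap_any(query, active).sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    or_value = (k / N) / (len(active) / len(active_background))
    return or_value, p


def overlap_fisher(
    set_a: set, set_b: set, universe: set
) -> tuple[float, float]:
    """Fisher's exact test (two-sided) for the overlap of two gene sets."""
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("gene sets must be subsets of the universe")
    n11 = len(set_a & set_b)
    n12 = len(set_a - set_b)
    n21 = len(set_b - set_a)
    n22 = len(set(universe)) - n11 - n12 - n21
    table = [[n11, n12], [n21, n22]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
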