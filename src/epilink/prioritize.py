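"""EPI-informed gene prioritization from GWAS summary statistics.

SNPs are assigned to genes either proximally (gene body plus 2 kb flanks)
or distally through enhancers linked to the gene in a state's reconstructed
network.  Per-gene p-values combine the assigned SNPs' GWAS p-values with
Fisher's method (SNPs treated as independent -- appropriate for the
synthetic generator, a documented limitation for LD-structured real data),
are adjusted per state with Benjamini-Hochberg, and the significant genes
are finally filtered for being relatively highly expressed in the state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ActivityMatrix, GenomicInterval, PromoterAnnotation, SampleTable
from .reconstruct import StateNetwork
from .evaluate import overlap_fisher

GENE_FLANK = 2000  # bp either side of the gene body for proximal assignment


@dataclass
class GeneResult:
    """Per-state gene-level association statistics."""

    gene_id: str
    state: str
    n_snps_proximal: int
    n_snps_distal: int
    gene_p: float
    fdr_q: float = float("nan")
    expressed_pass: bool = False

    @property
    def significant(self) -> bool:
        return self.fdr_q < 0.05


def assign_snps_to_genes(
    variants: pd.DataFrame,
    promoters: Sequence[PromoterAnnotation],
    enhancers: Sequence[GenomicInterval],
    network: StateNetwork,
    flank: int = GENE_FLANK,
) -> dict[str, dict[str, set]]:
    """Map each gene to its proximal and distal (EPI-routed) SNP sets.

    A SNP is proximal to a gene when its position falls in
    ``[gene_start - flank, gene_end + flank)``; it is distal when it falls
    inside an enhancer that has an edge to the gene in this state's network
    (binary edge presence; the ABC weight is not used for routing).  A SNP
    may map to several genes.
    """
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy(dtype=int)
    snp_ids = variants["snp_id"].to_numpy()

    out: dict[str, dict[str, set]] = {}
    for p in promoters:
        if p.gene_start is None or p.gene_end is None:
            raise ValueError(f"gene {p.gene_id} lacks gene body coordinates")
        lo, hi = p.gene_start - flank, p.gene_end + flank
        mask = (chroms == p.chrom) & (pos >= lo) & (pos < hi)
        if mask.any():
            out.setdefault(p.gene_id, {"proximal": set(), "distal": set()})[
                "proximal"
            ].update(snp_ids[mask])

    targets_of_enh: dict[str, set[str]] = {}
    for (eid, gid) in network.edges:
        targets_of_enh.setdefault(eid, set()).add(gid)
    for e in enhancers:
        genes = targets_of_enh.get(e.id)
        if not genes:
            continue
        mask = (chroms == e.chrom) & (pos >= e.start) & (pos < e.end)
        if mask.any():
            hit = set(snp_ids[mask])
            for gid in genes:
                out.setdefault(gid, {"proximal": set(), "distal": set()})[
                    "distal"
                ].update(hit)
    return out


def gene_pvalue(snp_p: Sequence[float]) -> float:
    """Fisher's combination of a gene's SNP p-values.

    X = -2 sum(ln p) ~ chi-square with 2k degrees of freedom under the null
    of independent uniform p-values; with a single SNP this is the identity.
    """
    p = np.asarray(list(snp_p), dtype=float)
    if p.size == 0:
        raise ValueError("gene_pvalue requires >= 1 SNP p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def significant_genes(
    gene_p: Mapping[str, float], state: str, alpha: float = 0.05,
    snp_counts: Mapping[str, tuple[int, int]] | None = None,
) -> list[GeneResult]:
    """Benjamini-Hochberg adjustment within a state; significant iff q < alpha."""
    if not gene_p:
        raise ValueError("no genes to adjust")
    genes = sorted(gene_p)
    p = np.array([gene_p[g] for g in genes])
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    results = []
    for g, pv, qv in zip(genes, p, q):
        n_prox, n_dist = (snp_counts or {}).get(g, (0, 0))
        results.append(
            GeneResult(gene_id=g, state=state, n_snps_proximal=n_prox,
                       n_snps_distal=n_dist, gene_p=float(pv), fdr_q=float(qv))
        )
    return results


def highly_expressed_genes(
    prom_activity: ActivityMatrix,
    sample_table: SampleTable,
    state: str,
    tpm_threshold: float = 1.0,
    percentile: float = 50.0,
) -> set[str]:
    """Relatively highly expressed genes of a state.

    Per sample a gene qualifies iff its TPM exceeds ``tpm_threshold`` AND
    strictly exceeds the ``percentile`` (default: median) of all *other*
    genes' TPM in that sample; the per-sample sets of the state's replicates
    are union-aggregated.
    """
    samples = sample_table.samples_of(state)  # raises if state unknown
    missing = [s for s in samples if s not in prom_activity.data.columns]
    if missing:
        raise ValueError(f"state {state!r}: samples missing from activity matrix: {missing}")
    qualified: set[str] = set()
    values = prom_activity.data[samples]
    for s in samples:
        col = values[s].to_numpy()
        n = col.size
        for gi, gene in enumerate(prom_activity.element_ids):
            tpm = col[gi]
            if tpm <= tpm_threshold:
                continue
            others = np.delete(col, gi) if n > 1 else np.array([])
            cut = np.percentile(others, percentile) if others.size else -np.inf
            if tpm > cut:
                qualified.add(gene)
    return qualified


def expression_filter(
    candidates: Sequence[str],
    prom_activity: ActivityMatrix,
    sample_table: SampleTable,
    state: str,
    tpm_threshold: float = 1.0,
    percentile: float = 50.0,
) -> set[str]:
    """Candidate genes that are relatively highly expressed in the state."""
    qualified = highly_expressed_genes(
        prom_activity, sample_table, state, tpm_threshold, percentile
    )
    return set(candidates) & qualified


def prioritize_state(
    variants: pd.DataFrame,
    promoters: Sequence[PromoterAnnotation],
    enhancers: Sequence[GenomicInterval],
    network: StateNetwork,
    prom_activity: ActivityMatrix,
    sample_table: SampleTable,
    state: str,
    alpha: float = 0.05,
    flank: int = GENE_FLANK,
) -> list[GeneResult]:
    """Full prioritization for one state: assignment, combination, BH, filter."""
    assigned = assign_snps_to_genes(variants, promoters, enhancers, network, flank=flank)
    if not assigned:
        return []
    p_of_snp = dict(zip(variants["snp_id"], variants["p"]))
    gene_p: dict[str, float] = {}
    snp_counts: dict[str, tuple[int, int]] = {}
    for gene, sets in assigned.items():
        snps = sets["proximal"] | sets["distal"]
        if not snps:
            continue  # genes with no assigned SNPs are omitted, not p = 1
        gene_p[gene] = gene_pvalue([p_of_snp[s] for s in sorted(snps)])
        snp_counts[gene] = (len(sets["proximal"]), len(sets["distal"]))
    results = significant_genes(gene_p, state, alpha=alpha, snp_counts=snp_counts)
    passing = expression_filter(
        [r.gene_id for r in results], prom_activity, sample_table, state
    )
    for r in results:
        r.expressed_pass = r.gene_id in passing
    return results


def results_to_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "state": r.state,
                "n_snps_proximal": r.n_snps_proximal,
                "n_snps_distal": r.n_snps_distal,
                "gene_p": r.gene_p,
                "fdr_q": r.fdr_q,
                "expressed_pass": r.expressed_pass,
            }
            for r in results
        ],
        columns=["gene_id", "state", "n_snps_proximal", "n_snps_distal",
                 "gene_p", "fdr_q", "expressed_pass"],
    )


def shared_genes(
    gene_sets: Mapping[str, set],
    categories: Mapping[str, str],
    universe: set,
) -> tuple[dict[str, set], pd.DataFrame]:
    """Genes shared by >= 2 traits within each category, and cross-category
    overlap (odds ratio + Fisher's exact p) of those shared sets."""
    by_category: dict[str, list[str]] = {}
    for trait, cat in categories.items():
        by_category.setdefault(cat, []).append(trait)

    shared: dict[str, set] = {}
    for cat, traits in sorted(by_category.items()):
        counts: dict[str, int] = {}
        for t in traits:
            for g in gene_sets.get(t, set()):
                counts[g] = counts.get(g, 0) + 1
        shared[cat] = {g for g, n in counts.items() if n >= 2}

    rows = []
    cats = sorted(shared)
    for i, ca in enumerate(cats):
        for cb in cats[i + 1:]:
            if shared[ca] or shared[cb]:
                odds, p = overlap_fisher(shared[ca], shared[cb], universe)
            else:
                odds, p = float("nan"), float("nan")
            rows.append({
                "category_a": ca, "category_b": cb,
                "n_shared_a": len(shared[ca]), "n_shared_b": len(shared[cb]),
                "n_overlap": len(shared[ca] & shared[cb]),
                "odds_ratio": odds, "p": p,
            })
    return shared, pd.DataFrame(
        rows, columns=["category_a", "category_b", "n_shared_a", "n_shared_b",
                       "n_overlap", "odds_ratio", "p"],
    )
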