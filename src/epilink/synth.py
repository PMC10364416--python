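"""Synthetic CAGE datasets with planted enhancer-promoter regulation.

The generator emulates the statistical structure the reconstruction pipeline
assumes: replicate samples grouped into cell/tissue states, elements active in
only a small fraction of states (high activity specificity), planted
enhancer->promoter links with positive activity coupling, noisy validation
link sets, and GWAS p-values inflated for SNPs falling inside causal genes'
bodies or their planted enhancers.

Everything is driven by a single integer seed through derived
``numpy.random.SeedSequence`` streams, so one number reproduces the full
fixture byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import (
    ActivityMatrix,
    GenomicInterval,
    PromoterAnnotation,
    SampleTable,
    write_activity,
    write_enhancers,
    write_promoters,
    write_sample_table,
)

MAX_LINK_DISTANCE = 1_000_000  # candidate window, bp

_LIFE_STAGES = ("fetal", "newborn", "adult", "other")


@dataclass
class SynthConfig:
    """Parameters of the simulated world.

    Defaults describe a small genome dense enough that every promoter has a
    realistic number (~100) of candidate enhancers within 1 Mb, element usage
    restricted to a minority of states (per-state mean activity is highly
    specific; at ``usage_specificity`` <= 0.2 the Gini index exceeds 0.8),
    active elements log-normal around a median of 5 TPM (so the >1 TPM usage
    rule is meaningful), and additive Gaussian noise on promoter activity
    sized to give planted pairs a Spearman correlation of about 0.7 across
    samples.
    """

    n_chrom: int = 4
    chrom_length: int = 10_000_000
    n_enh: int = 1000
    n_prom: int = 200
    n_states: int = 10
    replicates_per_state: int = 2
    links_per_promoter: tuple[int, int] = (2, 4)
    noise_sd: float = 6.0
    enh_obs_sigma: float = 0.5  # log-scale measurement noise on observed eRNA TPM
    active_median_tpm: float = 5.0
    active_sigma: float = 0.8
    inactive_max_tpm: float = 0.05
    beta_range: tuple[float, float] = (0.5, 1.5)
    usage_specificity: float = 0.4
    enhancer_width: int = 400
    link_distance_scale: float = 240_000.0  # bp; ~34% of links within 100 kb
    domain_size: int = 500_000  # bp; chromatin neighborhood sharing activity
    domain_coupling: float = 0.2  # prob. an element adopts its domain's states
    enhancer_sharing: float = 0.6  # prob. a link reuses a co-patterned enhancer
    coregulation: float = 0.4  # prob. a promoter shares its neighbor's states
    coreg_max_distance: int = 200_000  # bp; reach of promoter co-regulation
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chrom", "chrom_length", "n_enh", "n_prom", "n_states",
                     "replicates_per_state"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.usage_specificity <= 1):
            raise ValueError("usage_specificity must be in (0, 1]")
        lo, hi = self.links_per_promoter
        if lo < 0 or hi < lo:
            raise ValueError("links_per_promoter must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.enhancer_sharing <= 1):
            raise ValueError("enhancer_sharing must be in [0, 1]")
        if not (0 <= self.coregulation <= 1):
            raise ValueError("coregulation must be in [0, 1]")
        if not (0 <= self.domain_coupling <= 1):
            raise ValueError("domain_coupling must be in [0, 1]")
        if self.domain_size < 1:
            raise ValueError("domain_size must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset, used as the test oracle."""

    planted_links: list[tuple[str, str, float]]  # (enhancer_id, gene_id, beta_true)
    state_of_activity: dict[str, list[str]]  # element -> states where active
    causal_genes: dict[str, list[str]] = field(default_factory=dict)  # trait -> genes
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def link_pairs(self) -> set[tuple[str, str]]:
        return {(e, g) for e, g, _ in self.planted_links}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as handle:
            raw = json.load(handle)
        raw["planted_links"] = [tuple(x) for x in raw["planted_links"]]
        return cls(**raw)


@dataclass
class SimulatedDataset:
    """Bundle of everything :func:`simulate_dataset` produces."""

    enhancers: list[GenomicInterval]
    promoters: list[PromoterAnnotation]
    enh_activity: ActivityMatrix
    prom_activity: ActivityMatrix
    samples: SampleTable
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_enhancers(self.enhancers, outdir / "enhancers.bed")
        write_promoters(self.promoters, outdir / "promoters.tsv")
        write_activity(self.enh_activity, outdir / "enh_activity.tsv")
        write_activity(self.prom_activity, outdir / "prom_activity.tsv")
        write_sample_table(self.samples, outdir / "samples.tsv")
        self.truth.to_json(outdir / "truth.json")


def _draw_active_states(
    n_elements: int, n_states: int, specificity: float, rng: np.random.Generator
) -> np.ndarray:
    """Each element is active in exactly round(specificity * n_states) states
    (at least one), drawn uniformly without replacement."""
    k = max(1, round(specificity * n_states))
    active = np.zeros((n_elements, n_states), dtype=bool)
    for i in range(n_elements):
        active[i, rng.choice(n_states, size=k, replace=False)] = True
    return active


def simulate_dataset(config: SynthConfig) -> SimulatedDataset:
    """Simulate a state-structured CAGE activity dataset with planted links.

    Each element is active in a random ~``usage_specificity`` fraction of
    states.  A promoter with planted links takes, in its active states,
    activity = sum(beta_true * enhancer activity) + Gaussian noise (floored
    at 0); its planted enhancers are co-active in exactly its active states.
    A promoter with no planted links gets its own log-normal baseline in its
    active states.  Inactive elements receive sub-threshold activity
    (< 1 TPM) so the usage rule separates the two regimes.
    """
    ss = np.random.SeedSequence(config.seed)
    (geom_ss, state_ss, link_ss, act_ss, noise_ss) = ss.spawn(5)
    rng_geom = np.random.default_rng(geom_ss)
    rng_state = np.random.default_rng(state_ss)
    rng_link = np.random.default_rng(link_ss)
    rng_act = np.random.default_rng(act_ss)
    rng_noise = np.random.default_rng(noise_ss)

    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    # --- geometry ---------------------------------------------------------
    enh_chrom = rng_geom.integers(0, config.n_chrom, size=config.n_enh)
    enh_start = rng_geom.integers(0, config.chrom_length - config.enhancer_width,
                                  size=config.n_enh)
    order = np.lexsort((enh_start, enh_chrom))
    width = int(np.ceil(np.log10(config.n_enh + 1)))
    enhancers = [
        GenomicInterval(chroms[enh_chrom[i]], int(enh_start[i]),
                        int(enh_start[i]) + config.enhancer_width,
                        f"E{rank:0{width}d}")
        for rank, i in enumerate(order, start=1)
    ]

    prom_chrom = rng_geom.integers(0, config.n_chrom, size=config.n_prom)
    prom_tss = rng_geom.integers(1000, config.chrom_length - 60_000, size=config.n_prom)
    body_len = rng_geom.integers(5_000, 50_000, size=config.n_prom)
    strands = rng_geom.choice(["+", "-"], size=config.n_prom)
    porder = np.lexsort((prom_tss, prom_chrom))
    pwidth = int(np.ceil(np.log10(config.n_prom + 1)))
    promoters = []
    for rank, i in enumerate(porder, start=1):
        tss = int(prom_tss[i])
        if strands[i] == "+":
            body = (tss, min(tss + int(body_len[i]), config.chrom_length))
        else:
            body = (max(tss - int(body_len[i]), 0), tss + 1)
        promoters.append(
            PromoterAnnotation(
                gene_id=f"G{rank:0{pwidth}d}", chrom=chroms[prom_chrom[i]],
                tss=tss, strand=str(strands[i]),
                gene_start=body[0], gene_end=body[1],
            )
        )

    # --- samples ----------------------------------------------------------
    states = [f"state{i + 1:02d}" for i in range(config.n_states)]
    n_groups = max(1, config.n_states // 3)
    rows = []
    for i, state in enumerate(states):
        for r in range(config.replicates_per_state):
            rows.append({
                "sample_id": f"{state}_r{r + 1}",
                "state": state,
                "group": f"group{(i % n_groups) + 1}",
                "life_stage": _LIFE_STAGES[i % len(_LIFE_STAGES)],
            })
    samples = SampleTable(pd.DataFrame(rows))
    sample_state_idx = np.repeat(np.arange(config.n_states), config.replicates_per_state)
    m = len(rows)

    # --- state activity patterns -----------------------------------------
    enh_active = _draw_active_states(
        config.n_enh, config.n_states, config.usage_specificity, rng_state
    )
    prom_active = _draw_active_states(
        config.n_prom, config.n_states, config.usage_specificity, rng_state
    )
    if config.domain_coupling > 0:
        # elements in the same chromatin neighborhood tend to share their
        # activity pattern, so simple pairwise correlation picks up
        # hitchhiking neighbors of the truly linked enhancers
        n_domains = -(-config.chrom_length // config.domain_size)
        domain_active = _draw_active_states(
            config.n_chrom * n_domains, config.n_states,
            config.usage_specificity, rng_state,
        )

        def _domain_row(chrom_idx: int, pos: int) -> int:
            return chrom_idx * n_domains + pos // config.domain_size

        chrom_rank = {c: i for i, c in enumerate(chroms)}
        for i, e in enumerate(enhancers):
            if rng_state.random() < config.domain_coupling:
                enh_active[i] = domain_active[_domain_row(chrom_rank[e.chrom], e.midpoint)]
        for i, p in enumerate(promoters):
            if rng_state.random() < config.domain_coupling:
                prom_active[i] = domain_active[_domain_row(chrom_rank[p.chrom], p.tss)]
    if config.coregulation > 0:
        # neighbouring genes frequently sit in co-regulated clusters with a
        # common activity pattern (and, below, shared enhancers)
        for i in range(1, config.n_prom):
            prev, cur = promoters[i - 1], promoters[i]
            if (
                prev.chrom == cur.chrom
                and cur.tss - prev.tss <= config.coreg_max_distance
                and rng_state.random() < config.coregulation
            ):
                prom_active[i] = prom_active[i - 1]

    enh_ids = [e.id for e in enhancers]
    prom_ids = [p.gene_id for p in promoters]
    enh_index = {eid: i for i, eid in enumerate(enh_ids)}

    # --- planted links ----------------------------------------------------
    lo, hi = config.links_per_promoter
    enh_mid = np.array([e.midpoint for e in enhancers])
    enh_chrom_by_id = np.array([e.chrom for e in enhancers])
    planted: list[tuple[str, str, float]] = []
    planted_states: dict[int, np.ndarray] = {}
    for pi, prom in enumerate(promoters):
        if hi == 0:
            continue
        cis = np.flatnonzero(
            (enh_chrom_by_id == prom.chrom)
            & (np.abs(enh_mid - prom.tss) <= MAX_LINK_DISTANCE)
        )
        k = int(rng_link.integers(lo, hi + 1))
        if k == 0:
            continue
        if k > cis.size:
            raise ValueError(
                f"infeasible geometry: promoter {prom.gene_id} has only "
                f"{cis.size} candidate enhancers within 1 Mb but {k} links requested"
            )
        # nearer enhancers are preferred with an exponential distance decay,
        # mirroring the short-range bias of real enhancer-promoter links
        def _pick(pool: np.ndarray, size: int) -> np.ndarray:
            w = np.exp(-np.abs(enh_mid[pool] - prom.tss) / config.link_distance_scale)
            return rng_link.choice(pool, size=size, replace=False, p=w / w.sum())

        # real enhancers often regulate several co-expressed genes: with
        # probability ``enhancer_sharing`` a link slot reuses an enhancer
        # already serving a promoter with the identical activity pattern
        # (so sharing does not dilute the planted coupling); otherwise an
        # unused enhancer is planted
        shareable = np.array([
            ei for ei in cis
            if ei in planted_states and np.array_equal(planted_states[ei], prom_active[pi])
        ])
        fresh = np.array([ei for ei in cis if ei not in planted_states])
        chosen_list: list[int] = []
        for _ in range(k):
            pool_s = np.array([ei for ei in shareable if ei not in chosen_list])
            pool_f = np.array([ei for ei in fresh if ei not in chosen_list])
            use_shared = (
                pool_s.size > 0
                and rng_link.random() < config.enhancer_sharing
            ) or pool_f.size == 0
            pool = pool_s if use_shared and pool_s.size else pool_f
            if pool.size == 0:
                pool = np.array([ei for ei in cis if ei not in chosen_list])
            chosen_list.append(int(_pick(pool, 1)[0]))
        chosen = np.array(chosen_list)
        for ei in chosen:
            beta = float(rng_link.uniform(*config.beta_range))
            planted.append((enh_ids[ei], prom.gene_id, beta))
            # a planted enhancer is co-active exactly in its target
            # promoter's states (union over targets when reused)
            if ei in planted_states:
                planted_states[ei] = planted_states[ei] | prom_active[pi]
            else:
                planted_states[ei] = prom_active[pi].copy()
    for ei, pattern in planted_states.items():
        enh_active[ei] = pattern

    # --- activities -------------------------------------------------------
    mu = np.log(config.active_median_tpm)
    enh_act_sample = enh_active[:, sample_state_idx]  # n_enh x m
    # latent eRNA output drives the target promoter; the observed enhancer
    # TPM additionally carries multiplicative measurement noise (eRNA
    # quantification from CAGE is shallow and noisy)
    enh_latent = np.where(
        enh_act_sample,
        rng_act.lognormal(mu, config.active_sigma, size=(config.n_enh, m)),
        rng_act.uniform(0, config.inactive_max_tpm, size=(config.n_enh, m)),
    )
    if config.enh_obs_sigma > 0:
        enh_vals = enh_latent * rng_act.lognormal(
            0.0, config.enh_obs_sigma, size=(config.n_enh, m)
        )
    else:
        enh_vals = enh_latent

    links_of_prom: dict[str, list[tuple[int, float]]] = {p: [] for p in prom_ids}
    for eid, gid, beta in planted:
        links_of_prom[gid].append((enh_index[eid], beta))

    prom_act_sample = prom_active[:, sample_state_idx]  # n_prom x m
    prom_baseline = rng_act.lognormal(mu, config.active_sigma, size=(config.n_prom, m))
    prom_sub = rng_act.uniform(0, config.inactive_max_tpm, size=(config.n_prom, m))
    noise = rng_noise.normal(0.0, config.noise_sd, size=(config.n_prom, m)) \
        if config.noise_sd > 0 else np.zeros((config.n_prom, m))

    prom_vals = np.empty((config.n_prom, m))
    for pi, gid in enumerate(prom_ids):
        links = links_of_prom[gid]
        if links:
            signal = np.zeros(m)
            for ei, beta in links:
                signal += beta * enh_latent[ei]
        else:
            signal = prom_baseline[pi]
        active_row = np.maximum(signal + noise[pi], 0.0)
        prom_vals[pi] = np.where(prom_act_sample[pi], active_row, prom_sub[pi])

    sample_ids = [r["sample_id"] for r in rows]
    enh_matrix = ActivityMatrix(pd.DataFrame(enh_vals, index=enh_ids, columns=sample_ids))
    prom_matrix = ActivityMatrix(pd.DataFrame(prom_vals, index=prom_ids, columns=sample_ids))

    state_of_activity = {
        eid: [states[s] for s in np.flatnonzero(enh_active[i])]
        for i, eid in enumerate(enh_ids)
    }
    state_of_activity.update({
        gid: [states[s] for s in np.flatnonzero(prom_active[i])]
        for i, gid in enumerate(prom_ids)
    })

    truth = SyntheticTruth(
        planted_links=planted,
        state_of_activity=state_of_activity,
        chrom_sizes=chrom_sizes,
    )
    return SimulatedDataset(enhancers, promoters, enh_matrix, prom_matrix, samples, truth)


def candidate_pairs(dataset: SimulatedDataset,
                    max_distance: int = MAX_LINK_DISTANCE) -> list[tuple[str, str]]:
    """All (enhancer_id, gene_id) pairs on the same chromosome within 1 Mb."""
    pairs = []
    for prom in dataset.promoters:
        for e in dataset.enhancers:
            if e.chrom == prom.chrom and abs(e.midpoint - prom.tss) <= max_distance:
                pairs.append((e.id, prom.gene_id))
    return pairs


def make_validation(dataset: SimulatedDataset, sensitivity: float = 0.8,
                    false_link_rate: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Build a noisy validation link set from the planted truth.

    Each true link is included independently with probability ``sensitivity``;
    ``round(false_link_rate * n_true)`` false links are drawn uniformly from
    the non-linked within-1 Mb pairs.
    """
    if not (0 <= sensitivity <= 1 and 0 <= false_link_rate <= 1):
        raise ValueError("sensitivity and false_link_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    true_pairs = sorted(dataset.truth.link_pairs)
    keep = rng.random(len(true_pairs)) < sensitivity
    kept = [p for p, k in zip(true_pairs, keep) if k]

    n_false = round(false_link_rate * len(true_pairs))
    false_pairs: list[tuple[str, str]] = []
    if n_false > 0:
        pool = sorted(set(candidate_pairs(dataset)) - set(true_pairs))
        idx = rng.choice(len(pool), size=min(n_false, len(pool)), replace=False)
        false_pairs = [pool[i] for i in sorted(idx)]

    df = pd.DataFrame(kept + false_pairs, columns=["enhancer_id", "gene_id"])
    df["source"] = "synthetic"
    return df


def _private_signal_genes(dataset: SimulatedDataset, flank: int = 2000) -> list[str]:
    """Linked genes whose signal regions are private, so the causal truth of a
    simulated GWAS is well defined.

    A gene qualifies when (a) its body +/- flank does not overlap any other
    gene's body +/- flank, (b) none of its planted enhancers serves another
    gene, and (c) none of its planted enhancers lies inside another gene's
    proximal window.  Without these exclusions a neighbouring or co-regulated
    gene legitimately receives the inflated SNPs, and 'false positive' would
    be ill-defined.
    """
    regions = {
        p.gene_id: (p.chrom, p.gene_start - flank, p.gene_end + flank)
        for p in dataset.promoters
    }

    def overlaps(a, b):
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    targets_of_enh: dict[str, set[str]] = {}
    for eid, gid, _ in dataset.truth.planted_links:
        targets_of_enh.setdefault(eid, set()).add(gid)
    enh_by_id = {e.id: e for e in dataset.enhancers}

    out = []
    for gid in sorted({g for _, g, _ in dataset.truth.planted_links}):
        mine = regions[gid]
        if any(overlaps(mine, r) for g, r in regions.items() if g != gid):
            continue
        enhs = [e for e, gs in targets_of_enh.items() if gid in gs]
        if any(len(targets_of_enh[e]) > 1 for e in enhs):
            continue
        if any(
            overlaps((enh_by_id[e].chrom, enh_by_id[e].start, enh_by_id[e].end), r)
            for e in enhs
            for g, r in regions.items()
            if g != gid
        ):
            continue
        out.append(gid)
    return out


def make_gwas(
    dataset: SimulatedDataset,
    n_variants: int = 20_000,
    n_causal: int = 20,
    effect_shift: float = 9.0,
    maf_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    trait: str = "trait",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate GWAS summary statistics with signal planted in causal genes.

    SNPs are placed uniformly over the genome.  Background SNPs get p-values
    Uniform(0,1); SNPs inside a causal gene's body +/-2 kb, or inside one of
    its planted enhancers, get p ~ Beta(1/(1+effect_shift), 1), i.e. shifted
    toward 0 (``effect_shift=0`` recovers the uniform background law).
    Returns the variant table and the causal gene list; the causal genes are
    also recorded on ``dataset.truth.causal_genes[trait]``.
    """
    if effect_shift < 0:
        raise ValueError("effect_shift must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chroms = sorted(dataset.truth.chrom_sizes)
    sizes = np.array([dataset.truth.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    pool = _private_signal_genes(dataset)
    if not pool:
        pool = [p.gene_id for p in dataset.promoters]
    n_causal = min(n_causal, len(pool))
    causal = sorted(rng.choice(pool, size=n_causal, replace=False).tolist())

    # causal regions: gene body +/- 2 kb plus the gene's planted enhancers
    enh_by_id = {e.id: e for e in dataset.enhancers}
    regions: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for p in dataset.promoters:
        if p.gene_id in causal:
            regions[p.chrom].append((p.gene_start - 2000, p.gene_end + 2000))
    for eid, gid, _ in dataset.truth.planted_links:
        if gid in causal:
            e = enh_by_id[eid]
            regions[e.chrom].append((e.start, e.end))

    chrom_idx = rng.choice(len(chroms), size=n_variants, p=probs)
    pos = (rng.random(n_variants) * sizes[chrom_idx]).astype(int)

    in_causal = np.zeros(n_variants, dtype=bool)
    for ci, c in enumerate(chroms):
        if not regions[c]:
            continue
        mask = chrom_idx == ci
        pts = pos[mask]
        hit = np.zeros(pts.size, dtype=bool)
        for start, end in regions[c]:
            hit |= (pts >= start) & (pts < end)
        in_causal[mask] = hit

    p = rng.random(n_variants)
    if effect_shift > 0 and in_causal.any():
        a = 1.0 / (1.0 + effect_shift)
        p[in_causal] = rng.beta(a, 1.0, size=int(in_causal.sum()))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if maf_distribution is None:
        maf = rng.uniform(0.01, 0.5, size=n_variants)
    else:
        maf = np.asarray(maf_distribution(rng, n_variants), dtype=float)

    variants = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n_variants)],
        "chrom": [chroms[i] for i in chrom_idx],
        "pos": pos,
        "maf": maf,
        "p": p,
    })
    dataset.truth.causal_genes[trait] = causal
    return variants, causal


def gini(values: Sequence[float]) -> float:
    """Gini index of a non-negative vector (0 = perfectly even, ->1 = concentrated)."""
    x = np.sort(np.asarray(values, dtype=float))
    if (x < 0).any():
        raise ValueError("Gini index requires non-negative values")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / total).sum()) / n)
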