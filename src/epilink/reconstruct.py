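"""Five-step reconstruction of enhancer-promoter interactions (EPIs).

For every promoter the pipeline (1) enumerates candidate enhancers within
1 Mb on the same chromosome, (2) fits a joint LASSO of promoter activity on
all candidates and keeps enhancers with positive coefficients, (3) keeps
candidates whose Spearman correlation with the promoter exceeds an empirical
null built from trans-chromosomal enhancers at a 5% FDR, (4) calls each
surviving pair active per sample when both elements are in usage, scores
active pairs with an Activity-By-Contact (ABC) score, and (5) aggregates
replicate samples into one weighted network per cell/tissue state, keeping
the maximal ABC score per edge.

The fitted-model surface is :class:`EpiModel` / :class:`EpiResults`;
the individual steps are also exposed as module-level functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .io import (
    ActivityMatrix,
    GenomicInterval,
    PromoterAnnotation,
    SampleTable,
    UsageMatrix,
    usage_from_activity,
)

logger = logging.getLogger(__name__)

MAX_LINK_DISTANCE = 1_000_000
MIN_SAMPLES_FOR_LASSO = 8


@dataclass
class CandidateLink:
    """An enhancer-promoter pair under consideration."""

    enhancer_id: str
    gene_id: str
    distance: int  # |enhancer midpoint - TSS|, bp
    beta: float = float("nan")  # LASSO coefficient (standardized fit)
    rho: float = float("nan")  # Spearman correlation across all samples


@dataclass
class AbcParams:
    """Parameters of the ABC score's contact and background terms.

    Contact decays as ``C(d) = (d + d0) ** -gamma``; ``background`` is the
    promoter-level background term B_p added to the normalizing denominator.
    """

    gamma: float = 1.0
    d0: float = 5000.0
    background: float = 0.0

    def __post_init__(self):
        if self.gamma < 0 or self.d0 < 0 or self.background < 0:
            raise ValueError("require gamma >= 0, d0 >= 0, background >= 0")

    def contact(self, distance) -> np.ndarray:
        return (np.asarray(distance, dtype=float) + self.d0) ** (-self.gamma)


@dataclass
class EpiRecord:
    """Per-sample activity call and ABC score for one retained pair."""

    enhancer_id: str
    gene_id: str
    sample_id: str
    active: bool
    abc: float = 0.0


@dataclass
class StateNetwork:
    """Aggregated EPI set of one cell/tissue state with ABC edge weights."""

    state: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"state": self.state, "enhancer_id": e, "gene_id": g, "abc": w}
            for (e, g), w in sorted(self.edges.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        ]
        return pd.DataFrame(rows, columns=["state", "enhancer_id", "gene_id", "abc"])

    def to_graphml(self, path) -> None:
        import networkx as nx

        graph = nx.Graph(state=self.state)
        for (e, g), w in self.edges.items():
            graph.add_node(e, kind="enhancer")
            graph.add_node(g, kind="promoter")
            graph.add_edge(e, g, abc=w)
        nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# step 1: candidate enumeration + LASSO selection
# ---------------------------------------------------------------------------


def candidate_links(
    promoter: PromoterAnnotation,
    enhancers: Sequence[GenomicInterval],
    max_distance: int = MAX_LINK_DISTANCE,
) -> list[CandidateLink]:
    """Same-chromosome enhancers with midpoint-to-TSS distance <= 1 Mb, by distance."""
    out = []
    for e in enhancers:
        if e.chrom != promoter.chrom:
            continue
        d = abs(e.midpoint - promoter.tss)
        if d <= max_distance:
            out.append(CandidateLink(e.id, promoter.gene_id, int(d)))
    out.sort(key=lambda l: (l.distance, l.enhancer_id))
    return out


def lasso_select(
    promoter_activity: np.ndarray,
    candidate_activity: np.ndarray,
    seed: int = 0,
    cv: int = 5,
) -> np.ndarray:
    """Jointly regress promoter activity on all candidates with an L1 penalty.

    ``candidate_activity`` is (n_samples, n_candidates).  Activities are
    z-scored per element before fitting and the penalty is chosen by k-fold
    cross-validation; the returned coefficients are on the standardized
    scale.  Candidates with beta > 0 are the retained set.  A zero-variance
    promoter (no signal) yields all-zero coefficients.
    """
    y = np.asarray(promoter_activity, dtype=float)
    X = np.asarray(candidate_activity, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("candidate_activity must be (n_samples, n_candidates)")
    if y.shape[0] < MIN_SAMPLES_FOR_LASSO:
        raise ValueError(f"need >= {MIN_SAMPLES_FOR_LASSO} samples for the LASSO step")
    betas = np.zeros(X.shape[1])
    y_sd = y.std()
    if y_sd == 0:
        logger.info("zero-variance promoter: no candidates retained")
        return betas
    x_sd = X.std(axis=0)
    usable = x_sd > 0
    if not usable.any():
        return betas
    Xz = (X[:, usable] - X[:, usable].mean(axis=0)) / x_sd[usable]
    yz = (y - y.mean()) / y_sd
    folds = KFold(n_splits=cv, shuffle=True, random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LassoCV(cv=folds, max_iter=5000)
        model.fit(Xz, yz)
    betas[usable] = model.coef_
    return betas


# ---------------------------------------------------------------------------
# step 2: empirical-FDR correlation filter
# ---------------------------------------------------------------------------


def _rank_z(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm (nan if constant)."""
    ranks = stats.rankdata(values, axis=-1)
    ranks = ranks - ranks.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return ranks / norm


def spearman_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman correlation of ``x`` (m,) against every row of ``Y`` (n, m)."""
    zx = _rank_z(np.asarray(x, dtype=float))
    zY = _rank_z(np.asarray(Y, dtype=float))
    return zY @ zx


def quantile_threshold(null_rhos: np.ndarray, fdr: float) -> float:
    """The empirical (1 - fdr) quantile of a null correlation sample.

    Linear interpolation between order statistics, so the threshold is
    reproducible for small stub inputs.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    null_rhos = np.asarray(null_rhos, dtype=float)
    null_rhos = null_rhos[np.isfinite(null_rhos)]
    if null_rhos.size == 0:
        raise ValueError("empty null sample")
    return float(np.quantile(null_rhos, 1.0 - fdr, method="linear"))


def ratio_threshold(null_rhos: np.ndarray, observed_rhos: np.ndarray, fdr: float) -> float:
    """Ratio-style empirical FDR: smallest observed rho t such that
    (fraction of null > t) / (fraction of observed > t) <= fdr.

    Returns +inf when no observed threshold achieves the target.
    """
    null_rhos = np.asarray(null_rhos, dtype=float)
    null_rhos = null_rhos[np.isfinite(null_rhos)]
    obs = np.sort(np.asarray(observed_rhos, dtype=float))
    best = np.inf
    for t in obs:
        denom = float(np.mean(observed_rhos > t))
        if denom == 0:
            continue
        if float(np.mean(null_rhos > t)) / denom <= fdr:
            best = min(best, float(t))
    return best


def null_rho_threshold(
    promoter_activity: np.ndarray,
    trans_enhancer_pool: np.ndarray,
    n_null: int = 10_000,
    fdr: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Correlation threshold from random trans-chromosomal enhancer pairs.

    ``n_null`` enhancers are drawn from the pool (without replacement when
    the pool is large enough, otherwise with replacement and a warning),
    their Spearman correlations with the promoter form the null, and the
    threshold is the empirical (1 - fdr) quantile of that null.
    """
    pool = np.asarray(trans_enhancer_pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ValueError("trans enhancer pool must be a non-empty (n, m) array")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replace = pool.shape[0] < n_null
    if replace:
        warnings.warn(
            f"trans pool ({pool.shape[0]}) smaller than n_null ({n_null}); "
            "sampling with replacement"
        )
    idx = rng.choice(pool.shape[0], size=n_null, replace=replace)
    # rho is deterministic per pool row, so compute unique rows once
    uniq, inverse = np.unique(idx, return_inverse=True)
    rhos = spearman_many(promoter_activity, pool[uniq])[inverse]
    return quantile_threshold(rhos, fdr)


def correlation_filter(links: Sequence[CandidateLink], threshold: float) -> list[CandidateLink]:
    """Retain links whose Spearman rho strictly exceeds the null threshold."""
    return [l for l in links if np.isfinite(l.rho) and l.rho > threshold]


# ---------------------------------------------------------------------------
# steps 3-4: per-sample activation and ABC quantification
# ---------------------------------------------------------------------------


def activate_per_sample(
    links: Sequence[CandidateLink],
    enh_usage: UsageMatrix,
    prom_usage: UsageMatrix,
    sample_id: str,
) -> list[EpiRecord]:
    """Call a pair active in a sample iff both its elements are in usage there."""
    records = []
    for l in links:
        active = enh_usage.is_in_usage(l.enhancer_id, sample_id) and prom_usage.is_in_usage(
            l.gene_id, sample_id
        )
        records.append(EpiRecord(l.enhancer_id, l.gene_id, sample_id, active))
    return records


def abc_quantify(
    distances: np.ndarray,
    enhancer_activity: np.ndarray,
    promoter_activity: float,
    params: AbcParams | None = None,
) -> np.ndarray:
    """ABC scores for the active enhancers of one promoter in one sample.

    score_e = sqrt(A_e * A_p) * C(d_e) / (sum_e' sqrt(A_e' * A_p) * C(d_e') + B_p)

    with Activity the geometric mean of enhancer and promoter TPM and
    Contact a power-law distance decay.  Scores lie in [0, 1] and sum to
    <= 1 (to exactly 1 - B_p share when B_p > 0 participates).
    """
    params = params or AbcParams()
    a = np.sqrt(np.asarray(enhancer_activity, dtype=float) * float(promoter_activity))
    contrib = a * params.contact(distances)
    denom = contrib.sum() + params.background
    if denom == 0:
        return np.zeros(0)
    return contrib / denom


# ---------------------------------------------------------------------------
# step 5: replicate aggregation
# ---------------------------------------------------------------------------


def aggregate_state(
    records_by_sample: Mapping[str, Sequence[EpiRecord]],
    sample_table: SampleTable,
    state: str,
) -> StateNetwork:
    """Union of pairs active in >= 1 replicate of the state, with max ABC score."""
    samples = sample_table.samples_of(state)  # raises on empty state
    network = StateNetwork(state=state)
    for sample_id in samples:
        for rec in records_by_sample.get(sample_id, []):
            if not rec.active or rec.abc <= 0:
                continue
            key = (rec.enhancer_id, rec.gene_id)
            if key not in network.edges or rec.abc > network.edges[key]:
                network.edges[key] = rec.abc
            network.provenance.setdefault(key, []).append(sample_id)
    return network


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunables of the reconstruction pipeline (defaults follow the method)."""

    usage_threshold: float = 1.0
    max_distance: int = MAX_LINK_DISTANCE
    n_null: int = 10_000
    fdr: float = 0.05
    abc: AbcParams = field(default_factory=AbcParams)
    cv_folds: int = 5
    fdr_mode: str = "quantile"  # or "ratio"

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.fdr_mode not in {"quantile", "ratio"}:
            raise ValueError("fdr_mode must be 'quantile' or 'ratio'")
        if isinstance(self.abc, dict):
            self.abc = AbcParams(**self.abc)


class EpiModel:
    """EPI reconstruction model over a CAGE activity dataset.

    Parameters mirror the input files: enhancer intervals, promoter
    annotations, the two activity matrices on a common sample axis, and the
    sample-to-state table.  ``fit`` runs the five-step pipeline and returns
    an :class:`EpiResults`.
    """

    def __init__(
        self,
        enhancers: Sequence[GenomicInterval],
        promoters: Sequence[PromoterAnnotation],
        enh_activity: ActivityMatrix,
        prom_activity: ActivityMatrix,
        samples: SampleTable,
        config: PipelineConfig | None = None,
    ):
        if enh_activity.sample_ids != prom_activity.sample_ids:
            raise ValueError("enhancer and promoter activity matrices have different samples")
        known = set(samples.data["sample_id"])
        if set(enh_activity.sample_ids) - known:
            raise ValueError("activity matrix contains samples absent from the sample table")
        self.enhancers = list(enhancers)
        self.promoters = list(promoters)
        self.enh_activity = enh_activity
        self.prom_activity = prom_activity
        self.samples = samples
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataset(cls, dataset, config: PipelineConfig | None = None) -> "EpiModel":
        return cls(
            dataset.enhancers,
            dataset.promoters,
            dataset.enh_activity,
            dataset.prom_activity,
            dataset.samples,
            config,
        )

    def fit(self, seed: int = 0) -> "EpiResults":
        cfg = self.config
        enh_ids = self.enh_activity.element_ids
        enh_index = {eid: i for i, eid in enumerate(enh_ids)}
        enh_values = self.enh_activity.values
        sample_ids = self.enh_activity.sample_ids
        enh_chrom = np.array([e.chrom for e in self.enhancers])
        enh_rows = np.array([enh_index[e.id] for e in self.enhancers])
        enh_rank_z = _rank_z(enh_values)

        enh_usage = usage_from_activity(self.enh_activity, cfg.usage_threshold)
        prom_usage = usage_from_activity(self.prom_activity, cfg.usage_threshold)

        master = np.random.SeedSequence(int(seed))
        prom_seeds = master.spawn(len(self.promoters))
        lasso_seed = int(seed) % (2**31)

        funnel = {
            "n_promoters": len(self.promoters),
            "n_candidates": 0,
            "n_lasso_retained": 0,
            "n_corr_retained": 0,
            "n_active_pair_samples": 0,
        }
        retained_by_prom: dict[str, list[CandidateLink]] = {}
        enh_lookup = {e.id: e for e in self.enhancers}
        records_by_sample: dict[str, list[EpiRecord]] = {s: [] for s in sample_ids}

        for pi, prom in enumerate(self.promoters):
            if prom.gene_id not in self.prom_activity.data.index:
                raise KeyError(f"promoter {prom.gene_id} missing from activity matrix")
            cands = candidate_links(prom, self.enhancers, cfg.max_distance)
            funnel["n_candidates"] += len(cands)
            if not cands:
                continue
            y = self.prom_activity.row(prom.gene_id)
            cand_rows = np.array([enh_index[c.enhancer_id] for c in cands])
            betas = lasso_select(y, enh_values[cand_rows].T, seed=lasso_seed,
                                 cv=cfg.cv_folds)
            for c, b in zip(cands, betas):
                c.beta = float(b)
            survivors = [c for c in cands if c.beta > 0]
            funnel["n_lasso_retained"] += len(survivors)
            if not survivors:
                continue

            rng = np.random.default_rng(prom_seeds[pi])
            trans = enh_rows[enh_chrom != prom.chrom]
            if trans.size == 0:
                raise ValueError(
                    f"no trans-chromosomal enhancers available for {prom.gene_id}"
                )
            zy = _rank_z(y)
            surv_rows = np.array([enh_index[c.enhancer_id] for c in survivors])
            obs_rhos = enh_rank_z[surv_rows] @ zy
            for c, r in zip(survivors, obs_rhos):
                c.rho = float(r)
            if cfg.fdr_mode == "quantile":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    threshold = null_rho_threshold(
                        y, enh_values[trans], n_null=cfg.n_null, fdr=cfg.fdr, seed=rng
                    )
            else:
                null_rhos = enh_rank_z[trans] @ zy
                threshold = ratio_threshold(null_rhos, obs_rhos, cfg.fdr)
            retained = correlation_filter(survivors, threshold)
            funnel["n_corr_retained"] += len(retained)
            if not retained:
                continue
            retained_by_prom[prom.gene_id] = retained

            distances = np.array([c.distance for c in retained], dtype=float)
            retained_rows = np.array([enh_index[c.enhancer_id] for c in retained])
            for si, sample_id in enumerate(sample_ids):
                recs = activate_per_sample(retained, enh_usage, prom_usage, sample_id)
                active_idx = [i for i, r in enumerate(recs) if r.active]
                if active_idx:
                    funnel["n_active_pair_samples"] += len(active_idx)
                    scores = abc_quantify(
                        distances[active_idx],
                        enh_values[retained_rows[active_idx], si],
                        self.prom_activity.data.iat[
                            self.prom_activity.data.index.get_loc(prom.gene_id), si
                        ],
                        cfg.abc,
                    )
                    for i, s in zip(active_idx, scores):
                        recs[i].abc = float(s)
                records_by_sample[sample_id].extend(recs)

        networks = {
            state: aggregate_state(records_by_sample, self.samples, state)
            for state in self.samples.states
        }
        funnel["n_edges_aggregated"] = sum(len(n) for n in networks.values())
        links_rows = []
        for gid, links in retained_by_prom.items():
            for l in links:
                e = enh_lookup[l.enhancer_id]
                links_rows.append(
                    {
                        "gene_id": gid,
                        "enhancer_id": l.enhancer_id,
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "distance": l.distance,
                        "beta": l.beta,
                        "rho": l.rho,
                    }
                )
        links_table = pd.DataFrame(
            links_rows,
            columns=["gene_id", "enhancer_id", "chrom", "start", "end",
                     "distance", "beta", "rho"],
        ).sort_values(["gene_id", "enhancer_id"], ignore_index=True)
        return EpiResults(
            model=self,
            networks=networks,
            links_table=links_table,
            records_by_sample=records_by_sample,
            funnel=funnel,
            seed=int(seed),
        )


@dataclass
class EpiResults:
    """Fitted EPI networks plus the per-step funnel and per-sample calls."""

    model: EpiModel
    networks: dict[str, StateNetwork]
    links_table: pd.DataFrame
    records_by_sample: dict[str, list[EpiRecord]]
    funnel: dict[str, int]
    seed: int

    def edge_scores(self) -> dict[tuple[str, str], float]:
        """Max ABC score of each edge across all state networks."""
        scores: dict[tuple[str, str], float] = {}
        for net in self.networks.values():
            for key, w in net.edges.items():
                if key not in scores or w > scores[key]:
                    scores[key] = w
        return scores

    def edges_dataframe(self) -> pd.DataFrame:
        frames = [net.to_dataframe() for _, net in sorted(self.networks.items())]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["state", "enhancer_id", "gene_id", "abc"]
        )

    def summary(self) -> str:
        f = self.funnel
        lines = [
            "EPI reconstruction summary",
            "==========================",
            f"promoters:                  {f['n_promoters']}",
            f"candidate pairs (<=1 Mb):   {f['n_candidates']}",
            f"LASSO-retained (beta > 0):  {f['n_lasso_retained']}",
            f"correlation-retained:       {f['n_corr_retained']}",
            f"active pair-samples:        {f['n_active_pair_samples']}",
            f"aggregated state edges:     {f['n_edges_aggregated']}",
            f"states:                     {len(self.networks)}",
            f"seed:                       {self.seed}",
        ]
        return "\n".join(lines)

    def to_dir(self, outdir) -> None:
        """Write per-state edge lists, the retained-link table and metadata."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        enh_lookup = {e.id: e for e in self.model.enhancers}
        link_info = self.links_table.set_index(["enhancer_id", "gene_id"])
        rows = []
        for state, net in sorted(self.networks.items()):
            for (eid, gid), w in sorted(net.edges.items(), key=lambda kv: (kv[0][1], kv[0][0])):
                e = enh_lookup[eid]
                info = link_info.loc[(eid, gid)]
                rows.append(
                    {
                        "state": state,
                        "enhancer_id": eid,
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "gene_id": gid,
                        "distance": int(info["distance"]),
                        "beta": float(info["beta"]),
                        "rho": float(info["rho"]),
                        "abc": w,
                    }
                )
        pd.DataFrame(
            rows,
            columns=["state", "enhancer_id", "chrom", "start", "end", "gene_id",
                     "distance", "beta", "rho", "abc"],
        ).to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.8g")
        self.links_table.to_csv(outdir / "links.tsv", sep="\t", index=False,
                                float_format="%.8g")
        meta = {
            "seed": self.seed,
            "funnel": self.funnel,
            "params": asdict(self.model.config),
        }
        with open(outdir / "run_metadata.json", "w", encoding="utf-8") as handle:
            json.dump(meta, handle, indent=1, sort_keys=True)


def load_networks(path) -> dict[str, StateNetwork]:
    """Read back per-state networks from an ``edges.tsv`` written by ``to_dir``."""
    from pathlib import Path

    df = pd.read_csv(Path(path) / "edges.tsv", sep="\t")
    networks: dict[str, StateNetwork] = {}
    for row in df.itertuples(index=False):
        net = networks.setdefault(row.state, StateNetwork(state=row.state))
        net.edges[(row.enhancer_id, row.gene_id)] = float(row.abc)
    return networks


def reconstruct_all(dataset, config: PipelineConfig | None = None, seed: int = 0) -> EpiResults:
    """Convenience wrapper: build an :class:`EpiModel` from a dataset and fit it."""
    return EpiModel.from_dataset(dataset, config).fit(seed=seed)
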