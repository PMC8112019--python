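"""Guided Grad-CAM saliency in region-pair space and graph-theoretic hub isolation.

Saliency for one (model, instance) pair: Grad-CAM at the (single) convolution
layer — channel weights are the row-averaged gradients of the target-class
logit with respect to the conv activations, the map is the rectified weighted
activation sum, broadcast across each rectangle row — multiplied elementwise
by the guided-backpropagation input gradient, absolute value taken, then
back-projected through the member's scramble permutation to region pairs.
Maps are averaged over instances and models into a class activation map
(CAM).

Hubs: the CAM is treated as a dense weighted graph (edge length inversely
proportional to saliency), edge betweenness centrality concentrates weight
on the most-travelled comparisons, communities are found by modularity
maximisation over the betweenness-weighted graph, and regions are ranked by
within-community CAM strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import EdgePermutation
from .nn import TrainedModel
from .similarity import matrix_correlation

__all__ = [
    "CAMMatrix",
    "EffectSizeMatrix",
    "CommunityPartition",
    "HubReport",
    "gradcam_edge_map",
    "average_cams",
    "ensemble_cam",
    "edge_effect_sizes",
    "cam_vs_effects",
    "edge_betweenness_matrix",
    "communities_by_modularity",
    "hub_report",
    "rank_univariate_cam",
    "cam_region_strength",
]


@dataclass(frozen=True)
class CAMMatrix:
    """Averaged edge-saliency matrix (symmetric, nonnegative, zero diagonal)."""

    values: np.ndarray
    n_contributions: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("CAM must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EffectSizeMatrix:
    """Per-edge case-vs-control Cohen's d with nonparametric p and BH q."""

    d_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray


@dataclass(frozen=True)
class CommunityPartition:
    assignment: dict[int, int]  # region index -> community id
    modularity: float


@dataclass(frozen=True)
class HubReport:
    per_community: dict[int, list[tuple[int, float]]]  # community -> [(region, strength)]
    top_hubs: list[tuple[int, float]]  # global top-k (region, strength)


def gradcam_edge_maps(
    model: TrainedModel,
    encoded: np.ndarray,
    perm: EdgePermutation,
    target_class: int = 1,
    channel: int | None = None,
    contrastive: bool = True,
) -> np.ndarray:
    """Guided Grad-CAM for a batch of encoded instances, in region-pair space.

    ``encoded`` is a (batch, rows, cols, channels) rectangle stack;
    ``target_class`` defaults to the case output unit, and by default the
    backpropagated score is that class's log-odds (its logit minus the
    other's), which drops the common-mode gradient the softmax cancels.
    With ``channel`` the saliency of a single input channel is returned;
    otherwise channels are summed.  Each output map is symmetric and
    nonnegative with zero diagonal.  Returns (batch, n_regions, n_regions).
    """
    x = np.asarray(encoded, dtype=float)
    if x.ndim == 3:
        x = x[None]
    logits, cache = model._forward(x, train=False)
    if not np.all(np.isfinite(logits)):
        raise RuntimeError("saliency failure: non-finite logits (degenerate model)")
    # Grad-CAM weights: row-averaged exact gradients at the conv activations
    da1, _ = model.backward_from_logit(cache, target_class, guided=False,
                                       contrastive=contrastive)
    a1 = cache["a1"]  # (batch, rows, filters)
    alpha = da1.mean(axis=1)  # (batch, filters)
    cam_row = np.maximum(np.einsum("brf,bf->br", a1, alpha), 0.0)
    # guided backprop to the input
    _, dx = model.backward_from_logit(cache, target_class, guided=True,
                                      contrastive=contrastive)
    sal = np.abs(dx * cam_row[:, :, None, None])
    rects = sal[:, :, :, channel] if channel is not None else sal.sum(axis=3)
    n = perm.n_regions
    out = np.zeros((rects.shape[0], n, n))
    out[:, perm.rows_i, perm.rows_j] = rects
    out[:, perm.rows_j, perm.rows_i] = rects
    return out


def gradcam_edge_map(
    model: TrainedModel,
    encoded: np.ndarray,
    perm: EdgePermutation,
    target_class: int = 1,
    channel: int | None = None,
) -> np.ndarray:
    """Guided Grad-CAM for one encoded (rows, cols[, channels]) instance."""
    x = np.asarray(encoded, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    return gradcam_edge_maps(model, x[None], perm, target_class, channel)[0]


def average_cams(maps: list[np.ndarray]) -> CAMMatrix:
    """Cellwise arithmetic mean of saliency matrices."""
    if not maps:
        raise ValueError("no saliency maps to average")
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    return CAMMatrix(values=arr.mean(axis=0), n_contributions=len(maps))


def ensemble_cam(
    result,
    instances,
    channels: tuple[str, ...] = ("structural",),
    target_class: int = 1,
    channel: int | None = None,
    scope: str = "all",
) -> CAMMatrix:
    """Average guided Grad-CAM over instances and ensemble members.

    ``result`` is an :class:`~wassconn.ensemble.EnsembleResult`; each map is
    computed with the member's own model and scramble permutation.  With
    ``scope="all"`` (default) every member contributes a map for every data
    instance; ``scope="test"`` restricts each member to the instances it
    predicted (its own test set).
    """
    from .encoding import Instance, encode_instance

    if scope not in ("all", "test"):
        raise ValueError(f"scope must be 'all' or 'test', got {scope!r}")
    preds_by_model = result.predictions.groupby("model_id")["instance_id"]
    total = None
    n_maps = 0
    for member in result.members:
        if scope == "test":
            if member.model_id not in preds_by_model.groups:
                continue
            ids = list(preds_by_model.get_group(member.model_id))
        else:
            ids = sorted(instances)
        encoded = []
        for iid in ids:
            inst = instances[iid]
            sub = Instance(
                instance_id=inst.instance_id, subject_id=inst.subject_id,
                channels={c: inst.channels[c] for c in channels},
                label=inst.label,
            )
            encoded.append(
                encode_instance(sub, member.permutation, channel_order=channels)
            )
        batch = np.stack(encoded)
        scaler = getattr(member, "scaler", None)
        if scaler is not None:
            batch = (batch - scaler[0]) / scaler[1]
        maps = gradcam_edge_maps(
            member.model, batch, member.permutation,
            target_class=target_class, channel=channel,
        )
        total = maps.sum(axis=0) if total is None else total + maps.sum(axis=0)
        n_maps += maps.shape[0]
    if n_maps == 0:
        raise ValueError("no saliency maps to average")
    return CAMMatrix(values=total / n_maps, n_contributions=n_maps)


def edge_effect_sizes(cases: list[np.ndarray], controls: list[np.ndarray]) -> EffectSizeMatrix:
    """Per-edge Cohen's d (pooled s.d.), Mann-Whitney p and BH q.

    Edges with zero pooled s.d. get NaN d (warned); their p is left NaN and
    excluded from the multiplicity correction.
    """
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 matrices per group")
    a = np.stack([np.asarray(m, dtype=float) for m in cases])
    b = np.stack([np.asarray(m, dtype=float) for m in controls])
    n = a.shape[1]
    iu = np.triu_indices(n, k=1)
    xa = a[:, iu[0], iu[1]]  # (n_cases, n_edges)
    xb = b[:, iu[0], iu[1]]
    na, nb = xa.shape[0], xb.shape[0]
    pooled = np.sqrt(
        ((na - 1) * xa.var(axis=0, ddof=1) + (nb - 1) * xb.var(axis=0, ddof=1))
        / (na + nb - 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (xa.mean(axis=0) - xb.mean(axis=0)) / pooled
    zero_sd = pooled == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} edges have zero pooled s.d.; d set to NaN",
            stacklevel=2,
        )
        d = np.where(zero_sd, np.nan, d)
    p = np.full(d.shape, np.nan)
    ok = ~zero_sd
    if ok.any():
        res = stats.mannwhitneyu(xa[:, ok], xb[:, ok], alternative="two-sided", axis=0)
        p[ok] = res.pvalue
    q = np.full(d.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    def to_mat(v):
        m = np.full((n, n), np.nan)
        m[iu] = v
        m[iu[1], iu[0]] = v
        np.fill_diagonal(m, 0.0 if v is not p else 1.0)
        return m

    dm = to_mat(d)
    pm = to_mat(p)
    qm = to_mat(q)
    np.fill_diagonal(pm, 1.0)
    np.fill_diagonal(qm, 1.0)
    return EffectSizeMatrix(d_values=dm, p_values=pm, q_values=qm)


def cam_vs_effects(cam: CAMMatrix, eff: EffectSizeMatrix) -> dict[str, float]:
    """Correlate CAM saliency with |Cohen's d| over the upper triangle.

    Saliency is sign-blind, hence |d|.  Returns Pearson r/p and Spearman
    rho/p, dropping missing cells pairwise.
    """
    absd = np.abs(eff.d_values)
    r, p = matrix_correlation(cam.values, absd, method="pearson")
    rho, sp = matrix_correlation(cam.values, absd, method="spearman")
    return {"pearson_r": r, "pearson_p": p, "spearman_rho": rho, "spearman_p": sp}


def _cam_graph(values: np.ndarray, eps_rel: float = 1e-12) -> nx.Graph:
    n = values.shape[0]
    vmax = np.nanmax(values)
    if not vmax > 0:
        raise ValueError("all-zero CAM: no graph to analyse")
    eps = eps_rel * vmax
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        w = values[i, j]
        if w > 0:
            g.add_edge(int(i), int(j), weight=float(w), length=1.0 / (w + eps))
    return g


def edge_betweenness_matrix(cam: CAMMatrix | np.ndarray) -> np.ndarray:
    """Weighted edge betweenness centrality of the CAM graph.

    High-saliency edges get short lengths (1 / (value + eps)) so they carry
    shortest paths; the betweenness of an edge is the number of source-target
    shortest paths traversing it (unordered node pairs, fractional on ties).
    """
    values = np.asarray(getattr(cam, "values", cam), dtype=float)
    g = _cam_graph(values)
    bc = nx.edge_betweenness_centrality(g, normalized=False, weight="length")
    out = np.zeros_like(values)
    for (i, j), v in bc.items():
        out[i, j] = v
        out[j, i] = v
    return out


def communities_by_modularity(
    bw: np.ndarray, seed: int, n_restarts: int = 20
) -> CommunityPartition:
    """Seeded multi-restart Louvain modularity maximisation.

    Runs the greedy multi-level algorithm from several seeded restarts and
    keeps the partition with the highest weighted modularity Q; never returns
    a partition with Q below the trivial one-community partition (Q = 0).
    """
    values = np.asarray(getattr(bw, "values", bw), dtype=float)
    n = values.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if values[i, j] > 0:
            g.add_edge(int(i), int(j), weight=float(values[i, j]))
    if g.number_of_edges() == 0:
        return CommunityPartition(assignment={i: 0 for i in range(n)}, modularity=0.0)
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best_q = -np.inf
    best = None
    for s in restart_seeds:
        comms = nx.community.louvain_communities(g, weight="weight", seed=int(s))
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best_q = q
            best = comms
    if best_q < 0.0:  # never worse than the trivial partition
        best = [set(range(n))]
        best_q = nx.community.modularity(g, best, weight="weight")
    assignment = {}
    for cid, members in enumerate(sorted(best, key=lambda c: min(c))):
        for node in members:
            assignment[int(node)] = cid
    return CommunityPartition(assignment=assignment, modularity=float(best_q))


def cam_region_strength(cam: CAMMatrix | np.ndarray) -> np.ndarray:
    """Per-region total incident CAM saliency."""
    values = np.asarray(getattr(cam, "values", cam), dtype=float)
    return values.sum(axis=1)


def hub_report(
    part: CommunityPartition, cam: CAMMatrix | np.ndarray, k: int = 3
) -> HubReport:
    """Rank regions by CAM strength per community; list global top-k hubs.

    Within each community, regions are ranked by the sum of their incident
    CAM values restricted to edges inside that community.  The global top-k
    list ranks regions across communities by their total incident CAM
    strength.  Ties break by ascending region index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.asarray(getattr(cam, "values", cam), dtype=float)
    n = values.shape[0]
    comm = np.array([part.assignment[i] for i in range(n)])
    within = np.zeros(n)
    for i in range(n):
        same = comm == comm[i]
        within[i] = values[i, same].sum()
    per_comm: dict[int, list[tuple[int, float]]] = {}
    for cid in sorted(set(part.assignment.values())):
        members = np.flatnonzero(comm == cid)
        order = members[np.lexsort((members, -within[members]))]
        per_comm[int(cid)] = [(int(i), float(within[i])) for i in order]
    total = values.sum(axis=1)
    order = np.lexsort((np.arange(n), -total))
    top = [(int(i), float(total[i])) for i in order[:k]]
    return HubReport(per_community=per_comm, top_hubs=top)


def rank_univariate_cam(
    cam_vector: np.ndarray, region_names: list[str] | None = None
) -> list[tuple[int, str, float]]:
    """Descending ranking of per-region saliency values.

    Returns (region index, name, value) triples; ties keep ascending region
    order.  Used for the univariate (tiled grey-matter volume) channel, whose
    CAM collapses to one value per region.
    """
    v = np.asarray(cam_vector, dtype=float).ravel()
    order = np.lexsort((np.arange(v.size), -v))
    names = region_names or [f"region_{i + 1}" for i in range(v.size)]
    return [(int(i), names[int(i)], float(v[i])) for i in order]
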