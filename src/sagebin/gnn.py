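"""Coverage-aware GraphSAGE embeddings on the assembly graph.

Two ideas distinguish this model from plain unsupervised GraphSAGE:

1. **Coverage-weighted neighborhood sampling.** On an assembly graph the
   read coverage of a link counts the reads spanning the junction, so it
   grades how much the link should be trusted. For a contig ``u`` with
   neighbors ``v_i`` at coverages ``rc_i`` the positive-sampling
   probability is ``rc_i / sum(rc)`` and the negative-sampling
   probability its inverse, ``(1/rc_i) / sum(1/rc)``. A disconnected
   contig draws its negatives uniformly from all other contigs.

2. **Coverage-scaled loss.** The positive term of the unsupervised
   binary cross-entropy loss is multiplied by the link's normalized read
   coverage, so low-coverage (likely spurious) links pull embeddings
   together only weakly:

       J(z_u) = -rc_norm(u,v) * log(sigmoid(z_u . z_v))
                - Q * E_{vn ~ Pn} [ log(sigmoid(-z_u . z_vn)) ]

   where the expectation is estimated as the Monte-Carlo mean over the Q
   sampled negatives.

Each layer concatenates a contig's hidden state with the mean of its
sampled neighbors' hidden states and applies a dense layer with ReLU
(the final layer is linear). Initial hidden states are the
contig-specific VAE embeddings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._nn import Adam, dense_backward, dense_forward, dense_init, sigmoid
from .vae import EmbeddingMatrix

logger = logging.getLogger(__name__)

_LOG_CLAMP = 1e-9


@dataclass
class GNNConfig:
    n_layers: int = 3
    hidden_dim: int = 512
    output_dim: int = 64
    activation: str = "relu"
    learning_rate: float = 5e-5
    epochs: int = 100
    Q: int = 5
    neighbors_per_layer: list[int] = field(default_factory=lambda: [10, 10, 10])
    random_negative_frac: float = 0.5
    # per-layer L2 normalization of hidden states, as in the original
    # GraphSAGE algorithm; prevents the embedding-norm collapse that
    # otherwise parks the unsupervised loss at its z=0 saddle point
    l2_normalize: bool = True
    # early stopping is opt-in: per-epoch loss is stochastic (edges are
    # resampled), so a plateau rule needs a deliberately chosen delta
    early_stop_delta: float | None = None
    early_stop_patience: int = 2
    batch_size: int | None = None  # None: auto from graph size
    checkpoint_interval: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_layers != len(self.neighbors_per_layer):
            raise ValueError("n_layers must equal len(neighbors_per_layer)")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if min(self.hidden_dim, self.output_dim) <= 0:
            raise ValueError("dimensions must be positive")


@dataclass
class SamplingDistribution:
    """Per-contig positive and negative sampling laws.

    ``pos[u] = (neighbor_indices, probs)`` with probs proportional to the
    link read coverage; ``neg[u]`` analogous with inverse-coverage probs.
    Contigs with fewer than two neighbors have no useful inverse-coverage
    law, so their entry in ``neg`` is None and negatives fall back to a
    uniform draw over non-neighbors (for disconnected contigs: over all
    other contigs).
    """

    contig_ids: list[str]
    pos: dict[int, tuple[np.ndarray, np.ndarray]]
    neg: dict[int, tuple[np.ndarray, np.ndarray] | None]
    neighbor_sets: dict[int, set]
    # per-node min(rc)/max(rc) over incident links (1.0 when uniform or
    # degree <= 1); measures how much coverage distinguishes the links
    coverage_min_over_max: dict[int, float] = None

    @property
    def n(self) -> int:
        return len(self.contig_ids)


def build_sampling(graph) -> SamplingDistribution:
    """Build coverage-proportional positive and inverse-coverage negative
    sampling distributions from an assembly graph."""
    ids = list(graph.contig_ids)
    index = {c: i for i, c in enumerate(ids)}
    nbrs: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(ids))}
    for e, rc in graph.edge_coverage.items():
        u, v = sorted(e)
        nbrs[index[u]].append((index[v], rc))
        nbrs[index[v]].append((index[u], rc))
    pos, neg, nsets, disp = {}, {}, {}, {}
    for i, lst in nbrs.items():
        lst.sort()
        nsets[i] = {j for j, _ in lst}
        disp[i] = 1.0
        if not lst:
            pos[i] = (np.empty(0, dtype=int), np.empty(0))
            neg[i] = None
            continue
        idx = np.array([j for j, _ in lst], dtype=int)
        rc = np.array([r for _, r in lst], dtype=float)
        pos[i] = (idx, rc / rc.sum())
        if len(lst) >= 2:
            inv = 1.0 / rc
            neg[i] = (idx, inv / inv.sum())
            disp[i] = float(rc.min() / rc.max())
        else:
            neg[i] = None
    return SamplingDistribution(ids, pos, neg, nsets, disp)


def _uniform_non_neighbors(dist: SamplingDistribution, u: int, q: int, rng: np.random.Generator) -> list[int]:
    forbidden = dist.neighbor_sets[u] | {u}
    out: list[int] = []
    n = dist.n
    if n - len(forbidden) <= 0:
        return out
    while len(out) < q:
        j = int(rng.integers(n))
        if j not in forbidden:
            out.append(j)
    return out


def sample_edges(dist: SamplingDistribution, u: int, Q: int, rng: np.random.Generator):
    """Draw one positive neighbor and Q i.i.d. negatives for contig ``u``.

    Positive: from the coverage-proportional law (None if disconnected).
    Negatives: from the inverse-coverage law over neighbors when u has
    degree >= 2, otherwise uniform over non-neighbors.
    """
    idx, p = dist.pos[u]
    v = int(rng.choice(idx, p=p)) if len(idx) else None
    if dist.neg[u] is not None:
        nidx, np_ = dist.neg[u]
        negs = [int(x) for x in rng.choice(nidx, size=Q, p=np_)]
    else:
        negs = _uniform_non_neighbors(dist, u, Q, rng)
    return v, negs


def normalize_coverage(graph) -> dict[frozenset, float]:
    """Normalize edge read coverages by the graph-wide maximum, mapping
    them into (0, 1] while preserving ratios."""
    if not graph.edge_coverage:
        return {}
    mx = max(graph.edge_coverage.values())
    return {e: rc / mx for e, rc in graph.edge_coverage.items()}


def edge_loss(z_u, z_v, rc_norm: float, negatives, Q: int | None = None) -> float:
    """Coverage-scaled unsupervised loss for one sampled positive edge.

    ``J = -rc_norm * log s(z_u.z_v) - Q * mean_n log s(-z_u.z_vn)`` with
    ``s`` the logistic sigmoid; logs are clamped at 1e-9. ``z_v`` may be
    None (disconnected contig), in which case only the negative term
    contributes.
    """
    if not 0.0 <= rc_norm <= 1.0:
        raise ValueError(f"rc_norm must lie in [0, 1], got {rc_norm}")
    z_u = np.asarray(z_u, dtype=float)
    if not np.isfinite(z_u).all():
        raise ValueError("non-finite embedding")
    j = 0.0
    if z_v is not None:
        z_v = np.asarray(z_v, dtype=float)
        if not np.isfinite(z_v).all():
            raise ValueError("non-finite embedding")
        j -= rc_norm * math.log(max(sigmoid(float(z_u @ z_v)), _LOG_CLAMP))
    if negatives:
        q = Q if Q is not None else len(negatives)
        terms = []
        for zn in negatives:
            zn = np.asarray(zn, dtype=float)
            if not np.isfinite(zn).all():
                raise ValueError("non-finite embedding")
            terms.append(math.log(max(sigmoid(-float(z_u @ zn)), _LOG_CLAMP)))
        j -= q * float(np.mean(terms))
    return j


def _aggregation_matrix(dist: SamplingDistribution, fanout: int, rng: np.random.Generator) -> sp.csr_matrix:
    """Row-stochastic neighbor-mean matrix over <=fanout sampled neighbors
    per contig; contigs with no neighbors get an all-zero row (their
    aggregate is the zero vector)."""
    rows, cols, vals = [], [], []
    for u in range(dist.n):
        idx, p = dist.pos[u]
        if len(idx) == 0:
            continue
        if len(idx) > fanout:
            chosen = rng.choice(idx, size=fanout, replace=False, p=p)
        else:
            chosen = idx
        w = 1.0 / len(chosen)
        for j in chosen:
            rows.append(u)
            cols.append(int(j))
            vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(dist.n, dist.n))


def sage_layer(h_self: np.ndarray, h_agg: np.ndarray, weight: np.ndarray, bias=None, activate: bool = True) -> np.ndarray:
    """One GraphSAGE layer: activation(W @ [h_self || h_agg]).

    ``h_agg`` is the mean of the sampled neighbors' hidden states (zero
    vector for neighborless contigs). The final layer of the network is
    applied with ``activate=False``.
    """
    cat = np.hstack([np.atleast_2d(h_self), np.atleast_2d(h_agg)])
    if cat.shape[1] != weight.shape[0]:
        raise ValueError(f"dimension mismatch: cat {cat.shape[1]} vs W {weight.shape[0]}")
    out = cat @ weight
    if bias is not None:
        out = out + bias
    return np.maximum(out, 0.0) if activate else out


class _SageNet:
    def __init__(self, input_dim: int, config: GNNConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict = {}
        dims = [input_dim] + [config.hidden_dim] * (config.n_layers - 1) + [config.output_dim]
        for layer in range(config.n_layers):
            dense_init(rng, 2 * dims[layer], dims[layer + 1], f"sage{layer}", self.params)
        self.dims = dims

    def forward(self, h0: np.ndarray, mats: list[sp.csr_matrix]):
        """Returns (embeddings, caches) where caches hold per-layer inputs,
        pre-activations and pre-normalization states for backprop."""
        h = h0
        caches = []
        L = self.config.n_layers
        for layer in range(L):
            agg = mats[layer] @ h
            cat = np.hstack([h, agg])
            z = dense_forward(cat, f"sage{layer}", self.params)
            act = np.maximum(z, 0.0) if layer < L - 1 else z
            if self.config.l2_normalize:
                norms = np.maximum(np.linalg.norm(act, axis=1, keepdims=True), 1e-12)
                out = act / norms
            else:
                norms = None
                out = act
            caches.append((cat, z, out, norms))
            h = out
        return h, caches

    def backward(self, dz_out: np.ndarray, h0: np.ndarray, mats: list[sp.csr_matrix], caches) -> dict:
        grads: dict = {}
        L = self.config.n_layers
        dh = dz_out
        for layer in reversed(range(L)):
            cat, z, out, norms = caches[layer]
            if norms is not None:
                # y = a/||a||  =>  da = (dy - y (y . dy)) / ||a||
                dh = (dh - out * (out * dh).sum(axis=1, keepdims=True)) / norms
            dz = dh if layer == L - 1 else dh * (z > 0)
            dcat = dense_backward(cat, dz, f"sage{layer}", self.params, grads)
            d_in = self.dims[layer]
            dself, dagg = dcat[:, :d_in], dcat[:, d_in:]
            dh = dself + mats[layer].T @ dagg
        return grads


def _epoch_loss_and_grad(z, batch, pos_pairs, neg_lists, rc_norm_of, Q, n_loss_nodes):
    """Loss over a contig batch and its gradient w.r.t. the output
    embeddings z. Mean over all loss-bearing contigs of the epoch."""
    dz = np.zeros_like(z)
    total = 0.0
    inv = 1.0 / n_loss_nodes
    for u in batch:
        zu = z[u]
        v = pos_pairs.get(u)
        if v is not None:
            rc = rc_norm_of[u]
            s = sigmoid(float(zu @ z[v]))
            total -= rc * math.log(max(s, _LOG_CLAMP)) * inv
            coef = -rc * (1.0 - s) * inv
            dz[u] += coef * z[v]
            dz[v] += coef * zu
        negs = neg_lists.get(u, ())
        if len(negs):
            for vn in negs:  # -Q * mean == -sum over the Q draws
                a = float(zu @ z[vn])
                t = sigmoid(-a)
                total -= math.log(max(t, _LOG_CLAMP)) * inv
                coef = sigmoid(a) * inv
                dz[u] += coef * z[vn]
                dz[vn] += coef * zu
    return total, dz


def train_gnn(
    graph,
    init_features: EmbeddingMatrix,
    config: GNNConfig,
    markers=None,
    checkpoint_scorer=None,
):
    """Train the coverage-weighted GraphSAGE model.

    ``init_features`` are the contig-specific (VAE) embeddings, in any
    contig order covering the graph. Per epoch, every connected contig
    contributes one coverage-sampled positive edge plus Q negatives;
    disconnected contigs contribute negative-only terms. Training stops
    early when the loss improves by less than ``early_stop_delta`` for
    ``early_stop_patience`` consecutive epochs.

    Checkpoint selection: when a ``checkpoint_scorer`` (a callable
    mapping a gnn EmbeddingMatrix to a comparable score) or a marker
    table is provided, embeddings are scored every
    ``checkpoint_interval`` epochs and the best-scoring checkpoint is
    returned; otherwise the final epoch's embeddings are returned.

    Returns ``(EmbeddingMatrix('gnn'), info)`` where info holds the loss
    trace, the selected epoch and the per-checkpoint scores.
    """
    if not graph.contig_ids:
        raise ValueError("graph has no contigs")
    ids = list(graph.contig_ids)
    missing = set(ids) - set(init_features.contig_ids)
    if missing:
        raise ValueError(f"init features missing {len(missing)} contigs: {sorted(missing)[:5]}")
    row_of = {c: i for i, c in enumerate(init_features.contig_ids)}
    h0 = init_features.matrix[[row_of[c] for c in ids]]

    rng = np.random.default_rng(config.seed)
    dist = build_sampling(graph)
    rcn = normalize_coverage(graph)
    index = {c: i for i, c in enumerate(ids)}
    rc_norm_pair = {frozenset((index[u], index[v])): w for e, w in rcn.items() for u, v in [sorted(e)]}

    net = _SageNet(h0.shape[1], config, rng)
    opt = Adam(net.params, lr=config.learning_rate)
    n = len(ids)
    batch_size = config.batch_size or min(max(64, n // 4), n) or n

    if checkpoint_scorer is None and markers is not None and markers:
        checkpoint_scorer = _marker_scorer(graph, init_features, markers)

    trace: list[float] = []
    best = None  # (score, epoch, embeddings)
    scores: list[tuple[int, object]] = []
    stall = 0
    epochs_run = 0
    for epoch in range(config.epochs):
        # fresh neighbor sample and edge sample each epoch
        mats = [_aggregation_matrix(dist, f, rng) for f in config.neighbors_per_layer]
        pos_pairs: dict[int, int] = {}
        neg_lists: dict[int, list[int]] = {}
        for u in range(n):
            v, negs = _sample_training_edges(dist, u, config, rng)
            if v is not None:
                pos_pairs[u] = v
            neg_lists[u] = negs
        rc_norm_of = {u: rc_norm_pair.get(frozenset((u, v)), 0.0) for u, v in pos_pairs.items()}

        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            z, caches = net.forward(h0, mats)
            loss, dz = _epoch_loss_and_grad(z, batch, pos_pairs, neg_lists, rc_norm_of, config.Q, n)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf GNN loss at epoch {epoch}")
            grads = net.backward(dz, h0, mats, caches)
            opt.step(grads)
            epoch_loss += loss
        trace.append(epoch_loss)
        epochs_run = epoch + 1

        if checkpoint_scorer is not None and (epoch + 1) % config.checkpoint_interval == 0:
            z, _ = net.forward(h0, mats)
            emb = EmbeddingMatrix(ids, z, "gnn")
            score = checkpoint_scorer(emb)
            scores.append((epoch, score))
            if best is None or score > best[0]:
                best = (score, epoch, emb)

        if config.early_stop_delta is not None and len(trace) >= 2:
            stall = stall + 1 if trace[-2] - trace[-1] < config.early_stop_delta else 0
            if stall >= config.early_stop_patience:
                logger.info("early stop at epoch %d (loss plateau)", epoch)
                break

    final_mats = [_aggregation_matrix(dist, f, rng) for f in config.neighbors_per_layer]
    z, _ = net.forward(h0, final_mats)
    last = EmbeddingMatrix(ids, z, "gnn")
    if best is not None:
        emb, selected = best[2], best[1]
    else:
        emb, selected = last, epochs_run - 1
    info = {"loss_trace": trace, "selected_epoch": selected, "checkpoint_scores": scores}
    return emb, info


def _sample_training_edges(dist, u, config: GNNConfig, rng):
    """Training-time sampling: positives as in :func:`sample_edges`;
    negatives mix inverse-coverage neighbor draws with uniform
    non-neighbor draws.

    Inverse-coverage neighbor negatives are only informative when a
    node's link coverages actually differ — with uniform coverage the
    negative law coincides with the positive law and sampling from it
    just pushes true neighbors apart. The per-node probability of a
    neighbor draw is therefore scaled by the coverage dispersion
    ``1 - min(rc)/max(rc)`` (0 for uniform links), on top of the
    configured random-negative fraction."""
    idx, p = dist.pos[u]
    v = int(rng.choice(idx, p=p)) if len(idx) else None
    negs: list[int] = []
    if dist.neg[u] is not None:
        nidx, np_ = dist.neg[u]
        dispersion = 1.0 - dist.coverage_min_over_max[u]
        p_neighbor = (1.0 - config.random_negative_frac) * dispersion
        for _ in range(config.Q):
            if rng.random() < p_neighbor:
                negs.append(int(rng.choice(nidx, p=np_)))
            else:
                negs.extend(_uniform_non_neighbors(dist, u, 1, rng))
    else:
        negs = _uniform_non_neighbors(dist, u, config.Q, rng)
    return v, negs


def _marker_scorer(graph, vae_embeddings: EmbeddingMatrix, markers):
    """Default checkpoint scorer: cluster the concatenated embeddings and
    count near-complete, low-contamination bins on the marker table."""
    from .clustering import concat_embeddings, iterative_medoid_cluster
    from .evaluation import checkpoint_score, marker_quality

    lengths = graph.contig_length

    def scorer(gnn_emb: EmbeddingMatrix):
        concat = concat_embeddings(vae_embeddings, gnn_emb)
        bins = iterative_medoid_cluster(concat, seed=0)
        quality = marker_quality(bins, markers, lengths)
        return checkpoint_score(quality)

    return scorer
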