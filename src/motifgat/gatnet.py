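"""Three-layer graph-attention network for TFBS classification.

Layer 1 runs single-head graph attention independently in the similarity
and coexisting k-mer subgraphs.  A k-mer's initial embedding is its
neighbor-normalized weight-matrix column

    h(k(x)) = W(:, x) / sum_{y in N(x)} W(x, y),

raw pairwise scores are

    e(x, y) = LeakyReLU( a^T [ W_proj h(x) || W_proj h(y) ] ),

softmax-normalized over N(x) into coefficients alpha(x, y), and the
learned embedding is E(k(x)) = ReLU( sum_y alpha(x, y) W_proj h(y) ).

Layer 2 embeds each sequence z from its inclusive k-mer counts,
h_seq(z) = W_inclu(:, z)^T W_proj_inclu, scores every occurring k-mer by
LeakyReLU of the inner product with its layer-1 embedding, softmax-
normalizes separately per subgraph into beta_sim / beta_co, and aggregates

    E_seq(z) = ReLU( sum_x beta_sim(z,x) E_sim(k(x)) + beta_co(z,x) E_co(k(x)) ).

Layer 3 is a single fully-connected unit with a sigmoid, trained with
binary cross-entropy.

Everything is dense numpy with hand-derived gradients for this fixed
architecture (checked against finite differences in the test suite), a
full-batch Adam loop, inverted dropout on the attention coefficients and
on E_seq, and exponential learning-rate decay.  The graphs this model
targets are small (m <= 4^lenk k-mer nodes), so dense masked attention is
both the simplest and the fastest formulation on a CPU.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import SequenceRecord
from .hetgraph import HeterogeneousGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParameters",
    "TrainConfig",
    "GraphTensors",
    "init_parameters",
    "init_kmer_embedding",
    "kmer_attention_scores",
    "normalize_attention",
    "aggregate_kmer_embedding",
    "init_seq_embedding",
    "seq_attention",
    "aggregate_seq_embedding",
    "predict_tfbs",
    "forward",
    "predict",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.2


@dataclass
class ModelParameters:
    """All learnable tensors; ``d_k`` equals the sequence embedding dimension."""

    a_sim: np.ndarray      # (2 d_k,)
    a_co: np.ndarray       # (2 d_k,)
    Wmat_sim: np.ndarray   # (d_k, m)
    Wmat_co: np.ndarray    # (d_k, m)
    Wmat_inclu: np.ndarray  # (m, d_k)
    clf_w: np.ndarray      # (d_k,)
    clf_b: float = 0.0

    @property
    def d_k(self) -> int:
        return self.Wmat_sim.shape[0]

    @property
    def m(self) -> int:
        return self.Wmat_sim.shape[1]

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "a_sim": self.a_sim, "a_co": self.a_co,
            "Wmat_sim": self.Wmat_sim, "Wmat_co": self.Wmat_co,
            "Wmat_inclu": self.Wmat_inclu, "clf_w": self.clf_w,
        }


@dataclass
class TrainConfig:
    """Optimization settings.

    ``decay`` is the natural (per-epoch exponential) learning-rate decay by
    default: ``lr_t = learning_rate * exp(-decay * t)``.  Setting
    ``decay_mode="weight_decay"`` reinterprets it as additive L2 weight
    decay with a constant learning rate.
    """

    epochs: int = 300
    learning_rate: float = 0.02
    decay: float = 0.001
    dropout: float = 0.3
    lenk: int = 5
    d_k: int = 100
    rng_seed: int = 0
    decay_mode: str = "lr_exp"  # or "weight_decay"
    leaky_slope: float = LEAKY_SLOPE

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError(f"learning_rate={self.learning_rate} outside (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout={self.dropout} outside [0, 1)")
        if self.decay_mode not in ("lr_exp", "weight_decay"):
            raise ValueError(f"unknown decay_mode {self.decay_mode!r}")


def init_parameters(m: int, d_k: int, rng: np.random.Generator) -> ModelParameters:
    """Glorot-style uniform initialization, seeded."""

    def glorot(*shape: int) -> np.ndarray:
        fan = sum(shape) if len(shape) > 1 else shape[0] + 1
        limit = np.sqrt(6.0 / fan)
        return rng.uniform(-limit, limit, size=shape)

    return ModelParameters(
        a_sim=glorot(2 * d_k),
        a_co=glorot(2 * d_k),
        Wmat_sim=glorot(d_k, m),
        Wmat_co=glorot(d_k, m),
        Wmat_inclu=glorot(m, d_k),
        clf_w=glorot(d_k),
        clf_b=0.0,
    )


# ---------------------------------------------------------------------------
# dense graph views

@dataclass
class GraphTensors:
    """Dense arrays the network consumes, derived once from a graph.

    ``H_*`` holds the initial k-mer embeddings as columns; ``A_*`` are the
    boolean adjacency masks used by the masked softmax (isolated k-mers
    receive a unit self-loop so their embedding and attention row stay
    defined); ``X`` is the m×n inclusive count matrix and ``M`` its n×m
    occurrence mask; ``labels`` the per-sequence class.
    """

    H_sim: np.ndarray
    H_co: np.ndarray
    A_sim: np.ndarray
    A_co: np.ndarray
    X: np.ndarray
    M: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_graph(cls, graph: HeterogeneousGraph) -> "GraphTensors":
        H_sim, A_sim = _normalized_columns(graph.W_sim.toarray())
        H_co, A_co = _normalized_columns(graph.W_co.toarray())
        X = graph.W_inclu.toarray()
        return cls(
            H_sim=H_sim, H_co=H_co, A_sim=A_sim, A_co=A_co,
            X=X, M=(X.T > 0),
            labels=np.array([r.label for r in graph.sequences], dtype=float),
        )


def _normalized_columns(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-normalize a symmetric weight matrix; self-loop isolated nodes."""
    m = W.shape[0]
    A = W > 0
    np.fill_diagonal(A, False)
    H = np.array(W, dtype=float)
    colsum = H.sum(axis=0)
    isolated = colsum == 0
    if isolated.any():
        logger.info("self-looping %d isolated k-mer node(s)", int(isolated.sum()))
        idx = np.where(isolated)[0]
        H[idx, idx] = 1.0
        A[idx, idx] = True
        colsum = H.sum(axis=0)
    return H / colsum, A


# ---------------------------------------------------------------------------
# elementary layer operations (the readable, per-node forms)

def _leaky(x: np.ndarray | float, slope: float = LEAKY_SLOPE):
    return np.where(np.asarray(x) > 0, x, slope * np.asarray(x))


def init_kmer_embedding(graph: HeterogeneousGraph, subgraph_tag: str) -> np.ndarray:
    """Initial k-mer embeddings for one subgraph, as the columns of an m×m matrix.

    Column x is the subgraph weight column of k-mer x divided by the total
    weight of its neighborhood, so its entries sum to 1 over the neighbor
    support.  Isolated k-mers fall back to a unit self-loop.
    """
    if subgraph_tag == "similarity":
        W = graph.W_sim
    elif subgraph_tag == "coexisting":
        W = graph.W_co
    else:
        raise ValueError(f"unknown subgraph tag {subgraph_tag!r}")
    H, _ = _normalized_columns(W.toarray())
    return H


def kmer_attention_scores(
    params: ModelParameters,
    H: np.ndarray,
    x: int,
    y: int,
    subgraph_tag: str,
    slope: float = LEAKY_SLOPE,
) -> float:
    """Raw attention score e(x, y) = LeakyReLU(a^T [W h(x) || W h(y)])."""
    a, W = (
        (params.a_sim, params.Wmat_sim)
        if subgraph_tag == "similarity"
        else (params.a_co, params.Wmat_co)
    )
    px = W @ H[:, x]
    py = W @ H[:, y]
    if a.shape[0] != px.shape[0] + py.shape[0]:
        raise ValueError("attention vector length does not match 2*d_k")
    return float(_leaky(a[: params.d_k] @ px + a[params.d_k:] @ py, slope))


def normalize_attention(scores: np.ndarray) -> np.ndarray:
    """Softmax over a node's neighbor scores; sums to 1 and preserves order."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot normalize over an empty neighbor set")
    shifted = scores - scores.max()
    e = np.exp(shifted)
    return e / e.sum()


def aggregate_kmer_embedding(
    params: ModelParameters,
    H: np.ndarray,
    alpha: np.ndarray,
    neighbor_ids: Sequence[int],
    subgraph_tag: str,
) -> np.ndarray:
    """E(k(x)) = ReLU(sum_y alpha(x,y) W h(y)) over the neighbor set."""
    W = params.Wmat_sim if subgraph_tag == "similarity" else params.Wmat_co
    acc = np.zeros(params.d_k)
    for a_xy, y in zip(alpha, neighbor_ids):
        acc += a_xy * (W @ H[:, y])
    return np.maximum(acc, 0.0)


def init_seq_embedding(graph: HeterogeneousGraph, params: ModelParameters, z: int) -> np.ndarray:
    """h_seq(z) = W_inclu(:, z)^T W_proj — the projected inclusive count column."""
    col = np.asarray(graph.W_inclu[:, z].todense()).ravel()
    return col @ params.Wmat_inclu


def seq_attention(
    params: ModelParameters,
    h_seq_z: np.ndarray,
    E_sim: np.ndarray,
    E_co: np.ndarray,
    neighbor_ids: Sequence[int],
    slope: float = LEAKY_SLOPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive attention rows (beta_sim, beta_co) over a sequence's k-mers.

    Raw scores are LeakyReLU of the inner product between the sequence
    embedding and each k-mer's layer-1 embedding; each row is softmax-
    normalized separately.
    """
    ids = list(neighbor_ids)
    if not ids:
        raise ValueError("sequence has no k-mer neighbors")
    b_sim = _leaky(E_sim[ids] @ h_seq_z, slope)
    b_co = _leaky(E_co[ids] @ h_seq_z, slope)
    return normalize_attention(b_sim), normalize_attention(b_co)


def aggregate_seq_embedding(
    beta_sim: np.ndarray,
    beta_co: np.ndarray,
    E_sim: np.ndarray,
    E_co: np.ndarray,
    neighbor_ids: Sequence[int],
) -> np.ndarray:
    """E_seq(z) = ReLU(sum_x beta_sim E_sim(k(x)) + beta_co E_co(k(x)))."""
    ids = list(neighbor_ids)
    pre = beta_sim @ E_sim[ids] + beta_co @ E_co[ids]
    return np.maximum(pre, 0.0)


def predict_tfbs(params: ModelParameters, E_seq_z: np.ndarray) -> float:
    """Sigmoid probability that the sequence contains a TFBS."""
    logit = float(params.clf_w @ E_seq_z + params.clf_b)
    return float(1.0 / (1.0 + np.exp(-logit)))


# ---------------------------------------------------------------------------
# vectorized forward / backward

def _masked_softmax(S: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax restricted to ``mask``; masked-out entries are 0."""
    neg = np.where(mask, S, -np.inf)
    shifted = neg - neg.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _dropout_mask(shape: tuple, p: float, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(shape) >= p) / (1.0 - p)


def forward(
    params: ModelParameters,
    gt: GraphTensors,
    X: np.ndarray | None = None,
    M: np.ndarray | None = None,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    slope: float = LEAKY_SLOPE,
) -> dict:
    """Full forward pass; returns a cache of all intermediates.

    ``X``/``M`` default to the graph's own sequences; passing the inclusive
    count matrix of held-out sequences scores them against the k-mer
    embeddings learned on the training graph.  With ``dropout > 0`` (and an
    rng) inverted dropout is applied to the attention coefficient rows and
    to the sequence embeddings.
    """
    X = gt.X if X is None else X
    M = gt.M if M is None else M
    cache: dict = {"X": X, "M": M, "slope": slope, "dropout": dropout}
    for tag, H, A, W, a in (
        ("sim", gt.H_sim, gt.A_sim, params.Wmat_sim, params.a_sim),
        ("co", gt.H_co, gt.A_co, params.Wmat_co, params.a_co),
    ):
        d = params.d_k
        P = W @ H                          # (d, m): projected initial embeddings
        u = a[:d] @ P                      # source-side score component
        v = a[d:] @ P                      # target-side score component
        S = u[:, None] + v[None, :]
        E_raw = _leaky(S, slope)
        alpha = _masked_softmax(E_raw, A)
        if dropout > 0.0:
            D_alpha = _dropout_mask(alpha.shape, dropout, rng)
            alpha_d = alpha * D_alpha
        else:
            D_alpha = None
            alpha_d = alpha
        Z = alpha_d @ P.T                  # (m, d)
        E = np.maximum(Z, 0.0)
        cache[tag] = {
            "P": P, "S": S, "alpha": alpha, "D_alpha": D_alpha,
            "alpha_d": alpha_d, "Z": Z, "E": E,
        }
    Hseq = X.T @ params.Wmat_inclu         # (n, d)
    cache["Hseq"] = Hseq
    for tag in ("sim", "co"):
        E = cache[tag]["E"]
        B_pre = Hseq @ E.T                 # (n, m) inner products
        B_raw = _leaky(B_pre, slope)
        beta = _masked_softmax(B_raw, M)
        if dropout > 0.0:
            D_beta = _dropout_mask(beta.shape, dropout, rng)
            beta_d = beta * D_beta
        else:
            D_beta = None
            beta_d = beta
        cache[tag].update(B_pre=B_pre, beta=beta, D_beta=D_beta, beta_d=beta_d)
    S_pre = cache["sim"]["beta_d"] @ cache["sim"]["E"] + cache["co"]["beta_d"] @ cache["co"]["E"]
    E_seq = np.maximum(S_pre, 0.0)
    if dropout > 0.0:
        D_eseq = _dropout_mask(E_seq.shape, dropout, rng)
        E_seq_d = E_seq * D_eseq
    else:
        D_eseq = None
        E_seq_d = E_seq
    logit = E_seq_d @ params.clf_w + params.clf_b
    prob = 1.0 / (1.0 + np.exp(-logit))
    cache.update(S_pre=S_pre, E_seq=E_seq, D_eseq=D_eseq, E_seq_d=E_seq_d,
                 logit=logit, prob=prob)
    return cache


def bce_loss(prob: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def backward(
    params: ModelParameters,
    gt: GraphTensors,
    cache: dict,
    labels: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of mean binary cross-entropy w.r.t. every parameter tensor."""
    slope = cache["slope"]
    X, M = cache["X"], cache["M"]
    n = labels.shape[0]
    d = params.d_k

    dlogit = (cache["prob"] - labels) / n
    g_clf_w = cache["E_seq_d"].T @ dlogit
    g_clf_b = float(dlogit.sum())
    dE_seq_d = np.outer(dlogit, params.clf_w)
    dE_seq = dE_seq_d if cache["D_eseq"] is None else dE_seq_d * cache["D_eseq"]
    dS_pre = dE_seq * (cache["S_pre"] > 0)

    grads: dict[str, np.ndarray] = {
        "clf_w": g_clf_w, "clf_b": np.asarray(g_clf_b),
    }
    dHseq = np.zeros_like(cache["Hseq"])
    dE_total: dict[str, np.ndarray] = {}
    for tag in ("sim", "co"):
        c = cache[tag]
        dbeta_d = dS_pre @ c["E"].T                       # (n, m)
        dE_from_agg = c["beta_d"].T @ dS_pre              # (m, d)
        dbeta = dbeta_d if c["D_beta"] is None else dbeta_d * c["D_beta"]
        # softmax rows: dB_raw = beta * (dbeta - sum(dbeta * beta))
        row_dot = (dbeta * c["beta"]).sum(axis=1, keepdims=True)
        dB_raw = c["beta"] * (dbeta - row_dot)
        dB_pre = dB_raw * np.where(c["B_pre"] > 0, 1.0, slope)
        dB_pre = np.where(M, dB_pre, 0.0)
        dHseq += dB_pre @ c["E"]
        dE_total[tag] = dE_from_agg + dB_pre.T @ cache["Hseq"]

    grads["Wmat_inclu"] = X @ dHseq

    for tag, H, A, W, a in (
        ("sim", gt.H_sim, gt.A_sim, params.Wmat_sim, params.a_sim),
        ("co", gt.H_co, gt.A_co, params.Wmat_co, params.a_co),
    ):
        c = cache[tag]
        dZ = dE_total[tag] * (c["Z"] > 0)
        dalpha_d = dZ @ c["P"]                            # (m, m)
        dP = (c["alpha_d"].T @ dZ).T                      # (d, m)
        dalpha = dalpha_d if c["D_alpha"] is None else dalpha_d * c["D_alpha"]
        row_dot = (dalpha * c["alpha"]).sum(axis=1, keepdims=True)
        dE_raw = c["alpha"] * (dalpha - row_dot)
        dS = dE_raw * np.where(c["S"] > 0, 1.0, slope)
        dS = np.where(A, dS, 0.0)
        du = dS.sum(axis=1)
        dv = dS.sum(axis=0)
        dP += a[:d, None] * du[None, :] + a[d:, None] * dv[None, :]
        grads[f"a_{tag}"] = np.concatenate([c["P"] @ du, c["P"] @ dv])
        grads[f"Wmat_{tag}"] = dP @ H.T
    return grads


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, shapes: dict[str, tuple], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def inclusive_counts(
    graph: HeterogeneousGraph, records: Sequence[SequenceRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive count matrix (m×n) of arbitrary records against a graph's vocabulary.

    K-mers absent from the training vocabulary are ignored; a record whose
    k-mers are all unseen yields an empty column (scored 0.5 downstream).
    """
    vocab = graph.vocab
    lenk = vocab.lenk
    X = np.zeros((len(vocab), len(records)))
    for z, rec in enumerate(records):
        seq = rec.sequence
        for i in range(len(seq) - lenk + 1):
            kid = vocab.index.get(seq[i : i + lenk])
            if kid is not None:
                X[kid, z] += 1.0
    return X, (X.T > 0)


def predict(
    params: ModelParameters,
    graph: HeterogeneousGraph,
    records: Sequence[SequenceRecord] | None = None,
    gt: GraphTensors | None = None,
) -> np.ndarray:
    """Binding probabilities for records (default: the graph's own sequences)."""
    gt = GraphTensors.from_graph(graph) if gt is None else gt
    if records is None:
        cache = forward(params, gt)
        return cache["prob"]
    X, M = inclusive_counts(graph, records)
    empty = ~M.any(axis=1)
    if empty.any():
        logger.warning("%d sequence(s) share no k-mer with the training vocabulary", int(empty.sum()))
        M = M.copy()
        M[empty, 0] = True  # dummy neighbor; embedding contribution is weighted by beta over zero counts
    cache = forward(params, gt, X=X, M=M)
    prob = cache["prob"]
    if empty.any():
        prob = prob.copy()
        prob[empty] = 0.5
    return prob


def _f1_at_half(labels: np.ndarray, prob: np.ndarray) -> float:
    pred = prob >= 0.5
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def train(
    graph: HeterogeneousGraph,
    config: TrainConfig,
    validation: Sequence[SequenceRecord] | None = None,
) -> tuple[ModelParameters, list[dict]]:
    """Full-batch Adam training on the graph's sequences.

    Returns the parameters of the epoch with the best validation F1 (the
    final parameters when no validation set is given) together with the
    per-epoch history of loss, learning rate and validation metrics.
    Deterministic for a fixed ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    gt = GraphTensors.from_graph(graph)
    params = init_parameters(graph.m, config.d_k, rng)
    if config.epochs == 0:
        return params, []
    labels = gt.labels
    pdict = params.arrays()
    opt = _Adam({k: v.shape for k, v in pdict.items()} | {"clf_b": ()})
    history: list[dict] = []
    best_f1 = -1.0
    best_params = params.copy()
    X_val = M_val = val_labels = None
    if validation:
        X_val, M_val = inclusive_counts(graph, validation)
        val_labels = np.array([r.label for r in validation], dtype=float)

    b_store = np.asarray(params.clf_b, dtype=float)
    for epoch in range(config.epochs):
        cache = forward(params, gt, dropout=config.dropout, rng=rng,
                        slope=config.leaky_slope)
        loss = bce_loss(cache["prob"], labels)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
        grads = backward(params, gt, cache, labels)
        if config.decay_mode == "weight_decay":
            lr = config.learning_rate
            for k, v in pdict.items():
                grads[k] = grads[k] + config.decay * v
        else:
            lr = config.learning_rate * np.exp(-config.decay * epoch)
        full = dict(pdict)
        full["clf_b"] = b_store
        opt.step(full, grads, lr)
        params.clf_b = float(b_store)

        entry = {"epoch": epoch, "lr": float(lr), "train_loss": loss}
        if validation:
            val_cache = forward(params, gt, X=X_val, M=M_val, slope=config.leaky_slope)
            entry["val_f1"] = _f1_at_half(val_labels, val_cache["prob"])
            entry["val_acc"] = float(np.mean((val_cache["prob"] >= 0.5) == (val_labels == 1)))
            if entry["val_f1"] > best_f1:
                best_f1 = entry["val_f1"]
                best_params = params.copy()
        history.append(entry)
    if validation:
        logger.info("best validation F1 %.4f", best_f1)
        return best_params, history
    return params, history


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(params: ModelParameters, graph: HeterogeneousGraph, path: str | Path,
                    config: TrainConfig | None = None) -> None:
    """Save parameters plus the vocabulary needed to rebind them to data."""
    path = Path(path)
    arrays = {k: v for k, v in params.arrays().items()}
    arrays["clf_b"] = np.asarray(params.clf_b)
    arrays["kmers"] = np.asarray(graph.vocab.kmers)
    arrays["lenk"] = np.asarray(graph.vocab.lenk)
    if config is not None:
        import json

        arrays["config_json"] = np.asarray(json.dumps(vars(config)))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParameters, list[str], int]:
    """Load parameters; returns (params, kmer list, lenk)."""
    data = np.load(path, allow_pickle=False)
    params = ModelParameters(
        a_sim=data["a_sim"], a_co=data["a_co"],
        Wmat_sim=data["Wmat_sim"], Wmat_co=data["Wmat_co"],
        Wmat_inclu=data["Wmat_inclu"], clf_w=data["clf_w"],
        clf_b=float(data["clf_b"]),
    )
    return params, [str(k) for k in data["kmers"]], int(data["lenk"])
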