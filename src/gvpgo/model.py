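"""The GO-term predictor: GVP-GNN encoder, label-query transformer decoder.

Per residue, five embedded feature streams — amino-acid tokens, backbone
torsions, pLDDT, the precomputed sequence embedding, and (through the GVP
layers) the geometric edge/orientation features — are summed into a
d_model-dimensional representation. The GVP graph layers mix scalar and
vector channels over the kNN graph; only their rotation-invariant scalar
output feeds the transformer encoder, so the final predictions are
invariant under rigid motions of the input structure. The decoder carries
one learned query vector per candidate GO term: each layer applies
self-attention over the queries (modelling term co-occurrence),
cross-attention against the encoder output, and a feed-forward block; a
linear map plus logistic head yields one confidence per term. No
attention mask is used anywhere. Training minimizes a positively
reweighted binary cross-entropy (weight 3.0 on positive labels by
default) with Adam.

The model is exposed as the scikit-learn-style estimator
:class:`GvpGoClassifier` (fit / predict_proba / get_params); the
module-level ``train`` / ``predict`` / ``permutation_importance``
functions are thin wrappers over it.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Adam, Tensor, concat, layer_norm, softmax
from .geometry import FeatureBundle, apply_plddt_mask, featurize, rbf_encode
from .go_graph import AnnotationSet, GoDag, PredictionSet, propagate_predictions
from .gvp import GvpConvLayer, GvpParams, gvp_forward, gvp_stack_forward
from .structure_io import ProteinStructure, UNKNOWN_TOKEN

__all__ = [
    "ModelConfig",
    "GvpGoClassifier",
    "embed_and_sum",
    "weighted_bce_loss",
    "train",
    "predict",
    "permutation_importance",
    "permute_feature",
    "save_checkpoint",
    "load_checkpoint",
]

FEATURE_NAMES = (
    "esm", "token", "dihedral", "distance",
    "edge_vector", "orientation_vector", "plddt", "sidechain_vector",
)

_N_ORIENT_CHANNELS = 6   # forward + backward for N, CA, C
_N_SIDECHAIN_CHANNELS = 2
_DIHEDRAL_DIM = 9        # sin/cos of phi, psi, omega + 3 defined flags


@dataclass
class ModelConfig:
    """Hyperparameters. ``d_model`` must be divisible by ``n_heads``."""

    d_model: int = 128
    n_heads: int = 8
    n_gvp_layers: int = 2
    n_encoder_layers: int = 4
    n_decoder_layers: int = 2
    n_vector_channels: int = 16
    d_ff: int = 0                 # 0 -> 2 * d_model
    n_rbf: int = 16
    k_neighbors: int = 30
    plddt_threshold: float = 0.9
    pos_weight: float = 3.0
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 30
    patience: int = 5
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("n_gvp_layers", "n_encoder_layers", "n_decoder_layers", "n_heads", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pos_weight <= 0:
            raise ValueError("pos_weight must be positive")
        if self.d_ff == 0:
            self.d_ff = 2 * self.d_model


# -- parameter container ------------------------------------------------------


@dataclass
class _AttnBlock:
    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]


@dataclass
class _EncoderLayer:
    attn: _AttnBlock
    ln1_g: Tensor
    ln1_b: Tensor
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    ln2_g: Tensor
    ln2_b: Tensor

    def tensors(self) -> list[Tensor]:
        return self.attn.tensors() + [self.ln1_g, self.ln1_b, self.W1, self.b1,
                                      self.W2, self.b2, self.ln2_g, self.ln2_b]


@dataclass
class _DecoderLayer:
    self_attn: _AttnBlock
    ln1_g: Tensor
    ln1_b: Tensor
    cross_attn: _AttnBlock
    ln2_g: Tensor
    ln2_b: Tensor
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    ln3_g: Tensor
    ln3_b: Tensor

    def tensors(self) -> list[Tensor]:
        return (self.self_attn.tensors() + [self.ln1_g, self.ln1_b]
                + self.cross_attn.tensors() + [self.ln2_g, self.ln2_b]
                + [self.W1, self.b1, self.W2, self.b2, self.ln3_g, self.ln3_b])


@dataclass
class ModelParams:
    """All learned tensors; ``named_tensors`` flattens them for checkpoints."""

    token_table: Tensor
    dihedral_W: Tensor
    dihedral_b: Tensor
    plddt_W: Tensor
    plddt_b: Tensor
    esm_W: Tensor
    esm_b: Tensor
    gvp_in: GvpParams
    gvp_layers: list[GvpConvLayer]
    encoder: list[_EncoderLayer]
    query_table: Tensor
    decoder: list[_DecoderLayer]
    out_w: Tensor
    out_b: Tensor

    def all_tensors(self) -> list[Tensor]:
        out = [self.token_table, self.dihedral_W, self.dihedral_b, self.plddt_W,
               self.plddt_b, self.esm_W, self.esm_b]
        out += self.gvp_in.tensors()
        for layer in self.gvp_layers:
            out += layer.tensors()
        for layer in self.encoder:
            out += layer.tensors()
        out.append(self.query_table)
        for layer in self.decoder:
            out += layer.tensors()
        out += [self.out_w, self.out_b]
        return out

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.all_tensors()))

    def named_tensors(self) -> dict[str, Tensor]:
        names: dict[str, Tensor] = {}

        def add(prefix: str, obj) -> None:
            if isinstance(obj, Tensor):
                names[prefix] = obj
            elif isinstance(obj, GvpParams):
                for f in ("W_h", "W_mu", "W_m", "b_m"):
                    names[f"{prefix}.{f}"] = getattr(obj, f)
            elif isinstance(obj, GvpConvLayer):
                add(f"{prefix}.message", obj.message)
                add(f"{prefix}.update", obj.update)
                for f in ("ln_gain", "ln_bias", "ln_gain2", "ln_bias2"):
                    names[f"{prefix}.{f}"] = getattr(obj, f)
            elif isinstance(obj, (_EncoderLayer, _DecoderLayer, _AttnBlock)):
                for f in obj.__dataclass_fields__:
                    add(f"{prefix}.{f}", getattr(obj, f))
            else:
                raise TypeError(type(obj))

        for f in ("token_table", "dihedral_W", "dihedral_b", "plddt_W", "plddt_b",
                  "esm_W", "esm_b", "gvp_in", "query_table", "out_w", "out_b"):
            add(f, getattr(self, f))
        for i, layer in enumerate(self.gvp_layers):
            add(f"gvp_layers.{i}", layer)
        for i, layer in enumerate(self.encoder):
            add(f"encoder.{i}", layer)
        for i, layer in enumerate(self.decoder):
            add(f"decoder.{i}", layer)
        return names


def _init_attn(rng: np.random.Generator, d: int) -> _AttnBlock:
    s = 1.0 / np.sqrt(d)
    mk = lambda: Tensor(rng.normal(0, s, size=(d, d)), requires_grad=True)
    return _AttnBlock(mk(), mk(), mk(), mk())


def _init_params(rng: np.random.Generator, config: ModelConfig, d_emb: int, n_terms: int) -> ModelParams:
    d, dff = config.d_model, config.d_ff
    s = 1.0 / np.sqrt(d)

    def lin(n_in, n_out):
        return (Tensor(rng.normal(0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out)), requires_grad=True),
                Tensor(np.zeros(n_out), requires_grad=True))

    dihedral_W, dihedral_b = lin(_DIHEDRAL_DIM, d)
    plddt_W, plddt_b = lin(1, d)
    esm_W, esm_b = lin(d_emb, d)
    n_vec_in = _N_ORIENT_CHANNELS + _N_SIDECHAIN_CHANNELS
    encoder = []
    for _ in range(config.n_encoder_layers):
        W1, b1 = lin(d, dff)
        W2, b2 = lin(dff, d)
        encoder.append(_EncoderLayer(
            attn=_init_attn(rng, d),
            ln1_g=Tensor(np.ones(d), requires_grad=True), ln1_b=Tensor(np.zeros(d), requires_grad=True),
            W1=W1, b1=b1, W2=W2, b2=b2,
            ln2_g=Tensor(np.ones(d), requires_grad=True), ln2_b=Tensor(np.zeros(d), requires_grad=True),
        ))
    decoder = []
    for _ in range(config.n_decoder_layers):
        W1, b1 = lin(d, dff)
        W2, b2 = lin(dff, d)
        decoder.append(_DecoderLayer(
            self_attn=_init_attn(rng, d),
            ln1_g=Tensor(np.ones(d), requires_grad=True), ln1_b=Tensor(np.zeros(d), requires_grad=True),
            cross_attn=_init_attn(rng, d),
            ln2_g=Tensor(np.ones(d), requires_grad=True), ln2_b=Tensor(np.zeros(d), requires_grad=True),
            W1=W1, b1=b1, W2=W2, b2=b2,
            ln3_g=Tensor(np.ones(d), requires_grad=True), ln3_b=Tensor(np.zeros(d), requires_grad=True),
        ))
    return ModelParams(
        token_table=Tensor(rng.normal(0, s, size=(UNKNOWN_TOKEN + 1, d)), requires_grad=True),
        dihedral_W=dihedral_W, dihedral_b=dihedral_b,
        plddt_W=plddt_W, plddt_b=plddt_b,
        esm_W=esm_W, esm_b=esm_b,
        gvp_in=GvpParams.init(rng, n_in=d, v_in=n_vec_in, n_out=d, v_out=config.n_vector_channels),
        gvp_layers=[
            GvpConvLayer.init(rng, ns=d, nv=config.n_vector_channels, es=config.n_rbf, ev=1)
            for _ in range(config.n_gvp_layers)
        ],
        encoder=encoder,
        query_table=Tensor(rng.normal(0, s, size=(n_terms, d)), requires_grad=True),
        decoder=decoder,
        out_w=Tensor(rng.normal(0, s, size=(d,)), requires_grad=True),
        out_b=Tensor(np.zeros(()), requires_grad=True),
    )


# -- forward pieces -----------------------------------------------------------


def _dihedral_features(bundle: FeatureBundle) -> np.ndarray:
    flags = bundle.dihedral_defined.astype(float)
    sin = np.sin(bundle.dihedrals) * flags
    cos = np.cos(bundle.dihedrals) * flags
    return np.concatenate([sin, cos, flags], axis=1)


def embed_and_sum(bundle: FeatureBundle, params: ModelParams) -> Tensor:
    """Element-wise sum of the token, dihedral, pLDDT and sequence-embedding streams."""
    if bundle.seq_embedding is None:
        raise ValueError("missing feature stream: seq_embedding")
    if bundle.seq_embedding.shape[1] != params.esm_W.shape[0]:
        raise ValueError(
            f"sequence-embedding dimension {bundle.seq_embedding.shape[1]} does not match "
            f"model ({params.esm_W.shape[0]})"
        )
    tok = params.token_table[bundle.tokens]
    dih = Tensor(_dihedral_features(bundle)) @ params.dihedral_W + params.dihedral_b
    pl = Tensor(bundle.plddt[:, None]) @ params.plddt_W + params.plddt_b
    esm = Tensor(bundle.seq_embedding) @ params.esm_W + params.esm_b
    return tok + dih + pl + esm


def _mha(x_q: Tensor, x_kv: Tensor, block: _AttnBlock, n_heads: int) -> Tensor:
    Lq, d = x_q.shape
    Lk = x_kv.shape[0]
    dh = d // n_heads
    q = (x_q @ block.Wq).reshape(Lq, n_heads, dh).swapaxes(0, 1)
    k = (x_kv @ block.Wk).reshape(Lk, n_heads, dh).swapaxes(0, 1)
    v = (x_kv @ block.Wv).reshape(Lk, n_heads, dh).swapaxes(0, 1)
    scores = (q @ k.T) * (1.0 / np.sqrt(dh))
    attn = softmax(scores, axis=-1)
    out = (attn @ v).swapaxes(0, 1).reshape(Lq, d)
    return out @ block.Wo


def _ffn(x: Tensor, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor) -> Tensor:
    return (x @ W1 + b1).relu() @ W2 + b2


def _encode(bundle: FeatureBundle, params: ModelParams, config: ModelConfig) -> Tensor:
    """Per-residue context states: GVP stack output summed with the embedding sum."""
    if bundle.n_residues == 0:
        raise ValueError("empty protein")
    node_s = embed_and_sum(bundle, params)
    vec = np.concatenate([
        bundle.orientation_forward,
        bundle.orientation_backward,
        bundle.sidechain_vectors,
    ], axis=1)  # (L, 8, 3)
    s0, v0 = gvp_forward(node_s, Tensor(vec), params.gvp_in)
    edge_s = Tensor(rbf_encode(bundle.edge_distance, n_centers=config.n_rbf))
    edge_v = Tensor(bundle.edge_vector[:, None, :])
    s, _ = gvp_stack_forward(params.gvp_layers, s0, v0, bundle.edges, edge_s, edge_v)
    x = s + node_s
    for layer in params.encoder:
        x = layer_norm(x + _mha(x, x, layer.attn, config.n_heads), layer.ln1_g, layer.ln1_b)
        x = layer_norm(x + _ffn(x, layer.W1, layer.b1, layer.W2, layer.b2), layer.ln2_g, layer.ln2_b)
    return x


def _decode(context: Tensor, params: ModelParams, config: ModelConfig) -> Tensor:
    """Confidences over the candidate terms from the encoder context."""
    if params.query_table.shape[0] == 0:
        raise ValueError("zero candidate terms")
    q = params.query_table
    for layer in params.decoder:
        q = layer_norm(q + _mha(q, q, layer.self_attn, config.n_heads), layer.ln1_g, layer.ln1_b)
        q = layer_norm(q + _mha(q, context, layer.cross_attn, config.n_heads), layer.ln2_g, layer.ln2_b)
        q = layer_norm(q + _ffn(q, layer.W1, layer.b1, layer.W2, layer.b2), layer.ln3_g, layer.ln3_b)
    logits = q @ params.out_w + params.out_b
    return logits.sigmoid()


def weighted_bce_loss(pred: Tensor | np.ndarray, labels: np.ndarray, pos_weight: float = 3.0) -> Tensor:
    """Mean over terms of -[w * y * ln(p) + (1 - y) * ln(1 - p)].

    Predictions exactly at 0 or 1 are clamped to [1e-7, 1 - 1e-7] with a warning.
    """
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    if np.any((p.data <= 0.0) | (p.data >= 1.0)):
        warnings.warn("predictions at 0 or 1 clamped to [1e-7, 1 - 1e-7]", stacklevel=2)
    p = p.clip(1e-7, 1.0 - 1e-7)
    loss = -(pos_weight * y * p.log() + (1.0 - y) * (1.0 - p).log())
    return loss.mean()


# -- feature permutation ------------------------------------------------------


def permute_feature(bundles: list[FeatureBundle], feature_name: str, seed: int) -> list[FeatureBundle]:
    """Shuffle one feature's values across all residues (or edges) of the set.

    The pooled shuffle preserves the marginal value distribution while
    destroying the protein-to-feature association, mirroring residue-level
    permutation importance. Bundles should be unmasked; masking is applied
    downstream so a permuted pLDDT stream also permutes the mask.
    """
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}; expected one of {FEATURE_NAMES}")
    rng = np.random.default_rng(seed)
    out = [copy.deepcopy(b) for b in bundles]

    def pooled(get, set_):
        values = np.concatenate([get(b) for b in out], axis=0)
        perm = rng.permutation(len(values))
        values = values[perm]
        ofs = 0
        for b in out:
            n = len(get(b))
            set_(b, values[ofs:ofs + n])
            ofs += n

    if feature_name == "esm":
        pooled(lambda b: b.seq_embedding, lambda b, v: setattr(b, "seq_embedding", v))
    elif feature_name == "token":
        pooled(lambda b: b.tokens, lambda b, v: setattr(b, "tokens", v))
    elif feature_name == "plddt":
        pooled(lambda b: b.plddt, lambda b, v: setattr(b, "plddt", v))
    elif feature_name == "dihedral":
        stacked = lambda b: np.concatenate([b.dihedrals, b.dihedral_defined.astype(float)], axis=1)

        def set_dih(b, v):
            b.dihedrals = v[:, :3]
            b.dihedral_defined = v[:, 3:].astype(bool)

        pooled(stacked, set_dih)
    elif feature_name == "distance":
        pooled(lambda b: b.edge_distance, lambda b, v: setattr(b, "edge_distance", v))
    elif feature_name == "edge_vector":
        pooled(lambda b: b.edge_vector, lambda b, v: setattr(b, "edge_vector", v))
    elif feature_name == "orientation_vector":
        stacked = lambda b: np.concatenate(
            [b.orientation_forward.reshape(len(b.plddt), -1),
             b.orientation_backward.reshape(len(b.plddt), -1),
             b.orientation_defined.astype(float)], axis=1)

        def set_orient(b, v):
            L = len(b.plddt)
            b.orientation_forward = v[:, :9].reshape(L, 3, 3)
            b.orientation_backward = v[:, 9:18].reshape(L, 3, 3)
            b.orientation_defined = v[:, 18:].astype(bool)

        pooled(stacked, set_orient)
    elif feature_name == "sidechain_vector":
        stacked = lambda b: b.sidechain_vectors.reshape(len(b.plddt), -1)

        def set_sc(b, v):
            b.sidechain_vectors = v.reshape(len(b.plddt), 2, 3)

        pooled(stacked, set_sc)
    return out


# -- the estimator ------------------------------------------------------------


class GvpGoClassifier(BaseEstimator):
    """Multi-label GO-term classifier over protein structures (scikit-learn style).

    Parameters mirror :class:`ModelConfig`. ``fit`` consumes a list of
    unmasked :class:`FeatureBundle` and a binary label matrix aligned with
    ``terms``; ``predict_proba`` returns per-term confidences in [0, 1].
    """

    def __init__(self, d_model: int = 128, n_heads: int = 8, n_gvp_layers: int = 2,
                 n_encoder_layers: int = 4, n_decoder_layers: int = 2,
                 n_vector_channels: int = 16, d_ff: int = 0, n_rbf: int = 16,
                 k_neighbors: int = 30, plddt_threshold: float = 0.9,
                 pos_weight: float = 3.0, learning_rate: float = 1e-4,
                 batch_size: int = 8, max_epochs: int = 30, patience: int = 5,
                 grad_clip: float = 1.0, seed: int = 0, warm_start: bool = False):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_gvp_layers = n_gvp_layers
        self.n_encoder_layers = n_encoder_layers
        self.n_decoder_layers = n_decoder_layers
        self.n_vector_channels = n_vector_channels
        self.d_ff = d_ff
        self.n_rbf = n_rbf
        self.k_neighbors = k_neighbors
        self.plddt_threshold = plddt_threshold
        self.pos_weight = pos_weight
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.grad_clip = grad_clip
        self.seed = seed
        self.warm_start = warm_start

    # -- configuration plumbing ----------------------------------------------
    def config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in ModelConfig.__dataclass_fields__})

    @classmethod
    def from_config(cls, config: ModelConfig) -> "GvpGoClassifier":
        return cls(**asdict(config))

    # -- core ------------------------------------------------------------------
    def _prepare(self, bundle: FeatureBundle) -> FeatureBundle:
        return apply_plddt_mask(bundle, self.plddt_threshold)

    def _forward(self, bundle: FeatureBundle) -> Tensor:
        cfg = self.config()
        context = _encode(bundle, self.params_, cfg)
        return _decode(context, self.params_, cfg)

    def initialize(self, d_emb: int, terms: list[str]) -> "GvpGoClassifier":
        """Random initialization without training (usable for predict_proba)."""
        rng = np.random.default_rng(self.seed)
        self.classes_ = list(terms)
        self.d_emb_ = d_emb
        self.params_ = _init_params(rng, self.config(), d_emb, len(terms))
        self.loss_history_ = []
        self.val_loss_history_ = []
        return self

    def fit(self, X: list[FeatureBundle], y: np.ndarray, terms: list[str] | None = None,
            validation: tuple[list[FeatureBundle], np.ndarray] | None = None,
            epoch_callback=None) -> "GvpGoClassifier":
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[0] != len(X):
            raise ValueError("y must be (n_proteins, n_terms) aligned with X")
        if terms is None:
            terms = [f"term_{j}" for j in range(y.shape[1])]
        if len(terms) != y.shape[1]:
            raise ValueError("terms must match the label matrix width")
        if not (self.warm_start and hasattr(self, "params_")):
            self.initialize(X[0].seq_embedding.shape[1], terms)
        cfg = self.config()
        masked = [self._prepare(b) for b in X]
        masked_val = [self._prepare(b) for b in validation[0]] if validation else None

        opt = Adam(self.params_.all_tensors(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        n = len(masked)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                batch_loss = 0.0
                for i in idx:
                    pred = self._forward(masked[i])
                    loss = weighted_bce_loss(pred, y[i], cfg.pos_weight)
                    if not np.isfinite(loss.data):
                        raise RuntimeError(
                            f"training diverged: non-finite loss at epoch {epoch}, protein index {i}"
                        )
                    (loss * (1.0 / len(idx))).backward()
                    batch_loss += float(loss.data) / len(idx)
                opt.clip_grad_norm(cfg.grad_clip)
                opt.step()
                epoch_losses.append(batch_loss)
            self.loss_history_.append(float(np.mean(epoch_losses)))
            if masked_val is not None:
                val_loss = 0.0
                for b, yv in zip(masked_val, validation[1]):
                    pred = self._forward(b)
                    val_loss += float(weighted_bce_loss(pred, yv, cfg.pos_weight).data)
                val_loss /= len(masked_val)
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = [t.data.copy() for t in self.params_.all_tensors()]
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            if epoch_callback is not None and epoch_callback(self, epoch):
                break
            if masked_val is not None and bad_epochs > cfg.patience:
                break
        if best_state is not None:
            for t, d in zip(self.params_.all_tensors(), best_state):
                t.data = d
        return self

    def predict_proba(self, X: list[FeatureBundle], masked: bool = False) -> np.ndarray:
        out = np.zeros((len(X), len(self.classes_)))
        for i, b in enumerate(X):
            bb = b if masked else self._prepare(b)
            out[i] = self._forward(bb).data
        return out

    def predict(self, X: list[FeatureBundle], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def predict_structure(self, structure: ProteinStructure, seq_embedding: np.ndarray) -> dict[str, float]:
        """Full featurize -> encode -> decode pipeline for one protein."""
        bundle = featurize(structure, seq_embedding, k=self.k_neighbors)
        probs = self.predict_proba([bundle])[0]
        return dict(zip(self.classes_, probs.tolist()))

    def prediction_set(self, X: list[FeatureBundle], dag: GoDag | None = None) -> PredictionSet:
        """PredictionSet over the candidate terms, optionally max-propagated."""
        probs = self.predict_proba(X)
        ps = PredictionSet({
            b.protein_id: {t: float(p) for t, p in zip(self.classes_, row)}
            for b, row in zip(X, probs)
        })
        return propagate_predictions(ps, dag) if dag is not None else ps

    def n_parameters(self) -> int:
        return self.params_.n_parameters()


# -- module-level wrappers ----------------------------------------------------


def train(
    train_data: tuple[list[FeatureBundle], np.ndarray],
    config: ModelConfig,
    terms: list[str] | None = None,
    validation: tuple[list[FeatureBundle], np.ndarray] | None = None,
    epoch_callback=None,
) -> tuple[GvpGoClassifier, dict]:
    """Fit a classifier; returns (estimator, history dict)."""
    est = GvpGoClassifier.from_config(config)
    est.fit(train_data[0], train_data[1], terms=terms, validation=validation,
            epoch_callback=epoch_callback)
    return est, {"loss": est.loss_history_, "val_loss": est.val_loss_history_}


def predict(structure: ProteinStructure, seq_embedding: np.ndarray,
            estimator: GvpGoClassifier) -> dict[str, float]:
    return estimator.predict_structure(structure, seq_embedding)


def permutation_importance(
    estimator: GvpGoClassifier,
    bundles: list[FeatureBundle],
    truth: AnnotationSet,
    dag: GoDag,
    feature_name: str,
    seed: int = 0,
    ic: dict[str, float] | None = None,
) -> dict:
    """Metric changes when one feature is residue-level permuted at test time.

    Returns per-ontology baseline and permuted Fmax/Smin/AUPR plus macro
    deltas (permuted minus baseline).
    """
    from .evaluation import EvaluationInput, aupr as _aupr, fmax as _fmax, smin as _smin

    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")

    def metrics(bs: list[FeatureBundle]) -> dict[str, dict[str, float]]:
        preds = estimator.prediction_set(bs, dag=dag)
        out: dict[str, dict[str, float]] = {}
        for ont in ("MFO", "BPO", "CCO"):
            ns_terms = dag.terms_in(ont) - set(dag.roots.values())
            if not any(truth.annotations[p] & ns_terms for p in truth.annotations):
                continue
            inp = EvaluationInput(predictions=preds, truth=truth, ontology=ont, dag=dag, ic=ic)
            f, _ = _fmax(inp)
            entry = {"fmax": f, "aupr": _aupr(inp)}
            if ic is not None:
                entry["smin"] = _smin(inp)[0]
            out[ont] = entry
        return out

    base = metrics(bundles)
    permuted = metrics(permute_feature(bundles, feature_name, seed))
    deltas = {
        m: float(np.mean([permuted[o][m] - base[o][m] for o in base]))
        for m in next(iter(base.values()))
    }
    return {"feature": feature_name, "baseline": base, "permuted": permuted, "delta": deltas}


# -- checkpointing ------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(estimator: GvpGoClassifier, path: str | Path) -> Path:
    """Named-tensor archive (.npz) with a JSON header echoing the configuration."""
    path = Path(path)
    header = {
        "format_version": _CHECKPOINT_VERSION,
        "config": asdict(estimator.config()),
        "terms": estimator.classes_,
        "d_emb": estimator.d_emb_,
    }
    arrays = {f"param/{k}": t.data for k, t in estimator.params_.named_tensors().items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> GvpGoClassifier:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        if header["format_version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['format_version']}")
        est = GvpGoClassifier(**header["config"])
        est.initialize(header["d_emb"], header["terms"])
        named = est.params_.named_tensors()
        for key in archive.files:
            if key.startswith("param/"):
                named[key[len("param/"):]].data = archive[key].astype(float)
    est.loss_history_ = []
    est.val_loss_history_ = []
    return est
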