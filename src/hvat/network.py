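"""The hybrid two-branch network.

The main branch — a Value-Aware Transformer (VAT) — runs a stack of standard
transformer encoder blocks over the clinical-token embeddings and reads the
output at the special summary token (position 0) as a fixed-width summary of
the whole sequence.  The second branch is a residual feed-forward network over
the 7-dimensional static vector.  The branch outputs are fused by summation,
passed through another residual feed-forward block, and mapped to a risk
probability by a single sigmoid node.  The loss is the *sum* of binary
cross-entropies over the patients in a mini-batch (mini-batches hold a roughly
constant number of tokens, not patients, so summing keeps the gradient scale
comparable across batches).

Ablation variants reuse the same forward path: ``without_ffnn`` zeroes the
static branch's contribution, ``without_vat`` zeroes the transformer's.
Because the fusion is a sum, zeroing a branch is equivalent to removing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .embedding import EmbeddingTables, temporal_embedding
from .tokenization import TokenSequence

VARIANTS = ("full", "without_ffnn", "without_vat")


@dataclass
class HvatConfig:
    """Architecture hyperparameters; defaults are the prototype settings."""

    d: int = 32
    n_blocks: int = 2
    n_heads: int = 2
    dropout: float = 0.1
    ffnn_hidden: int = 32
    static_dim: int = 7
    variant: str = "full"
    te_convention: str = "one_based"

    def __post_init__(self) -> None:
        if self.d % 2 != 0:
            raise ValueError("d must be even (sin/cos pairs)")
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class BatchTensors:
    """Padded mini-batch.  ``valid`` marks real tokens; every sequence has its
    special summary token at position 0."""

    t: np.ndarray  # (B, L) int
    concept: np.ndarray  # (B, L) int
    value: np.ndarray  # (B, L) float
    valid: np.ndarray  # (B, L) bool
    static: np.ndarray  # (B, static_dim) float
    labels: np.ndarray  # (B,) int
    patient_ids: list[str] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return self.t.shape[0]

    @property
    def n_tokens(self) -> int:
        return int(self.valid.sum())


def make_batch(
    sequences: Sequence[TokenSequence],
    statics: np.ndarray,
    labels: np.ndarray,
) -> BatchTensors:
    """Pad a group of token sequences into batch tensors."""
    if len(sequences) == 0:
        raise ValueError("empty batch")
    lengths = [len(s.tokens) for s in sequences]
    L = max(lengths)
    B = len(sequences)
    t = np.zeros((B, L), dtype=np.int64)
    concept = np.zeros((B, L), dtype=np.int64)
    value = np.zeros((B, L), dtype=np.float64)
    valid = np.zeros((B, L), dtype=bool)
    for i, seq in enumerate(sequences):
        if not seq.tokens or seq.tokens[0].t != 0:
            raise ValueError(f"sequence for {seq.patient_id} lacks the special token at position 0")
        n = len(seq.tokens)
        t[i, :n] = [tok.t for tok in seq.tokens]
        concept[i, :n] = [tok.concept for tok in seq.tokens]
        value[i, :n] = [tok.value for tok in seq.tokens]
        valid[i, :n] = True
    return BatchTensors(
        t=t,
        concept=concept,
        value=value,
        valid=valid,
        static=np.asarray(statics, dtype=np.float64),
        labels=np.asarray(labels),
        patient_ids=[s.patient_id for s in sequences],
    )


def _linear_params(rng, fan_in: int, fan_out: int) -> tuple[Parameter, Parameter]:
    w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
    b = Parameter(np.zeros(fan_out))
    return w, b


class HvatModel:
    """Parameters plus forward passes for the full model and its ablations."""

    def __init__(self, config: HvatConfig, n_concept_rows: int, seed: int = 0):
        self.config = config
        self.n_concept_rows = n_concept_rows
        self.params: dict[str, Parameter] = {}
        self._rng = np.random.default_rng(seed)
        self.initialize(seed)

    # -- initialization --------------------------------------------------
    def initialize(self, seed: int) -> None:
        """(Re-)initialize all weights with He fan-in scaling; reproducible."""
        rng = np.random.default_rng(seed)
        c = self.config
        d, h = c.d, c.ffnn_hidden
        p: dict[str, Parameter] = {}
        # He fan-in scaling targets weight matrices acting on activations;
        # embedding rows use the standard-normal init customary for lookup
        # tables, which also keeps them commensurate with the fixed temporal
        # encoding (per-dimension RMS 1/sqrt(2)).
        p["ce"] = Parameter(rng.normal(0.0, 1.0, size=(self.n_concept_rows, d)))
        p["ve"] = Parameter(rng.normal(0.0, 1.0, size=(self.n_concept_rows, d)))
        for i in range(c.n_blocks):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"blk{i}.{name}"], p[f"blk{i}.{name}_b"] = _linear_params(rng, d, d)
            p[f"blk{i}.ln1_g"] = Parameter(np.ones(d))
            p[f"blk{i}.ln1_b"] = Parameter(np.zeros(d))
            p[f"blk{i}.ff1"], p[f"blk{i}.ff1_b"] = _linear_params(rng, d, 4 * d)
            p[f"blk{i}.ff2"], p[f"blk{i}.ff2_b"] = _linear_params(rng, 4 * d, d)
            p[f"blk{i}.ln2_g"] = Parameter(np.ones(d))
            p[f"blk{i}.ln2_b"] = Parameter(np.zeros(d))
        p["static.win"], p["static.win_b"] = _linear_params(rng, c.static_dim, d)
        p["static.w1"], p["static.w1_b"] = _linear_params(rng, d, h)
        p["static.w2"], p["static.w2_b"] = _linear_params(rng, h, d)
        p["fusion.w1"], p["fusion.w1_b"] = _linear_params(rng, d, h)
        p["fusion.w2"], p["fusion.w2_b"] = _linear_params(rng, h, d)
        p["head.w"], p["head.w_b"] = _linear_params(rng, d, 1)
        self.params = p
        self._rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    # -- parameter groups ------------------------------------------------
    def parameter_groups(self) -> dict[str, list[tuple[str, Parameter]]]:
        """Disjoint, exhaustive split into the three learning-rate groups:
        the VAT branch (embedding tables + transformer blocks), the static
        branch, and the remaining fusion/output part."""
        groups: dict[str, list[tuple[str, Parameter]]] = {"vat": [], "static": [], "head": []}
        for name, par in self.params.items():
            if name in ("ce", "ve") or name.startswith("blk"):
                groups["vat"].append((name, par))
            elif name.startswith("static."):
                groups["static"].append((name, par))
            else:
                groups["head"].append((name, par))
        return groups

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for par in self.params.values():
            par.grad = None

    @property
    def embedding_tables(self) -> EmbeddingTables:
        return EmbeddingTables(
            d=self.config.d,
            concept=self.params["ce"].data,
            value=self.params["ve"].data,
            convention=self.config.te_convention,
        )

    # -- forward passes --------------------------------------------------
    def _linear(self, x: Tensor, name: str) -> Tensor:
        return x @ self.params[name] + self.params[f"{name}_b"]

    def vat_forward(self, batch: BatchTensors, training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        """Transformer branch: returns the position-0 (summary-token) output,
        one d-vector per patient, regardless of sequence lengths."""
        if batch.n_patients == 0:
            raise ValueError("empty batch")
        c = self.config
        rng = rng if rng is not None else self._rng
        te = temporal_embedding(batch.t, c.d, c.te_convention)  # fixed, no grad
        ce = ad.gather_rows(self.params["ce"], batch.concept)
        ve = ad.gather_rows(self.params["ve"], batch.concept)
        x = ad.constant(te) + ce + Tensor(batch.value[..., None]) * ve  # (B, L, d)

        B, L = batch.t.shape
        H, dh = c.n_heads, c.d // c.n_heads
        key_mask = batch.valid[:, None, None, :]  # (B, 1, 1, L)
        for i in range(c.n_blocks):
            # multi-head self-attention, post-norm layout
            q = self._linear(x, f"blk{i}.wq")
            k = self._linear(x, f"blk{i}.wk")
            v = self._linear(x, f"blk{i}.wv")
            split = lambda z: ad.transpose(ad.reshape(z, (B, L, H, dh)), (0, 2, 1, 3))
            qh, kh, vh = split(q), split(k), split(v)  # (B, H, L, dh)
            scores = qh @ ad.transpose(kh, (0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            attn = ad.masked_softmax(scores, key_mask)  # (B, H, L, L)
            ctx = attn @ vh
            ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, L, c.d))
            ctx = ad.dropout(self._linear(ctx, f"blk{i}.wo"), c.dropout, rng, training)
            x = ad.layer_norm(x + ctx, self.params[f"blk{i}.ln1_g"], self.params[f"blk{i}.ln1_b"])
            # position-wise feed-forward
            ff = self._linear(ad.relu(self._linear(x, f"blk{i}.ff1")), f"blk{i}.ff2")
            ff = ad.dropout(ff, c.dropout, rng, training)
            x = ad.layer_norm(x + ff, self.params[f"blk{i}.ln2_g"], self.params[f"blk{i}.ln2_b"])
        # summary = position-0 output
        picked = ad.tsum(x * Tensor(_position0_mask(B, L)), axis=1)  # (B, d)
        return picked

    def static_branch_forward(self, static: np.ndarray, training: bool = False,
                              rng: np.random.Generator | None = None) -> Tensor:
        """Residual feed-forward branch over the static vector."""
        if static.shape[-1] != self.config.static_dim:
            raise ValueError(
                f"static vector width {static.shape[-1]} != configured {self.config.static_dim}"
            )
        rng = rng if rng is not None else self._rng
        x = self._linear(Tensor(static), "static.win")
        hidden = ad.relu(self._linear(x, "static.w1"))
        hidden = ad.dropout(hidden, self.config.dropout, rng, training)
        return x + self._linear(hidden, "static.w2")

    def forward(self, batch: BatchTensors, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Full forward pass: fused branches -> residual block -> single
        sigmoid node; probability per patient in (0, 1)."""
        return ad.sigmoid(self.forward_logits(batch, training, rng))

    def forward_logits(self, batch: BatchTensors, training: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Pre-sigmoid logits; used with :func:`logit_loss` during training so
        the gradient stays exact even when the sigmoid saturates."""
        c = self.config
        rng = rng if rng is not None else self._rng
        if c.variant == "without_vat":
            fused = self.static_branch_forward(batch.static, training, rng)
        elif c.variant == "without_ffnn":
            fused = self.vat_forward(batch, training, rng)
        else:
            fused = self.vat_forward(batch, training, rng) + self.static_branch_forward(
                batch.static, training, rng
            )
        hidden = ad.relu(self._linear(fused, "fusion.w1"))
        hidden = ad.dropout(hidden, c.dropout, rng, training)
        fused = fused + self._linear(hidden, "fusion.w2")
        return ad.reshape(self._linear(fused, "head.w"), (batch.n_patients,))

    def predict_proba(self, batch: BatchTensors) -> np.ndarray:
        """Evaluation-mode probabilities as a plain array."""
        return self.forward(batch, training=False).data.copy()

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: par.data.copy() for name, par in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, par in self.params.items():
            par.data = np.array(state[name], dtype=np.float64)

    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: config, weights, and optional metadata
        (vocabulary, normalization stats).  Loading reproduces bit-identical
        evaluation outputs."""
        meta = {
            "config": asdict(self.config),
            "n_concept_rows": self.n_concept_rows,
            "extra": extra or {},
        }
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["HvatModel", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {
                k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
            }
        model = cls(HvatConfig(**meta["config"]), meta["n_concept_rows"], seed=0)
        model.load_state_dict(state)
        return model, meta["extra"]


def _position0_mask(B: int, L: int) -> np.ndarray:
    m = np.zeros((B, L, 1))
    m[:, 0, 0] = 1.0
    return m


def batch_loss(probabilities: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Summed binary cross-entropy over the patients of a mini-batch.

    Probabilities are clamped to [eps, 1-eps] for numerical safety.
    """
    y = np.asarray(labels, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    p = ad.clip(probabilities, eps, 1.0 - eps)
    terms = Tensor(y) * ad.log(p) + Tensor(1.0 - y) * ad.log(1.0 - p)
    return -ad.tsum(terms)


def logit_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Summed binary cross-entropy computed from logits.

    Identical value to ``batch_loss(sigmoid(logits), labels)`` away from the
    clamp, but the gradient (p - y per patient) stays exact under saturation,
    so confidently-wrong predictions remain correctable.
    """
    y = np.asarray(labels, dtype=np.float64)
    x = logits.data
    # softplus(x) - y*x, with softplus evaluated stably
    softplus = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.array((softplus - y * x).sum()), (logits,))
    p = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(g * (p - y))

    out._backward = backward
    return out


def predict_sequences(
    model: HvatModel,
    sequences: Iterable[TokenSequence],
    statics: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 256,
) -> np.ndarray:
    """Evaluation-mode probabilities for a list of sequences, batched for
    memory; output order matches input order."""
    sequences = list(sequences)
    out = np.empty(len(sequences))
    for lo in range(0, len(sequences), batch_size):
        hi = min(lo + batch_size, len(sequences))
        batch = make_batch(sequences[lo:hi], statics[lo:hi], labels[lo:hi])
        out[lo:hi] = model.predict_proba(batch)
    return out
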