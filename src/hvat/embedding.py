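"""Token embedding: fixed sinusoidal temporal encoding plus learned concept
and value embeddings.

A clinical token (t, C, v) maps to ``E(t, C, v) = TE(t) + CE(C) + v * VE(C)``,
where TE is a parameter-free sinusoid over the temporal index and CE / VE are
learned per-concept tables.  The value embedding VE supplies a direction along
which the (normalized) value v moves the token — this is what makes the
transformer branch value-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tokenization import ClinicalToken


def angular_frequencies(d: int, convention: str = "one_based") -> np.ndarray:
    """Frequencies omega_k for the sinusoidal temporal encoding.

    ``one_based`` (default, as specified for this architecture): omega_k = 10000^(-2k/d) for k = 1..d/2.
    ``classic``: omega_k = 10000^(-2(k-1)/d), the original transformer's
    zero-based convention, kept as a switch for comparison experiments.
    """
    if d % 2 != 0 or d <= 0:
        raise ValueError("embedding dimension d must be a positive even integer")
    k = np.arange(1, d // 2 + 1, dtype=np.float64)
    if convention == "one_based":
        return 10000.0 ** (-2.0 * k / d)
    if convention == "classic":
        return 10000.0 ** (-2.0 * (k - 1) / d)
    raise ValueError(f"unknown temporal-encoding convention {convention!r}")


def temporal_embedding(t, d: int, convention: str = "one_based") -> np.ndarray:
    """TE(t) = [sin(t w1), cos(t w1), ..., sin(t w_{d/2}), cos(t w_{d/2})].

    ``t`` may be a scalar or an integer array; the sinusoid axis is appended.
    Fixed — never updated during learning.
    """
    omega = angular_frequencies(d, convention)
    t_arr = np.asarray(t, dtype=np.float64)
    angles = t_arr[..., None] * omega  # (..., d/2)
    out = np.empty(angles.shape[:-1] + (d,), dtype=np.float64)
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles)
    return out


@dataclass
class EmbeddingTables:
    """Learned concept (CE) and value (VE) embedding tables, one row per
    concept including the special summary concept at row 0."""

    d: int
    concept: np.ndarray  # (n_rows, d)
    value: np.ndarray  # (n_rows, d)
    convention: str = "one_based"

    def __post_init__(self) -> None:
        if self.d % 2 != 0:
            raise ValueError("d must be even")
        if self.concept.shape != self.value.shape or self.concept.shape[1] != self.d:
            raise ValueError("concept and value tables must both be (n_rows, d)")

    @classmethod
    def initialize(cls, n_rows: int, d: int, rng: np.random.Generator,
                   convention: str = "one_based") -> "EmbeddingTables":
        """Standard-normal rows, the customary init for embedding lookups;
        unit entries keep the learned tables commensurate with the fixed
        temporal encoding."""
        return cls(
            d=d,
            concept=rng.normal(0.0, 1.0, size=(n_rows, d)),
            value=rng.normal(0.0, 1.0, size=(n_rows, d)),
            convention=convention,
        )


def token_embedding(token: ClinicalToken, tables: EmbeddingTables) -> np.ndarray:
    """E(t, C, v) = TE(t) + CE(C) + v * VE(C)."""
    if not 0 <= token.concept < tables.concept.shape[0]:
        raise IndexError(f"concept index {token.concept} outside embedding table")
    return (
        temporal_embedding(token.t, tables.d, tables.convention)
        + tables.concept[token.concept]
        + token.value * tables.value[token.concept]
    )
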