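"""Model-prediction seed vectors for k-means clustering.

Three theoretical accounts of STN function predict distinct task-related
activity patterns, encoded here as canonical 30-D shape vectors (same
ordering as :data:`stndecide.cluster.vectors.VECTOR_ORDER`):

- pooling-normalization: choice- and coherence-dependent activity that
  ramps up during motion viewing;
- early-brake: an early choice- and coherence-independent rise that
  dissipates toward saccade onset;
- nonlinear-gating: coherence-dependent ramping shared by both choices
  during motion viewing, with choice-selective peri-saccade activity.

A fourth, arbitrary seed (orthogonalized against the three) completes
the four-cluster seeding.  Amplitudes are in baseline-z units; only the
qualitative structure is constrained by the theories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeedSet", "make_model_seeds"]

_U = np.array([0.2, 0.4, 0.6, 0.8, 1.0])  # normalized coherence ranks


@dataclass(frozen=True)
class SeedSet:
    """Four 30-D seed vectors with provenance labels."""

    vectors: np.ndarray  # (4, 30)
    labels: tuple = (
        "pooling-normalization",
        "early-brake",
        "nonlinear-gating",
        "arbitrary",
    )

    def __post_init__(self):
        if self.vectors.shape != (4, 30):
            raise ValueError("SeedSet needs exactly four 30-D vectors")


def _assemble(e1_pref, e1_oth, e2_pref, e2_oth, e3_pref, e3_oth) -> np.ndarray:
    return np.concatenate([e1_pref, e1_oth, e2_pref, e2_oth, e3_pref, e3_oth])


def make_model_seeds() -> SeedSet:
    """The three model-prediction seeds plus one orthogonalized seed."""
    u = _U
    ones = np.ones(5)

    s1 = _assemble(
        0.5 + 1.0 * u, 0.2 + 0.3 * u,
        1.0 + 1.5 * u, 0.3 + 0.3 * u,
        2.5 * ones, 1.0 * ones,
    )
    s2 = _assemble(
        2.0 * ones, 2.0 * ones,
        1.0 * ones, 1.0 * ones,
        0.2 * ones, 0.2 * ones,
    )
    s3 = _assemble(
        0.3 + 0.5 * u, 0.3 + 0.5 * u,
        0.8 + 1.2 * u, 0.8 + 1.2 * u,
        2.0 * ones, 0.5 * ones,
    )
    # deterministic 'arbitrary' seed: a fixed oscillatory pattern,
    # projected out of the span of the three (centered) model seeds
    raw = np.cos(np.arange(30) * 2.1) + 0.3
    V = np.column_stack([s - s.mean() for s in (s1, s2, s3)])
    raw = raw - V @ np.linalg.lstsq(V, raw, rcond=None)[0]
    s4 = raw / np.abs(raw).max()
    return SeedSet(vectors=np.vstack([s1, s2, s3, s4]))
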