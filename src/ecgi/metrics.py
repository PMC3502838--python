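"""Reconstruction-accuracy metrics.

For one time instant, with φᵉ the simulated (true) TMP distribution over
the n source nodes and φᶜ the reconstruction:

    RE = ‖φᶜ − φᵉ‖ / ‖φᵉ‖
    CC = Σᵢ (φᶜᵢ − φ̄ᶜ)(φᵉᵢ − φ̄ᵉ) / (‖φᶜ − φ̄ᶜ‖ ‖φᵉ − φ̄ᵉ‖)

CC is the Pearson correlation over nodes; both are computed on raw
millivolt values, never on scaled quantities.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError, ValidationError

__all__ = ["relative_error", "correlation_coeff"]


def _pair(phi_c, phi_e) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(phi_c, dtype=float).ravel()
    e = np.asarray(phi_e, dtype=float).ravel()
    if c.size != e.size:
        raise ValidationError("vectors must have equal length")
    return c, e


def relative_error(phi_c, phi_e) -> float:
    """Euclidean-norm relative error ‖φᶜ − φᵉ‖ / ‖φᵉ‖ (≥ 0)."""
    c, e = _pair(phi_c, phi_e)
    denom = float(np.linalg.norm(e))
    if denom == 0:
        raise DegenerateInputError("reference vector has zero norm")
    return float(np.linalg.norm(c - e) / denom)


def correlation_coeff(phi_c, phi_e) -> float:
    """Centered cosine similarity (Pearson correlation over nodes), in
    [-1, 1]; constant vectors are degenerate."""
    c, e = _pair(phi_c, phi_e)
    if c.size < 2:
        raise ValidationError("need at least 2 nodes")
    cc = c - c.mean()
    ee = e - e.mean()
    nc, ne = np.linalg.norm(cc), np.linalg.norm(ee)
    if nc == 0 or ne == 0:
        raise DegenerateInputError("constant vector has no correlation")
    return float(np.clip(cc @ ee / (nc * ne), -1.0, 1.0))
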