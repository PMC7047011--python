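"""Internal helpers: connectivity structures, seed derivation, row-wise Pearson."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: allowed 3D neighbourhood definitions (face / face+edge / face+edge+vertex)
CONNECTIVITIES = (6, 18, 26)

_CONN_TO_RANK = {6: 1, 18: 2, 26: 3}


def binary_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for a 6/18/26 neighbourhood."""
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
    return ndimage.generate_binary_structure(3, _CONN_TO_RANK[connectivity])


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    """Neighbour offsets for the given connectivity, excluding (0,0,0)."""
    st = binary_structure(connectivity)
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0) and st[dx + 1, dy + 1, dz + 1]:
                    offs.append((dx, dy, dz))
    return offs


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one master seed."""
    # stable string->int hash (Python's hash() is salted per process)
    tag = np.frombuffer(stage.encode("utf8"), dtype=np.uint8)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tag.tolist()])
    return np.random.default_rng(ss)


def center_normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit norm.

    Returns the normalized matrix and a boolean validity vector; rows with
    zero variance (constant series) are left as zeros and flagged invalid.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    valid = norms > 0
    out = np.zeros_like(Xc)
    out[valid] = Xc[valid] / norms[valid, None]
    return out, valid


def normalize_vector(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    vc = v - v.mean()
    nrm = np.linalg.norm(vc)
    if nrm == 0:
        raise ValueError("constant vector cannot be normalized for correlation")
    return vc / nrm
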