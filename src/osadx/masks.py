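"""Binary feature-selection masks and small helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["as_mask", "popcount", "jaccard", "mask_from_indices", "mask_to_str"]


def as_mask(bits, n: int = None) -> np.ndarray:
    """Coerce ``bits`` to a 1-D boolean mask, optionally checking length."""
    mask = np.asarray(bits)
    if mask.ndim != 1:
        raise ValueError("mask must be one-dimensional")
    mask = mask.astype(bool)
    if n is not None and mask.size != n:
        raise ValueError(f"mask length {mask.size} != expected {n}")
    return mask


def popcount(mask) -> int:
    return int(np.count_nonzero(as_mask(mask)))


def jaccard(a, b) -> float:
    """Jaccard similarity |a & b| / |a | b|; 1.0 for two empty masks."""
    a, b = as_mask(a), as_mask(b)
    if a.size != b.size:
        raise ValueError("masks must share a length")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def mask_from_indices(indices, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    idx = np.asarray(sorted(indices), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("index out of range for mask length")
    mask[idx] = True
    return mask


def mask_to_str(mask) -> str:
    return "".join("1" if b else "0" for b in as_mask(mask))
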