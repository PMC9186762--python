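"""Grey-level run-length matrix (GLRLM) texture statistics.

Pixel values inside the object are quantized to G=16 grey levels on the
per-object min-max range (a constant object maps entirely to level 1).
Maximal runs of equal level are enumerated along the four principal
directions (0, 45, 90, 135 degrees), restricted to mask pixels, and the
run-length matrices are summed over directions.  From the pooled matrix
p(i, j) with total run count Nr, grey-level marginals r_i and run-length
marginals c_j, the classical statistics are

    GLN   = sum_i r_i^2 / Nr          (grey-level non-uniformity)
    RLN   = sum_j c_j^2 / Nr          (run-length non-uniformity)
    HGLRE = sum_{i,j} p(i,j) i^2 / Nr (high grey-level run emphasis)
    LGLRE = sum_{i,j} p(i,j) / i^2 / Nr (low grey-level run emphasis)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GREY_LEVELS = 16


@dataclass
class GLRLMStats:
    matrix: np.ndarray  # (G, max_run_length), counts pooled over directions
    n_runs: float
    gln: float
    rln: float
    hglre: float
    lglre: float


def quantize(values: np.ndarray, mask: np.ndarray, levels: int = GREY_LEVELS) -> np.ndarray:
    """Quantized level image: 1..levels inside mask, 0 outside."""
    out = np.zeros(mask.shape, dtype=np.int64)
    v = np.asarray(values, float)[mask]
    lo, hi = v.min(), v.max()
    if hi == lo:
        out[mask] = 1
    else:
        q = np.floor((v - lo) / (hi - lo) * levels).astype(np.int64)
        out[mask] = np.clip(q, 0, levels - 1) + 1
    return out


def _lines(arr: np.ndarray, direction: tuple[int, int]):
    """Yield 1-D scan lines of *arr* along one of the 4 principal directions."""
    if direction == (0, 1):
        yield from arr
    elif direction == (1, 0):
        yield from arr.T
    elif direction == (1, 1):
        for k in range(-arr.shape[0] + 1, arr.shape[1]):
            yield np.diagonal(arr, offset=k)
    elif direction == (1, -1):
        flipped = arr[:, ::-1]
        for k in range(-arr.shape[0] + 1, arr.shape[1]):
            yield np.diagonal(flipped, offset=k)
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def _runs(line: np.ndarray):
    """Maximal (level, length) runs of equal nonzero value in a 1-D line."""
    level, length = 0, 0
    for v in line:
        if v == level:
            length += 1
        else:
            if level > 0:
                yield level, length
            level, length = int(v), 1
    if level > 0:
        yield level, length


DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glrlm_stats(
    image: np.ndarray, mask: np.ndarray, levels: int = GREY_LEVELS
) -> GLRLMStats:
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty object")
    q = quantize(image, mask, levels)
    max_len = max(mask.shape)
    p = np.zeros((levels, max_len), dtype=np.int64)
    for direction in DIRECTIONS:
        for line in _lines(q, direction):
            for level, length in _runs(line):
                p[level - 1, length - 1] += 1
    nr = float(p.sum())
    r = p.sum(axis=1).astype(float)
    c = p.sum(axis=0).astype(float)
    i2 = (np.arange(1, levels + 1, dtype=float)) ** 2
    gln = float((r**2).sum() / nr)
    rln = float((c**2).sum() / nr)
    hglre = float((p.sum(axis=1) * i2).sum() / nr)
    lglre = float((p.sum(axis=1) / i2).sum() / nr)
    return GLRLMStats(matrix=p, n_runs=nr, gln=gln, rln=rln, hglre=hglre, lglre=lglre)
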