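"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive (double loops, pairwise counting) and share no
code with the package internals they check.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(image, levels, distance, angle_deg, mask=None):
    """Count co-occurring pairs one pixel at a time; symmetrize; normalize.

    Returns (p, n_pairs) with n_pairs the directed pair count before
    symmetrization, mirroring the contract of the fast implementation.
    """
    image = np.asarray(image)
    h, w = image.shape
    dr, dc = OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((levels, levels), dtype=float)
    n_pairs = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask is not None and (mask[r, c] or mask[r2, c2]):
                continue
            counts[image[r, c], image[r2, c2]] += 1
            n_pairs += 1
    sym = counts + counts.T
    total = sym.sum()
    p = sym / total if total > 0 else sym
    return p, n_pairs


def concordant_pair_auc(scores, labels):
    """Mann-Whitney AUC: fraction of (positive, negative) score pairs that
    are concordant, with ties counted as one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
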