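"""Independent oracle implementations used to cross-check the package.

These deliberately avoid the code paths they verify: brute-force
enumeration instead of vectorized scans, explicit pair counting instead
of ROC integration.
"""

import numpy as np


def brute_force_auc(scores, labels):
    """Mann–Whitney by explicit enumeration of all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Threshold scan over distinct scores plus +inf, first-best tie-break."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best = None
    for c in sorted(set(scores)) + [np.inf]:
        pred = scores >= c
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (c, j, sens, spec)
    return best
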