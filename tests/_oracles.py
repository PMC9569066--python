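"""Independent brute-force oracles shared by test modules."""

import numpy as np


def exhaustive_otsu(hist):
    """Scan all 255 candidate thresholds, computing the between-class
    variance directly from its definition; smallest maximizer wins."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            var = 0.0
        else:
            mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / hist[: t + 1].sum()
            mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / hist[t + 1 :].sum()
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_t, best_var = t, var
    return best_t
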