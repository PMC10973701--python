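"""Loop-based reference implementations used as independent oracles."""

import numpy as np


def routing_oracle(u_hat, n_iters, normalization):
    """Unvectorized routing-by-agreement, written directly from the update
    rules: softmax priors, weighted sum, squash, agreement increment."""
    I, J, D = u_hat.shape
    b = np.zeros((I, J))
    v = c = None
    for _ in range(n_iters):
        c = np.zeros((I, J))
        if normalization == "over_lower":
            for j in range(J):
                e = np.exp(b[:, j] - b[:, j].max())
                c[:, j] = e / e.sum()
        else:
            for i in range(I):
                e = np.exp(b[i] - b[i].max())
                c[i] = e / e.sum()
        s = np.zeros((J, D))
        for j in range(J):
            for i in range(I):
                s[j] += c[i, j] * u_hat[i, j]
        v = np.zeros((J, D))
        for j in range(J):
            n2 = (s[j] ** 2).sum()
            if n2 > 0:
                v[j] = n2 / (1 + n2) * s[j] / np.sqrt(n2)
        for i in range(I):
            for j in range(J):
                b[i, j] += u_hat[i, j] @ v[j]
    return v, c
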