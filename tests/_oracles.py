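"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
codon string table, trapezoid integration with scipy pmf/pdf, textbook
Benjamini-Hochberg) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, norm

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

# Standard genetic code as the classic 64-character string over TCAG order.
_BASES = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq.upper()))


def translate(seq: str) -> str:
    """Frame-0 translation; incomplete tail dropped; non-ACGT codons -> X."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def has_ptc(mrna: str) -> bool:
    """Premature stop: a * strictly before the final codon of the frame-0 CDS."""
    aa = translate(mrna)
    return "*" in aa[:-1]


def bh_adjust(p_values) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def normalized_rate(psi, l_inc, l_skip):
    return l_inc * psi / (l_inc * psi + l_skip * (1.0 - psi))


def marginal_loglik_numint(mu, sigma, I, S, l_inc, l_skip, n_grid=2001, width=8.0):
    """Group marginal log-likelihood by direct trapezoid integration.

    Integrates Binomial(I; I+S, f(expit(z))) * Normal(z; mu, sigma) over a
    wide z grid, replicate by replicate.
    """
    I = np.asarray(I, float)
    S = np.asarray(S, float)
    z = np.linspace(mu - width * sigma - 1.0, mu + width * sigma + 1.0, n_grid)
    psi = 1.0 / (1.0 + np.exp(-z))
    f = normalized_rate(psi, l_inc, l_skip)
    dens = norm.pdf(z, mu, sigma)
    total = 0.0
    for Ir, Sr in zip(I, S):
        like = binom.pmf(Ir, Ir + Sr, f) * dens
        total += np.log(np.trapezoid(like, z))
    return total


def grid_fit_oracle(I, S, l_inc, l_skip, mu_grid, sigma_grid):
    """Brute-force grid MLE of (mu, sigma) under the marginal likelihood."""
    best = (-np.inf, None, None)
    for mu in mu_grid:
        for sigma in sigma_grid:
            ll = marginal_loglik_numint(mu, sigma, I, S, l_inc, l_skip)
            if ll > best[0]:
                best = (ll, mu, sigma)
    return {"loglik": best[0], "mu": best[1], "sigma": best[2]}


def grid_lrt_oracle(I1, S1, I2, S2, l_inc, l_skip, e, mu_grid, sigma_grid):
    """Brute-force LRT statistic over factorized (mu, sigma) grids."""
    ll1 = np.array(
        [[marginal_loglik_numint(m, s, I1, S1, l_inc, l_skip) for s in sigma_grid] for m in mu_grid]
    )
    ll2 = np.array(
        [[marginal_loglik_numint(m, s, I2, S2, l_inc, l_skip) for s in sigma_grid] for m in mu_grid]
    )
    # H1: free (mu1, mu2), shared sigma.
    h1 = max(
        ll1[i, k] + ll2[j, k]
        for k in range(len(sigma_grid))
        for i in range(len(mu_grid))
        for j in range(len(mu_grid))
    )
    # H0: |expit(mu1) - expit(mu2)| <= e.
    psi = 1.0 / (1.0 + np.exp(-np.asarray(mu_grid)))
    h0 = max(
        ll1[i, k] + ll2[j, k]
        for k in range(len(sigma_grid))
        for i in range(len(mu_grid))
        for j in range(len(mu_grid))
        if abs(psi[i] - psi[j]) <= e
    )
    return {"stat": max(0.0, 2.0 * (h1 - h0)), "h1": h1, "h0": h0}
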