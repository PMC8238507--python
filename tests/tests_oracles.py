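"""Independent numerical oracles shared by test modules."""

import numpy as np
from scipy import integrate


def bf10_g_quadrature(t: float, n: int, r: float = 1.0) -> float:
    """JZS Bayes factor via the g-prior route (inverse-gamma mixture of
    normals on the effect size), independent of the noncentral-t route used
    by the implementation."""
    nu = n - 1

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
            * r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-r * r / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den
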