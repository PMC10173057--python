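"""Independent brute-force oracles used to validate the package implementations.

Everything here is deliberately written with plain loops and textbook
formulas, sharing no code path with the package.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import vonmises


def brute_force_loglik(
    histories: dict[str, np.ndarray],
    f_first: dict[str, float],
    f_second: dict[tuple[str, str], float],
    p_det: dict[str, float],
) -> float:
    """Observed-data log-likelihood by explicit enumeration of latent states.

    ``histories`` maps species -> (n_sites, J) arrays of 0/1/NaN.  Natural
    parameters and detection probabilities are constant across sites.
    """
    species = list(histories)
    n_sites = next(iter(histories.values())).shape[0]
    total = 0.0
    for i in range(n_sites):
        site_lik = 0.0
        # unnormalized potentials over all 2^S states
        states = list(itertools.product([0, 1], repeat=len(species)))
        pots = []
        for z in states:
            nu = sum(z[s] * f_first[sp] for s, sp in enumerate(species))
            for (a, b), f in f_second.items():
                ia, ib = species.index(a), species.index(b)
                nu += z[ia] * z[ib] * f
            pots.append(math.exp(nu))
        norm = sum(pots)
        for z, pot in zip(states, pots):
            psi = pot / norm
            det = 1.0
            for s, sp in enumerate(species):
                y = histories[sp][i]
                p = p_det[sp]
                for yj in y:
                    if np.isnan(yj):
                        continue
                    if z[s] == 1:
                        det *= p if yj == 1 else (1 - p)
                    elif yj == 1:
                        det *= 0.0
            site_lik += psi * det
        total += math.log(site_lik)
    return total


def vonmises_min_overlap(mu1: float, k1: float, mu2: float, k2: float) -> float:
    """∫ min(f, g) over the circle for two exact von Mises densities (quadrature)."""
    f = vonmises(kappa=k1, loc=mu1).pdf
    g = vonmises(kappa=k2, loc=mu2).pdf
    val, _ = quad(lambda t: min(f(t), g(t)), 0.0, 2 * math.pi, limit=400)
    return val


def pianka_by_hand(u, v) -> float:
    num = sum(a * b for a, b in zip(u, v))
    return num / math.sqrt(sum(a * a for a in u) * sum(b * b for b in v))
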