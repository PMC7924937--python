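"""Binomial replication-fidelity model and endpoint-yield arithmetic.

The replicator copies information per 15-nt domain, not per base.  To
compare with a base-by-base copier, the per-domain fidelity p_K(N) is
modeled as the probability that an N-base domain copied with
per-nucleotide fidelity p acquires fewer than K point mutations:

    p_K(N) = sum_{k=0}^{K-1} C(N, k) p^{N-k} (1-p)^k

i.e. the cumulative binomial of the error count at error rate 1-p.
Inverting this for p at a measured per-domain fidelity projects the
hybridization replicator onto an equivalent per-nucleotide accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import binom


class FidelityError(ValueError):
    pass


@dataclass(frozen=True)
class FidelityModel:
    """(N, K, p): domain length, tolerated mutation count, per-nt fidelity."""

    N: int = 15
    K: int = 3
    p: float = 0.85

    def __post_init__(self):
        # K = N + 1 is the degenerate exhaustive tolerance (always faithful)
        if not 1 <= self.K <= self.N + 1:
            raise FidelityError(f"need 1 <= K <= N+1, got K={self.K}, N={self.N}")
        if not 0.0 <= self.p <= 1.0:
            raise FidelityError(f"p must be in [0, 1], got {self.p}")


def domain_fidelity(model: FidelityModel) -> float:
    """Per-information-domain fidelity p_K(N): P(#mutations <= K-1)."""
    return float(binom.cdf(model.K - 1, model.N, 1.0 - model.p))


def invert_per_nt_fidelity(N: int, K: int, target_domain_fidelity: float) -> float:
    """Per-nucleotide fidelity p solving p_K(N) = target.

    p_K(N) is strictly increasing in p on (0, 1), so the root is unique;
    found by bisection (Brent) to 1e-6 absolute tolerance.
    """
    if not 0.0 < target_domain_fidelity < 1.0:
        raise FidelityError("target domain fidelity must be in (0, 1)")
    FidelityModel(N, K, 0.5)  # validates (N, K)

    def f(p):
        return domain_fidelity(FidelityModel(N, K, p)) - target_domain_fidelity

    lo, hi = 0.0, 1.0
    if f(lo) > 0 or f(hi) < 0:
        raise FidelityError("target outside the achievable range for (N, K)")
    return float(brentq(f, lo, hi, xtol=1e-6))


def endpoint_domain_fidelity(c_defect: float, c_full: float) -> float:
    """Per-domain fidelity from endpoint yields: 1 - c_defect/c_full.

    ``c_defect`` is the product concentration of a reaction forced to
    make an error (one strand knocked out), ``c_full`` the intact
    reaction's endpoint.
    """
    if c_full <= 0:
        raise FidelityError("c_full must be positive")
    if not 0 <= c_defect <= c_full:
        raise FidelityError("need 0 <= c_defect <= c_full")
    return 1.0 - c_defect / c_full


def multi_defect_yield(single_defect_relative_yield: float, n_defects: int) -> float:
    """Relative yield of an n-defect reaction under independence:
    yield**n."""
    if not 0.0 <= single_defect_relative_yield <= 1.0:
        raise FidelityError("relative yield must be in [0, 1]")
    if n_defects < 1:
        raise FidelityError("n_defects must be >= 1")
    return single_defect_relative_yield ** n_defects
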