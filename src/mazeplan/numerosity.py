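"""Bit-limited numerosity perception.

Counts ``n`` in [1, 80] are passed through a capacity-limited channel that
may spend at most ``B`` bits on them. The channel ``Q(k|n)`` minimizes the
expected relative squared error ``((n - k) / n)^2`` subject to the mutual
information between count and estimate (under a Zipfian ``P(n) ∝ 1/n²``
prior) staying below ``B``. The exposed quantity is the expected subjective
estimate ``q(n) = Σ_k k Q(k|n)``: close to the identity for generous bit
budgets, collapsing toward the prior mean as ``B → 0``.

The constrained problem is solved by Blahut–Arimoto alternating
minimization at a fixed trade-off slope, with an outer bisection on the
slope to meet the information constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ParameterError

N_MIN = 1
N_MAX = 80
B_MIN = 0.1
B_MAX = 10.0

_LOG2 = np.log(2.0)


def zipf_prior(n_max: int = N_MAX) -> np.ndarray:
    """P(n) ∝ 1/n² over n = 1..n_max, normalized."""
    n = np.arange(1, n_max + 1, dtype=float)
    p = 1.0 / n**2
    return p / p.sum()


def _distortion_matrix(n_max: int = N_MAX) -> np.ndarray:
    # scale-invariant relative error: log-ratio squared. (Plain relative
    # squared error ((n-k)/n)^2 goes flat in k for large n, which collapses
    # large-count estimates onto the marginal and breaks monotonicity of q.)
    n = np.arange(1, n_max + 1, dtype=float)[:, None]
    k = np.arange(1, n_max + 1, dtype=float)[None, :]
    return np.log(n / k) ** 2


def _mutual_information_bits(prior: np.ndarray, Q: np.ndarray) -> float:
    m = prior @ Q
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Q > 0, np.log(Q / np.maximum(m[None, :], 1e-300)), 0.0)
    return float(np.sum(prior[:, None] * Q * ratio) / _LOG2)


def _blahut_arimoto(
    prior: np.ndarray,
    d: np.ndarray,
    slope: float,
    tol: float,
    max_iter: int,
    m0: np.ndarray | None = None,
) -> np.ndarray:
    """Channel minimizing distortion subject to the information budget traded
    at a fixed slope. Alternating minimization; convergence is declared when
    the (information, distortion) objective pair stops moving — the estimate
    mass may keep drifting along the objective's plateau, which does not
    affect the channel's operating point."""
    n_max = d.shape[0]
    if m0 is None:
        m = np.full(n_max, 1.0 / n_max)
    else:
        m = np.maximum(m0, 1e-12)  # multiplicative updates never revive zeros
        m /= m.sum()
    expd = np.exp(-slope * d)
    check_every = 200
    prev = (np.inf, np.inf)
    Q = None
    for it in range(1, max_iter + 1):
        Q = m[None, :] * expd
        Q /= Q.sum(axis=1, keepdims=True)
        m = prior @ Q
        if it % check_every == 0 or it == max_iter:
            info = _mutual_information_bits(prior, Q)
            dist = float(np.sum(prior[:, None] * Q * d))
            if abs(info - prev[0]) < tol and abs(dist - prev[1]) < tol:
                return Q
            prev = (info, dist)
    raise NumericalError(f"channel iteration did not converge at slope {slope}")


@dataclass(frozen=True)
class NumerosityChannel:
    """Built channel table for one bit threshold ``B``."""

    B: float
    prior: np.ndarray
    Q: np.ndarray  # Q[n-1, k-1] = P(estimate k | count n)
    q: np.ndarray  # q[n-1] = expected estimate for count n

    @property
    def mutual_information(self) -> float:
        return _mutual_information_bits(self.prior, self.Q)

    def table(self) -> str:
        """Delimited (B, n, q) text table for inspection."""
        lines = ["B\tn\tq"]
        for n in range(N_MIN, N_MAX + 1):
            lines.append(f"{self.B:g}\t{n}\t{self.q[n - 1]:.8f}")
        return "\n".join(lines) + "\n"


_CHANNEL_CACHE: dict[float, NumerosityChannel] = {}


def build_channel(
    B: float,
    tol: float = 1e-6,
    info_tol: float = 5e-3,
    max_iter: int = 300_000,
) -> NumerosityChannel:
    """Construct the channel for bit threshold ``B`` ∈ [0.1, 10].

    Bisects the rate-distortion slope until the channel's mutual information
    matches ``B`` (or the identity channel's information, whichever is
    smaller — for large ``B`` the constraint is slack and counting is exact).
    """
    if not (B_MIN <= B <= B_MAX):
        raise ParameterError(f"bit threshold B={B} outside [{B_MIN}, {B_MAX}]")
    key = round(float(B), 10)
    cached = _CHANNEL_CACHE.get(key)
    if cached is not None:
        return cached

    prior = zipf_prior()
    d = _distortion_matrix()

    entropy = float(-np.sum(prior * np.log2(prior)))
    if B >= entropy:
        # constraint slack: the prior carries fewer bits than the budget,
        # so exact counting (zero distortion) is optimal
        Q = np.eye(N_MAX)
    else:
        lo, hi = 0.0, 1.0
        warm = None
        Q_hi = _blahut_arimoto(prior, d, hi, tol, max_iter, warm)
        warm = prior @ Q_hi
        while _mutual_information_bits(prior, Q_hi) < B:
            lo, hi = hi, hi * 4.0
            Q_hi = _blahut_arimoto(prior, d, hi, tol, max_iter, warm)
            warm = prior @ Q_hi
        Q = _blahut_arimoto(prior, d, lo, tol, max_iter, warm)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            Q_mid = _blahut_arimoto(prior, d, mid, tol, max_iter, warm)
            warm = prior @ Q_mid
            info = _mutual_information_bits(prior, Q_mid)
            if info <= B:
                lo, Q = mid, Q_mid
                if B - info < info_tol:
                    break
            else:
                hi = mid
            if hi - lo < 1e-9 * max(hi, 1.0):
                break

    q = Q @ np.arange(1, N_MAX + 1, dtype=float)
    channel = NumerosityChannel(B=float(B), prior=prior, Q=Q, q=q)
    _CHANNEL_CACHE[key] = channel
    return channel


def subjective_quantity(channel: NumerosityChannel, n: float) -> float:
    """Expected subjective estimate q(n); counts above 80 clamp with a warning."""
    if n < N_MIN:
        raise ParameterError(f"count n={n} below domain minimum {N_MIN}")
    if n > N_MAX:
        warnings.warn(f"count n={n} clamped to {N_MAX}", stacklevel=2)
        n = N_MAX
    idx = int(round(n)) - 1
    return float(channel.q[idx])
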