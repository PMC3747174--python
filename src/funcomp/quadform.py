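"""Null spectrum and tail probabilities of V = sum_i beta_i * chi2_1.

Under profile equality the global statistic V is asymptotically distributed
as a weighted sum of independent one-degree-of-freedom chi-square variables.
The weights beta are the non-zero eigenvalues of J @ Sigma, where Sigma is
the 2s x 2s joint profile covariance and J = [[I, -I], [-I, I]].  Because
J = K'K with K = [I, -I], the non-zero eigenvalues of J @ Sigma equal those
of the s x s symmetric matrix K Sigma K' = (m*A - k*B - k*B' + n*C)/(n+m),
which is what we diagonalise (2x cheaper and numerically symmetric).

Tail probabilities use three routes, in order of preference:

1. exact chi-square survival function when the positive weights are all
   equal (this covers the single-class case, where the global test reduces
   to an unpooled two-proportion z-test);
2. Ruben's expansion of the distribution as a mixture of central
   chi-squares with a common scale — all mixture coefficients are
   non-negative, so the truncation error is bounded by the unaccumulated
   mixture mass, giving rigorous error control;
3. trapezoidal inversion of the characteristic function (Imhof's integral
   evaluated the way Davies proposed), with the aliasing error controlled
   by a Chernoff bound on the far tail and the truncation error by an
   explicit envelope of the integrand.

A deterministic seeded Monte-Carlo estimate remains as a last resort for
spectra where neither series nor quadrature reaches the accuracy target.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .covariance import JointCovariance

__all__ = ["jmatrix", "null_betas", "qf_upper_tail", "qf_quantile"]

#: relative eigenvalue truncation threshold (fraction of the largest weight)
TRUNCATION_TOL = 1e-12

#: absolute accuracy target for tail probabilities
TAIL_EPS = 1e-9


def jmatrix(s: int) -> np.ndarray:
    """The 2s x 2s difference form [[I, -I], [-I, I]] (rank s, eigenvalues 0 and 2)."""
    I = np.eye(s)
    return np.block([[I, -I], [-I, I]])


def null_betas(S: JointCovariance | np.ndarray, tol: float = TRUNCATION_TOL) -> np.ndarray:
    """Eigenvalue spectrum of the null mixture, descending, length s.

    Accepts either a :class:`JointCovariance` (preferred; uses the reduced
    s x s problem) or a raw symmetric s x s reduced matrix.  Negative
    numerical eigenvalues within ``tol * max(beta)`` of zero are clipped to
    zero silently; more negative ones are clipped with a warning.
    """
    if isinstance(S, JointCovariance):
        R = S.reduced()
    else:
        R = np.asarray(S, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("reduced matrix must be square")
        if not np.allclose(R, R.T, atol=1e-8 * max(1.0, np.abs(R).max())):
            raise ValueError("reduced matrix is not symmetric")
        R = 0.5 * (R + R.T)
    w = np.linalg.eigvalsh(R)[::-1].copy()
    mx = max(float(w[0]), 0.0)
    floor = -tol * mx if mx > 0 else 0.0
    if np.any(w < floor - 1e-300):
        warnings.warn(
            f"clipping negative eigenvalue(s) down to {w.min():.3g} in null spectrum",
            stacklevel=2,
        )
    w[w <= tol * mx] = 0.0
    return w


def _ruben_upper_tail(beta: np.ndarray, x: float, eps: float = TAIL_EPS,
                      kmax: int = 120_000) -> float | None:
    """Ruben mixture-of-chi-squares series for P(Q > x); None if it stalls.

    With the common scale taken as the smallest weight, Q/b0 is a mixture
    sum_k a_k chi2_{s+2k} with a_k >= 0 and sum a_k = 1; the truncation
    error of the CDF is therefore at most the mass not yet accumulated.
    """
    b0 = float(beta.min())
    s = beta.size
    ratio = 1.0 - b0 / beta                       # each in [0, 1)
    log_a0 = 0.5 * float(np.sum(np.log(b0 / beta)))
    if log_a0 < -600.0:                           # a_0 underflows => slow series
        return None
    a = np.empty(kmax + 1)
    g = np.empty(kmax + 1)
    a[0] = np.exp(log_a0)
    cum = a[0]
    rpow = ratio.copy()
    K = None
    for k in range(1, kmax + 1):
        g[k] = 0.5 * float(np.sum(rpow))
        rpow *= ratio
        # a_k = (1/k) * sum_{r=1..k} g_r a_{k-r}
        a[k] = np.dot(g[1:k + 1], a[k - 1::-1][:k]) / k
        cum += a[k]
        if 1.0 - cum <= eps:
            K = k
            break
    if K is None:
        return None
    dfs = s + 2.0 * np.arange(K + 1)
    cdf = float(np.dot(a[:K + 1], chi2.cdf(x / b0, dfs)))
    return min(max(1.0 - cdf, 0.0), 1.0)


def _chernoff_point(beta: np.ndarray, eps: float) -> float:
    """c such that P(Q > c) <= eps, from the chi-square-mixture mgf."""
    bmax = float(beta.max())
    t = np.linspace(1e-4, 0.9999, 512) / (2.0 * bmax)
    cgf = -0.5 * np.sum(np.log1p(-2.0 * np.outer(t, beta)), axis=1)
    return float(np.min((cgf - np.log(eps)) / t))


def _truncation_point(beta: np.ndarray, eps: float) -> float:
    """U such that (1/pi) * Int_U^inf du / (u * rho(u)) <= eps.

    Uses the envelope rho(u) >= u^(j/2) * prod of the j largest weights^(1/2)
    for the best choice of j (valid since (1 + a^2)^(1/4) >= a^(1/2)).
    """
    bs = np.sort(beta)[::-1]
    j = np.arange(1, bs.size + 1)
    half_logprod = 0.5 * np.cumsum(np.log(bs))
    U = 1.0 / float(bs.max())
    for _ in range(300):
        log_bound = np.log(2.0 / np.pi) - np.log(j) - half_logprod \
            - 0.5 * j * np.log(U)
        if np.min(log_bound) <= np.log(eps):
            return U
        U *= 1.7
    raise RuntimeError("failed to bound the inversion integral")  # pragma: no cover


def _cf_inversion_upper_tail(beta: np.ndarray, x: float, eps: float = TAIL_EPS,
                             max_flops: float = 4e8) -> float | None:
    """Trapezoidal characteristic-function inversion of P(Q > x).

    P(Q > x) = 1/2 + (1/pi) Int_0^inf sin(theta(u)) / (u rho(u)) du with
    theta(u) = 0.5 sum arctan(beta_i u) - 0.5 x u and
    rho(u) = prod (1 + beta_i^2 u^2)^(1/4) (evaluated in log space).
    The midpoint sum with step 2*pi/(x + c) aliases the distribution by
    multiples of x + c, so its error is below P(Q > c); the sum is cut at
    the analytic truncation point.  Returns None if the required number of
    integrand evaluations is unreasonable for the spectrum.
    """
    c = _chernoff_point(beta, 0.25 * eps)
    period = x + c
    delta = 2.0 * np.pi / period
    U = _truncation_point(beta, 0.25 * eps)
    N = int(np.ceil(U / delta)) + 1
    if N * beta.size > max_flops:
        return None
    total = 0.0
    chunk = max(1, int(4e6 / beta.size))
    b = beta[None, :]
    for start in range(0, N, chunk):
        u = (np.arange(start, min(start + chunk, N)) + 0.5) * delta
        bu = b * u[:, None]
        theta = 0.5 * np.sum(np.arctan(bu), axis=1) - 0.5 * x * u
        log_rho = 0.25 * np.sum(np.log1p(bu * bu), axis=1)
        total += float(np.sum(np.sin(theta) * np.exp(-log_rho) / u))
    val = 0.5 + (delta / np.pi) * total
    return min(max(val, 0.0), 1.0)


def _mc_upper_tail(beta: np.ndarray, x: float, n_draws: int = 1_000_000,
                   seed: int = 20110401) -> float:
    """Deterministic Monte-Carlo estimate of the upper tail (last resort)."""
    rng = np.random.default_rng(seed)
    s = beta.size
    hits = 0
    chunk = max(1, min(n_draws, 8_000_000 // max(s, 1)))
    done = 0
    while done < n_draws:
        nb = min(chunk, n_draws - done)
        z = rng.standard_normal((nb, s))
        hits += int(np.count_nonzero((z * z) @ beta > x))
        done += nb
    return hits / n_draws


def qf_upper_tail(beta, x: float) -> float:
    """P(sum_i beta_i chi2_1 > x) for non-negative weights beta.

    Zero weights are ignored (they contribute a point mass at 0).  An
    all-zero spectrum means the statistic is identically zero: the p-value
    is 1 and a warning is emitted.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("weights must be non-negative")
    pos = beta[beta > 0]
    if pos.size == 0:
        warnings.warn("degenerate null spectrum (all weights zero); p-value = 1",
                      stacklevel=2)
        return 1.0
    if x <= 0:
        return 1.0
    if np.allclose(pos, pos[0], rtol=1e-13, atol=0.0):
        return float(chi2.sf(x / pos[0], df=pos.size))
    # route by weight spread: Ruben needs ~20 * bmax/bmin terms, so a wide
    # spectrum (frequent with overlapping lists, where the reduced matrix
    # nearly cancels) is far cheaper via CF inversion
    spread = float(pos.max() / pos.min())
    if spread <= 500.0:
        val = _ruben_upper_tail(pos, x)
        if val is None:
            val = _cf_inversion_upper_tail(pos, x)
    else:
        val = _cf_inversion_upper_tail(pos, x)
        if val is None:
            val = _ruben_upper_tail(pos, x)
    if val is None:  # pragma: no cover - requires an extreme spectrum
        warnings.warn("series and quadrature both stalled; "
                      "using seeded Monte-Carlo fallback", stacklevel=2)
        val = _mc_upper_tail(pos, x)
    return float(val)


def qf_quantile(beta, prob: float) -> float:
    """Quantile v with P(sum beta_i chi2_1 <= v) = prob, prob in (0, 1).

    This is the critical value v(alpha, s) of the global test when
    prob = 1 - alpha.  Solved by bracketing and Brent root refinement on
    the upper-tail function.
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    pos = beta[beta > 0]
    if pos.size == 0:
        raise ValueError("degenerate null: all weights zero, quantile undefined")
    if np.allclose(pos, pos[0], rtol=1e-13, atol=0.0):
        return float(pos[0] * chi2.ppf(prob, df=pos.size))
    target = 1.0 - prob
    hi = float(np.sum(pos))
    while qf_upper_tail(pos, hi) > target:
        hi *= 2.0
        if hi > 1e12 * np.sum(pos):  # pragma: no cover
            raise RuntimeError("failed to bracket quantile")
    return float(brentq(lambda v: qf_upper_tail(pos, v) - target, 0.0, hi,
                        xtol=1e-12, rtol=1e-14))
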