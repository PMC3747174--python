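"""Covariance of functional profiles, single-list and joint two-list.

The expanded cell counts of a list of n genes are multinomial, so the
contracted profile P-hat is a linear image of a multinomial vector and
sqrt(n) * (P-hat - P) is asymptotically normal with covariance

    sigma_ii = p_i (1 - p_i),        sigma_ij = p_ij - p_i p_j  (i != j),

where p_ij is the joint marginal (genes annotated in both classes).  When
two lists of sizes n and m share k genes, the scaled stacked deviation
sqrt(nm/(n+m)) * (P-hat - P, Q-hat - Q) has the 2s x 2s covariance

    [[ m/(n+m) * A,  k/(n+m) * B ],
     [ k/(n+m) * B', n/(n+m) * C ]]

with A = (k/n) S0 + ((n-k)/n) S1, B = S0, C = (k/m) S0 + ((m-k)/m) SQ1,
where S0, S1, SQ1 are the single-profile covariances of the shared and
exclusive sub-lists.  The cross-block is driven entirely by the shared
component: disjoint lists (k = 0) give a block-diagonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import ExpandedProfile, PairDecomposition, membership_matrix

__all__ = ["JointCovariance", "profile_covariance", "joint_covariance"]


def profile_covariance(e: ExpandedProfile, class_order=None) -> np.ndarray:
    """Plug-in covariance estimate of a single contracted profile.

    Returns the s x s symmetric matrix with diagonal p_i(1-p_i) and
    off-diagonal p_ij - p_i p_j.  Positive semi-definite (it equals
    M Cov_multinomial M' for the class-membership indicator matrix M).
    """
    if class_order is not None and list(class_order) != list(e.class_order):
        raise ValueError("class_order mismatch with expanded profile")
    if e.n == 0:
        raise ValueError("cannot estimate covariance from an empty profile")
    M, cnt = membership_matrix(e)
    f = cnt / e.n
    p = M @ f
    # joint marginals p_ij = sum of cell frequencies where both classes present
    joint = (M * f) @ M.T
    sigma = joint - np.outer(p, p)
    # exact Bernoulli variance on the diagonal (joint diagonal is p_i itself)
    np.fill_diagonal(sigma, p * (1.0 - p))
    return sigma


@dataclass
class JointCovariance:
    """The 2s x 2s joint covariance with its A/B/C component blocks."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    n: int
    m: int
    k: int

    @property
    def s(self) -> int:
        return self.A.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Assembled 2s x 2s matrix."""
        n, m, k = self.n, self.m, self.k
        t = n + m
        return np.block([
            [m / t * self.A, k / t * self.B],
            [k / t * self.B.T, n / t * self.C],
        ])

    def reduced(self) -> np.ndarray:
        """The s x s matrix (m*A - k*B - k*B' + n*C)/(n+m).

        Its eigenvalues are the non-zero eigenvalues of J @ matrix, where J
        is the 2s x 2s difference form [[I, -I], [-I, I]] — see quadform.
        """
        n, m, k = self.n, self.m, self.k
        R = (m * self.A - k * self.B - k * self.B.T + n * self.C) / (n + m)
        return 0.5 * (R + R.T)


def joint_covariance(dec: PairDecomposition, class_order=None) -> JointCovariance:
    """Assemble the joint covariance from a pair decomposition.

    Empty components (k = 0, n - k = 0 or m - k = 0) contribute zero with
    zero weight; their covariance is never evaluated, avoiding 0/0.
    """
    if class_order is not None and list(class_order) != list(dec.class_order):
        raise ValueError("class_order mismatch with decomposition")
    n, m, k = dec.n, dec.m, dec.k
    if n < 1 or m < 1:
        raise ValueError("both lists must contain at least one annotated gene")
    if k > min(n, m):
        raise ValueError("k cannot exceed min(n, m)")
    s = dec.s
    S0 = profile_covariance(dec.P0) if k > 0 else np.zeros((s, s))
    S1 = profile_covariance(dec.P1) if n - k > 0 else np.zeros((s, s))
    SQ1 = profile_covariance(dec.Q1) if m - k > 0 else np.zeros((s, s))
    A = (k / n) * S0 + ((n - k) / n) * S1
    B = S0
    C = (k / m) * S0 + ((m - k) / m) * SQ1
    return JointCovariance(A=A, B=B, C=C, n=n, m=m, k=k)
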