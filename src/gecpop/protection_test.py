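"""Weighted permutation test for protected vs unprotected carcass ratios.

Most surveyed ecosystems contain both protected and unprotected land, so
their two carcass ratios are not independent; other ecosystems have only one
protection status.  The comparison therefore combines a weighted paired t
statistic over complete ecosystems with a weighted two-sample t over
incomplete ones:

    T = t_paired * sqrt(a) + t_unpaired * sqrt(1 - a),
    a = 2 n_paired / (n_paired + n),

where n is the total number of carcass-ratio estimates and n_paired the
number contributed by complete ecosystems (two each).  Observations are
weighted by the estimated number of elephants so small populations do not
dominate.  Significance comes from permuting protection labels: sign flips
within complete ecosystems, label shuffles across incomplete ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EcosystemRatioPair",
    "PermutationResult",
    "weighting_factor",
    "combined_statistic",
    "permutation_test",
    "permutation_test_exact",
]


@dataclass(frozen=True)
class EcosystemRatioPair:
    """Carcass ratios for one ecosystem, by protection status.

    A complete ecosystem has both ratios; an incomplete one has exactly one.
    Weights are the estimated number of elephants on each side.
    """

    ecosystem_id: str
    protected_ratio: float | None = None
    unprotected_ratio: float | None = None
    protected_weight: float = 0.0
    unprotected_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.protected_ratio is None and self.unprotected_ratio is None:
            raise ValueError(
                f"ecosystem {self.ecosystem_id!r}: at least one ratio required"
            )
        if self.protected_weight < 0 or self.unprotected_weight < 0:
            raise ValueError("weights must be >= 0")

    @property
    def complete(self) -> bool:
        return self.protected_ratio is not None and self.unprotected_ratio is not None


@dataclass(frozen=True)
class PermutationResult:
    t_paired: float
    t_unpaired: float
    a: float
    t_observed: float
    p_value: float | None
    n_permutations: int


def weighting_factor(n_paired: int, n_total: int) -> float:
    """a = 2 n_paired / (n_paired + n_total); a=0 all-unpaired, a=1 all-paired."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_paired <= n_total:
        raise ValueError("need 0 <= n_paired <= n_total")
    if n_paired % 2:
        raise ValueError("n_paired counts estimates and must be even")
    a = 2.0 * n_paired / (n_paired + n_total)
    if a > 1.0:
        raise ValueError("a > 1: n_paired miscounted")
    return a


# ---------------------------------------------------------------------------
# Weighted t components (reliability weights, effective sample size)
# ---------------------------------------------------------------------------

def _weighted_t_one_sample(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted one-sample t of rows of x against 0; rows with an
    undefined variance (fewer than two effective observations) give 0."""
    x = np.atleast_2d(x)
    wsum = w.sum()
    w2sum = (w**2).sum()
    mean = x @ w / wsum
    dev2 = (x - mean[:, None]) ** 2
    denom = wsum - w2sum / wsum
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = dev2 @ w / denom
        n_eff = wsum**2 / w2sum
        t = mean / np.sqrt(s2 / n_eff)
    t[~np.isfinite(t)] = 0.0
    if denom <= 0:
        t[:] = 0.0
    return t


def _weighted_group_moments(mask: np.ndarray, w: np.ndarray, x: np.ndarray):
    """Per-row weighted mean, variance, effective n for the masked group."""
    a1 = mask @ w
    a2 = mask @ (w**2)
    s1 = mask @ (w * x)
    q1 = mask @ (w * x**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / a1
        varnum = q1 - s1**2 / a1
        s2 = varnum / (a1 - a2 / a1)
        n_eff = a1**2 / a2
    return mean, s2, n_eff, mask.sum(axis=1)


def _weighted_t_two_sample(
    labels: np.ndarray, x: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Weighted classical (pooled-variance) two-group t per row of the
    boolean label matrix (True = protected).  Rows where a group is empty or
    the pooled variance is undefined (fewer than three observations in
    total) give 0."""
    labels = np.atleast_2d(labels).astype(float)
    m1, _, n1, c1 = _weighted_group_moments(labels, w, x)
    m2, _, n2, c2 = _weighted_group_moments(1.0 - labels, w, x)

    def _pieces(mask):
        a1 = mask @ w
        a2 = mask @ (w**2)
        s1 = mask @ (w * x)
        q1 = mask @ (w * x**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            varnum = q1 - s1**2 / a1
            denom = a1 - a2 / a1
        return np.nan_to_num(varnum), np.nan_to_num(denom)

    vn1, d1 = _pieces(labels)
    vn2, d2 = _pieces(1.0 - labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (vn1 + vn2) / (d1 + d2)
        t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.where((c1 >= 1) & (c2 >= 1) & (c1 + c2 >= 3) & np.isfinite(t), t, 0.0)
    return t


def _split(pairs: Sequence[EcosystemRatioPair]):
    complete = [p for p in pairs if p.complete]
    incomplete = [p for p in pairs if not p.complete]
    diffs = np.array(
        [p.protected_ratio - p.unprotected_ratio for p in complete], dtype=float
    )
    # one weight per complete ecosystem: its total estimated elephants
    wpair = np.array(
        [p.protected_weight + p.unprotected_weight for p in complete], dtype=float
    )
    vals, wts, lbls = [], [], []
    for p in incomplete:
        if p.protected_ratio is not None:
            vals.append(p.protected_ratio)
            wts.append(p.protected_weight)
            lbls.append(True)
        else:
            vals.append(p.unprotected_ratio)
            wts.append(p.unprotected_weight)
            lbls.append(False)
    return (diffs, wpair,
            np.array(vals, float), np.array(wts, float), np.array(lbls, bool))


def _statistic(signs, diffs, wpair, labels, vals, wts):
    """T for each row of signs (R x k) and labels (R x m)."""
    R = signs.shape[0] if signs.ndim == 2 else labels.shape[0]
    t_p = (
        _weighted_t_one_sample(signs * diffs, wpair)
        if diffs.size >= 2 else np.zeros(R)
    )
    t_u = (
        _weighted_t_two_sample(labels, vals, wts)
        if vals.size >= 2 else np.zeros(R)
    )
    n_paired = 2 * diffs.size
    n_total = n_paired + vals.size
    a = weighting_factor(n_paired, n_total)
    T = t_p * math.sqrt(a) + t_u * math.sqrt(1.0 - a)
    return t_p, t_u, a, T


def combined_statistic(pairs: Sequence[EcosystemRatioPair]) -> PermutationResult:
    """T_observed and its components for the observed protection labels."""
    if not pairs:
        raise ValueError("no ecosystems provided")
    diffs, wpair, vals, wts, lbls = _split(pairs)
    t_p, t_u, a, T = _statistic(
        np.ones((1, diffs.size)), diffs, wpair, lbls[None, :], vals, wts
    )
    return PermutationResult(
        t_paired=float(t_p[0]), t_unpaired=float(t_u[0]), a=a,
        t_observed=float(T[0]), p_value=None, n_permutations=0,
    )


def permutation_test(
    pairs: Sequence[EcosystemRatioPair],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided permutation p-value for the protection effect.

    Complete ecosystems have their two labels swapped at random (a sign flip
    of the paired difference; the ecosystem weight is unchanged); incomplete
    ecosystems have their protection labels shuffled jointly (each
    observation keeps its own weight).  p uses the add-one correction
    (1 + #{|T*| >= |T_obs|}) / (R + 1) so it is never exactly 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    obs = combined_statistic(pairs)
    diffs, wpair, vals, wts, lbls = _split(pairs)
    rng = np.random.default_rng(seed)
    R = n_permutations
    signs = rng.integers(0, 2, size=(R, diffs.size)) * 2 - 1
    if vals.size:
        order = np.argsort(rng.random((R, vals.size)), axis=1)
        labels = lbls[order]
    else:
        labels = np.zeros((R, 0), bool)
    _, _, _, T = _statistic(signs.astype(float), diffs, wpair, labels, vals, wts)
    tol = 1e-12 * max(1.0, abs(obs.t_observed))
    hits = int(np.sum(np.abs(T) >= abs(obs.t_observed) - tol))
    p = (1.0 + hits) / (R + 1.0)
    return PermutationResult(
        t_paired=obs.t_paired, t_unpaired=obs.t_unpaired, a=obs.a,
        t_observed=obs.t_observed, p_value=p, n_permutations=R,
    )


def permutation_test_exact(pairs: Sequence[EcosystemRatioPair]) -> PermutationResult:
    """Exhaustive enumeration of all sign flips and label arrangements.

    Feasible for small problems (2^k sign patterns times C(m, m_protected)
    label placements); p is the plain fraction of enumerated |T*| >= |T_obs|,
    which includes the identity permutation.
    """
    obs = combined_statistic(pairs)
    diffs, wpair, vals, wts, lbls = _split(pairs)
    k, m = diffs.size, vals.size
    sign_rows = (
        np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
        if k else np.zeros((1, 0))
    )
    n_prot = int(lbls.sum())
    if m:
        label_rows = []
        for pos in itertools.combinations(range(m), n_prot):
            row = np.zeros(m, bool)
            row[list(pos)] = True
            label_rows.append(row)
        label_rows = np.array(label_rows, bool)
    else:
        label_rows = np.zeros((1, 0), bool)

    Ts = []
    for srow in sign_rows:
        _, _, _, T = _statistic(
            np.tile(srow, (label_rows.shape[0], 1)), diffs, wpair,
            label_rows, vals, wts,
        )
        Ts.append(T)
    T = np.concatenate(Ts)
    tol = 1e-12 * max(1.0, abs(obs.t_observed))
    p = float(np.mean(np.abs(T) >= abs(obs.t_observed) - tol))
    return PermutationResult(
        t_paired=obs.t_paired, t_unpaired=obs.t_unpaired, a=obs.a,
        t_observed=obs.t_observed, p_value=p, n_permutations=int(T.size),
    )
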