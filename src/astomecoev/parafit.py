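"""Distance-based global host-symbiont congruence (ParaFit-type) test.

Host and symbiont distance matrices are turned into principal coordinates
(Gower-centred double-centred PCoA); when the distances are non-Euclidean the
Lingoes correction adds a constant to the off-diagonal squared distances so
no negative eigenvalues remain.  The global statistic is the sum of squared
elements of the fourth-corner matrix D = P' A' H linking symbiont coordinates
P and host coordinates H through the binary association matrix A; its null
distribution is obtained by independently permuting each symbiont's
host-association vector.  Per-link statistics are the drop in the global
statistic when a link is removed (the difference form), tested against the
same permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import DistanceMatrix

__all__ = [
    "PcoaResult",
    "LinkMatrix",
    "ParafitResult",
    "pcoa_lingoes",
    "parafit_global",
    "parafit_links",
]

_REL_TOL = 1e-10  # eigenvalue tolerance, relative to the largest eigenvalue


@dataclass
class PcoaResult:
    coordinates: np.ndarray       # points x retained axes
    eigenvalues: np.ndarray       # nonincreasing, retained axes only
    lingoes_constant: float       # 0.0 when no correction was needed


@dataclass
class LinkMatrix:
    """Hosts-by-symbionts binary incidence."""

    hosts: list[str]
    symbionts: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.hosts), len(self.symbionts)):
            raise ValueError("link matrix shape mismatch")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("link entries must be 0 or 1")
        if self.values.sum() == 0:
            raise ValueError("empty link matrix")
        empty = np.where(self.values.sum(axis=0) == 0)[0]
        if empty.size:
            raise ValueError(
                f"symbionts with no links: {[self.symbionts[i] for i in empty]}")


@dataclass
class ParafitResult:
    global_statistic: float
    p_global: float
    per_link: list[tuple[str, str, float, float]]  # host, symbiont, stat, p
    n_permutations: int


def _gower_center(d_sq: np.ndarray) -> np.ndarray:
    n = d_sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_sq @ j


def pcoa_lingoes(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates with the Lingoes correction.

    If the smallest eigenvalue of the centred matrix is below -tol, the
    constant c = |lambda_min| is added to all off-diagonal squared distances
    (d'^2 = d^2 + 2c) and the decomposition repeated; afterwards no
    eigenvalue is meaningfully negative.  Axes with eigenvalues above the
    relative tolerance are retained and scaled by sqrt(lambda).
    """
    d = np.asarray(dm.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    def decompose(d_sq: np.ndarray):
        g = _gower_center(d_sq)
        vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(d ** 2)
    scale = max(abs(vals[0]), 1.0)
    c = 0.0
    if vals[-1] < -_REL_TOL * scale:
        c = float(-vals[-1])
        d_sq = d ** 2 + 2.0 * c
        np.fill_diagonal(d_sq, 0.0)
        vals, vecs = decompose(d_sq)
    tol = _REL_TOL * max(abs(vals[0]), 1.0)
    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return PcoaResult(coordinates=coords, eigenvalues=vals[keep],
                      lingoes_constant=c)


def _coords_for(dm: DistanceMatrix, labels: Sequence[str]) -> np.ndarray:
    order = [dm.labels.index(l) for l in labels]
    sub = DistanceMatrix(labels=list(labels),
                         values=dm.values[np.ix_(order, order)])
    return pcoa_lingoes(sub).coordinates


def _global_stat(h: np.ndarray, p: np.ndarray, a: np.ndarray) -> float:
    d = p.T @ a.T @ h
    return float((d ** 2).sum())


def parafit_global(d_host: DistanceMatrix, d_symb: DistanceMatrix,
                   links: LinkMatrix, n_permutations: int = 999,
                   seed: int = 0,
                   compute_links: bool = False) -> ParafitResult:
    """Global test of host-symbiont congruence with a permutation null.

    Each symbiont's host-association vector (a column of A) is permuted over
    hosts independently; p = (1 + #{null >= observed}) / (n_permutations + 1).
    With ``compute_links`` the per-link difference statistics and their
    p-values from the same permutations are included.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    h = _coords_for(d_host, links.hosts)
    p = _coords_for(d_symb, links.symbionts)
    a = links.values
    n_hosts, n_symb = a.shape
    rng = np.random.default_rng(seed)

    observed = _global_stat(h, p, a)
    link_cells = [(i, j) for i in range(n_hosts) for j in range(n_symb)
                  if a[i, j] == 1.0]
    obs_link_stats = {}
    if compute_links:
        for (i, j) in link_cells:
            a_red = a.copy()
            a_red[i, j] = 0.0
            obs_link_stats[(i, j)] = observed - _global_stat(h, p, a_red)

    count_ge = 0
    link_count_ge = {cell: 0 for cell in link_cells} if compute_links else {}
    for _ in range(n_permutations):
        a_perm = np.empty_like(a)
        for j in range(n_symb):
            a_perm[:, j] = a[rng.permutation(n_hosts), j]
        stat = _global_stat(h, p, a_perm)
        if stat >= observed - 1e-12:
            count_ge += 1
        if compute_links:
            d = p.T @ a_perm.T @ h
            for cell in link_cells:
                i, j = cell
                if a_perm[i, j] == 1.0:
                    # removing one link: D drops by the outer product term
                    d_red = d - np.outer(p[j], h[i])
                    perm_link = stat - float((d_red ** 2).sum())
                else:
                    # cell absent after permutation: the reduced computation
                    # removes nothing, so the difference statistic is zero
                    perm_link = 0.0
                if perm_link >= obs_link_stats[cell] - 1e-12:
                    link_count_ge[cell] += 1
    p_global = (1 + count_ge) / (n_permutations + 1)
    per_link = []
    if compute_links:
        for cell in link_cells:
            i, j = cell
            per_link.append((
                links.hosts[i], links.symbionts[j],
                obs_link_stats[cell],
                (1 + link_count_ge[cell]) / (n_permutations + 1),
            ))
    return ParafitResult(global_statistic=observed, p_global=p_global,
                         per_link=per_link, n_permutations=n_permutations)


def parafit_links(d_host: DistanceMatrix, d_symb: DistanceMatrix,
                  links: LinkMatrix, n_permutations: int = 999,
                  seed: int = 0) -> ParafitResult:
    """Global test plus per-link contribution statistics."""
    return parafit_global(d_host, d_symb, links, n_permutations=n_permutations,
                          seed=seed, compute_links=True)
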