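"""Corrected unweighted phylogenetic interaction-adjusted (PINA) similarity.

The unweighted PINA index compares two host communities by summing the
pairwise phylogenetic association Phi between their symbiont members.  The
corrected form normalises the cross-sample association sum by the geometric
mean of the two within-sample sums,

    P_U(A, B) = sum_{i in A} sum_{j in B} Phi_ij /
                sqrt( sum_{i,j in A} Phi_ij * sum_{i,j in B} Phi_ij ),

which is the unique normalisation under which a sample compared with itself
scores exactly 1 (identity of indiscernibles).  With Phi equal to the
identity matrix the index reduces to the cosine (Ochiai) similarity
|A ∩ B| / sqrt(|A| |B|).  P_U can exceed 1 for association matrices that are
not positive semidefinite; this is a property of the index, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.manifold import smacof

from .seqio import DistanceMatrix

__all__ = [
    "AssociationMatrix",
    "HostSample",
    "PinaMatrix",
    "MdsConfig",
    "association_from_distances",
    "pina_unweighted",
    "pina_matrix",
    "mds_embed",
]


@dataclass
class AssociationMatrix:
    """Symmetric symbiont-by-symbiont association matrix with unit diagonal."""

    taxa: list[str]
    phi: np.ndarray
    mode: str = "custom"

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.taxa)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa")
        if not np.allclose(self.phi, self.phi.T, atol=1e-12):
            raise ValueError("phi is not symmetric")
        if not np.allclose(np.diag(self.phi), 1.0, atol=1e-12):
            raise ValueError("phi diagonal must be 1")
        if (self.phi < -1e-12).any() or (self.phi > 1 + 1e-12).any():
            raise ValueError("phi entries must lie in [0, 1]")

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)


@dataclass
class HostSample:
    """A host species and the set of symbiont taxa it carries."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"host sample {self.name!r} has no members")


@dataclass
class PinaMatrix:
    hosts: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.hosts)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match hosts")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.hosts.index(a), self.hosts.index(b)])


@dataclass
class MdsConfig:
    """Metric-MDS (SMACOF) settings; the defaults follow the convergence
    protocol used for the ordinations (20,000 iterations, 250 random
    initialisations, epsilon 1e-8)."""

    n_components: int = 2
    max_iterations: int = 20000
    n_initializations: int = 250
    convergence_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_components, self.max_iterations, self.n_initializations) < 1:
            raise ValueError("MdsConfig sizes must be positive")
        if self.convergence_epsilon <= 0:
            raise ValueError("convergence_epsilon must be > 0")


def association_from_distances(dm: DistanceMatrix,
                               mode: str = "linear") -> AssociationMatrix:
    """Transform a distance matrix into an association matrix Phi.

    ``linear``: Phi_ij = 1 - d_ij, suited to p-distances (requires d <= 1).
    ``max_rescaled``: Phi_ij = 1 - d_ij / max(d), suited to unbounded
    cophenetic distances.  The diagonal is forced to exactly 1.
    """
    d = np.array(dm.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix has undefined entries")
    if mode == "linear":
        if (d > 1 + 1e-12).any():
            raise ValueError("linear mode requires distances <= 1")
        phi = 1.0 - d
    elif mode == "max_rescaled":
        dmax = d.max()
        phi = 1.0 - d / dmax if dmax > 0 else np.ones_like(d)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(phi, 1.0)
    return AssociationMatrix(taxa=list(dm.labels), phi=phi, mode=mode)


def _cross_sum(idx_a: np.ndarray, idx_b: np.ndarray, phi: np.ndarray) -> float:
    return float(phi[np.ix_(idx_a, idx_b)].sum())


def pina_unweighted(a: HostSample, b: HostSample,
                    phi: AssociationMatrix) -> float:
    """Corrected unweighted PINA similarity of two host samples."""
    try:
        ia = np.array([phi.index(t) for t in sorted(a.members)])
        ib = np.array([phi.index(t) for t in sorted(b.members)])
    except ValueError as exc:
        raise ValueError(f"sample member missing from association matrix: {exc}")
    within_a = _cross_sum(ia, ia, phi.phi)
    within_b = _cross_sum(ib, ib, phi.phi)
    if within_a <= 0 or within_b <= 0:
        raise ValueError("degenerate association: nonpositive within-sample sum")
    num = _cross_sum(ia, ib, phi.phi)
    return num / np.sqrt(within_a * within_b)


def pina_matrix(samples: Sequence[HostSample],
                phi: AssociationMatrix) -> PinaMatrix:
    """All pairwise corrected unweighted PINA similarities; unit diagonal."""
    if len(samples) < 2:
        raise ValueError("need at least two host samples")
    names = [s.name for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate host sample names")
    n = len(samples)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pina_unweighted(samples[i], samples[j], phi)
    return PinaMatrix(hosts=names, values=out)


def mds_embed(matrix: PinaMatrix | DistanceMatrix,
              config: Optional[MdsConfig] = None) -> tuple[np.ndarray, float]:
    """Metric MDS (SMACOF) embedding; returns (coordinates, final stress).

    A similarity matrix is first converted to dissimilarities as 1 - s.  The
    best (lowest-stress) embedding over the configured number of random
    initialisations is returned; the run is reproducible under a fixed seed.
    """
    config = config or MdsConfig()
    if isinstance(matrix, PinaMatrix):
        diss = 1.0 - matrix.values
        np.fill_diagonal(diss, 0.0)
        diss = np.clip(diss, 0.0, None)
    else:
        diss = np.array(matrix.values, dtype=float)
        if np.isnan(diss).any():
            raise ValueError("distance matrix has undefined entries")
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError("input must be square")
    coords, stress = smacof(
        diss,
        metric=True,
        n_components=config.n_components,
        init=None,
        n_init=config.n_initializations,
        max_iter=config.max_iterations,
        eps=config.convergence_epsilon,
        random_state=config.seed,
        normalized_stress=False,
    )
    return coords, float(stress)
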