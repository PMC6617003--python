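"""Random-effect structures: iid, intrinsic CAR, AR(1) and the four
space-time interaction priors.

The latent surface decomposes as ``S_it = u_i + v_i + k_t + l_t + phi_it``
with u spatially unstructured, v intrinsic-CAR (Besag), k temporally
unstructured, l stationary AR(1), and phi one of four interaction types
combining unstructured/structured space with unstructured/structured time:

====  =================================  ===========================
type  structure                          rank (I areas, T months)
====  =================================  ===========================
I     iid                                I*T
II    RW1 in time, iid across areas      I*(T-1)
III   ICAR in space, iid across months   T*(I-1)
IV    RW1 x ICAR                         (T-1)*(I-1)
====  =================================  ===========================

Interaction fields are stored area-major (``I x T``); their joint
precision refers to the C-order flattening ``(i, t) -> i*T + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core_data import AdjacencyGraph

INTERACTION_TYPES = ("I", "II", "III", "IV")


@dataclass
class STEffects:
    """One realization (or posterior summary) of the decomposed surface."""

    u: np.ndarray                  # length I
    v: np.ndarray                  # length I, sum-to-zero
    k: np.ndarray                  # length T
    l: np.ndarray                  # length T
    phi: np.ndarray                # I x T
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    sigma_k: float = 0.0
    sigma_l: float = 0.0
    sigma_phi: float = 0.0
    rho: float = 0.0
    sigma_r: float = 0.0
    interaction_type: str = "III"

    def surface(self) -> np.ndarray:
        """S = u + v + k + l + phi as an I x T matrix."""
        space = self.u + self.v
        time = self.k + self.l
        return space[:, None] + time[None, :] + self.phi


def icar_precision(graph: AdjacencyGraph) -> sparse.csr_matrix:
    """Intrinsic CAR structure matrix Q = D - A (unit scale, rank I-1
    on a connected graph); every row sums to zero."""
    A = graph.adjacency_matrix()
    D = sparse.diags(np.asarray(A.sum(axis=1)).ravel())
    return (D - A).tocsr()


def rw1_precision(T: int) -> sparse.csr_matrix:
    """First-order random-walk structure matrix (rank T-1)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    main = np.full(T, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(T - 1, -1.0)
    return sparse.diags([off, main, off], [-1, 0, 1]).tocsr()


def icar_full_conditional(v: np.ndarray, i: int, graph: AdjacencyGraph,
                          sigma_v: float) -> tuple[float, float]:
    """Conditional law of v_i given its neighbors under the intrinsic CAR:
    Normal(neighbor mean, sigma_v^2 / n_i)."""
    nbrs = graph.neighbor_lists[i]
    if not nbrs:
        raise ValueError(
            f"area {i} has no neighbors; the ICAR conditional is undefined "
            f"(connect the area or drop it from the graph)")
    v = np.asarray(v, dtype=float)
    return float(v[nbrs].mean()), float(sigma_v / np.sqrt(len(nbrs)))


def ar1_log_density(l: np.ndarray, rho: float, sigma_l: float) -> float:
    """Joint log-density of a stationary AR(1) path.

    l_1 ~ N(0, sigma^2/(1-rho^2)); l_t | l_{t-1} ~ N(rho l_{t-1}, sigma^2).
    Includes all additive constants.
    """
    if abs(rho) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
    if sigma_l <= 0:
        raise ValueError("sigma_l must be > 0")
    l = np.asarray(l, dtype=float)
    T = l.size
    var0 = sigma_l**2 / (1 - rho**2)
    out = -0.5 * np.log(2 * np.pi * var0) - l[0]**2 / (2 * var0)
    if T > 1:
        innov = l[1:] - rho * l[:-1]
        out += (-(T - 1) / 2 * np.log(2 * np.pi * sigma_l**2)
                - np.sum(innov**2) / (2 * sigma_l**2))
    return float(out)


def ar1_precision(T: int, rho: float, sigma_l: float) -> np.ndarray:
    """Dense tridiagonal precision of the stationary AR(1) path."""
    Q = np.zeros((T, T))
    idx = np.arange(T)
    Q[idx, idx] = 1 + rho**2
    Q[0, 0] = Q[-1, -1] = 1.0
    if T > 1:
        Q[idx[:-1], idx[1:]] = -rho
        Q[idx[1:], idx[:-1]] = -rho
    return Q / sigma_l**2


def sample_ar1(T: int, rho: float, sigma_l: float,
               rng: np.random.Generator) -> np.ndarray:
    """Draw a stationary AR(1) path of length T."""
    if abs(rho) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
    l = np.empty(T)
    z = rng.standard_normal(T)
    l[0] = z[0] * sigma_l / np.sqrt(1 - rho**2)
    for t in range(1, T):
        l[t] = rho * l[t - 1] + sigma_l * z[t]
    return l


def interaction_precision(itype: str, graph: AdjacencyGraph, T: int,
                          sigma_phi: float = 1.0):
    """Sparse joint precision of the interaction field and its rank.

    C-order (area-major) flattening of the I x T field; scaled by
    1/sigma_phi^2.  Types III/IV require a connected graph.
    """
    if itype not in INTERACTION_TYPES:
        raise ValueError(f"interaction type must be one of {INTERACTION_TYPES}")
    I = graph.n_areas
    if itype in ("III", "IV") and not graph.is_connected():
        raise ValueError(
            f"type {itype} interaction requires a connected adjacency graph")
    eye_I = sparse.identity(I, format="csr")
    eye_T = sparse.identity(T, format="csr")
    if itype == "I":
        Q, rank = sparse.identity(I * T, format="csr"), I * T
    elif itype == "II":
        Q, rank = sparse.kron(eye_I, rw1_precision(T), format="csr"), I * (T - 1)
    elif itype == "III":
        Q, rank = sparse.kron(icar_precision(graph), eye_T, format="csr"), T * (I - 1)
    else:
        Q = sparse.kron(icar_precision(graph), rw1_precision(T), format="csr")
        rank = (I - 1) * (T - 1)
    return Q / sigma_phi**2, rank


# ---------------------------------------------------------------------------
# spectral machinery for intrinsic GMRFs
# ---------------------------------------------------------------------------

@dataclass
class GMRFSpectrum:
    """Eigendecomposition of an intrinsic structure matrix.

    ``null_mask`` flags (numerically) zero eigenvalues — the improper
    directions of the intrinsic prior, removed by sum-to-zero constraints.
    """

    eigvals: np.ndarray
    eigvecs: np.ndarray
    null_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, float(self.eigvals.max(initial=1.0)))
        self.null_mask = self.eigvals < tol


_ICAR_SPECTRA: dict[int, GMRFSpectrum] = {}


def icar_spectrum(graph: AdjacencyGraph) -> GMRFSpectrum:
    """Cached eigendecomposition of the ICAR structure matrix."""
    key = id(graph)
    spec = _ICAR_SPECTRA.get(key)
    if spec is None:
        vals, vecs = np.linalg.eigh(icar_precision(graph).toarray())
        spec = GMRFSpectrum(vals, vecs)
        _ICAR_SPECTRA[key] = spec
    return spec


def rw1_spectrum(T: int) -> GMRFSpectrum:
    vals, vecs = np.linalg.eigh(rw1_precision(T).toarray())
    return GMRFSpectrum(vals, vecs)


def sample_constrained_gmrf(spec: GMRFSpectrum, sigma: float,
                            rng: np.random.Generator,
                            size: int = 1) -> np.ndarray:
    """Draw from the intrinsic GMRF conditioned on zero projection onto
    its null space (for ICAR/RW1: the sum-to-zero constraint).

    Covariance is sigma^2 times the Moore-Penrose pseudo-inverse of the
    structure matrix.  Returns ``size x n`` (squeezed if size == 1).
    """
    keep = ~spec.null_mask
    lam = spec.eigvals[keep]
    z = rng.standard_normal((size, keep.sum()))
    x = (z / np.sqrt(lam)) @ spec.eigvecs[:, keep].T * sigma
    return x[0] if size == 1 else x


def sample_constrained_icar(graph: AdjacencyGraph, sigma: float,
                            rng: np.random.Generator,
                            size: int = 1) -> np.ndarray:
    """Constrained (sum-to-zero) intrinsic CAR draw over the graph."""
    if not graph.is_connected():
        raise ValueError("constrained ICAR sampling requires a connected graph")
    return sample_constrained_gmrf(icar_spectrum(graph), sigma, rng, size)


def sample_interaction(itype: str, graph: AdjacencyGraph, T: int,
                       sigma_phi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw an I x T interaction field from the (constrained) prior.

    Type I: iid; II: independent constrained RW1 path per area;
    III: independent constrained ICAR field per month; IV: full
    Kronecker RW1 x ICAR draw constrained on both margins.
    """
    I = graph.n_areas
    if itype == "I":
        return rng.standard_normal((I, T)) * sigma_phi
    if itype == "II":
        return sample_constrained_gmrf(rw1_spectrum(T), sigma_phi, rng, size=I)
    if itype == "III":
        draws = sample_constrained_icar(graph, sigma_phi, rng, size=T)
        return draws.T.copy()
    if itype == "IV":
        ss, ts = icar_spectrum(graph), rw1_spectrum(T)
        lam = np.outer(ss.eigvals, ts.eigvals)
        keep = ~(ss.null_mask[:, None] | ts.null_mask[None, :])
        z = np.where(keep, rng.standard_normal((I, T)) / np.sqrt(np.where(keep, lam, 1.0)), 0.0)
        return sigma_phi * ss.eigvecs @ z @ ts.eigvecs.T
    raise ValueError(f"interaction type must be one of {INTERACTION_TYPES}")
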