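"""Principal network projection and core networks.

The stage network's adjacency matrix N (rows = target profiles) is decomposed
by SVD, N = U S V'. The right singular vectors v_i are the eigen-interactions
— principal patterns of interaction — and the fraction of the network
explained by the i-th one is r_i = sigma_i^2 / sum_j sigma_j^2 x 100%. The
smallest K with cumulative energy >= 85% (the usual PCA convention) defines
the principal modes; each protein is scored by the magnitude of its
interaction row's projection onto them, and proteins scoring above a
threshold (default > 6, admittedly data-scale dependent) form the core
network: the induced subgraph that concentrates the network's main structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .funcnet import DifferentialNetwork
from .netbuild import StageNetwork


@dataclass
class EigenDecomposition:
    """SVD of a stage network's adjacency with energy bookkeeping."""

    singular_values: np.ndarray
    eigen_interactions: np.ndarray  # columns of V, orthonormal
    energy_fractions: np.ndarray  # r_i, percent
    n_principal: int  # K: smallest count reaching the energy threshold
    energy_threshold: float
    protein_order: list[str]


def eigen_decompose(net: StageNetwork, energy_threshold: float = 85.0) -> EigenDecomposition:
    """Singular value decomposition of the dense stage-network matrix.

    ``energy_threshold`` is in percent; K is the smallest number of leading
    modes whose energy fractions sum to at least the threshold.
    """
    order = list(net.proteins)
    N = net.to_matrix(order)
    if not N.any():
        raise ValueError("all-zero network has no structure to decompose")
    _, s, Vt = np.linalg.svd(N)
    energy = s**2
    r = energy / energy.sum() * 100.0
    cumulative = np.cumsum(r)
    # guard the float boundary: 3 x 33.333..% must reach 100% at K = 3
    K = int(np.searchsorted(cumulative, energy_threshold - 1e-9) + 1)
    K = min(K, len(s))
    return EigenDecomposition(
        singular_values=s,
        eigen_interactions=Vt.T,
        energy_fractions=r,
        n_principal=K,
        energy_threshold=energy_threshold,
        protein_order=order,
    )


def protein_similarity(
    net: StageNetwork, eig: EigenDecomposition, mode: str = "l2"
) -> dict[str, float]:
    """Similarity of each protein's interactions to the principal modes.

    The interaction row a_i = (alpha_i1 ... alpha_iP) is projected onto the K
    principal eigen-interactions. ``mode='l2'`` (default) scores the 2-norm
    of the K projection coefficients — equal to ||a_i|| when K = P by
    orthonormality; ``mode='max'`` scores the largest absolute single-mode
    inner product instead.
    """
    if mode not in ("l2", "max"):
        raise ValueError("mode must be 'l2' or 'max'")
    A = net.to_matrix(eig.protein_order)
    proj = A @ eig.eigen_interactions[:, : eig.n_principal]
    if mode == "l2":
        scores = np.linalg.norm(proj, axis=1)
    else:
        scores = np.max(np.abs(proj), axis=1)
    return {p: float(s) for p, s in zip(eig.protein_order, scores)}


def select_core(similarity: dict[str, float], threshold: float = 6.0) -> set[str]:
    """Proteins whose similarity strictly exceeds the threshold."""
    return {p for p, s in similarity.items() if s > threshold}


@dataclass
class CoreNetwork:
    """Induced subgraph of a stage network on its core proteins."""

    core_proteins: list[str]
    adjacency: dict[tuple[str, str], float]
    beta: dict[str, float]
    similarity: dict[str, float] = field(default_factory=dict)
    stage: str = "C"


def core_network(
    net: StageNetwork, core, similarity: dict[str, float] | None = None
) -> CoreNetwork:
    """Restrict a stage network to its core proteins.

    Keeps the interactions with both endpoints in the core and carries the
    basal levels (and similarity scores, when given) over unchanged.
    """
    core = set(core)
    unknown = core - set(net.proteins)
    if unknown:
        raise ValueError(f"core proteins not in network: {sorted(unknown)[:5]}")
    adjacency = {
        (i, k): a for (i, k), a in net.adjacency.items() if i in core and k in core
    }
    return CoreNetwork(
        core_proteins=sorted(core),
        adjacency=adjacency,
        beta={p: net.beta[p] for p in core if p in net.beta},
        similarity={p: similarity[p] for p in core} if similarity else {},
        stage=net.stage,
    )


def flag_regulation_candidates(
    diff: DifferentialNetwork,
    mirna_targets: dict[str, list[str]],
    beta_change_min: float,
):
    """Partition large basal-level changes into miRNA vs. methylation candidates.

    Proteins whose |delta beta| reaches ``beta_change_min`` and that appear
    in the supplied miRNA-target table are candidate subjects of miRNA
    regulation; the remaining large-change proteins are candidate targets of
    methylation regulation. Returns two ``{protein: delta_beta}`` maps (the
    sign of delta beta carries the direction of the change).
    """
    if diff.node_delta is None:
        raise ValueError("differential network carries no basal-level changes")
    large = {
        p: d for p, d in diff.node_delta.items() if abs(d) >= beta_change_min
    }
    mirna = {p: d for p, d in large.items() if mirna_targets.get(p)}
    methylation = {p: d for p, d in large.items() if p not in mirna}
    return mirna, methylation
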