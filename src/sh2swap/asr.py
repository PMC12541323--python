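"""Maximum-likelihood ancestral sequence reconstruction on a fixed tree.

The model is a reversible 20-state continuous-time Markov chain built from an
empirical exchangeability matrix (the packaged default is JTT, estimated from
pairwise-aligned SWISS-PROT sequences) and its equilibrium amino-acid
frequencies.  Branch lengths come from the input tree and are taken as given;
there is no rate heterogeneity across sites and no branch-length
re-optimization.

Two reconstruction modes are provided, following the two standard ML
formulations:

* **marginal** — for one internal node, the per-site posterior distribution of
  its state given all leaf data, maximized site-by-site;
* **joint** — the single assignment of states to *all* internal nodes that
  maximizes the joint probability of the full tree (max-product dynamic
  programming).

Alignment gaps are handled by either of two strategies: ``prune`` removes
every column containing at least one gap (reconstruction against the shortest
sequence), while ``fill`` keeps every column and treats gaps as missing data
whose likelihood contribution is marginalized, so the reconstruction emits a
residue at every column (alignment against the longest sequence).

States are ordered alphabetically (``ACDEFGHIKLMNPQRSTVWY``) throughout, so
``argmax`` ties resolve to the lexicographically first amino acid; ties are
additionally logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seq_core import AMINO_ACIDS, AlignedSet, PhyloTree, ProteinSequence

log = logging.getLogger(__name__)

N_STATES = 20
_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING = -1


@dataclass
class RateModel:
    """Reversible amino-acid substitution model.

    ``exchangeabilities`` is the symmetric matrix S (zero diagonal) and
    ``frequencies`` the stationary distribution pi.  The generator is
    Q_ij = S_ij * pi_j (i != j), with the diagonal set so rows sum to zero,
    scaled so the expected substitution rate -sum_i pi_i Q_ii equals 1 —
    branch lengths are then in expected substitutions per site.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        S, pi = self.exchangeabilities, self.frequencies
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be 20x20 symmetric")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be positive and sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        self.Q = Q / rate
        # Symmetrize for the eigendecomposition: B = D^1/2 Q D^-1/2 is
        # symmetric for a reversible chain, giving an exact, stable expm.
        sqrt_pi = np.sqrt(pi)
        B = sqrt_pi[:, None] * self.Q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        # exp(Qt) = D^-1/2 V exp(L t) V^T D^1/2  with D = diag(pi)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]
        self._right = eigvec.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are probability distributions."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def load_paml_dat(path: str | Path | None = None) -> RateModel:
    """Load a PAML-layout ``.dat`` model file (lower triangle + frequencies).

    The file lists the strict lower triangle of the exchangeability matrix in
    19 rows followed by the 20 equilibrium frequencies, all in PAML
    amino-acid order; the loader reorders to the package's alphabetical
    state order.  With no argument, the packaged JTT matrix is loaded.
    """
    if path is None:
        ref = resources.files("sh2swap.data") / "jtt.dat"
        text = ref.read_text()
        name = "JTT"
    else:
        text = Path(path).read_text()
        name = Path(path).stem
    values: list[float] = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            values.extend(float(x) for x in line.split())
    if len(values) != 190 + 20:
        raise ValueError(f"expected 210 numbers in model file, got {len(values)}")
    S_paml = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S_paml[i, j] = S_paml[j, i] = values[k]
            k += 1
    pi_paml = np.array(values[190:])
    pi_paml /= pi_paml.sum()
    perm = [_PAML_ORDER.index(aa) for aa in AMINO_ACIDS]
    S = S_paml[np.ix_(perm, perm)]
    pi = pi_paml[perm]
    return RateModel(exchangeabilities=S, frequencies=pi, name=name)


# ---------------------------------------------------------------------------
# Gap handling


def prune_gap_columns(msa: AlignedSet) -> tuple[AlignedSet, list[int]]:
    """Remove every column containing at least one gap.

    Returns the pruned alignment and the list of retained original column
    indices (the column provenance map).  All columns gapped somewhere is an
    error.
    """
    kept = [
        j for j in range(msa.n_columns) if "-" not in msa.column(j)
    ]
    if not kept:
        raise ValueError("every column contains a gap; nothing left to analyze")
    records = [
        ProteinSequence(r.id, "".join(r.residues[j] for j in kept)) for r in msa
    ]
    return AlignedSet(records), kept


def fill_gap_columns(msa: AlignedSet) -> AlignedSet:
    """Keep all columns; gaps are treated as missing data downstream.

    A gap contributes a vector of ones to the pruning recursion (exact
    marginalization over the unobserved state), so reconstruction emits a
    residue at every column.  The alignment itself is returned unchanged —
    the gap characters are the missing-data markers.
    """
    return msa


def _encode(msa: AlignedSet) -> dict[str, np.ndarray]:
    out = {}
    for rec in msa:
        codes = np.array(
            [_AA_INDEX.get(aa, MISSING) for aa in rec.residues], dtype=np.int64
        )
        out[rec.id] = codes
    return out


# ---------------------------------------------------------------------------
# Tree indexing

@dataclass
class _Node:
    label: str
    index: int
    parent: int  # -1 for root
    branch_length: float  # to parent
    children: list[int]
    leaf_id: str | None  # bound sequence id, leaves only


def _index_tree(tree: PhyloTree) -> list[_Node]:
    """Flatten the dendropy tree into postorder-indexable nodes with labels."""
    nodes: list[_Node] = []
    mapping: dict[int, int] = {}
    counter = 0
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            leaf_id = label
        else:
            label = nd.label or (nd.taxon.label if nd.taxon else None)
            if not label:
                counter += 1
                label = f"node{counter}"
                nd.label = label
            leaf_id = None
        parent = mapping[id(nd.parent_node)] if nd.parent_node is not None else -1
        idx = len(nodes)
        mapping[id(nd)] = idx
        bl = nd.edge.length if nd.edge.length is not None else 0.0
        nodes.append(_Node(label, idx, parent, float(bl), [], leaf_id))
        if parent >= 0:
            nodes[parent].children.append(idx)
    labels = [n.label for n in nodes]
    if len(labels) != len(set(labels)):
        raise ValueError("node labels must be unique after auto-labelling")
    return nodes


def internal_node_labels(tree: PhyloTree) -> list[str]:
    return [n.label for n in _index_tree(tree) if n.leaf_id is None]


# ---------------------------------------------------------------------------
# Likelihood


@dataclass
class AncestorResult:
    """Reconstruction output for one internal node."""

    node_label: str
    map_sequence: str
    posteriors: np.ndarray | None  # (n_sites, 20) in marginal mode
    log_likelihood: float


def _leaf_conditional(codes: np.ndarray, n_sites: int) -> np.ndarray:
    L = np.zeros((n_sites, N_STATES))
    obs = codes >= 0
    L[np.arange(n_sites)[obs], codes[obs]] = 1.0
    L[~obs, :] = 1.0  # missing data: marginalized
    return L


def _check_bound(nodes: list[_Node], seqs: dict[str, np.ndarray]) -> None:
    for n in nodes:
        if n.leaf_id is not None and n.leaf_id not in seqs:
            raise ValueError(f"leaf {n.label!r} has no bound sequence")


def site_likelihood(tree: PhyloTree, msa: AlignedSet, model: RateModel) -> float:
    """Total log-likelihood by Felsenstein pruning, summed over sites.

    For a reversible model the value is independent of root placement
    (the pulley principle).
    """
    nodes = _index_tree(tree)
    seqs = _encode(msa)
    _check_bound(nodes, seqs)
    n_sites = msa.n_columns
    cond, scale = _pruning_conditionals(nodes, seqs, model, n_sites)
    root = 0
    site_l = cond[root] @ model.frequencies
    return float(np.sum(np.log(site_l)) + scale.sum())


def _pruning_conditionals(
    nodes: list[_Node],
    seqs: dict[str, np.ndarray],
    model: RateModel,
    n_sites: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Postorder conditionals L_v(site, state) with per-site log scaling."""
    cond: list[np.ndarray | None] = [None] * len(nodes)
    scale = np.zeros(n_sites)
    for n in reversed(nodes):  # preorder list reversed = valid postorder
        if n.leaf_id is not None:
            cond[n.index] = _leaf_conditional(seqs[n.leaf_id], n_sites)
        else:
            L = np.ones((n_sites, N_STATES))
            for c in n.children:
                P = model.transition_matrix(nodes[c].branch_length)
                L *= cond[c] @ P.T
            m = L.max(axis=1)
            m[m == 0] = 1.0
            L /= m[:, None]
            scale += np.log(m)
            cond[n.index] = L
    return cond, scale  # type: ignore[return-value]


def marginal_reconstruct(
    tree: PhyloTree,
    msa: AlignedSet,
    model: RateModel,
    node: str,
    gap_mode: str = "prune",
) -> AncestorResult:
    """Per-site posterior state distribution at one internal node.

    The posterior P(state at node | leaf data) is computed by re-rooting the
    (reversible) tree at the requested node and running the pruning recursion
    from there: the posterior is then proportional to pi_x times the
    conditional likelihood of all data given state x at the node.
    """
    msa = _apply_gap_mode(msa, gap_mode)
    nodes = _index_tree(tree)
    target = _find_internal(nodes, node)
    seqs = _encode(msa)
    _check_bound(nodes, seqs)
    n_sites = msa.n_columns

    adj = _adjacency(nodes)
    L, logscale = _conditional_from(target, adj, nodes, seqs, model, n_sites)
    joint = L * model.frequencies[None, :]
    site_l = joint.sum(axis=1)
    post = joint / site_l[:, None]
    loglik = float(np.sum(np.log(site_l)) + logscale)
    map_idx = post.argmax(axis=1)
    _log_ties(post, map_idx, node)
    map_seq = "".join(AMINO_ACIDS[i] for i in map_idx)
    return AncestorResult(node, map_seq, post, loglik)


def joint_reconstruct(
    tree: PhyloTree,
    msa: AlignedSet,
    model: RateModel,
    gap_mode: str = "prune",
) -> dict[str, AncestorResult]:
    """Jointly most probable assignment of states to all internal nodes.

    Max-product dynamic programming per site: an upward pass computes, for
    every node and every possible parent state, the best subtree score and
    backpointer; the root picks the global argmax and a downward pass reads
    the assignment off.  Ties resolve to the lexicographically first amino
    acid.  The returned log-likelihood (shared by all nodes) is the log joint
    probability of the best assignment together with the leaf data.
    """
    msa = _apply_gap_mode(msa, gap_mode)
    nodes = _index_tree(tree)
    seqs = _encode(msa)
    _check_bound(nodes, seqs)
    n_sites = msa.n_columns
    internals = [n.index for n in nodes if n.leaf_id is None]
    if not internals:
        raise ValueError("tree has no internal node")

    with np.errstate(divide="ignore"):
        logP = {
            n.index: np.log(model.transition_matrix(n.branch_length))
            for n in nodes
            if n.parent >= 0
        }
        log_pi = np.log(model.frequencies)

    # C[v]: (n_sites, 20) best log score of subtree v given each parent state.
    C: dict[int, np.ndarray] = {}
    B: dict[int, np.ndarray] = {}
    for n in reversed(nodes):
        if n.index == 0:
            continue
        if n.leaf_id is not None:
            codes = seqs[n.leaf_id]
            lp = logP[n.index]
            Cv = np.empty((n_sites, N_STATES))
            obs = codes >= 0
            Cv[obs] = lp[:, codes[obs]].T
            # missing leaf: sum_i P[j,i] = 1 -> log contribution 0
            Cv[~obs] = 0.0
            C[n.index] = Cv
            B[n.index] = np.repeat(
                codes[:, None], N_STATES, axis=1
            )  # leaf state is its own observation (unused for missing)
        else:
            inner = np.zeros((n_sites, N_STATES))
            for c in n.children:
                inner += C[c]
            # score[site, parent_state, own_state]
            score = logP[n.index][None, :, :] + inner[:, None, :]
            B[n.index] = score.argmax(axis=2)
            C[n.index] = score.max(axis=2)

    root = nodes[0]
    inner = np.zeros((n_sites, N_STATES))
    for c in root.children:
        inner += C[c]
    root_score = log_pi[None, :] + inner
    assign = {root.index: root_score.argmax(axis=1)}
    total_loglik = float(root_score.max(axis=1).sum())
    for n in nodes[1:]:
        if n.leaf_id is not None:
            continue
        parent_states = assign[n.parent]
        assign[n.index] = B[n.index][np.arange(n_sites), parent_states]

    out = {}
    for idx, states in assign.items():
        label = nodes[idx].label
        seq = "".join(AMINO_ACIDS[i] for i in states)
        out[label] = AncestorResult(label, seq, None, total_loglik)
    return out


def reconstruct_all_marginal(
    tree: PhyloTree, msa: AlignedSet, model: RateModel, gap_mode: str = "prune"
) -> dict[str, AncestorResult]:
    return {
        lbl: marginal_reconstruct(tree, msa, model, lbl, gap_mode=gap_mode)
        for lbl in internal_node_labels(tree)
    }


# -- helpers ----------------------------------------------------------------


def _apply_gap_mode(msa: AlignedSet, gap_mode: str) -> AlignedSet:
    if gap_mode == "prune":
        pruned, _ = prune_gap_columns(msa)
        return pruned
    if gap_mode == "fill":
        return fill_gap_columns(msa)
    raise ValueError(f"unknown gap_mode {gap_mode!r} (expected 'prune' or 'fill')")


def _find_internal(nodes: list[_Node], label: str) -> int:
    for n in nodes:
        if n.label == label:
            if n.leaf_id is not None:
                raise ValueError(f"node {label!r} is a leaf; reconstruction targets internal nodes")
            return n.index
    raise KeyError(f"no node labelled {label!r}")


def _adjacency(nodes: list[_Node]) -> dict[int, list[tuple[int, float]]]:
    adj: dict[int, list[tuple[int, float]]] = {n.index: [] for n in nodes}
    for n in nodes:
        if n.parent >= 0:
            adj[n.parent].append((n.index, n.branch_length))
            adj[n.index].append((n.parent, n.branch_length))
    return adj


def _conditional_from(
    start: int,
    adj: dict[int, list[tuple[int, float]]],
    nodes: list[_Node],
    seqs: dict[str, np.ndarray],
    model: RateModel,
    n_sites: int,
) -> tuple[np.ndarray, float]:
    """Conditional likelihood of all data given each state at ``start``.

    Iterative DFS over the unrooted adjacency graph (valid for reversible
    models).  Returns the (n_sites, 20) conditional and a summed log scaler.
    """
    logscale = 0.0
    cache: dict[tuple[int, int], np.ndarray] = {}

    order: list[tuple[int, int]] = []  # (node, coming_from)
    stack = [(start, -1)]
    while stack:
        v, frm = stack.pop()
        order.append((v, frm))
        for u, _t in adj[v]:
            if u != frm:
                stack.append((u, v))

    for v, frm in reversed(order):
        n = nodes[v]
        if n.leaf_id is not None and all(u == frm for u, _ in adj[v]):
            L = _leaf_conditional(seqs[n.leaf_id], n_sites)
        else:
            L = np.ones((n_sites, N_STATES))
            if n.leaf_id is not None:  # leaf used as interior start point
                L *= _leaf_conditional(seqs[n.leaf_id], n_sites)
            for u, t in adj[v]:
                if u == frm:
                    continue
                P = model.transition_matrix(t)
                L = L * (cache[(u, v)] @ P.T)
        if frm != -1:
            m = L.max(axis=1)
            m[m == 0] = 1.0
            L = L / m[:, None]
            logscale += float(np.sum(np.log(m)))
            cache[(v, frm)] = L
    # root of this traversal
    L = np.ones((n_sites, N_STATES))
    n = nodes[start]
    if n.leaf_id is not None:
        L *= _leaf_conditional(seqs[n.leaf_id], n_sites)
    for u, t in adj[start]:
        P = model.transition_matrix(t)
        L = L * (cache[(u, start)] @ P.T)
    m = L.max(axis=1)
    m[m == 0] = 1.0
    L = L / m[:, None]
    logscale += float(np.sum(np.log(m)))
    return L, logscale


def _log_ties(post: np.ndarray, map_idx: np.ndarray, node: str) -> None:
    best = post[np.arange(post.shape[0]), map_idx]
    n_tied = int(np.sum((np.abs(post - best[:, None]) < 1e-12).sum(axis=1) > 1))
    if n_tied:
        log.info("node %s: %d sites with tied MAP state (lexicographic break)", node, n_tied)
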