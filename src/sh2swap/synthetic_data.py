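"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three things the pipeline consumes:

* domain sets with controlled identity structure (for curation tests),
* a random phylogeny with sequences evolved along it under the same
  substitution model the reconstruction uses, retaining the true internal
  states (for reconstruction-recovery tests),
* complete sort-seq experiments with planted per-variant enrichments.

The sort-seq generative model mirrors the estimand of the fitness score:
library proportions pi are drawn once per experiment from a symmetric
Dirichlet (alpha = 5, giving realistic unevenness in per-variant depth);
each replicate's input sample is Multinomial(N_in, pi) and its sorted sample
is Multinomial(N_sort, w / sum w) with selection weight w_i = pi_i * 10^g_i,
where g_i is the variant's true log10 enrichment.  Under this model the
wild-type-normalized log-ratio score is a consistent estimator of
g_i - mean(g over wild-type synonyms), so planted values are recoverable to
within counting noise.  Wild-type synonyms have g = 0 exactly; stop-class
variants carry a strong negative g; an optional gain class carries positive
g.  Every draw is seeded — there is no silent nondeterminism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .asr import AMINO_ACIDS, N_STATES, RateModel
from .seq_core import AlignedSet, PhyloTree, ProteinSequence


@dataclass
class SimConfig:
    """Study conditions for one synthetic sort-seq experiment."""

    n_variants: int = 300
    n_wt_synonyms: int = 20
    n_stop: int = 10
    gain_values: tuple[float, ...] = (0.23,)
    fitness_mu: float = 0.0
    fitness_sigma: float = 0.3
    stop_fitness: float = -1.5
    input_depth: int = 1_000_000
    sort_depth: int = 1_000_000
    replicates: int = 4
    dirichlet_alpha: float = 5.0
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; there is no silent nondeterminism")
        if self.input_depth <= 0 or self.sort_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")


def make_ground_truth(config: SimConfig) -> pd.DataFrame:
    """Planted per-variant enrichments: columns ``g`` and ``class``.

    Classes: ``wt_synonym`` (g = 0 exactly), ``stop`` (strong negative),
    ``gain`` (one variant per configured positive value), ``extant``
    (normal(mu, sigma) background distribution).
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0x6774])
    ids, gs, classes = [], [], []
    for i in range(config.n_wt_synonyms):
        ids.append(f"wt_syn_{i+1:03d}")
        gs.append(0.0)
        classes.append("wt_synonym")
    for i in range(config.n_stop):
        ids.append(f"stop_{i+1:03d}")
        gs.append(config.stop_fitness)
        classes.append("stop")
    for i, g in enumerate(config.gain_values):
        ids.append(f"gain_{i+1:03d}")
        gs.append(float(g))
        classes.append("gain")
    n_extant = config.n_variants - len(ids)
    if n_extant < 0:
        raise ValueError("n_variants smaller than the planted classes")
    for i in range(n_extant):
        ids.append(f"var_{i+1:04d}")
        gs.append(float(rng.normal(config.fitness_mu, config.fitness_sigma)))
        classes.append("extant")
    return pd.DataFrame({"g": gs, "class": classes}, index=pd.Index(ids, name="variant_id"))


def simulate_experiment(
    truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Simulate input/sorted read counts for every replicate.

    Returns a CountTable (variants x (sample, replicate) MultiIndex columns).
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0xC0DE])
    n = len(truth)
    pi = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    w = pi * np.power(10.0, truth["g"].to_numpy())
    w = w / w.sum()
    data = {}
    for rep in range(1, config.replicates + 1):
        data[("input", rep)] = rng.multinomial(config.input_depth, pi)
        data[("sort", rep)] = rng.multinomial(config.sort_depth, w)
    table = pd.DataFrame(data, index=truth.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample", "replicate"])
    return table


def simulate_reads(
    oligos: dict[str, str],
    counts: Sequence[int],
    config: SimConfig,
    stream: int = 0,
) -> list[str]:
    """Uniform fixed-length fragments of each variant's oligo, with errors.

    ``counts`` gives the number of reads per variant (ordered as ``oligos``);
    substitution errors are applied uniformly at ``config.error_rate``.
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0x5EAD, stream])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads: list[str] = []
    for (vid, oligo), n_reads in zip(oligos.items(), counts):
        L = min(config.read_length, len(oligo))
        max_start = len(oligo) - L
        starts = rng.integers(0, max_start + 1, size=n_reads)
        for s in starts:
            frag = oligo[s : s + L]
            if config.error_rate > 0:
                arr = np.frombuffer(frag.encode(), dtype="S1").copy()
                hit = rng.random(L) < config.error_rate
                if hit.any():
                    arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                frag = arr.tobytes().decode()
            reads.append(frag)
    return reads


# ---------------------------------------------------------------------------
# Domains with controlled identity


def simulate_domains(
    n: int,
    ref: ProteinSequence,
    identity_targets: Sequence[float],
    seed: int,
) -> list[ProteinSequence]:
    """Mutants of ``ref`` hitting each identity target to within one column.

    ``identity_targets`` is cycled over the ``n`` outputs.  Substituted
    residues are always different from the reference residue, so the realized
    identity is exact at column resolution.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    L = len(ref.residues)
    out = []
    for i in range(n):
        target = identity_targets[i % len(identity_targets)]
        if not 0 < target <= 100:
            raise ValueError(f"identity target {target} outside (0, 100]")
        n_keep = round(L * target / 100.0)
        n_mut = L - n_keep
        if n_mut > L:
            raise ValueError("unreachable identity target")
        positions = rng.choice(L, size=n_mut, replace=False)
        residues = list(ref.residues)
        for p in positions:
            alts = [a for a in AMINO_ACIDS if a != ref.residues[p]]
            residues[p] = alts[rng.integers(len(alts))]
        out.append(ProteinSequence(f"sim_domain_{i+1:04d}", "".join(residues)))
    return out


# ---------------------------------------------------------------------------
# Trees and evolved sequences


def simulate_tree_and_sequences(
    n_leaves: int,
    branch_scale: float,
    model: RateModel,
    n_sites: int = 82,
    root_seq: str | None = None,
    seed: int = 0,
) -> tuple[PhyloTree, AlignedSet, dict[str, str]]:
    """Random topology + sequences evolved site-independently under ``model``.

    Every branch has length ``branch_scale`` (expected substitutions/site).
    Returns the tree (internal nodes labelled ``anc*``), the leaf alignment,
    and the true internal-node sequences keyed by label.
    """
    if branch_scale < 0:
        raise ValueError("branch_scale must be non-negative")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x7EE])

    taxa = dendropy.TaxonNamespace([f"leaf_{i+1}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # random topology by sequential joining
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node(taxon=taxa[i])
        nd.edge.length = branch_scale
        nodes.append(nd)
    anc_counter = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        anc_counter += 1
        parent = dendropy.Node()
        parent.label = f"anc{anc_counter}"
        parent.edge.length = branch_scale
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = tree.seed_node
    root.label = "root"
    for nd in nodes:
        root.add_child(nd)

    # evolve sequences root-down
    pi = model.frequencies
    if root_seq is None:
        root_states = rng.choice(N_STATES, size=n_sites, p=pi)
    else:
        if len(root_seq) != n_sites:
            raise ValueError("root_seq length must equal n_sites")
        root_states = np.array([AMINO_ACIDS.index(a) for a in root_seq])

    states: dict[int, np.ndarray] = {id(root): root_states}
    internal_truth: dict[str, str] = {"root": _decode(root_states)}
    leaf_records: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        parent_states = states[id(nd.parent_node)]
        P = model.transition_matrix(nd.edge.length or 0.0)
        cum = P.cumsum(axis=1)
        u = rng.random(n_sites)
        child_states = (cum[parent_states] < u[:, None]).sum(axis=1)
        states[id(nd)] = child_states
        if nd.is_leaf():
            leaf_records[nd.taxon.label] = _decode(child_states)
        else:
            internal_truth[nd.label] = _decode(child_states)

    msa = AlignedSet(
        [ProteinSequence(lbl, seq) for lbl, seq in leaf_records.items()]
    )
    return PhyloTree(tree), msa, internal_truth


def _decode(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(s)] for s in states)
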