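"""DNA-barcode species delimitation: K2P distances, NJ trees, monophyly.

Mirrors the standard COI-barcode identification workflow: pairwise Kimura
2-parameter distances on an aligned barcode fragment, a neighbor-joining
tree, bootstrap supports from column resampling, and a per-species
monophyly report.  Equal-length barcode fragments are treated as
positionally aligned; no progressive aligner is included.

The K2P distance is ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` where P
and Q are the transition and transversion proportions over
pairwise-complete sites (gaps and ambiguity codes dropped per pair by
default).  Saturated pairs (either log argument <= 0) yield ``inf`` as a
documented sentinel; :func:`nj_tree` refuses matrices containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeAlignment",
    "DistanceMatrix",
    "TreeWithSupport",
    "MonophylyReport",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_supports",
    "species_monophyly",
    "simulate_barcodes",
    "read_fasta",
    "write_fasta",
    "write_phylip_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = "AGCT"  # order matters for the simulator: transitions are 0<->1, 2<->3
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class BarcodeAlignment:
    """Aligned, species-labelled barcode sequences.

    ``records`` is a list of (sequence_id, species_label, sequence) with all
    sequences the same length over {A, C, G, T, -, N}.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for sid, species, _ in self.records:
            if not species:
                raise ValueError(f"sequence {sid!r}: empty species label")

    @property
    def length(self) -> int:
        return len(self.records[0][2])

    @property
    def sequence_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.records]

    @property
    def species_labels(self) -> dict[str, str]:
        return {sid: sp for sid, sp, _ in self.records}

    def resample_columns(self, rng: np.random.Generator) -> "BarcodeAlignment":
        """Bootstrap replicate: columns resampled with replacement."""
        idx = rng.integers(0, self.length, self.length)
        return BarcodeAlignment(
            records=[
                (sid, sp, "".join(seq[i] for i in idx)) for sid, sp, seq in self.records
            ]
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if np.any(m[np.isfinite(m)] < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @property
    def has_saturation(self) -> bool:
        return bool(np.any(~np.isfinite(self.matrix)))


@dataclass
class TreeWithSupport:
    """Unrooted NJ tree; internal-edge bootstrap supports in [0, 100] when set."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_replicates_used: int = 0

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class MonophylyReport:
    """Per-species monophyly verdicts and the overall success percentage."""

    per_species: dict[str, dict]
    overall_pct: float
    n_species: int
    n_monophyletic: int


# ---------------------------------------------------------------------------
# K2P distance


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance (substitutions/site) between two sequences.

    Sites where either sequence is not an unambiguous base are excluded
    pairwise.  Returns ``inf`` on saturation; raises when no comparable
    sites remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n_sites = n_ts = n_tv = 0
    for ca, cb in zip(a, b):
        if ca not in _BASE_INDEX or cb not in _BASE_INDEX:
            continue
        n_sites += 1
        if ca == cb:
            continue
        same_class = ({ca, cb} <= _PURINES) or ({ca, cb} <= _PYRIMIDINES)
        if same_class:
            n_ts += 1
        else:
            n_tv += 1
    if n_sites == 0:
        raise ValueError("no comparable (unambiguous) sites between sequences")
    p = n_ts / n_sites
    q = n_tv / n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        logger.warning("saturated pair (P=%.3f, Q=%.3f): distance set to inf", p, q)
        return float("inf")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def k2p_matrix(aln: BarcodeAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All pairwise K2P distances for an alignment.

    ``deletion='pairwise'`` drops ambiguous sites per pair;
    ``deletion='complete'`` first removes every column containing any
    non-ACGT symbol.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    seqs = [seq.upper() for _, _, seq in aln.records]
    if deletion == "complete":
        keep = [
            i
            for i in range(aln.length)
            if all(s[i] in _BASE_INDEX for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
        if not keep:
            raise ValueError("complete deletion removed all columns")
    k = len(seqs)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = k2p_distance(seqs[i], seqs[j])
    return DistanceMatrix(labels=list(aln.sequence_ids), matrix=m)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> TreeWithSupport:
    """Neighbor-joining tree from a distance matrix (supports unset).

    Standard agglomeration on the Q-matrix criterion; on additive input
    distances the path lengths of the returned tree reproduce the matrix
    exactly.  Negative branch-length estimates are clamped to zero with the
    usual compensating transfer to the sibling branch.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.has_saturation:
        raise ValueError(
            "distance matrix contains saturated (infinite) entries; filter or "
            "recompute distances before tree building"
        )
    d = dm.matrix.astype(float).copy()
    # each active node is a newick fragment (without trailing branch length)
    nodes: list[str] = [_quote(lbl) for lbl in dm.labels]
    n_clamped = 0

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        qmat = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(qmat, np.inf)
        i, j = np.unravel_index(np.argmin(qmat), qmat.shape)
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        vj = d[i, j] - vi
        if vi < 0:
            vj += -vi
            vi = 0.0
            n_clamped += 1
        if vj < 0:
            vi += -vj
            vj = 0.0
            n_clamped += 1
        new_node = f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})"
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_next = np.empty((r - 1, r - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [new_node]

    # resolve the final three nodes with the three-point formulas
    v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lens = []
    for v in (v0, v1, v2):
        if v < 0:
            n_clamped += 1
            v = 0.0
        lens.append(v)
    if n_clamped:
        logger.info("clamped %d negative NJ branch length(s) to zero", n_clamped)
    newick = (
        f"({nodes[0]}:{lens[0]:.10g},{nodes[1]}:{lens[1]:.10g},"
        f"{nodes[2]}:{lens[2]:.10g});"
    )
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return TreeWithSupport(tree=tree)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _internal_bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side
    paired with its complement via canonical frozenset-of-frozensets keys)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = frozenset({side, all_leaves - side})
            out[key] = node
    return out


def bootstrap_supports(
    aln: BarcodeAlignment,
    n_boot: int = 1000,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> TreeWithSupport:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal edge = percentage of valid replicates whose NJ
    tree contains the same bipartition.  Replicates whose distance matrix is
    saturated are skipped with a warning and removed from the denominator.
    """
    base_dm = k2p_matrix(aln, deletion=deletion)
    result = nj_tree(base_dm)
    target = _internal_bipartitions(result.tree)
    hits = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    n_valid = 0
    for _ in range(n_boot):
        rep = aln.resample_columns(rng)
        try:
            dm = k2p_matrix(rep, deletion=deletion)
            rep_tree = nj_tree(dm)
        except ValueError:
            logger.warning("bootstrap replicate skipped (saturated or degenerate)")
            continue
        n_valid += 1
        rep_bips = _internal_bipartitions(rep_tree.tree)
        for key in hits:
            if key in rep_bips:
                hits[key] += 1
    if n_valid == 0:
        raise ValueError("all bootstrap replicates failed")
    supports = {key: 100.0 * c / n_valid for key, c in hits.items()}
    for key, node in target.items():
        node.label = f"{supports[key]:.0f}"
    result.supports = supports
    result.n_replicates_used = n_valid
    return result


def species_monophyly(
    tree: TreeWithSupport | dendropy.Tree, labels: Mapping[str, str]
) -> MonophylyReport:
    """Monophyly verdict per species on an (unrooted) tree.

    A species is monophyletic iff some edge bipartition isolates exactly its
    leaves; single-sequence species are trivially monophyletic and flagged.
    """
    t = tree.tree if isinstance(tree, TreeWithSupport) else tree
    leaf_labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    missing = [lbl for lbl in leaf_labels if lbl not in labels]
    if missing:
        raise ValueError(f"leaves without species labels: {missing}")
    all_leaves = frozenset(leaf_labels)
    sides: set[frozenset] = set()
    for key in _internal_bipartitions(t):
        sides.update(key)
    # every trivial bipartition (single leaf | rest) exists on any tree
    by_species: dict[str, set[str]] = {}
    for leaf in leaf_labels:
        by_species.setdefault(labels[leaf], set()).add(leaf)

    per_species: dict[str, dict] = {}
    n_mono = 0
    for sp in sorted(by_species):
        leaves = frozenset(by_species[sp])
        if len(leaves) == 1:
            mono, trivial = True, True
        elif len(leaves) == len(all_leaves) - 1:
            # complement is a single leaf; its pendant edge isolates this species
            mono, trivial = True, False
        elif len(leaves) == len(all_leaves):
            mono, trivial = True, False  # the whole tree is one species
        else:
            mono = leaves in sides or (all_leaves - leaves) in sides
            trivial = False
        n_mono += mono
        per_species[sp] = {
            "n_sequences": len(leaves),
            "monophyletic": bool(mono),
            "trivial": trivial,
        }
    n_species = len(by_species)
    return MonophylyReport(
        per_species=per_species,
        overall_pct=100.0 * n_mono / n_species,
        n_species=n_species,
        n_monophyletic=n_mono,
    )


# ---------------------------------------------------------------------------
# Barcode simulator (test fixture generator)


def _k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """K2P site substitution probabilities after expected distance ``d``.

    ``kappa`` is the transition/transversion *rate* ratio alpha/beta; rates
    are scaled so the expected number of substitutions per site equals d.
    Base order A, G, C, T (transitions within {A,G} and {C,T}).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    P = np.full((4, 4), p_tv)
    for i, j in ((0, 1), (1, 0), (2, 3), (3, 2)):
        P[i, j] = p_ts
    np.fill_diagonal(P, p_same)
    return P


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return seq.copy()
    P = _k2p_transition_matrix(d, kappa)
    cum = np.cumsum(P, axis=1)
    u = rng.random(seq.size)
    return (u[:, None] > cum[seq]).sum(axis=1).astype(np.int8)


def simulate_barcodes(
    n_species: int,
    seqs_per_species: int,
    length: int = 650,
    intra_d: float = 0.01,
    inter_d: float = 0.10,
    seed: int | None = None,
    kappa: float = 4.0,
) -> BarcodeAlignment:
    """Simulate species-labelled barcode fragments under a K2P process.

    Species ancestors diverge from a common root so that expected pairwise
    interspecific distance is about ``inter_d``; conspecific sequences
    diverge from their ancestor by ``intra_d`` in expectation.  With
    ``intra_d = 0`` conspecific sequences are identical.
    """
    if not intra_d < inter_d:
        raise ValueError("need intra_d < inter_d")
    if length < 100:
        raise ValueError("barcode length must be >= 100")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, length).astype(np.int8)
    records: list[tuple[str, str, str]] = []
    width = len(str(n_species))
    for s in range(1, n_species + 1):
        ancestor = _evolve(root, inter_d / 2.0, kappa, rng)
        species = f"sp{s:0{width}d}"
        for k in range(1, seqs_per_species + 1):
            leaf = _evolve(ancestor, intra_d / 2.0, kappa, rng)
            records.append(
                (f"{species}_{k}", species, "".join(_BASES[b] for b in leaf))
            )
    return BarcodeAlignment(records=records)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, delimiter: str = "|") -> BarcodeAlignment:
    """Read an aligned FASTA whose headers are ``sequence_id<delim>species``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if delimiter not in header:
            raise ValueError(
                f"{path}: header {header!r} lacks the {delimiter!r} species delimiter"
            )
        sid, species = header.split(delimiter, 1)
        records.append((sid, species, str(rec.seq).upper()))
    return BarcodeAlignment(records=records)


def write_fasta(aln: BarcodeAlignment, path: str | Path, delimiter: str = "|") -> None:
    with open(path, "w") as fh:
        for sid, species, seq in aln.records:
            fh.write(f">{sid}{delimiter}{species}\n{seq}\n")


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP-format distance matrix (relaxed label width)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for lbl, row in zip(dm.labels, dm.matrix):
            fh.write(lbl.ljust(12) + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
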