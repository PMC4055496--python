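"""Distance-based phylogenetics for COI barcodes.

Implements pairwise p- and Kimura 2-parameter (K2P) distances on
equal-length gap-free alignments, Saitou–Nei neighbour joining with a
deterministic tie-break, and nonparametric bootstrap supports mapped
onto the full-data tree.  Trees are emitted as Newick with branch
lengths and integer supports as internal node labels.

K2P separates the transition fraction P from the transversion fraction
Q and estimates

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries an ambiguous base (N) or a gap are
excluded pairwise.  When the log argument is non-positive the pair is
saturated and a :class:`SaturationError` is raised naming the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "Clade",
    "p_distance",
    "k2p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "to_newick",
    "bipartitions",
    "patristic_distances",
    "random_additive_matrix",
]

# A/C/G/T -> 0..3; everything else (N, gaps, IUPAC ambiguity) -> 255.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, other=255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SaturationError(ValueError):
    """K2P distance undefined: substitution fractions saturate the model."""

    def __init__(self, pair: tuple[str, str] | None = None):
        self.pair = pair
        label = f" for pair {pair[0]!r}/{pair[1]!r}" if pair else ""
        super().__init__(f"K2P distance saturated (log argument <= 0){label}")


def _as_encoded(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def _valid_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length for distance computation")
    return (a < 4) & (b < 4)


def p_distance(seq_a, seq_b) -> float:
    """Proportion of differing sites, excluding N/gap sites pairwise."""
    a, b = _as_encoded(seq_a), _as_encoded(seq_b)
    valid = _valid_mask(a, b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites between sequences")
    return float(((a != b) & valid).sum()) / n


def k2p_distance(seq_a, seq_b, *, labels: tuple[str, str] | None = None) -> float:
    """Kimura 2-parameter distance between two aligned sequences."""
    a, b = _as_encoded(seq_a), _as_encoded(seq_b)
    valid = _valid_mask(a, b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites between sequences")
    diff = (a != b) & valid
    # A(0)/G(2) are even, C(1)/T(3) are odd: a substitution is a
    # transition iff both bases share parity.
    transition = diff & ((a & 1) == (b & 1))
    P = float(transition.sum()) / n
    Q = float(diff.sum()) / n - P
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(labels)
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


_MODELS: dict[str, Callable] = {"k2p": k2p_distance, "p": p_distance}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances with taxon labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @classmethod
    def from_alignment(
        cls, labels: Sequence[str], sequences: Sequence[str], model: str = "k2p"
    ) -> "DistanceMatrix":
        """Compute all pairwise distances on equal-length sequences."""
        dist = _MODELS[model]
        enc = [_as_encoded(s) for s in sequences]
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                kwargs = {"labels": (labels[i], labels[j])} if model == "k2p" else {}
                D[i, j] = D[j, i] = dist(enc[i], enc[j], **kwargs)
        return cls(tuple(labels), D)


@dataclass
class Clade:
    """Node of an (un)rooted tree; ``length`` is the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf():
            return [self]
        out: list[Clade] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())


def neighbor_joining(dm: DistanceMatrix) -> Clade:
    """Saitou–Nei neighbour joining.

    Joins the pair minimising the Q-criterion at every step; exact ties
    are broken by the lexicographic order of the clusters' smallest leaf
    labels.  Negative branch-length estimates are clamped to zero.  The
    returned tree is unrooted, represented with a trifurcating root.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")

    # canonical taxon order for full determinism regardless of input order
    order = sorted(range(n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    D = dm.values[np.ix_(order, order)].astype(float).copy()

    nodes: list[Clade] = [Clade(name=lab) for lab in labels]
    keys: list[str] = list(labels)  # smallest leaf label in each cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        # scan the upper triangle only: floating-point evaluation of
        # -r_i - r_j is not exactly symmetric, which would break the
        # exact-equality tie scan below
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        best = None
        for ii, jj in np.argwhere(Q == qmin):
            key = tuple(sorted((keys[active[ii]], keys[active[jj]])))
            if best is None or key < best[0]:
                best = (key, int(ii), int(jj))
        _, ii, jj = best
        i, j = active[ii], active[jj]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = d_ij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        joined = Clade(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        nodes[i] = joined
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # final three clusters: three-point formulas around the central node
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(length, 0.0)
    return Clade(children=[nodes[a], nodes[b], nodes[c]])


def to_newick(root: Clade, *, include_support: bool = True) -> str:
    """Serialise a tree as Newick; supports become internal node labels."""

    def fmt(node: Clade) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(child) for child in node.children)
        label = ""
        if include_support and node.support is not None:
            label = str(int(round(node.support)))
        return f"({inner}){label}:{node.length:.6f}"

    inner = ",".join(fmt(child) for child in root.children)
    return f"({inner});"


def bipartitions(root: Clade) -> dict[frozenset[str], Clade]:
    """Internal-edge bipartitions, canonicalised as the leaf side that
    excludes the alphabetically first taxon.  Maps bipartition -> the
    child node below the edge."""
    all_leaves = root.leaf_names()
    anchor = min(all_leaves)
    out: dict[frozenset[str], Clade] = {}

    def walk(node: Clade):
        for child in node.children:
            side = child.leaf_names()
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = side if anchor not in side else all_leaves - side
                out[frozenset(canon)] = child
            walk(child)

    walk(root)
    return out


def patristic_distances(root: Clade) -> DistanceMatrix:
    """Leaf-to-leaf path lengths along the tree."""

    def collect(node: Clade) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
        if node.is_leaf():
            return {node.name: node.length}, {}
        depths: dict[str, float] = {}
        pairs: dict[tuple[str, str], float] = {}
        per_child = []
        for child in node.children:
            d, p = collect(child)
            per_child.append(d)
            pairs.update(p)
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                for la, da in per_child[i].items():
                    for lb, db in per_child[j].items():
                        pairs[tuple(sorted((la, lb)))] = da + db
        for d in per_child:
            for leaf, depth in d.items():
                depths[leaf] = depth + node.length
        return depths, pairs

    _, pairs = collect(root)
    labels = tuple(sorted(root.leaf_names()))
    n = len(labels)
    D = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for (la, lb), d in pairs.items():
        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = d
    return DistanceMatrix(labels, D)


@dataclass
class BootstrapReport:
    n_replicates: int
    n_skipped: int


def bootstrap_support(
    labels: Sequence[str],
    sequences: Sequence[str],
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    model: str = "k2p",
) -> tuple[Clade, BootstrapReport]:
    """NJ tree from the full alignment with bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times;
    a tree is rebuilt per replicate and each internal bipartition of the
    full-data tree receives the percentage of replicates containing it.
    Replicates whose distance matrix is undefined (K2P saturation) are
    skipped and counted in the report.  Results are reproducible under a
    fixed seed and invariant to the input order of taxa.
    """
    if len(labels) < 3:
        raise ValueError("bootstrap requires at least 3 taxa")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires an alignment of equal-length sequences")
    n_cols = lengths.pop()
    if n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")

    # canonical order so supports do not depend on taxon input order
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    mat = np.stack([_as_encoded(sequences[i]) for i in order])

    full = neighbor_joining(DistanceMatrix.from_alignment(labels, mat, model))
    if n_reps == 0:
        return full, BootstrapReport(0, 0)

    splits = bipartitions(full)
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = mat[:, cols]
        try:
            dm = DistanceMatrix.from_alignment(labels, resampled, model)
        except (SaturationError, ValueError):
            skipped += 1
            continue
        rep_splits = bipartitions(neighbor_joining(dm))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    done = n_reps - skipped
    for split, node in splits.items():
        node.support = 100.0 * counts[split] / done if done else 0.0
    return full, BootstrapReport(n_reps, skipped)


def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator, *, min_length: float = 0.05, max_length: float = 1.0
) -> tuple[DistanceMatrix, Clade]:
    """Random unrooted binary tree and its (additive) path-length matrix.

    Useful as an independent oracle: NJ applied to the returned matrix
    must recover the generating topology exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"t{i:02d}" for i in range(n_taxa)]

    def edge(lo=min_length, hi=max_length):
        return float(rng.uniform(lo, hi))

    root = Clade(
        children=[Clade(name=labels[0], length=edge()),
                  Clade(name=labels[1], length=edge()),
                  Clade(name=labels[2], length=edge())]
    )
    # attach each further leaf by splitting a uniformly chosen edge
    for lab in labels[3:]:
        edges = []

        def gather(node):
            for child in node.children:
                edges.append((node, child))
                gather(child)

        gather(root)
        parent, child = edges[rng.integers(len(edges))]
        split_at = float(rng.uniform(0.25, 0.75)) * child.length
        mid = Clade(length=child.length - split_at,
                    children=[child, Clade(name=lab, length=edge())])
        child.length = split_at
        parent.children[parent.children.index(child)] = mid
    return patristic_distances(root), root
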