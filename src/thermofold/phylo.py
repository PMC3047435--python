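"""Distance-based phylogeny from structure-derived alignments.

Pairwise evolutionary distances are maximum-likelihood estimates under the
Jones-Taylor-Thornton (JTT) empirical amino-acid replacement model: for
each sequence pair the branch length t maximizing
sum_sites log(pi(a) P(a->b; t)) is found by bounded scalar optimization,
with gap-containing columns skipped (pairwise deletion) and no rate
heterogeneity.  Trees are built with the canonical Saitou-Nei
neighbor-joining algorithm; negative branch lengths are clamped to zero
with the deficit shifted to the sibling branch.  The closest
thermophile-mesophile pair is read off the tree by patristic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import TreeNode

logger = logging.getLogger(__name__)

JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"
T_MIN, T_MAX = 1e-6, 10.0


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Packaged JTT exchangeabilities (20x20 symmetric) and frequencies."""
    ref = resources.files("thermofold.data") / "jtt.dat"
    text = ref.read_text()
    section = None
    ex_vals: list[float] = []
    freqs: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "EXCHANGEABILITIES":
            section = "ex"
            continue
        if line == "FREQUENCIES":
            section = "fr"
            continue
        vals = [float(x) for x in line.split()]
        (ex_vals if section == "ex" else freqs).extend(vals)
    if len(ex_vals) != 190 or len(freqs) != 20:
        raise ValueError("malformed jtt.dat")
    s = np.zeros((20, 20))
    k = 0
    for col in range(19):              # column-major strict lower triangle
        for row in range(col + 1, 20):
            s[row, col] = s[col, row] = ex_vals[k]
            k += 1
    return s, np.array(freqs)


class _JTTModel:
    """Eigendecomposed JTT rate matrix, scaled to one substitution/site."""

    def __init__(self) -> None:
        s, pi = _load_jtt()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(1))
        scale = -(pi * np.diag(q)).sum()
        q /= scale
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]   # symmetric similar matrix
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        self.eigenvalues = w
        self.m = sqrt_pi[:, None] * u                   # M = diag(sqrt pi) U
        self.index = {aa: i for i, aa in enumerate(JTT_ORDER)}

    def joint_matrix(self, t: float) -> np.ndarray:
        """pi_a * P_ab(t); symmetric by time reversibility (and by
        construction, which makes the ML distance exactly symmetric)."""
        e = np.exp(self.eigenvalues * t)
        return (self.m * e) @ self.m.T


_MODEL: _JTTModel | None = None


def jtt_model() -> _JTTModel:
    global _MODEL
    if _MODEL is None:
        _MODEL = _JTTModel()
    return _MODEL


def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    model = jtt_model()
    counts = np.zeros((20, 20))
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        ia, ib = model.index.get(ca), model.index.get(cb)
        if ia is None or ib is None:    # gaps and ambiguity codes skipped
            continue
        counts[ia, ib] += 1
    return counts


def jtt_ml_distance(seq_a: str, seq_b: str, tol: float = 1e-8) -> float:
    """ML branch length (substitutions/site) between two aligned sequences."""
    counts = _pair_counts(seq_a, seq_b)
    n = counts.sum()
    if n == 0:
        raise ValueError("no comparable (both non-gap) columns")
    # time reversibility makes the likelihood direction-free; symmetrizing
    # the counts makes the computed distance exactly symmetric as well
    counts = 0.5 * (counts + counts.T)
    model = jtt_model()
    mask = counts > 0

    def neg_loglik(t: float) -> float:
        joint = model.joint_matrix(t)
        return -float((counts[mask] * np.log(np.maximum(joint[mask], 1e-300))).sum())

    res = minimize_scalar(neg_loglik, bounds=(T_MIN, T_MAX), method="bounded",
                          options={"xatol": tol})
    t_hat = float(res.x)
    if t_hat > T_MAX - 1e-3:
        logger.warning("ML distance at upper bound (%.3f); capped", T_MAX)
        t_hat = T_MAX
    return t_hat


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and nonnegative")

    def to_phylip(self) -> str:
        lines = [f"    {len(self.labels)}"]
        for label, row in zip(self.labels, self.d):
            name = f"{label[:10]:<10}"
            lines.append(name + " ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def read_fasta_alignment(text: str) -> dict[str, str]:
    from Bio import SeqIO

    records = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(StringIO(text), "fasta")}
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise ValueError("alignment records differ in length")
    return records


def distance_matrix_from_msa(msa: dict[str, str]) -> DistanceMatrix:
    """All pairwise JTT ML distances (pairwise deletion of gap columns)."""
    labels = list(msa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_ml_distance(msa[labels[i]], msa[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero and the deficit moved to
    the sibling branch, preserving the pairwise path length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three labels")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        gi, gj = active[i_s], active[j_s]
        dij = sub[i_s, j_s]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[gi], nodes[gj]
        child_i.length = round(li, 12)
        child_j.length = round(lj, 12)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        for k_s, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            new_row[gk] = 0.5 * (sub[i_s, k_s] + sub[j_s, k_s] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    ga, gb = active
    la = d[ga, gb]
    root = TreeNode()
    last = nodes[gb]
    first = nodes[ga]
    first.length = round(max(la, 0.0), 12)
    last.length = 0.0
    root.append(first)
    root.append(last)
    return root


def serialize_newick(tree: TreeNode) -> str:
    out = StringIO()
    tree.write(out)
    return out.getvalue().strip()


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text))


def patristic_distances(tree: TreeNode):
    return tree.tip_tip_distances()


def closest_cross_pair(tree: TreeNode, labels: dict[str, str]) -> tuple[str, str]:
    """Thermophile-mesophile leaf pair with minimal patristic distance.

    Ties break lexicographically on the sorted id pair.  Returns the pair
    ordered (thermophile, mesophile).
    """
    tips = [t.name for t in tree.tips()]
    thermo = [t for t in tips if labels.get(t) == "thermophile"]
    meso = [t for t in tips if labels.get(t) == "mesophile"]
    if not thermo or not meso:
        raise ValueError("tree must contain both thermophile and mesophile leaves")
    dmat = tree.tip_tip_distances()
    best = None
    for t in thermo:
        for m in meso:
            key = (float(dmat[t, m]), tuple(sorted((t, m))))
            if best is None or key < best[0]:
                best = (key, (t, m))
    return best[1]
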