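"""Pairwise structure superposition and substitution tallying.

A pair of structures is superposed by seeding residue equivalences from a
global sequence alignment (BLOSUM62, affine gaps), fitting the optimal
rigid transform with the Kabsch algorithm on C-alpha atoms, then
iteratively re-pairing residues by nearest C-alpha within 3.5 A and
re-fitting until the pair set stabilizes.  Substitutions at structurally
equivalent positions of a focus amino acid are tallied into eight chemical
classes: polar, aromatic, hydrophobic, acidic, basic, proline, cysteine,
glycine (proline, glycine and cysteine counted separately because of their
special structural roles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .structure_io import Structure, extract_sequence, first_protein_chain

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES: dict[str, str] = {}
for _cls, _members in {
    "polar": "STNQ", "aromatic": "FWYH", "hydrophobic": "AVLIM",
    "acidic": "DE", "basic": "KR", "proline": "P", "cysteine": "C",
    "glycine": "G",
}.items():
    for _aa in _members:
        SUBSTITUTION_CLASSES[_aa] = _cls
TALLY_CLASSES = ("polar", "aromatic", "hydrophobic", "acidic", "basic",
                 "proline", "cysteine", "glycine")


class AlignmentError(RuntimeError):
    """Raised when a pair of structures cannot be superposed."""


@dataclass
class PairAlignment:
    id_a: str
    id_b: str
    pairs: list[tuple[tuple[str, str, str], tuple[str, str, str]]]
    gaps: int
    rmsd: float
    identity_pct: float
    rotation: np.ndarray
    translation: np.ndarray

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)


@dataclass
class SubstitutionTally:
    focus_aa: str
    direction: str                       # "thermo->meso" or "meso->thermo"
    counts: dict[str, int]
    conserved: int
    unaligned: int
    total_occurrences: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_occurrences = sum(self.counts.values()) + self.conserved + self.unaligned


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of b onto a.

    Returns (rotation, translation, rmsd) such that
    ``coords_b @ rotation.T + translation`` best fits ``coords_a``; the
    reflection branch is corrected so det(rotation) = +1.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3")
    if len(a) < 3:
        raise ValueError("need at least three points")
    ca, cb = a.mean(0), b.mean(0)
    aa, bb = a - ca, b - cb
    if np.linalg.matrix_rank(bb) < 2 or np.linalg.matrix_rank(aa) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    h = bb.T @ aa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    fitted = bb @ rot.T + ca
    rmsd = float(np.sqrt(((fitted - a) ** 2).sum() / len(a)))
    return rot, trans, rmsd


def _seed_pairs_from_sequences(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    # BLOSUM62 has no 'X'; map unknowns to the wildcard-free score via 'A'
    clean_a = seq_a.replace("X", "A")
    clean_b = seq_b.replace("X", "A")
    aln = aligner.align(clean_a, clean_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def _parse_seed_alignment(fasta_text: str) -> list[tuple[int, int]]:
    """Equivalent position pairs from a two-record aligned FASTA."""
    from io import StringIO

    from Bio import SeqIO

    records = list(SeqIO.parse(StringIO(fasta_text), "fasta"))
    if len(records) != 2:
        raise AlignmentError(f"seed alignment must hold 2 records, got {len(records)}")
    sa, sb = str(records[0].seq), str(records[1].seq)
    if len(sa) != len(sb):
        raise AlignmentError("seed alignment records differ in length")
    pairs, ia, ib = [], 0, 0
    for ca, cb in zip(sa, sb):
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


def align_pair(
    a: Structure,
    b: Structure,
    seed_alignment: str | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
    repair_cutoff: float = 3.5,
    max_iter: int = 20,
    min_pairs: int = 30,
) -> PairAlignment:
    """Superpose two structures and report alignment statistics.

    Equivalences come from ``seed_alignment`` (aligned FASTA) when given,
    otherwise from a global sequence alignment; superposition is then
    refined by nearest-C-alpha re-pairing.
    """
    chain_a = chain_a or first_protein_chain(a)
    chain_b = chain_b or first_protein_chain(b)
    res_a = [r for r in a.chains[chain_a] if r.coord("CA") is not None]
    res_b = [r for r in b.chains[chain_b] if r.coord("CA") is not None]
    if len(res_a) < min_pairs or len(res_b) < min_pairs:
        raise AlignmentError("structures must have at least "
                             f"{min_pairs} residues with C-alpha")
    ca_a = np.array([r.coord("CA") for r in res_a])
    ca_b = np.array([r.coord("CA") for r in res_b])
    seq_a = "".join(r.aa for r in res_a)
    seq_b = "".join(r.aa for r in res_b)

    if seed_alignment is not None:
        pairs = _parse_seed_alignment(seed_alignment)
        bad = [(i, j) for i, j in pairs if i >= len(res_a) or j >= len(res_b)]
        if bad:
            raise AlignmentError("seed alignment refers to residues beyond the structures")
    else:
        pairs = _seed_pairs_from_sequences(seq_a, seq_b)
    if len(pairs) < 3:
        raise AlignmentError("fewer than three seeded equivalences")

    def fit(prs):
        ia = [i for i, _ in prs]
        ib = [j for _, j in prs]
        return kabsch(ca_a[ia], ca_b[ib])

    rot, trans, rmsd = fit(pairs)
    for _ in range(max_iter):
        moved_b = ca_b @ rot.T + trans
        tree = cKDTree(moved_b)
        dists, nearest = tree.query(ca_a, k=1)
        # mutual nearest neighbours within the cutoff, ties by sequence order
        back_tree = cKDTree(ca_a)
        bdists, bnearest = back_tree.query(moved_b, k=1)
        new_pairs = [(i, int(nearest[i])) for i in range(len(ca_a))
                     if dists[i] <= repair_cutoff and bnearest[nearest[i]] == i]
        new_pairs.sort()
        if len(new_pairs) < 3:
            break
        new_rot, new_trans, new_rmsd = fit(new_pairs)
        if new_pairs == pairs:
            rot, trans, rmsd = new_rot, new_trans, new_rmsd
            break
        # accept only non-worsening refinements (more pairs or lower rmsd)
        if new_rmsd <= rmsd + 1e-9 or len(new_pairs) > len(pairs):
            pairs, rot, trans, rmsd = new_pairs, new_rot, new_trans, new_rmsd
        else:
            break

    if len(pairs) < min_pairs:
        raise AlignmentError(f"only {len(pairs)} equivalent pairs after refinement "
                             f"(need {min_pairs})")
    identical = sum(1 for i, j in pairs if res_a[i].aa == res_b[j].aa)
    identity = 100.0 * identical / len(pairs)
    gaps = (len(res_a) - len(pairs)) + (len(res_b) - len(pairs))
    pair_ids = [((chain_a, res_a[i].seq_id, res_a[i].aa),
                 (chain_b, res_b[j].seq_id, res_b[j].aa)) for i, j in pairs]
    return PairAlignment(id_a=a.id, id_b=b.id, pairs=pair_ids, gaps=gaps,
                         rmsd=rmsd, identity_pct=identity,
                         rotation=rot, translation=trans)


def tally_substitutions(pa: PairAlignment, focus_aa: str,
                        direction: str = "thermo->meso",
                        class_map: dict[str, str] | None = None,
                        source_occurrences: int | None = None) -> SubstitutionTally:
    """Count partner amino-acid classes at aligned positions of a focus
    amino acid.

    ``direction`` names which structure carries the focus amino acid:
    "thermo->meso" reads focus positions off structure A, "meso->thermo"
    off structure B.  When ``source_occurrences`` (the focus amino acid's
    count in the full source structure) is given, positions outside the
    alignment are reported as ``unaligned`` so that
    counts + conserved + unaligned equals the occurrence total.
    """
    if focus_aa not in SUBSTITUTION_CLASSES:
        raise ValueError(f"focus amino acid {focus_aa!r} is not standard")
    class_map = class_map or SUBSTITUTION_CLASSES
    source_idx, partner_idx = (0, 1) if direction == "thermo->meso" else (1, 0)
    counts = {c: 0 for c in TALLY_CLASSES}
    conserved = 0
    aligned_source_positions = 0
    for pair in pa.pairs:
        src, other = pair[source_idx], pair[partner_idx]
        if src[2] != focus_aa:
            continue
        aligned_source_positions += 1
        if other[2] == focus_aa:
            conserved += 1
        elif other[2] in class_map:
            counts[class_map[other[2]]] += 1
    unaligned = 0
    if source_occurrences is not None:
        unaligned = source_occurrences - aligned_source_positions
        if unaligned < 0:
            raise ValueError("source_occurrences below aligned focus positions")
    return SubstitutionTally(focus_aa=focus_aa, direction=direction,
                             counts=counts, conserved=conserved,
                             unaligned=unaligned)


def count_focus_occurrences(s: Structure, chain: str, focus_aa: str) -> int:
    return extract_sequence(s, chain).count(focus_aa)


def pair_table(pa: PairAlignment):
    """Table 2-style one-row summary."""
    import pandas as pd

    return pd.DataFrame([{
        "id_a": pa.id_a, "id_b": pa.id_b, "rmsd": round(pa.rmsd, 2),
        "identity_pct": round(pa.identity_pct, 1),
        "aligned": pa.n_aligned, "gaps": pa.gaps,
    }])
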