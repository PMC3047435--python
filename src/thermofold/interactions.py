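"""Intramolecular interaction detection from atomic coordinates.

Nine interaction categories are detected with purely geometric criteria:
salt bridges (ionic), aromatic-aromatic pairs, aromatic-sulfur pairs,
cation-pi pairs, disulfide bridges, hydrophobic contacts, and hydrogen
bonds split into main-chain/main-chain (MC-MC), main-chain/side-chain
(MC-SC) and side-chain/side-chain (SC-SC).  Distance cutoffs follow the
conventions of interaction calculators used in comparative thermostability
studies: 6 A for ionic and cation-pi, a 4.5-7 A centroid window for
aromatic pairs, and 5.3 A for aromatic-sulfur.

Classification note: an N/O atom pair that satisfies the salt-bridge
criterion (cationic side-chain nitrogen vs anionic side-chain oxygen) is
reported as ionic only, never double-counted as a hydrogen bond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

CATEGORIES = (
    "hydrophobic",
    "hbond_mc_mc",
    "hbond_mc_sc",
    "hbond_sc_sc",
    "disulfide",
    "ionic",
    "aromatic_aromatic",
    "aromatic_sulfur",
    "cation_pi",
)

CATIONIC_ATOMS = {"K": ("NZ",), "R": ("NE", "NH1", "NH2"), "H": ("ND1", "NE2")}
ANIONIC_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
# six-membered ring definitions for the pi systems (Trp uses its six-ring)
RING_ATOMS = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
CATION_REFERENCE = {"K": "NZ", "R": "CZ"}
SULFUR_ATOMS = {"C": "SG", "M": "SD"}
HYDROPHOBIC_AAS = frozenset("AVLIMFWPY")
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# heavy-atom hydrogen-bond chemistry (N/O only; sulfur excluded)
SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"), "N": ("ND2",), "Q": ("NE2",),
    "H": ("ND1", "NE2"), "K": ("NZ",), "S": ("OG",), "T": ("OG1",),
    "W": ("NE1",), "Y": ("OH",),
}
SIDECHAIN_ACCEPTORS = {
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"), "N": ("OD1",), "Q": ("OE1",),
    "H": ("ND1", "NE2"), "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
}


@dataclass
class InteractionConfig:
    ionic_cutoff: float = 6.0
    aromatic_min: float = 4.5
    aromatic_max: float = 7.0
    aromatic_sulfur_cutoff: float = 5.3
    cation_pi_cutoff: float = 6.0
    hbond_da_cutoff: float = 3.5
    disulfide_cutoff: float = 2.5
    hydrophobic_cutoff: float = 5.0
    min_seq_separation: int = 2

    def __post_init__(self) -> None:
        for name in ("ionic_cutoff", "aromatic_min", "aromatic_max",
                     "aromatic_sulfur_cutoff", "cation_pi_cutoff",
                     "hbond_da_cutoff", "disulfide_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.aromatic_min >= self.aromatic_max:
            raise ValueError("aromatic_min must be below aromatic_max")


@dataclass(frozen=True)
class Interaction:
    category: str
    partner_a: tuple[str, str, str]  # (chain, seq_id, aa)
    partner_b: tuple[str, str, str]
    distance: float

    def residue_pair(self) -> frozenset:
        return frozenset((self.partner_a, self.partner_b))


@dataclass
class InteractionSet:
    structure_id: str
    interactions: list[Interaction]
    residue_count: int
    counts: dict[str, int] = field(init=False)
    normalized_counts: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {c: 0 for c in CATEGORIES}
        for it in self.interactions:
            self.counts[it.category] += 1
        denom = max(self.residue_count, 1)
        self.normalized_counts = {c: n / denom for c, n in self.counts.items()}


def _indexed_residues(s: Structure) -> list[tuple[str, Residue]]:
    return [(cid, r) for cid, r in s.residues() if r.aa != "X"]


def _partner(cid: str, r: Residue) -> tuple[str, str, str]:
    return (cid, r.seq_id, r.aa)


def sequence_separation(cid_a: str, res_a: Residue, cid_b: str, res_b: Residue) -> int:
    """Author residue-number separation within a chain; huge across chains."""
    if cid_a != cid_b:
        return 10**6
    return abs(res_a.number - res_b.number)


def _min_dist(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    diffs = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(-1)).min())


def ring_centroid(res: Residue) -> np.ndarray | None:
    names = RING_ATOMS.get(res.aa)
    if names is None or not res.has_atoms(names):
        return None
    return np.mean([res.coord(n) for n in names], axis=0)


def _pair_loop(s, cfg, aas_a, aas_b):
    """Yield (cid_a, res_a, cid_b, res_b) over residue pairs of the given
    amino-acid sets respecting the minimum sequence separation."""
    reslist = _indexed_residues(s)
    for (ca, ra), (cb, rb) in combinations(reslist, 2):
        ok = (ra.aa in aas_a and rb.aa in aas_b) or (ra.aa in aas_b and rb.aa in aas_a)
        if not ok:
            continue
        if sequence_separation(ca, ra, cb, rb) < cfg.min_seq_separation:
            continue
        if ra.aa in aas_a and rb.aa in aas_b:
            yield ca, ra, cb, rb
        else:
            yield cb, rb, ca, ra


def find_ionic(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Salt bridges: cationic side-chain N within the cutoff of an anionic
    side-chain O; one interaction per residue pair at the minimal distance."""
    cfg = cfg or InteractionConfig()
    out = []
    for ca, ra, cb, rb in _pair_loop(s, cfg, set(CATIONIC_ATOMS), set(ANIONIC_ATOMS)):
        cat_coords = [ra.coord(n) for n in CATIONIC_ATOMS[ra.aa] if ra.coord(n) is not None]
        ani_coords = [rb.coord(n) for n in ANIONIC_ATOMS[rb.aa] if rb.coord(n) is not None]
        if not cat_coords or not ani_coords:
            logger.debug("ionic: %s %s/%s missing side-chain atoms; skipped",
                         s.id, ra.seq_id, rb.seq_id)
            continue
        d = _min_dist(np.array(cat_coords), np.array(ani_coords))
        if d <= cfg.ionic_cutoff:
            out.append(Interaction("ionic", _partner(ca, ra), _partner(cb, rb), d))
    return out


def find_aromatic_aromatic(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Aromatic pairs with ring-centroid distance inside the window."""
    cfg = cfg or InteractionConfig()
    out = []
    reslist = [(c, r) for c, r in _indexed_residues(s) if r.aa in RING_ATOMS]
    for (ca, ra), (cb, rb) in combinations(reslist, 2):
        if sequence_separation(ca, ra, cb, rb) < cfg.min_seq_separation:
            continue
        pa, pb = ring_centroid(ra), ring_centroid(rb)
        if pa is None or pb is None:
            logger.debug("aromatic: %s incomplete ring; skipped", s.id)
            continue
        d = float(np.linalg.norm(pa - pb))
        if cfg.aromatic_min <= d <= cfg.aromatic_max:
            out.append(Interaction("aromatic_aromatic", _partner(ca, ra), _partner(cb, rb), d))
    return out


def find_cation_pi(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Lys NZ / Arg CZ within the cutoff of an aromatic ring centroid."""
    cfg = cfg or InteractionConfig()
    out = []
    for ca, ra, cb, rb in _pair_loop(s, cfg, set(CATION_REFERENCE), set(RING_ATOMS)):
        p = ra.coord(CATION_REFERENCE[ra.aa])
        centroid = ring_centroid(rb)
        if p is None or centroid is None:
            continue
        d = float(np.linalg.norm(p - centroid))
        if d <= cfg.cation_pi_cutoff:
            out.append(Interaction("cation_pi", _partner(ca, ra), _partner(cb, rb), d))
    return out


def find_aromatic_sulfur(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Cys SG / Met SD within the cutoff of an aromatic ring centroid."""
    cfg = cfg or InteractionConfig()
    out = []
    for ca, ra, cb, rb in _pair_loop(s, cfg, set(SULFUR_ATOMS), set(RING_ATOMS)):
        p = ra.coord(SULFUR_ATOMS[ra.aa])
        centroid = ring_centroid(rb)
        if p is None or centroid is None:
            continue
        d = float(np.linalg.norm(p - centroid))
        if d <= cfg.aromatic_sulfur_cutoff:
            out.append(Interaction("aromatic_sulfur", _partner(ca, ra), _partner(cb, rb), d))
    return out


def find_disulfide(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    cfg = cfg or InteractionConfig()
    out = []
    cys = [(c, r) for c, r in _indexed_residues(s) if r.aa == "C" and r.coord("SG") is not None]
    for (ca, ra), (cb, rb) in combinations(cys, 2):
        d = float(np.linalg.norm(ra.coord("SG") - rb.coord("SG")))
        if d <= cfg.disulfide_cutoff:
            out.append(Interaction("disulfide", _partner(ca, ra), _partner(cb, rb), d))
    return out


def find_hydrophobic(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Apolar residue pairs with any side-chain carbon-carbon contact."""
    cfg = cfg or InteractionConfig()
    out = []
    def side_carbons(r):
        return np.array([a.coord for a in r.atoms
                         if a.element == "C" and a.name not in BACKBONE_ATOMS])
    for ca, ra, cb, rb in _pair_loop(s, cfg, HYDROPHOBIC_AAS, HYDROPHOBIC_AAS):
        xa, xb = side_carbons(ra), side_carbons(rb)
        if xa.size == 0 or xb.size == 0:
            continue
        d = _min_dist(xa, xb)
        if d <= cfg.hydrophobic_cutoff:
            out.append(Interaction("hydrophobic", _partner(ca, ra), _partner(cb, rb), d))
    return out


def _is_salt_bridge_pair(res_d: Residue, name_d: str, res_a: Residue, name_a: str) -> bool:
    def cationic(res, name):
        return name in CATIONIC_ATOMS.get(res.aa, ())
    def anionic(res, name):
        return name in ANIONIC_ATOMS.get(res.aa, ())
    return (cationic(res_d, name_d) and anionic(res_a, name_a)) or \
           (cationic(res_a, name_a) and anionic(res_d, name_d))


def find_hbonds(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Distance-only hydrogen bonds on donor/acceptor heavy atoms (N/O).

    Categories by backbone membership of the two atoms: MC-MC, MC-SC,
    SC-SC.  MC-MC bonds between sequence neighbours (separation below
    ``min_seq_separation``) are excluded, as are atom pairs that qualify
    as salt bridges (those are reported by :func:`find_ionic`).
    Counted per donor-acceptor atom pair, deduplicated as unordered pairs.
    """
    cfg = cfg or InteractionConfig()
    reslist = _indexed_residues(s)

    donors, acceptors = [], []
    for ci, (cid, r) in enumerate(reslist):
        if r.coord("N") is not None and r.aa != "P":
            donors.append((cid, r, "N", True))
        for n in SIDECHAIN_DONORS.get(r.aa, ()):
            if r.coord(n) is not None:
                donors.append((cid, r, n, False))
        for n in ("O", "OXT"):
            if r.coord(n) is not None:
                acceptors.append((cid, r, n, True))
        for n in SIDECHAIN_ACCEPTORS.get(r.aa, ()):
            if r.coord(n) is not None:
                acceptors.append((cid, r, n, False))

    seen: set[frozenset] = set()
    out = []
    for cd, rd, nd, d_mc in donors:
        for ca_, ra_, na, a_mc in acceptors:
            if rd is ra_:
                continue
            key = frozenset(((cd, rd.seq_id, nd), (ca_, ra_.seq_id, na)))
            if key in seen:
                continue
            d = float(np.linalg.norm(rd.coord(nd) - ra_.coord(na)))
            if d > cfg.hbond_da_cutoff:
                continue
            if _is_salt_bridge_pair(rd, nd, ra_, na):
                continue
            if d_mc and a_mc:
                if sequence_separation(cd, rd, ca_, ra_) < cfg.min_seq_separation:
                    continue
                category = "hbond_mc_mc"
            elif d_mc or a_mc:
                category = "hbond_mc_sc"
            else:
                category = "hbond_sc_sc"
            seen.add(key)
            out.append(Interaction(category, _partner(cd, rd), _partner(ca_, ra_), d))
    return out


_DETECTORS = (
    find_hydrophobic,
    find_hbonds,
    find_disulfide,
    find_ionic,
    find_aromatic_aromatic,
    find_aromatic_sulfur,
    find_cation_pi,
)


def find_all(s: Structure, cfg: InteractionConfig | None = None) -> list[Interaction]:
    cfg = cfg or InteractionConfig()
    out: list[Interaction] = []
    for det in _DETECTORS:
        out.extend(det(s, cfg))
    order = {c: i for i, c in enumerate(CATEGORIES)}
    out.sort(key=lambda it: (order[it.category],
                             sorted([it.partner_a, it.partner_b]),
                             it.distance))
    return out


def summarize_interactions(s: Structure, cfg: InteractionConfig | None = None) -> InteractionSet:
    """Detect all categories and report per-residue normalized counts."""
    cfg = cfg or InteractionConfig()
    return InteractionSet(structure_id=s.id, interactions=find_all(s, cfg),
                          residue_count=s.length)


def interactions_table(iset: InteractionSet):
    """Per-interaction table as a pandas DataFrame (delimited-text ready)."""
    import pandas as pd

    rows = [{
        "structure_id": iset.structure_id,
        "category": it.category,
        "chain_a": it.partner_a[0], "seq_id_a": it.partner_a[1], "aa_a": it.partner_a[2],
        "chain_b": it.partner_b[0], "seq_id_b": it.partner_b[1], "aa_b": it.partner_b[2],
        "distance": round(it.distance, 3),
    } for it in iset.interactions]
    return pd.DataFrame(rows, columns=["structure_id", "category", "chain_a", "seq_id_a",
                                       "aa_a", "chain_b", "seq_id_b", "aa_b", "distance"])
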