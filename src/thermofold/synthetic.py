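"""Synthetic fixtures: PDB files with planted geometry and composition
cohorts with planted effects.

Structures are assembled from idealized residues (standard bond lengths
and angles, one canonical rotamer per amino acid) placed on a coarse grid
so that the only interatomic contacts are the ones deliberately planted.
Every planted interaction's defining distance is tuned to its target
within 0.05 A and the result is verified against the package's own
detectors before the PDB text is returned, so generation fails loudly on
an unrealizable specification.

Cohorts are per-protein amino-acid frequency vectors drawn as multinomial
counts from a base composition, with optional additive per-amino-acid
shifts in the thermophile group and Gaussian jitter; the defaults mirror a
two-group comparative study of 17 thermophiles vs 13 mesophiles of
roughly 400-residue proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import interactions as _inter
from .compstats import CompositionProfile
from .structure_io import AA1TO3, STANDARD_AAS, Structure, parse_structure

__all__ = [
    "PlantedStructureSpec", "CohortSpec", "GenerationError",
    "make_planted_structure", "make_cohort", "make_paired_structures",
    "make_ideal_helix", "make_antiparallel_sheet", "make_extended_chain",
]


class GenerationError(RuntimeError):
    """Raised when a fixture specification cannot be realized."""


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: new atom x bonded to c with
    |x-c| = bond, angle(x,c,b) = angle and torsion(x,c,b,a) = torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # collinear frame; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, math.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis: np.ndarray, theta: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(theta), math.sin(theta)
    cc = 1 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])


# backbone ideal internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# side-chain topology: atom -> (frame atoms a, b, c), bond, angle, torsion.
# Chains use a single canonical (extended, chi = 180) rotamer; branches use
# +/-60.  Rings are built analytically (regular polygons) afterwards.
_SIDE_TOPO: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "A": [],
    "R": [("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
          ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
          ("CZ", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
          ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
          ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "N": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
          ("OD1", ("CA", "CB", "CG"), 1.23, 121.0, -90.0),
          ("ND2", ("CA", "CB", "CG"), 1.33, 117.0, 90.0)],
    "D": [("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
          ("OD1", ("CA", "CB", "CG"), 1.25, 119.0, -90.0),
          ("OD2", ("CA", "CB", "CG"), 1.25, 119.0, 90.0)],
    "C": [("SG", ("N", "CA", "CB"), 1.81, 114.0, 180.0)],
    "Q": [("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
          ("OE1", ("CB", "CG", "CD"), 1.23, 121.0, -90.0),
          ("NE2", ("CB", "CG", "CD"), 1.33, 117.0, 90.0)],
    "E": [("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
          ("OE1", ("CB", "CG", "CD"), 1.25, 119.0, -90.0),
          ("OE2", ("CB", "CG", "CD"), 1.25, 119.0, 90.0)],
    "G": [],
    "H": [("CG", ("N", "CA", "CB"), 1.50, 113.0, 180.0)],   # + pentagon
    "I": [("CG1", ("N", "CA", "CB"), 1.53, 110.0, 180.0),
          ("CG2", ("N", "CA", "CB"), 1.53, 110.0, -60.0),
          ("CD1", ("CA", "CB", "CG1"), 1.52, 114.0, 180.0)],
    "L": [("CG", ("N", "CA", "CB"), 1.53, 117.0, 180.0),
          ("CD1", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
          ("CD2", ("CA", "CB", "CG"), 1.52, 111.0, 60.0)],
    "K": [("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
          ("CE", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
          ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0)],
    "M": [("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("SD", ("CA", "CB", "CG"), 1.80, 112.0, 180.0),
          ("CE", ("CB", "CG", "SD"), 1.79, 100.0, 180.0)],
    "F": [("CG", ("N", "CA", "CB"), 1.50, 114.0, 180.0)],   # + hexagon
    "P": [("CG", ("N", "CA", "CB"), 1.49, 104.0, 30.0),
          ("CD", ("CA", "CB", "CG"), 1.50, 105.0, -35.0)],
    "S": [("OG", ("N", "CA", "CB"), 1.42, 111.0, 180.0)],
    "T": [("OG1", ("N", "CA", "CB"), 1.43, 110.0, 180.0),
          ("CG2", ("N", "CA", "CB"), 1.52, 111.0, -60.0)],
    "W": [("CG", ("N", "CA", "CB"), 1.50, 114.0, 180.0)],   # + fused rings
    "Y": [("CG", ("N", "CA", "CB"), 1.50, 114.0, 180.0)],   # + hexagon + OH
    "V": [("CG1", ("N", "CA", "CB"), 1.53, 111.0, 180.0),
          ("CG2", ("N", "CA", "CB"), 1.53, 111.0, -60.0)],
}

_RING_BOND = 1.39


def _regular_ring(atoms: dict[str, np.ndarray], names: list[str],
                  anchor: str, stem: str, plane_ref: str) -> None:
    """Place a regular polygon with vertex 0 at ``anchor``, lying in the
    plane of (plane_ref, stem, anchor), extending away from ``stem``."""
    n = len(names) + 1
    r = _RING_BOND / (2.0 * math.sin(math.pi / n))
    p_anchor, p_stem, p_ref = atoms[anchor], atoms[stem], atoms[plane_ref]
    u = p_anchor - p_stem
    u /= np.linalg.norm(u)
    normal = np.cross(p_stem - p_ref, u)
    normal /= np.linalg.norm(normal)
    v = np.cross(normal, u)
    center = p_anchor + u * r
    for k, name in enumerate(names, start=1):
        theta = math.pi + 2.0 * math.pi * k / n
        atoms[name] = center + r * (math.cos(theta) * u + math.sin(theta) * v)


def _build_side_chain(aa: str, atoms: dict[str, np.ndarray]) -> None:
    if aa == "G":
        return
    # CB off the backbone frame
    atoms["CB"] = _place(atoms["N"], atoms["C"], atoms["CA"], 1.53, 110.6, -122.6)
    for name, (fa, fb, fc), bond, ang, tor in _SIDE_TOPO[aa]:
        atoms[name] = _place(atoms[fa], atoms[fb], atoms[fc], bond, ang, tor)
    if aa in ("F", "Y"):
        _regular_ring(atoms, ["CD1", "CE1", "CZ", "CE2", "CD2"], "CG", "CB", "CA")
        if aa == "Y":
            center = np.mean([atoms[x] for x in
                              ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")], axis=0)
            direction = atoms["CZ"] - center
            atoms["OH"] = atoms["CZ"] + 1.38 * direction / np.linalg.norm(direction)
    elif aa == "H":
        _regular_ring(atoms, ["ND1", "CE1", "NE2", "CD2"], "CG", "CB", "CA")
    elif aa == "W":
        _regular_ring(atoms, ["CD1", "NE1", "CE2", "CD2"], "CG", "CB", "CA")
        _fuse_hexagon(atoms)


def _fuse_hexagon(atoms: dict[str, np.ndarray]) -> None:
    """Attach the Trp six-ring on the CE2-CD2 edge of the pentagon."""
    p0, p1 = atoms["CE2"], atoms["CD2"]
    penta_center = np.mean([atoms[x] for x in ("CG", "CD1", "NE1", "CE2", "CD2")], axis=0)
    mid = 0.5 * (p0 + p1)
    edge = p1 - p0
    edge_len = np.linalg.norm(edge)
    w = mid - penta_center
    w -= edge * (np.dot(w, edge) / edge_len**2)
    w /= np.linalg.norm(w)
    apothem = edge_len * math.sqrt(3.0) / 2.0
    r_hex = edge_len
    center = mid + w * apothem
    normal = np.cross(edge, w)
    normal /= np.linalg.norm(normal)
    u = (p0 - center) / np.linalg.norm(p0 - center)
    v = np.cross(normal, u)
    theta1 = math.atan2(np.dot(p1 - center, v), np.dot(p1 - center, u))
    step = theta1 / 5.0  # walk from p0 (angle 0) to p1 in five steps
    for k, name in enumerate(("CZ2", "CH2", "CZ3", "CE3"), start=1):
        th = step * k
        atoms[name] = center + r_hex * (math.cos(th) * u + math.sin(th) * v)


def _build_backbone(n: int, phis, psis, omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Connected backbone (N, CA, C, O per residue) from dihedral lists."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = _place(np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, -60.0)
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = res[-1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i in range(n):
        if i + 1 < n:
            res[i]["O"] = _place(res[i + 1]["N"], res[i]["CA"], res[i]["C"],
                                 _B_C_O, _A_CA_C_O, 180.0)
        else:
            res[i]["O"] = _place(res[i]["N"], res[i]["CA"], res[i]["C"],
                                 _B_C_O, _A_CA_C_O, psis[i] + 180.0 if i < len(psis) else 0.0)
    return res


def _build_residue(aa: str) -> dict[str, np.ndarray]:
    """A lone idealized residue with its side chain, near the origin."""
    bb = _build_backbone(1, [180.0], [180.0])[0]
    atoms = dict(bb)
    _build_side_chain(aa, atoms)
    return atoms


def _element_of(name: str) -> str:
    return name.strip()[0]


def _format_pdb(records: list[tuple[str, int, str, str, np.ndarray]]) -> str:
    """records: (chain, resnum, aa1, atom_name, coord)."""
    lines = []
    serial = 1
    prev_chain = None
    for chain, resnum, aa, name, xyz in records:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        resname = AA1TO3[aa]
        aname = name if len(name) == 4 else f" {name:<3}"
        lines.append(
            f"ATOM  {serial:>5} {aname}{'':1}{resname} {chain}{resnum:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {_element_of(name):>2}"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


_ATOM_ORDER = ["N", "CA", "C", "O", "CB"]


def _residue_records(chain: str, resnum: int, aa: str,
                     atoms: dict[str, np.ndarray]) -> list:
    names = [n for n in _ATOM_ORDER if n in atoms]
    names += [n for n in atoms if n not in _ATOM_ORDER]
    return [(chain, resnum, aa, n, atoms[n]) for n in names]


# ---------------------------------------------------------------------------
# planted-interaction structures
# ---------------------------------------------------------------------------

@dataclass
class PlantedStructureSpec:
    residues: list[str]
    planted_interactions: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    ss_motifs: list[tuple[str, int, int]] = field(default_factory=list)  # (kind, start, length)

    def __post_init__(self) -> None:
        n = len(self.residues)
        for aa in self.residues:
            if aa not in STANDARD_AAS:
                raise GenerationError(f"nonstandard residue {aa!r}")
        used: set[int] = set()
        for cat, (i, j), target in self.planted_interactions:
            if cat not in _PLANT_RULES:
                raise GenerationError(f"cannot plant category {cat!r}")
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise GenerationError(f"bad planted pair ({i}, {j})")
            if i in used or j in used:
                raise GenerationError("a residue may appear in one planted pair only")
            used.update((i, j))
            lo, hi = _PLANT_RULES[cat]["window"]
            if not lo <= target <= hi:
                raise GenerationError(
                    f"target {target} A outside realizable window [{lo}, {hi}] for {cat}")
        motif_res: set[int] = set()
        for kind, start, length in self.ss_motifs:
            if kind not in ("helix", "strand"):
                raise GenerationError(f"unknown motif kind {kind!r}")
            span = set(range(start, start + length))
            if not span <= set(range(n)):
                raise GenerationError("motif outside residue list")
            if span & used or span & motif_res:
                raise GenerationError("motif overlaps planted residues or another motif")
            motif_res |= span


# per-category planting rules: defining-metric evaluator and admissible window
def _ionic_points(res_aa, atoms):
    prim = {"K": "NZ", "R": "NH1", "H": "ND1"}.get(res_aa)
    return atoms[prim] if prim else atoms[{"D": "OD1", "E": "OE1"}[res_aa]]


_PLANT_RULES = {
    "ionic": {"window": (2.8, 6.0)},
    "aromatic_aromatic": {"window": (4.5, 7.0)},
    "aromatic_sulfur": {"window": (3.5, 5.3)},
    "cation_pi": {"window": (3.5, 6.0)},
    "disulfide": {"window": (1.9, 2.5)},
    "hydrophobic": {"window": (3.5, 5.0)},
    "hbond_sc_sc": {"window": (2.6, 3.5)},
}

_AROMATIC = set(_inter.RING_ATOMS)


def _defining_geometry(cat: str, aa: str, atoms: dict[str, np.ndarray],
                       role: str) -> tuple[np.ndarray, np.ndarray | None]:
    """(defining point, orientation direction) for a planted partner.

    The orientation direction is what gets aligned with the planting axis:
    the CA->point vector for atom-defined partners, the ring normal for
    aromatic partners.
    """
    if cat in ("aromatic_aromatic",) or (cat in ("cation_pi", "aromatic_sulfur")
                                         and aa in _AROMATIC and role == "b"):
        names = _inter.RING_ATOMS[aa]
        centroid = np.mean([atoms[x] for x in names], axis=0)
        n1 = np.cross(atoms[names[1]] - atoms[names[0]],
                      atoms[names[2]] - atoms[names[0]])
        return centroid, n1 / np.linalg.norm(n1)
    if cat == "ionic":
        point = _ionic_points(aa, atoms)
    elif cat == "cation_pi":
        point = atoms[_inter.CATION_REFERENCE[aa]]
    elif cat == "aromatic_sulfur":
        point = atoms[_inter.SULFUR_ATOMS[aa]]
        if aa == "M":
            # keep both sulfur-bonded carbons behind SD so no Met carbon
            # strays into hydrophobic-contact range of the ring
            return point, point - 0.5 * (atoms["CG"] + atoms["CE"])
    elif cat == "disulfide":
        point = atoms["SG"]
    elif cat == "hydrophobic":
        carbons = [n for n in atoms if n[0] == "C" and n not in ("CA", "C")]
        point = atoms[max(carbons, key=lambda n: len(n))]
    elif cat == "hbond_sc_sc":
        donor = next((n for n in _inter.SIDECHAIN_DONORS.get(aa, ()) if n in atoms), None)
        acc = next((n for n in _inter.SIDECHAIN_ACCEPTORS.get(aa, ()) if n in atoms), None)
        name = donor or acc
        if name is None:
            raise GenerationError(f"{aa} has no side-chain donor/acceptor")
        point = atoms[name]
    else:  # pragma: no cover
        raise GenerationError(f"no planting rule for {cat}")
    return point, point - atoms["CA"]


def _category_metric(cat: str, struct: Structure, key_a, key_b) -> float | None:
    """Measured defining distance of a detected interaction, if present."""
    cfg = _inter.InteractionConfig()
    finder = {
        "ionic": _inter.find_ionic, "aromatic_aromatic": _inter.find_aromatic_aromatic,
        "aromatic_sulfur": _inter.find_aromatic_sulfur, "cation_pi": _inter.find_cation_pi,
        "disulfide": _inter.find_disulfide, "hydrophobic": _inter.find_hydrophobic,
    }.get(cat)
    if finder is None:
        found = [it for it in _inter.find_hbonds(struct, cfg) if it.category == cat]
    else:
        # relax cutoffs so the metric is measurable even while off target
        relaxed = _inter.InteractionConfig(ionic_cutoff=50, aromatic_min=0.1,
                                           aromatic_max=50, aromatic_sulfur_cutoff=50,
                                           cation_pi_cutoff=50, disulfide_cutoff=50,
                                           hydrophobic_cutoff=50, hbond_da_cutoff=50)
        found = finder(struct, relaxed)
    want = {key_a, key_b}
    hits = [it.distance for it in found
            if {it.partner_a[:2], it.partner_b[:2]} == want]
    return min(hits) if hits else None


_HELIX_PHI_PSI = (-57.0, -47.0)
_STRAND_PHI_PSI = (-139.0, 135.0)


def make_planted_structure(spec: PlantedStructureSpec, seed: int = 0,
                           structure_id: str = "planted") -> str:
    """Emit PDB text realizing the spec; verified against the detectors.

    ``seed`` is accepted for interface uniformity; the construction is
    fully deterministic.
    """
    n = len(spec.residues)
    placed: dict[int, tuple[str, int, dict[str, np.ndarray]]] = {}
    site = 0

    def grid_offset(k: int) -> np.ndarray:
        return np.array([80.0 * (k % 5), 60.0 * (k // 5), 0.0])

    motif_members = {}
    for kind, start, length in spec.ss_motifs:
        phi, psi = _HELIX_PHI_PSI if kind == "helix" else _STRAND_PHI_PSI
        bb = _build_backbone(length, [phi] * length, [psi] * length)
        offset = grid_offset(site)
        site += 1
        for k in range(length):
            atoms = {name: xyz + offset for name, xyz in bb[k].items()}
            _build_side_chain(spec.residues[start + k], atoms)
            placed[start + k] = ("A", 0, atoms)   # resnum assigned later
            motif_members[start + k] = (kind, start)

    for cat, (ia, ib), target in spec.planted_interactions:
        aa_a, aa_b = spec.residues[ia], spec.residues[ib]
        atoms_a = _build_residue(aa_a)
        atoms_b = _build_residue(aa_b)
        pa, dir_a = _defining_geometry(cat, aa_a, atoms_a, "a")
        pb, dir_b = _defining_geometry(cat, aa_b, atoms_b, "b")
        xhat = np.array([1.0, 0.0, 0.0])
        rot_a = _rotation_between(dir_a, xhat)
        atoms_a = {k: rot_a @ (v - atoms_a["CA"]) for k, v in atoms_a.items()}
        rot_b = _rotation_between(dir_b, -xhat)
        atoms_b = {k: rot_b @ (v - atoms_b["CA"]) for k, v in atoms_b.items()}
        offset = grid_offset(site)
        site += 1
        atoms_a = {k: v + offset for k, v in atoms_a.items()}
        pa, _ = _defining_geometry(cat, aa_a, atoms_a, "a")
        # initial placement: defining points separated by target along x
        pb0, _ = _defining_geometry(cat, aa_b, atoms_b, "b")
        shift = pa + np.array([target, 0.0, 0.0]) - pb0
        atoms_b = {k: v + shift for k, v in atoms_b.items()}
        placed[ia] = ("A", 0, atoms_a)
        placed[ib] = ("A", 0, atoms_b)
        # tune the category's own metric onto the target
        for _ in range(8):
            trial = _records_to_structure(spec, placed, structure_id)
            key_a = ("A", str(10 * ia + 1))
            key_b = ("A", str(10 * ib + 1))
            measured = _category_metric(cat, trial, key_a, key_b)
            if measured is None:
                raise GenerationError(f"cannot measure {cat} metric while planting")
            err = target - measured
            if abs(err) <= 0.02:
                break
            atoms_b = {k: v + np.array([err, 0.0, 0.0]) for k, v in atoms_b.items()}
            placed[ib] = ("A", 0, atoms_b)
        else:
            raise GenerationError(f"could not tune {cat} distance to {target} A")

    for idx in range(n):
        if idx not in placed:
            atoms = _build_residue(spec.residues[idx])
            offset = grid_offset(site)
            site += 1
            placed[idx] = ("A", 0, {k: v + offset for k, v in atoms.items()})

    pdb_text = _spec_to_pdb(spec, placed)
    _verify_planted(spec, pdb_text, structure_id)
    return pdb_text


def _spec_resnum(spec: PlantedStructureSpec, idx: int) -> int:
    # scattered residues 10 apart (chain breaks); motif residues consecutive
    for kind, start, length in spec.ss_motifs:
        if start <= idx < start + length:
            return 10 * start + 1 + (idx - start)
    return 10 * idx + 1


def _spec_to_pdb(spec, placed) -> str:
    records = []
    for idx in sorted(placed):
        chain, _, atoms = placed[idx]
        records.extend(_residue_records(chain, _spec_resnum(spec, idx),
                                        spec.residues[idx], atoms))
    return _format_pdb(records)


def _records_to_structure(spec, placed, structure_id) -> Structure:
    return parse_structure(_spec_to_pdb(spec, placed), structure_id=structure_id)


def _verify_planted(spec: PlantedStructureSpec, pdb_text: str, structure_id: str) -> None:
    struct = parse_structure(pdb_text, structure_id=structure_id)
    iset = _inter.summarize_interactions(struct)
    detected = {(it.category, frozenset((it.partner_a[:2], it.partner_b[:2])))
                for it in iset.interactions}
    wanted = set()
    for cat, (ia, ib), target in spec.planted_interactions:
        wanted.add((cat, frozenset({("A", str(_spec_resnum(spec, ia))),
                                    ("A", str(_spec_resnum(spec, ib)))})))
    allow_mc = bool(spec.ss_motifs)
    extras = {d for d in detected if d not in wanted
              and not (allow_mc and d[0] in ("hbond_mc_mc",))}
    missing = wanted - detected
    if missing or extras:
        raise GenerationError(
            f"planted verification failed: missing={sorted(missing)} "
            f"extras={sorted(extras)}")
    for cat, (ia, ib), target in spec.planted_interactions:
        key_a = ("A", str(_spec_resnum(spec, ia)))
        key_b = ("A", str(_spec_resnum(spec, ib)))
        measured = _category_metric(cat, struct, key_a, key_b)
        if measured is None or abs(measured - target) > 0.05:
            raise GenerationError(
                f"{cat} defining distance {measured} not within 0.05 A of {target}")


# ---------------------------------------------------------------------------
# canonical secondary-structure fixtures
# ---------------------------------------------------------------------------

def make_ideal_helix(n: int = 12, aa: str = "A") -> str:
    """Poly-aa alpha helix (phi = -57, psi = -47)."""
    bb = _build_backbone(n, [_HELIX_PHI_PSI[0]] * n, [_HELIX_PHI_PSI[1]] * n)
    records = []
    for i, atoms in enumerate(bb):
        full = dict(atoms)
        _build_side_chain(aa, full)
        records.extend(_residue_records("A", i + 1, aa, full))
    return _format_pdb(records)


def make_extended_chain(n: int = 10, aa: str = "G") -> str:
    """Fully extended isolated chain (phi = psi = 180); no hydrogen bonds."""
    bb = _build_backbone(n, [180.0] * n, [180.0] * n)
    records = []
    for i, atoms in enumerate(bb):
        full = dict(atoms)
        _build_side_chain(aa, full)
        records.extend(_residue_records("A", i + 1, aa, full))
    return _format_pdb(records)


@lru_cache(maxsize=4)
def make_antiparallel_sheet(n_per_strand: int = 8) -> str:
    """Two antiparallel glycine strands positioned for a beta ladder.

    The second strand's placement is found by a deterministic grid search
    maximizing the number of Kabsch-Sander inter-strand hydrogen bonds.
    """
    from .environment import backbone_hbonds

    n = n_per_strand
    bb = _build_backbone(n, [_STRAND_PHI_PSI[0]] * n, [_STRAND_PHI_PSI[1]] * n)
    ca_first, ca_last = bb[0]["CA"], bb[-1]["CA"]
    axis = ca_last - ca_first
    rot = _rotation_between(axis / np.linalg.norm(axis), np.array([1.0, 0.0, 0.0]))
    center = 0.5 * (ca_first + ca_last)
    strand_a = [{k: rot @ (v - center) for k, v in res.items()} for res in bb]

    flip = _axis_angle(np.array([0.0, 0.0, 1.0]), math.pi)

    def build(dy: float, dx: float, dz: float, flip_rot) -> str:
        records = []
        for i, atoms in enumerate(strand_a):
            records.extend(_residue_records("A", i + 1, "G", atoms))
        for i, atoms in enumerate(strand_a):
            moved = {k: flip_rot @ v + np.array([dx, dy, dz]) for k, v in atoms.items()}
            records.extend(_residue_records("B", i + 1, "G", moved))
        return _format_pdb(records)

    def score(pdb_text: str) -> int:
        struct = parse_structure(pdb_text)
        na = len(struct.chains.get("A", []))
        bonds = backbone_hbonds(struct)
        return sum(1 for a, d in bonds if (a < na) != (d < na))

    flips = [flip, _axis_angle(np.array([0.0, 1.0, 0.0]), math.pi)]
    best = (-1, None)
    for fi, fr in enumerate(flips):
        for dy in np.arange(4.0, 5.81, 0.2):
            for dx in np.arange(-3.5, 3.51, 0.25):
                text = build(dy, dx, 0.0, fr)
                sc = score(text)
                if sc > best[0]:
                    best = (sc, (dy, dx, 0.0, fi))
    dy0, dx0, dz0, fi = best[1]
    for dy in np.arange(dy0 - 0.2, dy0 + 0.21, 0.05):
        for dx in np.arange(dx0 - 0.25, dx0 + 0.26, 0.05):
            text = build(dy, dx, dz0, flips[fi])
            sc = score(text)
            if sc > best[0]:
                best = (sc, (dy, dx, dz0, fi))
    dy, dx, dz, fi = best[1]
    if best[0] < 2:
        raise GenerationError("could not realize an antiparallel ladder")
    return build(dy, dx, dz, flips[fi])


# ---------------------------------------------------------------------------
# composition cohorts
# ---------------------------------------------------------------------------

_BASE_FREQ = {
    # typical globular-protein background composition
    "A": 0.0777, "R": 0.0516, "N": 0.0426, "D": 0.0530, "C": 0.0169,
    "Q": 0.0396, "E": 0.0632, "G": 0.0691, "H": 0.0227, "I": 0.0591,
    "L": 0.0960, "K": 0.0580, "M": 0.0238, "F": 0.0405, "P": 0.0469,
    "S": 0.0694, "T": 0.0550, "W": 0.0115, "Y": 0.0303, "V": 0.0667,
}
_BASE_TOTAL = sum(_BASE_FREQ.values())
BASE_FREQ = {aa: v / _BASE_TOTAL for aa, v in _BASE_FREQ.items()}


@dataclass
class CohortSpec:
    """Study conditions for a two-group composition cohort.

    Defaults mirror the comparative setting of the packaged dataset:
    17 thermophiles vs 13 mesophiles, ~400-residue proteins, no planted
    effects, small per-amino-acid jitter.
    """
    n_thermo: int = 17
    n_meso: int = 13
    base_freq: dict[str, float] = field(default_factory=lambda: dict(BASE_FREQ))
    effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005
    protein_length: int = 400
    seed: int = 0
    n_families: int = 3

    def __post_init__(self) -> None:
        if self.n_thermo < 2 or self.n_meso < 2:
            raise GenerationError("need at least two proteins per group")
        shifted = {aa: self.base_freq.get(aa, 0.0) + self.effects.get(aa, 0.0)
                   for aa in STANDARD_AAS}
        if min(shifted.values()) < 0:
            raise GenerationError("effects drive a frequency negative")


def _sample_profiles(rng, base: np.ndarray, n: int, length: int,
                     noise_sd: float, prefix: str, n_families: int):
    profiles = []
    for k in range(n):
        counts = rng.multinomial(length, base)
        freq = counts.astype(float) / length
        freq = freq + rng.normal(0.0, noise_sd, size=20)
        freq = np.clip(freq, 0.0, None)
        freq /= freq.sum()
        profiles.append(CompositionProfile(
            structure_id=f"{prefix}{k}",
            freq={aa: float(freq[i]) for i, aa in enumerate(STANDARD_AAS)},
            length=length,
            family=f"{prefix}fam{k % n_families}",
        ))
    return profiles


def make_cohort(spec: CohortSpec):
    """(thermophile profiles, mesophile profiles, truth table of effects)."""
    rng = np.random.default_rng(spec.seed)
    base = np.array([spec.base_freq[aa] for aa in STANDARD_AAS])
    base = base / base.sum()
    shifted = base + np.array([spec.effects.get(aa, 0.0) for aa in STANDARD_AAS])
    shifted = np.clip(shifted, 0.0, None)
    shifted /= shifted.sum()
    thermo = _sample_profiles(rng, shifted, spec.n_thermo, spec.protein_length,
                              spec.noise_sd, "T", spec.n_families)
    meso = _sample_profiles(rng, base, spec.n_meso, spec.protein_length,
                            spec.noise_sd, "M", spec.n_families)
    truth = {aa: spec.effects.get(aa, 0.0) for aa in STANDARD_AAS}
    return thermo, meso, truth


# ---------------------------------------------------------------------------
# paired structures for superposition and tallies
# ---------------------------------------------------------------------------

def make_paired_structures(
    n_residues: int = 60,
    identity_target: float = 1.0,
    substitutions: list[tuple[int, str]] | None = None,
    class_substitutions: dict[str, list[str]] | None = None,
    noise_sd: float = 0.2,
    rigid: bool = True,
    seed: int = 0,
    base_sequence: str | None = None,
) -> tuple[str, str, list[tuple[str, str]]]:
    """Structure B = structure A with substitutions, a rigid-body move and
    isotropic coordinate noise; returns (pdb_a, pdb_b, true equivalences).

    ``substitutions`` lists explicit (position, new_aa); alternatively
    ``class_substitutions`` maps a focus amino acid to replacement amino
    acids applied at its first occurrences.  ``identity_target`` adds
    random substitutions until 1 - identity of positions are changed.
    """
    rng = np.random.default_rng(seed)
    if base_sequence is not None:
        seq_a = list(base_sequence.upper())
        n_residues = len(seq_a)
    else:
        seq_a = list(rng.choice(list(STANDARD_AAS), size=n_residues))
    if n_residues < 4:
        raise GenerationError("need at least four residues")

    seq_b = list(seq_a)
    touched: set[int] = set()
    for pos, to_aa in substitutions or []:
        seq_b[pos] = to_aa
        touched.add(pos)
    for focus, repls in (class_substitutions or {}).items():
        sites = [i for i, aa in enumerate(seq_a) if aa == focus and i not in touched]
        if len(sites) < len(repls):
            raise GenerationError(f"sequence has only {len(sites)} spare {focus}")
        for site, to_aa in zip(sites, repls):
            seq_b[site] = to_aa
            touched.add(site)
    n_extra = int(round((1.0 - identity_target) * n_residues)) - len(touched)
    if n_extra > 0:
        candidates = [i for i in range(n_residues) if i not in touched]
        for pos in rng.choice(candidates, size=n_extra, replace=False):
            aa = seq_a[pos]
            seq_b[pos] = rng.choice([x for x in STANDARD_AAS if x != aa])
            touched.add(int(pos))

    # expanded random-coil backbone: unique, non-degenerate CA trace
    phis = rng.uniform(-160.0, -60.0, size=n_residues)
    psis = rng.uniform(60.0, 170.0, size=n_residues)
    bb = _build_backbone(n_residues, phis, psis)

    def assemble(seq):
        residues = []
        for i, atoms in enumerate(bb):
            full = dict(atoms)
            _build_side_chain(seq[i], full)
            residues.append(full)
        return residues

    res_a = assemble(seq_a)
    res_b = assemble(seq_b)

    if rigid:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        trans = rng.uniform(-20.0, 20.0, size=3)
    else:
        rot, trans = np.eye(3), np.zeros(3)
    res_b = [{k: rot @ v + trans + rng.normal(0.0, noise_sd, size=3)
              for k, v in atoms.items()} for atoms in res_b]

    def to_pdb(seq, residues):
        records = []
        for i, atoms in enumerate(residues):
            records.extend(_residue_records("A", i + 1, seq[i], atoms))
        return _format_pdb(records)

    equivalences = [(str(i + 1), str(i + 1)) for i in range(n_residues)]
    return to_pdb(seq_a, res_a), to_pdb(seq_b, res_b), equivalences


def make_related_family(
    n_members: int,
    length: int = 40,
    sub_rate: float = 0.15,
    noise_sd: float = 0.15,
    seed: int = 0,
    base_sequence: str | None = None,
) -> tuple[list[str], list[str]]:
    """Homologous synthetic structures: one shared backbone, per-member
    random substitutions, rigid-body moves and coordinate noise.

    Returns (pdb texts, sequences); the sequences are mutually aligned
    position-by-position (no indels), so they double as an MSA.
    """
    rng = np.random.default_rng(seed)
    if base_sequence is None:
        seq0 = list(rng.choice(list(STANDARD_AAS), size=length))
    else:
        seq0 = list(base_sequence.upper())
        length = len(seq0)
    phis = rng.uniform(-160.0, -60.0, size=length)
    psis = rng.uniform(60.0, 170.0, size=length)
    bb = _build_backbone(length, phis, psis)

    texts, seqs = [], []
    for _ in range(n_members):
        seq = list(seq0)
        n_sub = rng.binomial(length, sub_rate)
        for pos in rng.choice(length, size=n_sub, replace=False):
            seq[pos] = rng.choice([x for x in STANDARD_AAS if x != seq[pos]])
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        trans = rng.uniform(-20.0, 20.0, size=3)
        records = []
        for i, atoms in enumerate(bb):
            full = dict(atoms)
            _build_side_chain(seq[i], full)
            moved = {k: rot @ v + trans + rng.normal(0.0, noise_sd, size=3)
                     for k, v in full.items()}
            records.extend(_residue_records("A", i + 1, seq[i], moved))
        texts.append(_format_pdb(records))
        seqs.append("".join(seq))
    return texts, seqs
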