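"""Per-residue structural environment: solvent accessibility and secondary
structure.

Solvent-accessible surface area is computed with a Shrake-Rupley sphere
quadrature using a deterministic Fibonacci point set (no RNG), then turned
into relative accessibility by dividing by a per-amino-acid maximum from a
published theoretical max-ASA scale.  Relative accessibility is classified
as buried (< 9%), intermediate (9-36%) or exposed (> 36%).

Secondary structure is assigned with the Kabsch-Sander hydrogen-bond
energy criterion (backbone amide H placed geometrically, bond if
E < -0.5 kcal/mol), n-turn and bridge patterns reduced to the eight DSSP
states, which collapse to three classes: H/G/I -> helix, E/B -> sheet,
everything else -> loop.  A precomputed DSSP output file in the classic
fixed-column dialect can be ingested instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

# van der Waals radii (A); fallback used with a warning for unknown elements
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
FALLBACK_RADIUS = 1.70

# Theoretical maximum accessible surface areas (A^2) per residue type,
# Tien et al. 2013 ("theoretical" column); the scale is pluggable.
MAX_ASA_SCALES = {
    "tien2013_theoretical": {
        "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
        "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
        "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
        "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    },
    "miller1987": {
        "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
        "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
        "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
        "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
    },
}
DEFAULT_MAX_ASA_SCALE = "tien2013_theoretical"

SS3_CLASSES = ("helix", "sheet", "loop")
ACC_CLASSES = ("buried", "intermediate", "exposed")
BURIED_BELOW = 0.09
EXPOSED_ABOVE = 0.36


@dataclass
class ResidueEnvironment:
    residue: tuple[str, str, str]       # (chain, seq_id, aa)
    ss8: str
    ss3: str
    sasa: float
    rel_acc: float | None
    acc_class: str | None


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    s: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> dict[tuple[str, str], float]:
    """Per-residue solvent-accessible surface area (A^2).

    Each atom's expanded sphere (vdW + probe) is sampled with the Fibonacci
    point set; points falling inside any neighbouring expanded sphere are
    occluded.  Deterministic for a fixed ``n_points``.
    """
    radii = radii or VDW_RADII
    atoms, owners = [], []
    for cid, res in s.residues():
        for a in res.atoms:
            atoms.append(a)
            owners.append((cid, res.seq_id))
    if not atoms:
        return {}
    coords = np.array([a.coord for a in atoms])
    rads = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        if a.element not in radii:
            logger.warning("unknown element %r; using fallback radius %.2f A",
                           a.element, FALLBACK_RADIUS)
        rads[i] = radii.get(a.element, FALLBACK_RADIUS) + probe_radius

    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = rads.max()
    sasa: dict[tuple[str, str], float] = {owner: 0.0 for owner in owners}
    for i in range(len(atoms)):
        pts = coords[i] + rads[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], rads[i] + rmax)
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < rads[i] + rads[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= ((pts - coords[j]) ** 2).sum(1) > rads[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * math.pi * rads[i] ** 2 * accessible.sum() / n_points
        sasa[owners[i]] += area
    return sasa


def relative_accessibility(sasa: float, aa: str,
                           scale: str = DEFAULT_MAX_ASA_SCALE) -> float:
    """Residue SASA divided by its amino-acid-type maximum (not clipped)."""
    table = MAX_ASA_SCALES[scale]
    if aa not in table:
        raise KeyError(f"no max-accessibility value for residue type {aa!r}")
    return sasa / table[aa]


def classify_accessibility(rel_acc: float) -> str:
    if rel_acc < BURIED_BELOW:
        return "buried"
    if rel_acc <= EXPOSED_ABOVE:
        return "intermediate"
    return "exposed"


def reduce_ss(ss8: str) -> str:
    """DSSP eight-state letter to three classes.

    H/G/I -> helix; E/B -> sheet; T/S and the unassigned (blank) coil
    state -> loop.
    """
    if ss8 in "HGI":
        return "helix"
    if ss8 in "EB":
        return "sheet"
    return "loop"


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary-structure assignment
# ---------------------------------------------------------------------------

_HB_Q1Q2_F = 0.084 * 332.0  # kcal/mol * A, dimensional factor of the K-S energy
_HB_THRESHOLD = -0.5
_PEPTIDE_BOND_MAX = 2.5


def _backbone_segments(s: Structure) -> list[list[tuple[str, Residue]]]:
    """Covalently continuous runs of residues with full backbone (N, CA, C, O)."""
    segments: list[list[tuple[str, Residue]]] = []
    for cid in s.chains:
        current: list[tuple[str, Residue]] = []
        for r in s.chains[cid]:
            if not r.has_atoms(("N", "CA", "C", "O")):
                if current:
                    segments.append(current)
                current = []
                continue
            if current:
                prev = current[-1][1]
                if np.linalg.norm(prev.coord("C") - r.coord("N")) > _PEPTIDE_BOND_MAX:
                    segments.append(current)
                    current = []
            current.append((cid, r))
        if current:
            segments.append(current)
    return segments


def backbone_hbonds(s: Structure) -> set[tuple[int, int]]:
    """Kabsch-Sander backbone hydrogen bonds as (acceptor, donor) global
    indices over the concatenated backbone segments."""
    segments = _backbone_segments(s)
    flat: list[tuple[int, Residue]] = []   # (segment id, residue)
    for si, seg in enumerate(segments):
        for _, r in seg:
            flat.append((si, r))

    # geometric amide H: 1 A from N, along the preceding carbonyl O->C vector
    h_pos: list[np.ndarray | None] = []
    idx = 0
    for si, seg in enumerate(segments):
        for k, (_, r) in enumerate(seg):
            if k == 0 or r.aa == "P":
                h_pos.append(None)
            else:
                prev = seg[k - 1][1]
                v = prev.coord("C") - prev.coord("O")
                h_pos.append(r.coord("N") + v / np.linalg.norm(v))
            idx += 1

    bonds: set[tuple[int, int]] = set()
    n = len(flat)
    ca = np.array([r.coord("CA") for _, r in flat]) if n else np.empty((0, 3))
    tree = cKDTree(ca) if n else None
    for a in range(n):  # acceptor: C=O of residue a
        sa, ra = flat[a]
        c_a, o_a = ra.coord("C"), ra.coord("O")
        for d in tree.query_ball_point(ca[a], 9.0):
            if abs(d - a) < 2 and flat[d][0] == sa:
                continue
            if d == a:
                continue
            h = h_pos[d]
            if h is None:
                continue
            rd = flat[d][1]
            n_d = rd.coord("N")
            r_on = np.linalg.norm(n_d - o_a)
            r_ch = np.linalg.norm(h - c_a)
            r_oh = np.linalg.norm(h - o_a)
            r_cn = np.linalg.norm(n_d - c_a)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9
            else:
                energy = _HB_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HB_THRESHOLD:
                bonds.add((a, d))
    return bonds


def assign_ss(s: Structure) -> dict[tuple[str, str], str]:
    """Eight-state secondary structure per residue (simplified DSSP rules)."""
    segments = _backbone_segments(s)
    flat: list[tuple[int, str, Residue]] = []
    for si, seg in enumerate(segments):
        for cid, r in seg:
            flat.append((si, cid, r))
    n = len(flat)
    result = {(cid, r.seq_id): " " for _, cid, r in flat}
    for cid, r in s.residues():
        result.setdefault((cid, r.seq_id), " ")
    if n < 4:
        return result

    hb = backbone_hbonds(s)

    def same_seg(i, j):
        return 0 <= i < n and 0 <= j < n and flat[i][0] == flat[j][0]

    # n-turns: CO(i) accepts from NH(i+nt)
    turns = {3: set(), 4: set(), 5: set()}
    for nt in (3, 4, 5):
        for i in range(n - nt):
            if same_seg(i, i + nt) and (i, i + nt) in hb:
                turns[nt].add(i)

    ss = [" "] * n

    def mark_helix(nt, letter):
        for i in range(1, n - nt):
            if i - 1 in turns[nt] and i in turns[nt]:
                for k in range(i, i + nt):
                    if ss[k] == " " or ss[k] == letter:
                        ss[k] = letter

    mark_helix(4, "H")

    # bridges (parallel / antiparallel); hb_ad(a, d): CO of a accepts from NH of d
    def hb_ad(a, d):
        return 0 <= a < n and 0 <= d < n and (a, d) in hb

    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        for j in range(i + 3, n):
            par = (hb_ad(i - 1, j) and hb_ad(j, i + 1)) or \
                  (hb_ad(j - 1, i) and hb_ad(i, j + 1))
            anti = (hb_ad(i, j) and hb_ad(j, i)) or \
                   (hb_ad(i - 1, j + 1) and hb_ad(j - 1, i + 1))
            if par:
                bridges.append((i, j, "p"))
            elif anti:
                bridges.append((i, j, "a"))

    bridge_set = set((i, j, t) for i, j, t in bridges)
    for i, j, t in bridges:
        neighbours = ((i + 1, j + 1, "p"), (i - 1, j - 1, "p")) if t == "p" else \
                     ((i + 1, j - 1, "a"), (i - 1, j + 1, "a"))
        in_ladder = any(b in bridge_set for b in neighbours)
        letter = "E" if in_ladder else "B"
        for k in (i, j):
            if ss[k] == " " or (ss[k] == "B" and letter == "E"):
                ss[k] = letter

    mark_helix(3, "G")
    mark_helix(5, "I")

    # hydrogen-bonded turns
    for nt in (3, 4, 5):
        for i in turns[nt]:
            for k in range(i + 1, i + nt):
                if ss[k] == " ":
                    ss[k] = "T"

    # bends: kappa > 70 deg
    for i in range(2, n - 2):
        if not (same_seg(i - 2, i) and same_seg(i, i + 2)):
            continue
        u = flat[i][2].coord("CA") - flat[i - 2][2].coord("CA")
        v = flat[i + 2][2].coord("CA") - flat[i][2].coord("CA")
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        kappa = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        if kappa > 70.0 and ss[i] == " ":
            ss[i] = "S"

    for k, (_, cid, r) in enumerate(flat):
        result[(cid, r.seq_id)] = ss[k]
    return result


# ---------------------------------------------------------------------------
# assembly and DSSP-file ingestion
# ---------------------------------------------------------------------------

def compute_environment(
    s: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_asa_scale: str = DEFAULT_MAX_ASA_SCALE,
) -> list[ResidueEnvironment]:
    """Full per-residue environment table for a structure."""
    sasa = shrake_rupley(s, probe_radius=probe_radius, n_points=n_points)
    ss = assign_ss(s)
    out = []
    for cid, r in s.residues():
        key = (cid, r.seq_id)
        area = sasa.get(key, 0.0)
        ss8 = ss.get(key, " ")
        if r.aa == "X":
            rel, cls = None, None
        else:
            rel = relative_accessibility(area, r.aa, scale=max_asa_scale)
            cls = classify_accessibility(rel)
        out.append(ResidueEnvironment(
            residue=(cid, r.seq_id, r.aa),
            ss8=ss8, ss3=reduce_ss(ss8),
            sasa=area, rel_acc=rel, acc_class=cls,
        ))
    return out


def parse_dssp(dssp_text: str, max_asa_scale: str = DEFAULT_MAX_ASA_SCALE) -> list[ResidueEnvironment]:
    """Ingest a classic fixed-column DSSP output file verbatim.

    Relative accessibility is recomputed from the ACC column with the same
    max-ASA scale used for internal SASA values.
    """
    lines = dssp_text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith("  #  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a DSSP output file (missing '  #  RESIDUE' header)")
    out = []
    for line in lines[start:]:
        if len(line) < 38 or line[13] == "!":
            continue
        aa = line[13].upper()
        if aa.islower():  # SS-bonded cysteines are lowercase letters
            aa = "C"
        chain = line[11].strip() or "A"
        seq_id = (line[5:10].strip() + line[10].strip()).strip()
        ss8 = line[16] if line[16] != " " else " "
        acc = float(line[34:38])
        if aa in MAX_ASA_SCALES[max_asa_scale]:
            rel = relative_accessibility(acc, aa, scale=max_asa_scale)
            cls = classify_accessibility(rel)
        else:
            aa, rel, cls = "X", None, None
        out.append(ResidueEnvironment(
            residue=(chain, seq_id, aa),
            ss8=ss8, ss3=reduce_ss(ss8),
            sasa=acc, rel_acc=rel, acc_class=cls,
        ))
    return out


def environment_table(envs: list[ResidueEnvironment]):
    import pandas as pd

    return pd.DataFrame([{
        "chain": e.residue[0], "seq_id": e.residue[1], "aa": e.residue[2],
        "ss8": e.ss8, "ss3": e.ss3, "sasa": round(e.sasa, 2),
        "rel_acc": None if e.rel_acc is None else round(e.rel_acc, 4),
        "acc_class": e.acc_class,
    } for e in envs])
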