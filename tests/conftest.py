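"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately separate from the package
code: plain nested-loop scans over residue pairs implementing the
published distance criteria, a quaternion (Horn) superposition, and a
high-precision Welch t-test.  They exist so the package's detectors and
estimators can be checked against an independent route.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from thermofold.structure_io import Atom, Residue, Structure

# ---------------------------------------------------------------------------
# structure-building helpers
# ---------------------------------------------------------------------------


def make_residue(aa: str, name3: str, seq_id: str, atoms: dict[str, tuple]) -> Residue:
    return Residue(aa=aa, name=name3, seq_id=seq_id,
                   atoms=[Atom(n, n[0], np.array(c, dtype=float))
                          for n, c in atoms.items()])


def make_structure(residues: list[Residue], chain: str = "A",
                   structure_id: str = "test") -> Structure:
    return Structure(id=structure_id, chains={chain: residues})


@pytest.fixture
def lys_glu_pair():
    """Lys NZ / Glu OE1 at an adjustable distance along x."""
    def build(distance: float, seq_b: str = "21"):
        lys = make_residue("K", "LYS", "1", {"CA": (0, 0, 0), "NZ": (0, 0, 4)})
        glu = make_residue("E", "GLU", seq_b,
                           {"CA": (distance + 3.0, 0, 4),
                            "OE1": (distance, 0, 4),
                            "OE2": (distance + 2.2, 0, 5)})
        return make_structure([lys, glu])
    return build


# ---------------------------------------------------------------------------
# brute-force interaction oracle (independent of the package detectors)
# ---------------------------------------------------------------------------

_ORACLE_CATION = {"K": ["NZ"], "R": ["NE", "NH1", "NH2"], "H": ["ND1", "NE2"]}
_ORACLE_ANION = {"D": ["OD1", "OD2"], "E": ["OE1", "OE2"]}
_ORACLE_RING = {"F": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                "Y": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                "W": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]}
_ORACLE_HYDRO = set("AVLIMFWPY")
_ORACLE_DONOR = {"R": ["NE", "NH1", "NH2"], "N": ["ND2"], "Q": ["NE2"],
                 "H": ["ND1", "NE2"], "K": ["NZ"], "S": ["OG"], "T": ["OG1"],
                 "W": ["NE1"], "Y": ["OH"]}
_ORACLE_ACCEPTOR = {"D": ["OD1", "OD2"], "E": ["OE1", "OE2"], "N": ["OD1"],
                    "Q": ["OE1"], "H": ["ND1", "NE2"], "S": ["OG"],
                    "T": ["OG1"], "Y": ["OH"]}


def _dist(p, q):
    return math.dist(tuple(p), tuple(q))


def _centroid(res, names):
    coords = [res.coord(n) for n in names]
    if any(c is None for c in coords):
        return None
    return np.mean(coords, axis=0)


def _sep(cid_a, ra, cid_b, rb):
    if cid_a != cid_b:
        return 10**6
    return abs(ra.number - rb.number)


def oracle_pairs(structure, category, cfg) -> set[frozenset]:
    """All interacting residue pairs of a category by exhaustive scan."""
    residues = [(cid, r) for cid, r in structure.residues() if r.aa != "X"]
    found: set[frozenset] = set()
    for (ca, ra), (cb, rb) in combinations(residues, 2):
        key = frozenset(((ca, ra.seq_id), (cb, rb.seq_id)))
        sep_ok = _sep(ca, ra, cb, rb) >= cfg.min_seq_separation
        for x, y in ((ra, rb), (rb, ra)):
            if category == "ionic" and sep_ok:
                ds = [_dist(x.coord(m), y.coord(n))
                      for m in _ORACLE_CATION.get(x.aa, []) if x.coord(m) is not None
                      for n in _ORACLE_ANION.get(y.aa, []) if y.coord(n) is not None]
                if ds and min(ds) <= cfg.ionic_cutoff:
                    found.add(key)
            elif category == "aromatic_aromatic" and sep_ok:
                pa = _centroid(x, _ORACLE_RING.get(x.aa, ["missing"]))
                pb = _centroid(y, _ORACLE_RING.get(y.aa, ["missing"]))
                if pa is not None and pb is not None and \
                        cfg.aromatic_min <= _dist(pa, pb) <= cfg.aromatic_max:
                    found.add(key)
            elif category == "cation_pi" and sep_ok:
                ref = {"K": "NZ", "R": "CZ"}.get(x.aa)
                pb = _centroid(y, _ORACLE_RING.get(y.aa, ["missing"]))
                if ref and x.coord(ref) is not None and pb is not None and \
                        _dist(x.coord(ref), pb) <= cfg.cation_pi_cutoff:
                    found.add(key)
            elif category == "aromatic_sulfur" and sep_ok:
                sat = {"C": "SG", "M": "SD"}.get(x.aa)
                pb = _centroid(y, _ORACLE_RING.get(y.aa, ["missing"]))
                if sat and x.coord(sat) is not None and pb is not None and \
                        _dist(x.coord(sat), pb) <= cfg.aromatic_sulfur_cutoff:
                    found.add(key)
            elif category == "disulfide":
                if x.aa == "C" and y.aa == "C" and x.coord("SG") is not None \
                        and y.coord("SG") is not None \
                        and _dist(x.coord("SG"), y.coord("SG")) <= cfg.disulfide_cutoff:
                    found.add(key)
            elif category == "hydrophobic" and sep_ok:
                if x.aa in _ORACLE_HYDRO and y.aa in _ORACLE_HYDRO:
                    xs = [a.coord for a in x.atoms if a.element == "C"
                          and a.name not in ("CA", "C")]
                    ys = [a.coord for a in y.atoms if a.element == "C"
                          and a.name not in ("CA", "C")]
                    if xs and ys and min(_dist(p, q) for p in xs for q in ys) \
                            <= cfg.hydrophobic_cutoff:
                        found.add(key)
    return found


def oracle_hbond_pairs(structure, cfg) -> dict[str, set[frozenset]]:
    """Hydrogen-bonded residue pairs per category by exhaustive scan,
    excluding salt-bridge atom pairs (reported as ionic)."""
    residues = [(cid, r) for cid, r in structure.residues() if r.aa != "X"]
    out = {"hbond_mc_mc": set(), "hbond_mc_sc": set(), "hbond_sc_sc": set()}

    def donors(cid, r):
        d = []
        if r.coord("N") is not None and r.aa != "P":
            d.append(("N", True))
        d += [(n, False) for n in _ORACLE_DONOR.get(r.aa, []) if r.coord(n) is not None]
        return d

    def acceptors(cid, r):
        a = [(n, True) for n in ("O", "OXT") if r.coord(n) is not None]
        a += [(n, False) for n in _ORACLE_ACCEPTOR.get(r.aa, []) if r.coord(n) is not None]
        return a

    def salt_pair(rx, nx, ry, ny):
        cat_x = nx in _ORACLE_CATION.get(rx.aa, [])
        ani_y = ny in _ORACLE_ANION.get(ry.aa, [])
        cat_y = ny in _ORACLE_CATION.get(ry.aa, [])
        ani_x = nx in _ORACLE_ANION.get(rx.aa, [])
        return (cat_x and ani_y) or (cat_y and ani_x)

    for (ca, ra), (cb, rb) in combinations(residues, 2):
        key = frozenset(((ca, ra.seq_id), (cb, rb.seq_id)))
        for (dres, dcid), (ares, acid) in (((ra, ca), (rb, cb)), ((rb, cb), (ra, ca))):
            for dn, dmc in donors(dcid, dres):
                for an, amc in acceptors(acid, ares):
                    if _dist(dres.coord(dn), ares.coord(an)) > cfg.hbond_da_cutoff:
                        continue
                    if salt_pair(dres, dn, ares, an):
                        continue
                    if dmc and amc:
                        if _sep(dcid, dres, acid, ares) < cfg.min_seq_separation:
                            continue
                        out["hbond_mc_mc"].add(key)
                    elif dmc or amc:
                        out["hbond_mc_sc"].add(key)
                    else:
                        out["hbond_sc_sc"].add(key)
    return out


# ---------------------------------------------------------------------------
# quaternion (Horn) superposition oracle
# ---------------------------------------------------------------------------

def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenproblem."""
    a = a - a.mean(0)
    b = b - b.mean(0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = ((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam) / len(a)
    return math.sqrt(max(e, 0.0))


# ---------------------------------------------------------------------------
# high-precision Welch oracle (mpmath)
# ---------------------------------------------------------------------------

def welch_p_highprec(a, b) -> float:
    import mpmath as mp

    mp.mp.dps = 50
    a = [mp.mpf(repr(float(x))) for x in a]
    b = [mp.mpf(repr(float(x))) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / mp.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    x = df / (df + t ** 2)
    p = mp.betainc(df / 2, mp.mpf(1) / 2, 0, x, regularized=True)
    return float(p)
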