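"""Read PDB-format coordinate files into a light validated atomic model.

The model is deliberately small: chains of residues of atoms, first model
only, alternate locations resolved to a single conformer.  It carries just
what the downstream feature extractors need (names, elements, coordinates)
rather than wrapping a full crystallographic hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}
STANDARD_AAS = tuple(AA1TO3)


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be turned into a model."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise PDBParseError(f"non-finite coordinate for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise PDBParseError(f"occupancy {self.occupancy} outside [0,1] for {self.name}")


@dataclass
class Residue:
    aa: str                 # one-letter code, 'X' for nonstandard
    name: str               # three-letter code as read
    seq_id: str             # author number + insertion code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord

    def has_atoms(self, names: Sequence[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def number(self) -> int:
        """Author residue number without insertion code."""
        return int("".join(ch for ch in self.seq_id if ch in "-0123456789"))


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    model_index: int = 1

    def residues(self, chains: Sequence[str] | None = None) -> Iterator[tuple[str, Residue]]:
        for cid, reslist in self.chains.items():
            if chains is not None and cid not in chains:
                continue
            for r in reslist:
                yield cid, r

    @property
    def length(self) -> int:
        """Number of standard residues with at least one resolved atom."""
        return sum(1 for _, r in self.residues() if r.aa != "X" and r.atoms)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.residues())


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to altloc 'A'."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc not in ("", "A"), a.altloc))
        kept.append(group[0])
    return kept


def parse_structure(
    pdb_text: str,
    structure_id: str = "",
    chain_filter: Sequence[str] | None = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first model is kept.  HETATM records are dropped except
    selenomethionine (MSE), which is mapped to Met with SE renamed to SD.
    Duplicated alternate locations are resolved to the highest-occupancy
    conformer (ties break to altloc 'A').
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB text")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        cid = chain.name.strip() or "A"
        if chain_filter and cid not in chain_filter:
            continue
        reslist: list[Residue] = []
        seen_ids: set[str] = set()
        for res in chain:
            resname = res.name.strip().upper()
            is_atom_record = res.het_flag == "A"
            if not is_atom_record and resname != "MSE":
                continue
            if resname == "MSE":
                resname = "MET"
            seq_id = f"{res.seqid.num}{res.seqid.icode}".strip()
            atoms = []
            for at in res:
                if at.element.name in ("H", "D"):
                    continue
                name = at.name.strip()
                element = at.element.name.upper()
                if name == "SE" and res.name.strip().upper() == "MSE":
                    name, element = "SD", "S"
                atoms.append(Atom(
                    name=name,
                    element=element,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    altloc=at.altloc.strip() if isinstance(at.altloc, str) else (at.altloc or ""),
                ))
            if not atoms:
                continue
            if seq_id in seen_ids:
                # merged altloc groups that gemmi split; append atoms to prior
                prev = next(r for r in reslist if r.seq_id == seq_id)
                prev.atoms.extend(atoms)
                continue
            seen_ids.add(seq_id)
            reslist.append(Residue(
                aa=AA3TO1.get(resname, "X"),
                name=resname,
                seq_id=seq_id,
                atoms=atoms,
            ))
        if reslist:
            chains[cid] = reslist

    for reslist in chains.values():
        for r in reslist:
            r.atoms = _resolve_altlocs(r.atoms)

    structure = Structure(id=structure_id or st.name.strip().lower() or "structure", chains=chains)
    if structure.n_atoms == 0:
        raise PDBParseError("no ATOM records found")
    return structure


def extract_sequence(s: Structure, chain: str) -> str:
    """One-letter sequence of a chain, 'X' for nonstandard residues."""
    if chain not in s.chains:
        raise KeyError(f"chain {chain!r} not in structure {s.id} (has {sorted(s.chains)})")
    return "".join(r.aa for r in s.chains[chain])


def extract_sequences(s: Structure) -> dict[str, str]:
    return {cid: extract_sequence(s, cid) for cid in s.chains}


def first_protein_chain(s: Structure) -> str:
    """Chain id of the first chain containing standard amino-acid residues."""
    for cid, reslist in s.chains.items():
        if any(r.aa != "X" for r in reslist):
            return cid
    raise ValueError(f"structure {s.id} has no protein chain")


def load_manifest(path: str | None = None) -> pd.DataFrame:
    """Load a dataset manifest (pdb_id, chain, label, fold, family, ...).

    With no path, the packaged endoglucanase manifest is returned: 30 PDB
    entries in three folds, labelled thermophile (source organism optimum
    growth temperature above 40 degC) or mesophile.
    """
    if path is None:
        ref = resources.files("thermofold.data") / "endoglucanase_manifest.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pdb_id", "label", "fold"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"]) - {"thermophile", "mesophile"}
    if bad:
        raise ValueError(f"manifest labels must be thermophile/mesophile, got {sorted(bad)}")
    return df


def fetch_pdb(pdb_id: str, timeout: float = 30.0) -> str:
    """Thin helper fetching a PDB entry from RCSB; requires network access."""
    import urllib.request

    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as fh:  # noqa: S310
        return fh.read().decode()
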