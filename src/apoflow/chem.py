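"""Chemical and structural data model plus file I/O.

Three containers cover the state of a protein-ligand system:

* :class:`LigandGraph` — the bond topology of one or more ligand fragments,
  together with the adjacency / degree / Laplacian matrices (``L = D - A``)
  that define the harmonic conformational prior.
* :class:`ProteinStructure` — residue sequence and heavy-atom coordinates
  with explicit Calpha indexing, possibly spanning several chains.
* :class:`ComplexState` — joint protein/ligand coordinates at a flow time
  ``t`` in ``[0, 1]``.

All coordinates are in Angstrom; hydrogens are stripped everywhere (the
model operates on heavy atoms only); residue and atom indices are 0-based
in memory and 1-based in files.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
from biotite.sequence import ProteinSequence

from .errors import ContractError, InputError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9


# --------------------------------------------------------------------------
# Ligand
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandGraph:
    """Bond graph of a (possibly multi-fragment) ligand.

    Attributes
    ----------
    n_atoms : int
        Number of heavy atoms ``N_L``.
    elements : tuple of str
        Element symbol per atom.
    bonds : tuple of (int, int)
        Unordered atom-index pairs, stored with ``i < j``, no duplicates,
        no self-loops.
    fragment_id : ndarray of int, shape (n_atoms,)
        Connected-component label per atom, contiguous from 0.
    """

    n_atoms: int
    elements: tuple
    bonds: tuple
    fragment_id: np.ndarray

    def __post_init__(self):
        if self.n_atoms < 1:
            raise InputError("ligand must contain at least one heavy atom")
        for i, j in self.bonds:
            if i == j:
                raise InputError(f"self-loop bond on atom {i}")
            if not (0 <= i < j < self.n_atoms):
                raise InputError(f"bond ({i},{j}) out of range or unordered")
        if len(set(self.bonds)) != len(self.bonds):
            raise InputError("duplicate bonds")

    @property
    def n_fragments(self) -> int:
        return int(self.fragment_id.max()) + 1

    @property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    @property
    def laplacian(self) -> np.ndarray:
        return build_laplacian(self)

    @property
    def atom_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def build_laplacian(graph: LigandGraph) -> np.ndarray:
    """Graph Laplacian ``L = D - A`` of the ligand bond graph.

    ``L`` is symmetric positive semi-definite with row sums zero; its
    null-space dimension equals the number of connected fragments.
    """
    return graph.degree - graph.adjacency


def _fragments_from_bonds(n_atoms: int, bonds) -> np.ndarray:
    """Connected-component label per atom via union-find."""
    parent = list(range(n_atoms))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = [find(i) for i in range(n_atoms)]
    # relabel contiguously in order of first appearance
    label = {}
    out = np.empty(n_atoms, dtype=int)
    for idx, r in enumerate(roots):
        if r not in label:
            label[r] = len(label)
        out[idx] = label[r]
    return out


def parse_smiles(smiles: str, seed: int = 0):
    """Parse a SMILES string into a :class:`LigandGraph` and a reference
    3D conformer.

    Multi-fragment ligands ("."-separated SMILES) are supported; fragments
    are labelled by connected component. Hydrogens are stripped. The
    conformer is embedded deterministically from ``seed`` (ETKDG with hydrogens,
    then hydrogens removed) and serves as bond-length bookkeeping and as the
    target geometry in synthetic fixtures.

    Returns
    -------
    (LigandGraph, ndarray of shape (n_atoms, 3))
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    if mol.GetNumAtoms() == 0:
        raise InputError(f"SMILES {smiles!r} has zero heavy atoms")

    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        )
    )
    graph = LigandGraph(
        n_atoms=mol.GetNumAtoms(),
        elements=elements,
        bonds=bonds,
        fragment_id=_fragments_from_bonds(mol.GetNumAtoms(), bonds),
    )

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    ok = AllChem.EmbedMolecule(molh, params)
    if ok != 0:  # fall back to random coordinates, still seed-deterministic
        params.useRandomCoords = True
        ok = AllChem.EmbedMolecule(molh, params)
    if ok == 0:
        molh = Chem.RemoveHs(molh)
        conf = molh.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(molh.GetNumAtoms())]
        )
    else:  # single atoms and other unembeddable edge cases
        coords = np.zeros((graph.n_atoms, 3))
    return graph, coords


# --------------------------------------------------------------------------
# Protein
# --------------------------------------------------------------------------

@dataclass
class ProteinStructure:
    """Heavy-atom protein structure with residue-level bookkeeping.

    Attributes
    ----------
    sequence : str
        One-letter residue types, concatenated over chains (length ``S_P``).
    chain_id : tuple of str
        Chain identifier per residue.
    atom_coords : ndarray (N_P, 3)
        Heavy-atom coordinates in Angstrom.
    atom_to_residue : ndarray (N_P,)
        0-based residue index per heavy atom; surjective onto residues.
    ca_index : ndarray (S_P,)
        Heavy-atom index of the Calpha of each residue.
    atom_names : tuple of str
        PDB atom name per heavy atom (e.g. ``CA``, ``CB``).
    """

    sequence: str
    chain_id: tuple
    atom_coords: np.ndarray
    atom_to_residue: np.ndarray
    ca_index: np.ndarray
    atom_names: tuple

    def __post_init__(self):
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        if len(self.sequence) < 1:
            raise InputError("protein must contain at least one residue")
        if not np.all(np.isfinite(self.atom_coords)):
            raise InputError("non-finite protein coordinates")
        if self.n_atoms < self.n_residues:
            raise ContractError("fewer atoms than residues")
        if len(self.ca_index) != self.n_residues:
            raise ContractError("exactly one Calpha index per residue required")
        covered = np.unique(self.atom_to_residue)
        if not np.array_equal(covered, np.arange(self.n_residues)):
            raise ContractError("atom_to_residue must be surjective onto residues")
        if not np.array_equal(
            self.atom_to_residue[self.ca_index], np.arange(self.n_residues)
        ):
            raise ContractError("ca_index inconsistent with atom_to_residue")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return self.atom_coords.shape[0]

    @property
    def ca_coords(self) -> np.ndarray:
        return self.atom_coords[self.ca_index]

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.atom_coords.shape:
            raise ContractError("coordinate shape mismatch")
        return ProteinStructure(
            sequence=self.sequence,
            chain_id=self.chain_id,
            atom_coords=coords,
            atom_to_residue=self.atom_to_residue,
            ca_index=self.ca_index,
            atom_names=self.atom_names,
        )


_THREE_TO_ONE_EXTRA = {"MSE": "M", "SEC": "C", "PYL": "K"}


def _three_to_one(res_name: str):
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return _THREE_TO_ONE_EXTRA.get(res_name)


def read_protein_pdb(path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Heavy atoms of standard amino-acid residues only; altlocs resolved by
    highest occupancy; residues lacking a Calpha and non-standard residues
    are dropped with a logged warning; multiple chains are concatenated in
    file order with their chain identifiers retained.
    """
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, altloc="occupancy")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InputError(f"cannot parse PDB file {path}: {exc}") from exc

    array = array[struc.filter_amino_acids(array)]
    array = array[array.element != "H"]
    if array.array_length() == 0:
        raise InputError(f"no parseable amino-acid residues in {path}")

    sequence = []
    chain_ids = []
    coords = []
    atom_to_res = []
    ca_index = []
    atom_names = []
    n_res = 0
    for res in struc.residue_iter(array):
        res_name = res.res_name[0]
        one = _three_to_one(res_name)
        if one is None:
            logger.warning("dropping non-standard residue %s", res_name)
            continue
        ca_mask = res.atom_name == "CA"
        if not ca_mask.any():
            logger.warning(
                "dropping residue %s %s/%d lacking a Calpha",
                res_name, res.chain_id[0], int(res.res_id[0]),
            )
            continue
        base = len(atom_names)
        sequence.append(one)
        chain_ids.append(str(res.chain_id[0]))
        ca_index.append(base + int(np.flatnonzero(ca_mask)[0]))
        for k in range(res.array_length()):
            coords.append(res.coord[k])
            atom_to_res.append(n_res)
            atom_names.append(str(res.atom_name[k]))
        n_res += 1

    if n_res == 0:
        raise InputError(f"no standard residues with Calpha atoms in {path}")
    return ProteinStructure(
        sequence="".join(sequence),
        chain_id=tuple(chain_ids),
        atom_coords=np.array(coords, dtype=float),
        atom_to_residue=np.array(atom_to_res, dtype=int),
        ca_index=np.array(ca_index, dtype=int),
        atom_names=tuple(atom_names),
    )


# --------------------------------------------------------------------------
# Complex state
# --------------------------------------------------------------------------

@dataclass
class ComplexState:
    """Joint protein/ligand heavy-atom coordinates at flow time ``t``."""

    protein_coords: np.ndarray
    ligand_coords: np.ndarray
    time: float

    def __post_init__(self):
        self.protein_coords = np.asarray(self.protein_coords, dtype=float)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        if self.protein_coords.ndim != 2 or self.protein_coords.shape[1] != 3:
            raise ContractError("protein_coords must have shape (N_P, 3)")
        if self.ligand_coords.ndim != 2 or self.ligand_coords.shape[1] != 3:
            raise ContractError("ligand_coords must have shape (N_L, 3)")
        if not 0.0 <= self.time <= 1.0:
            raise ContractError(f"time {self.time} outside [0, 1]")

    def validate_against(self, structure: ProteinStructure, graph: LigandGraph):
        if self.protein_coords.shape[0] != structure.n_atoms:
            raise ContractError("protein atom count mismatch")
        if self.ligand_coords.shape[0] != graph.n_atoms:
            raise ContractError("ligand atom count mismatch")


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _one_to_three(one: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(one)
    except Exception:
        return "UNK"


def _complex_atom_array(structure, graph, state):
    n = structure.n_atoms + graph.n_atoms
    arr = struc.AtomArray(n)
    res_offset = 0
    for k in range(structure.n_atoms):
        r = structure.atom_to_residue[k]
        arr.chain_id[k] = structure.chain_id[r]
        arr.res_id[k] = r + 1
        arr.res_name[k] = _one_to_three(structure.sequence[r])
        arr.atom_name[k] = structure.atom_names[k]
        name = structure.atom_names[k]
        arr.element[k] = name[0] if name[0].isalpha() else name[1]
        arr.hetero[k] = False
    res_offset = structure.n_residues
    for k in range(graph.n_atoms):
        i = structure.n_atoms + k
        arr.chain_id[i] = "L"
        arr.res_id[i] = res_offset + 1 + int(graph.fragment_id[k])
        arr.res_name[i] = "LIG"
        arr.atom_name[i] = f"{graph.elements[k]}{k + 1}"
        arr.element[i] = graph.elements[k]
        arr.hetero[i] = True
    arr.coord = np.concatenate(
        [state.protein_coords, state.ligand_coords], axis=0
    ).astype(np.float32)
    return arr


def ligand_to_mol(graph: LigandGraph, coords: np.ndarray) -> Chem.Mol:
    """Build an RDKit molecule (single bonds, explicit coordinates) from a
    ligand graph. Bond orders are not tracked by :class:`LigandGraph`."""
    rw = Chem.RWMol()
    for el in graph.elements:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in graph.bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    conf = Chem.Conformer(graph.n_atoms)
    for k in range(graph.n_atoms):
        conf.SetAtomPosition(k, [float(c) for c in coords[k]])
    mol = rw.GetMol()
    mol.AddConformer(conf)
    return mol


def write_ligand_sdf(graph: LigandGraph, coords: np.ndarray, path):
    writer = Chem.SDWriter(str(path))
    writer.write(ligand_to_mol(graph, np.asarray(coords, dtype=float)))
    writer.close()


def read_ligand_sdf(path):
    """Read the first molecule of an SDF file; returns (LigandGraph, coords)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
    mol = next(iter(supplier), None)
    if mol is None:
        raise InputError(f"no molecule in SDF file {path}")
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        )
    )
    graph = LigandGraph(
        n_atoms=mol.GetNumAtoms(),
        elements=elements,
        bonds=bonds,
        fragment_id=_fragments_from_bonds(mol.GetNumAtoms(), bonds),
    )
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(graph.n_atoms)])
    return graph, coords


def write_complex(structure: ProteinStructure, graph: LigandGraph, states, path):
    """Write one :class:`ComplexState` or a trajectory of states to PDB.

    The protein is written as ATOM records and the ligand as HETATM records
    (chain ``L``); a companion SDF with the last-state ligand coordinates is
    written alongside. Multiple states become MODEL/ENDMDL blocks.
    """
    if isinstance(states, ComplexState):
        states = [states]
    for st in states:
        st.validate_against(structure, graph)
    arrays = [_complex_atom_array(structure, graph, st) for st in states]
    if len(arrays) == 1:
        obj = arrays[0]
    else:
        obj = struc.stack(arrays)
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(obj)
    tmp = f"{path}.tmp{os.getpid()}"
    pdb_file.write(tmp)
    os.replace(tmp, path)
    sdf_path = os.path.splitext(str(path))[0] + "_ligand.sdf"
    write_ligand_sdf(graph, states[-1].ligand_coords, sdf_path)


# --------------------------------------------------------------------------
# Sequence utilities
# --------------------------------------------------------------------------

def check_sequence_gaps(full_sequence: str, structure: ProteinStructure) -> bool:
    """True iff the structure's resolved residue sequence equals the intended
    complete sequence exactly (chains concatenated in order).

    Any missing, extra, or substituted residue counts as a gap and returns
    False; structures with gaps are dropped during dataset curation.
    """
    return structure.sequence == full_sequence.strip().upper()


def read_fasta(path) -> dict:
    """Read a FASTA file of full chain sequences; returns {header: sequence}."""
    import biotite.sequence.io.fasta as fasta_io

    f = fasta_io.FastaFile.read(str(path))
    return {name: str(seq) for name, seq in f.items()}
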