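"""Chemical structures, built-in descriptors, fingerprints, descriptor tables.

RDKit is the chemistry backend: SMILES parsing, canonicalization, aromaticity
perception and SMARTS matching all follow its conventions, and the canonical
SMILES is recorded on every structure so outputs are auditable.

The built-in descriptor set is deliberately small and exactly specified
(8 descriptors, below); models that need anything else supply values through
a CSV descriptor table.  Three fingerprint kinds are provided behind one
interface: hashed linear paths (1–7 bonds, 1024 bits), a ~50-pattern SMARTS
key set (binary), and its count variant.  A chemistry backend's own named
fingerprints can be plugged in via `register_fingerprint_kind`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as RdDescriptors
from rdkit.Chem import rdMolDescriptors

from .base import DescriptorSpec, QsarError, ValidationError
from .smarts_keys import SMARTS_KEYS

RDLogger.DisableLog("rdApp.*")  # structured errors are raised instead

__all__ = [
    "ChemicalStructure",
    "Fingerprint",
    "DescriptorVector",
    "SmilesParseError",
    "parse_smiles",
    "compute_descriptors",
    "available_descriptors",
    "read_descriptor_table",
    "read_smiles_file",
    "compute_fingerprint",
    "register_fingerprint_kind",
    "resolve_descriptor_vector",
]


class SmilesParseError(QsarError):
    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


@dataclass(frozen=True, eq=False)
class ChemicalStructure:
    id: str
    smiles: str
    canonical_smiles: str
    mol: object = field(repr=False, compare=False)

    def __eq__(self, other):
        return (
            isinstance(other, ChemicalStructure)
            and self.id == other.id
            and self.canonical_smiles == other.canonical_smiles
        )

    def __hash__(self):
        return hash((self.id, self.canonical_smiles))


def parse_smiles(text: str, id: Optional[str] = None) -> ChemicalStructure:
    """Parse a SMILES string into a structure with its canonical form."""
    if not text or not text.strip():
        raise SmilesParseError(text)
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(text)
    canonical = Chem.MolToSmiles(mol)
    return ChemicalStructure(id=id or canonical, smiles=text,
                             canonical_smiles=canonical, mol=mol)


# ---------------------------------------------------------------------------
# built-in descriptors
# ---------------------------------------------------------------------------

def _wiener_index(mol) -> float:
    # half the sum of the topological (bond-count) distance matrix over heavy atoms
    if mol.GetNumAtoms() < 2:
        return 0.0
    dm = Chem.GetDistanceMatrix(mol)
    return float(dm.sum() / 2.0)


BUILTIN_DESCRIPTORS: dict = {
    "molecular_weight": lambda m: float(RdDescriptors.MolWt(m)),
    "heavy_atom_count": lambda m: float(m.GetNumHeavyAtoms()),
    "ring_count": lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    "hbond_donor_count": lambda m: float(rdMolDescriptors.CalcNumHBD(m)),
    "hbond_acceptor_count": lambda m: float(rdMolDescriptors.CalcNumHBA(m)),
    "rotatable_bond_count": lambda m: float(rdMolDescriptors.CalcNumRotatableBonds(m)),
    "wiener_index": _wiener_index,
    "tpsa": lambda m: float(RdDescriptors.TPSA(m)),
}


def available_descriptors() -> list:
    return list(BUILTIN_DESCRIPTORS)


@dataclass(frozen=True)
class DescriptorVector:
    """Descriptor values aligned to a model's spec list, with provenance."""

    values: tuple
    provenance: tuple  # "computed" | "supplied" per value

    def __post_init__(self):
        if len(self.values) != len(self.provenance):
            raise ValidationError("values/provenance length mismatch")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def compute_descriptors(
    structure: ChemicalStructure, specs: Sequence[DescriptorSpec]
) -> DescriptorVector:
    """Compute the built-in descriptors named by ``specs`` for one structure.

    Every spec must have ``source="computed"`` and name a built-in
    descriptor; values are deterministic per canonical structure.
    """
    values = []
    for spec in specs:
        fn = BUILTIN_DESCRIPTORS.get(spec.name)
        if fn is None:
            raise ValidationError(
                f"unknown computed descriptor {spec.name!r}; available: "
                f"{', '.join(available_descriptors())}"
            )
        values.append(fn(structure.mol))
    return DescriptorVector(values=tuple(values),
                            provenance=("computed",) * len(values))


def read_descriptor_table(source) -> dict:
    """Read a CSV descriptor table (id column first, one descriptor per column).

    Returns a mapping id -> {descriptor name -> float}.  A missing cell is an
    immediate error naming its row and column; a table lacking a descriptor a
    model later needs is fine at read time (late binding at prediction time).
    """
    df = pd.read_csv(source, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError("descriptor table needs an id column plus >=1 descriptor")
    id_col = df.columns[0]
    out: dict = {}
    for _, row in df.iterrows():
        cid = str(row[id_col])
        vals = {}
        for col in df.columns[1:]:
            v = row[col]
            if pd.isna(v):
                raise ValidationError(
                    f"missing descriptor value at row {cid!r}, column {col!r}"
                )
            vals[col] = float(v)
        out[cid] = vals
    return out


def read_smiles_file(source) -> list:
    """Read a .smi file: one ``SMILES<whitespace>ID`` per line, '#' comments.

    Returns (id, smiles) pairs without parsing, so that a bad SMILES can be
    reported against its chemical id by the caller (`parse_smiles` per pair).
    Lines without an id get ``lineN``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    pairs = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"line{i}"
        pairs.append((cid, smiles))
    return pairs


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

HASHED_PATH_BITS = 1024
MAX_PATH_BONDS = 7


@dataclass(frozen=True)
class Fingerprint:
    """A binary or count fingerprint of a documented kind.

    ``bits`` is a frozenset of set-bit indices for binary kinds; ``counts``
    maps index -> positive count for count kinds (its keys are the bits).
    """

    kind: str
    length: int
    bits: frozenset = frozenset()
    counts: Mapping[int, int] | None = None

    def __post_init__(self):
        if self.counts is not None:
            object.__setattr__(self, "counts", dict(self.counts))
            object.__setattr__(self, "bits", frozenset(self.counts))
            if any(c <= 0 for c in self.counts.values()):
                raise ValidationError("fingerprint counts must be positive")
        if any(not (0 <= b < self.length) for b in self.bits):
            raise ValidationError("fingerprint bit index out of range")

    @property
    def is_count(self) -> bool:
        return self.counts is not None

    def __eq__(self, other):
        return (
            isinstance(other, Fingerprint)
            and self.kind == other.kind
            and self.length == other.length
            and self.bits == other.bits
            and (self.counts or None) == (other.counts or None)
        )

    def __hash__(self):
        return hash((self.kind, self.length, self.bits))


def _atom_token(atom) -> str:
    return atom.GetSymbol() + ("a" if atom.GetIsAromatic() else "")


def _bond_token(bond) -> str:
    return str(bond.GetBondType())


def _path_keys(mol):
    """Canonical string keys of all linear heavy-atom paths of 1..7 bonds."""
    keys = set()
    for nbonds in range(1, MAX_PATH_BONDS + 1):
        for bond_path in Chem.FindAllPathsOfLengthN(mol, nbonds, useBonds=True):
            bonds = [mol.GetBondWithIdx(b) for b in bond_path]
            # heavy-atom paths only: explicit (e.g. isotopic) hydrogens are
            # not part of the fingerprinted graph
            if any(b.GetBeginAtom().GetAtomicNum() == 1
                   or b.GetEndAtom().GetAtomicNum() == 1 for b in bonds):
                continue
            # reconstruct the atom sequence along the path
            if len(bonds) == 1:
                atoms = [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
            else:
                first = {bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()}
                second = {bonds[1].GetBeginAtomIdx(), bonds[1].GetEndAtomIdx()}
                shared = (first & second).pop()
                atoms = [(first - {shared}).pop(), shared]
                for b in bonds[1:]:
                    nxt = (b.GetEndAtomIdx() if b.GetBeginAtomIdx() == atoms[-1]
                           else b.GetBeginAtomIdx())
                    atoms.append(nxt)
            tokens = []
            for i, a in enumerate(atoms):
                tokens.append(_atom_token(mol.GetAtomWithIdx(a)))
                if i < len(bonds):
                    tokens.append(_bond_token(bonds[i]))
            fwd = "|".join(tokens)
            rev = "|".join(reversed(tokens))
            keys.add(min(fwd, rev))
    return keys


def _hashed_path_fp(mol) -> Fingerprint:
    bits = frozenset(zlib.crc32(k.encode()) % HASHED_PATH_BITS for k in _path_keys(mol))
    return Fingerprint(kind="hashed_path", length=HASHED_PATH_BITS, bits=bits)


_SMARTS_MOLS = None


def _smarts_mols():
    global _SMARTS_MOLS
    if _SMARTS_MOLS is None:
        _SMARTS_MOLS = [(i, name, Chem.MolFromSmarts(s))
                        for i, (name, s) in enumerate(SMARTS_KEYS.items())]
        bad = [name for _, name, m in _SMARTS_MOLS if m is None]
        assert not bad, f"invalid SMARTS in key dictionary: {bad}"
    return _SMARTS_MOLS


def _smarts_fp(mol, count: bool) -> Fingerprint:
    length = len(SMARTS_KEYS)
    if count:
        counts = {}
        for i, _name, patt in _smarts_mols():
            n = len(mol.GetSubstructMatches(patt, uniquify=True))
            if n:
                counts[i] = n
        return Fingerprint(kind="smarts_keys_count", length=length, counts=counts)
    bits = frozenset(i for i, _name, patt in _smarts_mols()
                     if mol.HasSubstructMatch(patt))
    return Fingerprint(kind="smarts_keys", length=length, bits=bits)


_FINGERPRINT_KINDS: dict = {
    "hashed_path": lambda s: _hashed_path_fp(s.mol),
    "smarts_keys": lambda s: _smarts_fp(s.mol, count=False),
    "smarts_keys_count": lambda s: _smarts_fp(s.mol, count=True),
}


def register_fingerprint_kind(name: str, fn: Callable) -> None:
    """Adapter point: plug in a backend-provided fingerprint.

    ``fn`` maps a ChemicalStructure to a Fingerprint whose ``kind`` equals
    ``name``.
    """
    _FINGERPRINT_KINDS[name] = fn


def available_fingerprint_kinds() -> list:
    return list(_FINGERPRINT_KINDS)


def compute_fingerprint(structure: ChemicalStructure, kind: str = "hashed_path") -> Fingerprint:
    try:
        fn = _FINGERPRINT_KINDS[kind]
    except KeyError:
        raise ValidationError(
            f"unknown fingerprint kind {kind!r}; available: "
            f"{', '.join(_FINGERPRINT_KINDS)}"
        ) from None
    return fn(structure)


# ---------------------------------------------------------------------------
# descriptor resolution for prediction
# ---------------------------------------------------------------------------

def resolve_descriptor_vector(
    specs: Sequence[DescriptorSpec],
    structure: Optional[ChemicalStructure] = None,
    supplied: Optional[Mapping[str, float]] = None,
) -> DescriptorVector:
    """Assemble a model-aligned descriptor vector for one target chemical.

    A supplied value (from a descriptor table) always wins; otherwise a
    ``source="computed"`` spec is computed from the structure.  A spec that
    can be satisfied by neither raises, naming the descriptor — this is the
    prediction-time (late-binding) check.
    """
    supplied = supplied or {}
    values, prov = [], []
    for spec in specs:
        if spec.name in supplied:
            values.append(float(supplied[spec.name]))
            prov.append("supplied")
        elif spec.source == "computed" and structure is not None:
            values.append(compute_descriptors(structure, [spec]).values[0])
            prov.append("computed")
        else:
            from .base import MissingDescriptorError

            raise MissingDescriptorError(
                spec.name,
                f"descriptor {spec.name!r} is neither supplied nor computable "
                f"({'no structure given' if structure is None else 'source=supplied'})",
            )
    return DescriptorVector(values=tuple(values), provenance=tuple(prov))
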