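"""Datasets, molecular graphs, and train/valid/test splitting.

Molecules enter as SMILES rows of a CSV and become directed molecular
graphs: every undirected bond u–v contributes two directed bonds u->v and
v->u carrying identical bond features, and each directed bond knows its
reverse.  This is the graph representation consumed by the directed
message-passing encoder, where hidden states live on directed bonds and the
message into bond v->w sums the states of bonds entering v except the
reverse bond w->v.

Splitting supports the benchmark convention: an 8:1:1 random split, and a
Bemis–Murcko scaffold split that keeps all molecules sharing a ring-system
scaffold in one partition (the harder generalization test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConfigurationError, DataError, ParseError

RDLogger.DisableLog("rdApp.*")  # benchmark CSVs contain occasional junk rows

__all__ = [
    "MoleculeRecord",
    "MolGraph",
    "BatchGraph",
    "SplitIndices",
    "ReadReport",
    "FeatureScheme",
    "read_dataset",
    "featurize_molecule",
    "batch_graphs",
    "random_split",
    "compute_scaffold",
    "scaffold_split",
    "DEFAULT_SCHEME",
]


# --------------------------------------------------------------------------
# feature scheme
# --------------------------------------------------------------------------

def _one_hot(value, choices: Sequence) -> list[float]:
    """One-hot over `choices` plus a trailing 'other' slot."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]

_BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]


class FeatureScheme:
    """Atom/bond descriptor set of the directed-MPNN encoder family.

    Atom: one-hot atomic number (1..100 + other), degree 0-5, formal charge
    {-2,-1,0,1,2}, chiral tag, attached-H count 0-4, hybridization, aromatic
    flag, atomic mass / 100.  Bond: null-bond flag, bond-type one-hot
    (single/double/triple/aromatic), conjugated, in-ring, stereo one-hot.
    Hydrogens are implicit (never graph nodes).
    """

    name = "dmpnn"
    d_atom = 133
    d_bond = 14

    def atom_features(self, atom: Chem.Atom) -> list[float]:
        return (
            _one_hot(atom.GetAtomicNum(), list(range(1, 101)))
            + _one_hot(atom.GetTotalDegree(), [0, 1, 2, 3, 4, 5])
            + _one_hot(atom.GetFormalCharge(), [-2, -1, 0, 1, 2])
            + _one_hot(int(atom.GetChiralTag()), [0, 1, 2, 3])
            + _one_hot(int(atom.GetTotalNumHs()), [0, 1, 2, 3, 4])
            + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + [atom.GetMass() * 0.01]
        )

    def bond_features(self, bond: Chem.Bond) -> list[float]:
        return (
            [0.0]  # null-bond flag (reserved; real bonds are 0)
            + [1.0 if bond.GetBondType() == t else 0.0 for t in _BOND_TYPES]
            + [1.0 if bond.GetIsConjugated() else 0.0]
            + [1.0 if bond.IsInRing() else 0.0]
            + _one_hot(int(bond.GetStereo()), [0, 1, 2, 3, 4, 5])
        )


class ScalarScheme(FeatureScheme):
    """Degenerate scheme (x_v = [1], e_vw = [1]) for hand-worked fixtures."""

    name = "scalar"
    d_atom = 1
    d_bond = 1

    def atom_features(self, atom) -> list[float]:
        return [1.0]

    def bond_features(self, bond) -> list[float]:
        return [1.0]


DEFAULT_SCHEME = FeatureScheme()
_SCHEMES: dict[str, FeatureScheme] = {
    "dmpnn": DEFAULT_SCHEME,
    "scalar": ScalarScheme(),
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    """One SMILES plus its target vector and observed-value mask."""

    smiles: str
    targets: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.float64).ravel()
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.targets.shape != self.mask.shape:
            raise ConfigurationError("targets and mask must have equal length")


@dataclass
class MolGraph:
    """Directed molecular graph with per-directed-bond reverse indices."""

    n_atoms: int
    n_dir_bonds: int
    atom_features: np.ndarray   # [n_atoms, d_atom]
    bond_features: np.ndarray   # [n_dir_bonds, d_bond]
    bond_origin: np.ndarray     # directed bond b = (v -> w): index of v
    bond_target: np.ndarray     # index of w
    reverse_index: np.ndarray   # index of (w -> v)

    @property
    def incoming(self) -> list[np.ndarray]:
        """For each atom v, the directed-bond indices (k -> v)."""
        inc: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for b, w in enumerate(self.bond_target):
            inc[int(w)].append(b)
        return [np.asarray(i, dtype=np.intp) for i in inc]

    def validate(self) -> None:
        rev = self.reverse_index
        assert np.array_equal(rev[rev], np.arange(self.n_dir_bonds))
        assert np.array_equal(self.bond_origin[rev], self.bond_target)
        assert np.array_equal(self.bond_target[rev], self.bond_origin)


@dataclass
class BatchGraph:
    """Concatenated MolGraphs with global indices and molecule membership."""

    n_mols: int
    n_atoms: int
    n_dir_bonds: int
    atom_features: np.ndarray
    bond_features: np.ndarray
    bond_origin: np.ndarray
    bond_target: np.ndarray
    reverse_index: np.ndarray
    atom_to_mol: np.ndarray          # atom -> molecule index
    atom_ranges: np.ndarray          # [n_mols, 2] half-open atom spans
    bond_ranges: np.ndarray          # [n_mols, 2] half-open directed-bond spans

    def unbatch(self) -> list[MolGraph]:
        out = []
        for m in range(self.n_mols):
            a0, a1 = self.atom_ranges[m]
            b0, b1 = self.bond_ranges[m]
            out.append(MolGraph(
                n_atoms=int(a1 - a0),
                n_dir_bonds=int(b1 - b0),
                atom_features=self.atom_features[a0:a1].copy(),
                bond_features=self.bond_features[b0:b1].copy(),
                bond_origin=self.bond_origin[b0:b1] - a0,
                bond_target=self.bond_target[b0:b1] - a0,
                reverse_index=self.reverse_index[b0:b1] - b0,
            ))
        return out


@dataclass
class SplitIndices:
    """Train/valid/test partition of record indices."""

    train: list[int]
    valid: list[int]
    test: list[int]
    method: str
    seed: int

    def validate(self, n: int) -> None:
        parts = [set(self.train), set(self.valid), set(self.test)]
        assert parts[0].isdisjoint(parts[1])
        assert parts[0].isdisjoint(parts[2])
        assert parts[1].isdisjoint(parts[2])
        assert parts[0] | parts[1] | parts[2] == set(range(n))

    def to_json(self) -> str:
        return json.dumps({"train": list(map(int, self.train)),
                           "valid": list(map(int, self.valid)),
                           "test": list(map(int, self.test)),
                           "method": self.method, "seed": int(self.seed)})

    @classmethod
    def from_json(cls, text: str) -> "SplitIndices":
        d = json.loads(text)
        return cls(d["train"], d["valid"], d["test"], d["method"], d["seed"])


@dataclass
class ReadReport:
    """Bookkeeping from read_dataset: how many rows were dropped and why."""

    n_rows: int
    n_kept: int
    n_dropped: int
    dropped_rows: list[int] = field(default_factory=list)
    task_names: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def read_dataset(path: str | Path, smiles_column: str = "smiles",
                 target_columns: Sequence[str] | None = None,
                 task: str = "regression",
                 ) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read a SMILES CSV into records, dropping (and counting) bad rows.

    Unnamed target columns default to every non-SMILES column.  Empty target
    cells become mask=False with a 0.0 placeholder.  Classification targets
    must be 0/1 where observed.
    """
    if task not in ("regression", "classification"):
        raise ConfigurationError(f"unknown task {task!r}")
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ConfigurationError(
            f"SMILES column {smiles_column!r} not in {list(df.columns)}")
    if target_columns is None:
        target_columns = [c for c in df.columns if c != smiles_column]
    else:
        missing = [c for c in target_columns if c not in df.columns]
        if missing:
            raise ConfigurationError(f"target columns not found: {missing}")
    if not target_columns:
        raise ConfigurationError("no target columns")

    records: list[MoleculeRecord] = []
    dropped: list[int] = []
    for i, row in df.iterrows():
        smiles = str(row[smiles_column])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumAtoms() == 0:
            dropped.append(int(i))
            continue
        vals = pd.to_numeric(row[list(target_columns)], errors="coerce").to_numpy(
            dtype=np.float64)
        mask = np.isfinite(vals)
        if task == "classification":
            observed = vals[mask]
            if not np.all(np.isin(observed, (0.0, 1.0))):
                raise DataError(
                    f"row {i}: classification targets must be 0/1 or empty")
        vals = np.where(mask, vals, 0.0)
        records.append(MoleculeRecord(smiles=smiles, targets=vals, mask=mask))
    if not records:
        raise DataError(f"no valid SMILES rows in {path}")
    report = ReadReport(n_rows=len(df), n_kept=len(records),
                        n_dropped=len(dropped), dropped_rows=dropped,
                        task_names=list(target_columns))
    return records, report


def featurize_molecule(smiles: str, scheme: str | FeatureScheme = "dmpnn",
                       ) -> MolGraph:
    """SMILES -> directed molecular graph under the named feature scheme."""
    if isinstance(scheme, str):
        try:
            scheme = _SCHEMES[scheme]
        except KeyError:
            raise ConfigurationError(f"unknown feature scheme {scheme!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise DataError(f"SMILES {smiles!r} yields zero atoms")

    atom_feats = np.asarray([scheme.atom_features(a) for a in mol.GetAtoms()],
                            dtype=np.float64).reshape(n_atoms, scheme.d_atom)
    bond_feats, origin, target, reverse = [], [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = scheme.bond_features(bond)
        b = len(origin)
        origin += [u, v]
        target += [v, u]
        bond_feats += [f, f]           # both directions share the features
        reverse += [b + 1, b]
    graph = MolGraph(
        n_atoms=n_atoms,
        n_dir_bonds=len(origin),
        atom_features=atom_feats,
        bond_features=np.asarray(bond_feats, dtype=np.float64).reshape(
            len(origin), scheme.d_bond),
        bond_origin=np.asarray(origin, dtype=np.intp),
        bond_target=np.asarray(target, dtype=np.intp),
        reverse_index=np.asarray(reverse, dtype=np.intp),
    )
    graph.validate()
    return graph


def batch_graphs(graphs: Sequence[MolGraph]) -> BatchGraph:
    """Concatenate graphs with index offsets and molecule membership."""
    if not graphs:
        raise ConfigurationError("batch_graphs needs a non-empty list")
    atom_off = bond_off = 0
    feats_a, feats_b = [], []
    origin, target, reverse, membership = [], [], [], []
    atom_ranges, bond_ranges = [], []
    for m, g in enumerate(graphs):
        feats_a.append(g.atom_features)
        feats_b.append(g.bond_features)
        origin.append(g.bond_origin + atom_off)
        target.append(g.bond_target + atom_off)
        reverse.append(g.reverse_index + bond_off)
        membership.append(np.full(g.n_atoms, m, dtype=np.intp))
        atom_ranges.append((atom_off, atom_off + g.n_atoms))
        bond_ranges.append((bond_off, bond_off + g.n_dir_bonds))
        atom_off += g.n_atoms
        bond_off += g.n_dir_bonds
    return BatchGraph(
        n_mols=len(graphs),
        n_atoms=atom_off,
        n_dir_bonds=bond_off,
        atom_features=np.concatenate(feats_a, axis=0),
        bond_features=(np.concatenate(feats_b, axis=0) if bond_off else
                       np.zeros((0, graphs[0].bond_features.shape[1]))),
        bond_origin=np.concatenate(origin) if origin else np.zeros(0, np.intp),
        bond_target=np.concatenate(target) if target else np.zeros(0, np.intp),
        reverse_index=np.concatenate(reverse) if reverse else np.zeros(0, np.intp),
        atom_to_mol=np.concatenate(membership),
        atom_ranges=np.asarray(atom_ranges, dtype=np.intp),
        bond_ranges=np.asarray(bond_ranges, dtype=np.intp),
    )


def _split_sizes(n: int) -> tuple[int, int, int]:
    """8:1:1 with conventional rounding; test takes the remainder."""
    n_train = int(np.floor(0.8 * n + 0.5))
    n_valid = int(np.floor(0.1 * n + 0.5))
    return n_train, n_valid, n - n_train - n_valid


def random_split(n: int, ratios: tuple = (0.8, 0.1, 0.1),
                 seed: int = 0) -> SplitIndices:
    """Seed-deterministic random 8:1:1 partition of range(n)."""
    if tuple(ratios) != (0.8, 0.1, 0.1):
        raise ConfigurationError("only the 8:1:1 ratio is supported")
    if n < 3:
        raise DataError(f"need n >= 3 to split; got {n}")
    n_train, n_valid, _ = _split_sizes(n)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=perm[:n_train].tolist(),
        valid=perm[n_train:n_train + n_valid].tolist(),
        test=perm[n_train + n_valid:].tolist(),
        method="random", seed=int(seed),
    )


def compute_scaffold(smiles: str, include_chirality: bool = False) -> str:
    """Canonical Bemis–Murcko scaffold key; acyclic molecules map to ''."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(
        mol=mol, includeChirality=include_chirality)


def scaffold_split(records: Sequence[MoleculeRecord],
                   ratios: tuple = (0.8, 0.1, 0.1), seed: int = 0,
                   include_chirality: bool = False) -> SplitIndices:
    """Scaffold-grouped 8:1:1 split: one scaffold never spans partitions.

    Groups are placed largest-first (train -> valid -> test, first whose
    quota is unfilled); the seed shuffles only the order of equal-size
    groups, so the partition is deterministic given (records, seed).
    """
    if tuple(ratios) != (0.8, 0.1, 0.1):
        raise ConfigurationError("only the 8:1:1 ratio is supported")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(
            compute_scaffold(rec.smiles, include_chirality), []).append(i)
    if len(groups) < 3:
        raise DataError(
            f"only {len(groups)} scaffold group(s); use random_split instead")

    rng = np.random.default_rng(seed)
    keys = sorted(groups)                     # deterministic base order
    tiebreak = rng.permutation(len(keys))     # shuffles equal-size ties only
    order = sorted(range(len(keys)),
                   key=lambda j: (-len(groups[keys[j]]), tiebreak[j]))

    n = len(records)
    n_train, n_valid, n_test = _split_sizes(n)
    quota = [n_train, n_valid, n_test]
    parts: list[list[int]] = [[], [], []]
    for j in order:
        members = groups[keys[j]]
        dest = next((p for p in range(3) if len(parts[p]) < quota[p]), 0)
        parts[dest].extend(members)
    split = SplitIndices(train=sorted(parts[0]), valid=sorted(parts[1]),
                         test=sorted(parts[2]), method="scaffold",
                         seed=int(seed))
    split.validate(n)
    return split
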