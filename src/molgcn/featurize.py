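"""SMILES -> molecular-graph featurization at configurable information levels.

Molecules are handled as heavy-atom graphs (hydrogens implicit, surfacing only
through the per-atom H-count feature).  The amount of chemistry exposed to the
network is controlled by an information *level*:

1. element one-hot per atom
2. level 1 + hybridization one-hot
3. level 2 + bond-type one-hot per edge
4. level 3 + chirality (CIP R/S/none), total H count, in-ring flag,
   in-aromatic-ring flag
5. level 4 + global molecular descriptors: molecular weight, net formal
   charge, rotatable-bond count (Lipinski definition)

All feature widths are a pure function of the level and the vocabularies, so
model shapes can be derived from a :class:`FeatureConfig` alone.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski


class FeaturizationError(ValueError):
    """A molecule could not be featurized under the active configuration."""


class SmilesParseError(FeaturizationError):
    """The SMILES string could not be parsed into a molecule."""


DEFAULT_ELEMENT_VOCAB = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "other")
DEFAULT_HYBRIDIZATION_VOCAB = ("SP", "SP2", "SP3", "SP3D", "SP3D2", "other")
DEFAULT_BOND_VOCAB = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
DEFAULT_CHIRALITY_VOCAB = ("R", "S", "none")

#: number of global molecular descriptors at level 5 (weight, charge, rotatable bonds)
N_MOL_FEATURES = 3


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Which information level is active, plus the vocabularies.

    ``mol_feature_standardization`` is either ``None`` (identity) or a pair of
    length-3 arrays ``(mean, scale)`` applied as ``(x - mean) / scale`` to the
    global descriptor vector.  ``strict`` turns out-of-vocabulary values into
    errors instead of routing them to the catch-all bucket.
    """

    level: int = 5
    element_vocab: Sequence[str] = DEFAULT_ELEMENT_VOCAB
    hybridization_vocab: Sequence[str] = DEFAULT_HYBRIDIZATION_VOCAB
    bond_vocab: Sequence[str] = DEFAULT_BOND_VOCAB
    chirality_vocab: Sequence[str] = DEFAULT_CHIRALITY_VOCAB
    mol_feature_standardization: Optional[tuple] = None
    strict: bool = False

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4, 5):
            raise ValueError(f"information level must be in 1..5, got {self.level!r}")
        for name in ("element_vocab", "hybridization_vocab", "bond_vocab",
                     "chirality_vocab"):
            vocab = getattr(self, name)
            if len(vocab) != len(set(vocab)):
                raise ValueError(f"{name} contains duplicates: {vocab}")
        if self.mol_feature_standardization is not None:
            mean, scale = self.mol_feature_standardization
            if len(mean) != N_MOL_FEATURES or len(scale) != N_MOL_FEATURES:
                raise ValueError("mol_feature_standardization must be a pair of "
                                 f"length-{N_MOL_FEATURES} sequences")

    def fingerprint(self) -> dict:
        """JSON-serializable identity of the featurization (level + vocabularies)."""
        return {
            "level": self.level,
            "element_vocab": list(self.element_vocab),
            "hybridization_vocab": list(self.hybridization_vocab),
            "bond_vocab": list(self.bond_vocab),
            "chirality_vocab": list(self.chirality_vocab),
        }


def feature_dimensions(config: FeatureConfig) -> tuple[int, int, int]:
    """Return ``(d_atom, d_bond, d_mol)`` for the active configuration."""
    d_atom = len(config.element_vocab)
    if config.level >= 2:
        d_atom += len(config.hybridization_vocab)
    if config.level >= 4:
        # chirality one-hot + H count + in-ring flag + in-aromatic-ring flag
        d_atom += len(config.chirality_vocab) + 3
    d_bond = len(config.bond_vocab) if config.level >= 3 else 0
    d_mol = N_MOL_FEATURES if config.level == 5 else 0
    return d_atom, d_bond, d_mol


@dataclasses.dataclass
class MolGraph:
    """One molecule as a featurized heavy-atom graph.

    ``edges`` stores each bonded pair once as an unordered ``(i, j)`` with
    ``i < j``; the model expands them to both directions.  Masked-out label
    entries carry a 0.0 sentinel and ``label_mask`` 0, so no NaN ever enters
    downstream arithmetic.
    """

    n_atoms: int
    atom_features: np.ndarray          # (n_atoms, d_atom)
    edges: np.ndarray                  # (n_edges, 2), int, i < j
    bond_features: np.ndarray          # (n_edges, d_bond)
    mol_features: np.ndarray           # (d_mol,)
    labels: Optional[np.ndarray] = None       # (c,)
    label_mask: Optional[np.ndarray] = None   # (c,), 1 = observed
    smiles: str = ""


def _one_hot(value: str, vocab: Sequence[str], what: str, strict: bool) -> np.ndarray:
    vec = np.zeros(len(vocab))
    if value in vocab:
        vec[list(vocab).index(value)] = 1.0
    elif vocab[-1] == "other" and not strict:
        vec[-1] = 1.0
    else:
        raise FeaturizationError(f"{what} {value!r} outside vocabulary {tuple(vocab)}")
    return vec


def _parse_mol(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def atom_feature_vector(mol: Chem.Mol, atom_index: int, config: FeatureConfig) -> np.ndarray:
    """Feature vector for one atom; block order is element, hybridization,
    chirality, H count, ring flags (later blocks only at the levels that add
    them)."""
    atom = mol.GetAtomWithIdx(atom_index)
    blocks = [_one_hot(atom.GetSymbol(), config.element_vocab, "element", config.strict)]
    if config.level >= 2:
        blocks.append(_one_hot(str(atom.GetHybridization()),
                               config.hybridization_vocab, "hybridization",
                               config.strict))
    if config.level >= 4:
        cip = atom.GetPropsAsDict().get("_CIPCode", "none")
        blocks.append(_one_hot(cip, config.chirality_vocab, "chirality", config.strict))
        blocks.append(np.array([float(atom.GetTotalNumHs()),
                                float(atom.IsInRing()),
                                float(atom.GetIsAromatic())]))
    return np.concatenate(blocks)


def bond_feature_vector(mol: Chem.Mol, i: int, j: int, config: FeatureConfig) -> np.ndarray:
    """Bond-type one-hot for the bond between atoms ``i`` and ``j``; symmetric
    in its endpoints.  Empty vector below level 3."""
    bond = mol.GetBondBetweenAtoms(int(i), int(j))
    if bond is None:
        raise FeaturizationError(f"atoms {i} and {j} are not bonded")
    if config.level < 3:
        return np.zeros(0)
    return _one_hot(str(bond.GetBondType()), config.bond_vocab, "bond type",
                    config.strict)


def molecule_feature_vector(mol: Chem.Mol, config: FeatureConfig) -> np.ndarray:
    """Global descriptors [molecular weight, net formal charge, rotatable-bond
    count], standardized if the config carries statistics.  Empty below
    level 5."""
    if config.level < 5:
        return np.zeros(0)
    raw = np.array([
        Descriptors.MolWt(mol),
        float(Chem.GetFormalCharge(mol)),
        float(Lipinski.NumRotatableBonds(mol)),
    ])
    if config.mol_feature_standardization is not None:
        mean, scale = config.mol_feature_standardization
        raw = (raw - np.asarray(mean, dtype=float)) / np.asarray(scale, dtype=float)
    return raw


def build_graph(smiles: str, config: FeatureConfig,
                labels: Optional[Sequence[float]] = None,
                mask: Optional[Sequence[float]] = None) -> MolGraph:
    """Parse a SMILES string and featurize it under ``config``.

    Raises :class:`SmilesParseError` on unparseable input.  Label entries with
    mask 0 are stored as 0.0 sentinels.
    """
    mol = _parse_mol(smiles)
    d_atom, d_bond, d_mol = feature_dimensions(config)
    n = mol.GetNumAtoms()
    atom_feats = np.zeros((n, d_atom))
    for idx in range(n):
        atom_feats[idx] = atom_feature_vector(mol, idx, config)
    pairs, bond_feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        i, j = (i, j) if i < j else (j, i)
        pairs.append((i, j))
        bond_feats.append(bond_feature_vector(mol, i, j, config))
    edges = np.array(pairs, dtype=np.int64).reshape(len(pairs), 2)
    bond_mat = (np.array(bond_feats).reshape(len(pairs), d_bond)
                if d_bond else np.zeros((len(pairs), 0)))

    label_arr = mask_arr = None
    if labels is not None:
        label_arr = np.asarray(labels, dtype=float).copy()
        if mask is not None:
            mask_arr = np.asarray(mask, dtype=float).copy()
        else:
            mask_arr = np.ones_like(label_arr)
        if mask_arr.shape != label_arr.shape:
            raise ValueError("label_mask must have the same length as labels")
        label_arr[mask_arr == 0] = 0.0
    return MolGraph(n_atoms=n, atom_features=atom_feats, edges=edges,
                    bond_features=bond_mat,
                    mol_features=molecule_feature_vector(mol, config),
                    labels=label_arr, label_mask=mask_arr, smiles=smiles)


def permute_graph(graph: MolGraph, perm: Sequence[int]) -> MolGraph:
    """Relabel atoms by ``perm`` (new index of old atom ``i`` is ``perm[i]``).

    Utility for invariance checks: the model's output must not depend on atom
    ordering.
    """
    perm = np.asarray(perm, dtype=np.int64)
    if sorted(perm.tolist()) != list(range(graph.n_atoms)):
        raise ValueError("perm must be a permutation of atom indices")
    inv = np.empty_like(perm)
    inv[perm] = np.arange(graph.n_atoms)
    new_atoms = graph.atom_features[inv]
    new_edges = np.sort(perm[graph.edges], axis=1) if len(graph.edges) else graph.edges
    return MolGraph(n_atoms=graph.n_atoms, atom_features=new_atoms,
                    edges=new_edges, bond_features=graph.bond_features.copy(),
                    mol_features=graph.mol_features.copy(),
                    labels=None if graph.labels is None else graph.labels.copy(),
                    label_mask=None if graph.label_mask is None else graph.label_mask.copy(),
                    smiles=graph.smiles)
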