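"""Seeded generator of benchmark-style CSV datasets: valid SMILES with
planted, featurization-level-dependent labels and controllable class
imbalance.

Molecules are assembled by bonding fragments from a curated library (alkyl
chains, saturated and aromatic rings, common functional groups) with a seeded
random walk, so every emitted SMILES is valid by construction (the generator
still self-checks each one through RDKit).  Label rules are chosen so that the
information levels are separable by design:

- substructure rules (aromatic ring, nitro, ...) need only connectivity and
  elements;
- the sp3-fraction rule needs hybridization features (level >= 2);
- molecular-weight / rotatable-bond rules are global properties that level 5
  exposes directly;
- the rare-quantile rule thresholds a continuous descriptor at the
  (1 - p)-quantile of the generated set, giving a *learnable* rare label with
  prevalence ~= p (a pure-noise rare task is also available).

Deterministic label rules are evaluated first; seeded flip noise and optional
missingness are applied afterwards.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski

from .featurize import _parse_mol

# fragments that can seed a molecule (multi-atom, at least one open valence)
SCAFFOLDS = [
    "CC", "CCC", "CCCC", "CC(C)C", "C=CC", "CC#C",
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1",
    "C1CCCCC1", "C1CCCC1", "C1CCOCC1", "C1CCNCC1",
    "CC(=O)C", "CCO", "CCN",
]

# (smiles, attachment-atom index) — attached to the growing molecule by a
# single bond at the given atom
SUBSTITUENTS = [
    ("C", 0), ("CC", 0), ("CCC", 0), ("CC(C)C", 1), ("C=C", 0), ("C#C", 0),
    ("c1ccccc1", 0), ("c1ccncc1", 0), ("c1ccsc1", 0),
    ("C1CCCCC1", 0), ("C1CCCC1", 0),
    ("O", 0), ("OC", 0), ("N", 0), ("N(C)C", 0), ("S", 0), ("SC", 0),
    ("C(=O)O", 0), ("C(=O)N", 0), ("C(=O)C", 0), ("C#N", 0),
    ("F", 0), ("Cl", 0), ("Br", 0), ("I", 0),
    ("[N+](=O)[O-]", 0), ("C(F)(F)F", 0), ("S(=O)(=O)C", 0),
    ("CO", 0), ("CCO", 0),
]


def _open_sites(mol: Chem.Mol) -> list:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _attach(mol: Chem.Mol, frag_smiles: str, attach_idx: int,
            site: int) -> Optional[Chem.Mol]:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms() + attach_idx, Chem.BondType.SINGLE)
    RDLogger.DisableLog("rdApp.error")  # rejected valences are expected here
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None
    finally:
        RDLogger.EnableLog("rdApp.error")


def generate_molecules(n: int, seed: int, max_substituents: int = 4) -> list:
    """Generate ``n`` valid SMILES strings by seeded fragment assembly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        mol = Chem.MolFromSmiles(SCAFFOLDS[rng.integers(len(SCAFFOLDS))])
        n_sub = int(rng.integers(0, max_substituents + 1))
        for _ in range(n_sub):
            frag, attach_idx = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
            sites = _open_sites(mol)
            if not sites:
                break
            for _attempt in range(4):
                site = int(sites[rng.integers(len(sites))])
                grown = _attach(mol, frag, attach_idx, site)
                if grown is not None:
                    mol = grown
                    break
        smiles = Chem.MolToSmiles(mol)
        _parse_mol(smiles)  # self-check: every emitted string must parse
        out.append(smiles)
    return out


@dataclasses.dataclass
class TaskSpec:
    """One planted label rule.

    rules: ``substructure`` (SMARTS presence), ``aromatic_ring``,
    ``sp3_fraction`` (fraction of heavy atoms sp3 >= threshold),
    ``mol_weight`` (MolWt >= threshold; ``None`` = median of the set),
    ``rotatable`` (rotatable bonds >= threshold), ``rare_quantile``
    (descriptor > (1 - p)-quantile: learnable rare label of prevalence ~p;
    ``descriptor`` is ``molwt`` or ``tpsa``), ``random_rare`` (pure
    Bernoulli(p) noise label).
    """

    name: str
    rule: str
    noise: float = 0.0
    threshold: Optional[float] = None
    target_prevalence: Optional[float] = None
    smarts: Optional[str] = None
    descriptor: str = "molwt"
    missing_rate: float = 0.0

    _RULES = ("substructure", "aromatic_ring", "sp3_fraction", "mol_weight",
              "rotatable", "rare_quantile", "random_rare")

    def __post_init__(self) -> None:
        if self.rule not in self._RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {self._RULES}")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.rule in ("rare_quantile", "random_rare"):
            p = self.target_prevalence
            if p is None or not 0.0 < p < 1.0:
                raise ValueError(f"rule {self.rule} needs target_prevalence in (0,1)")
        if self.descriptor not in ("molwt", "tpsa"):
            raise ValueError(f"descriptor must be 'molwt' or 'tpsa', got {self.descriptor!r}")
        if self.rule == "substructure":
            if self.smarts is None or Chem.MolFromSmarts(self.smarts) is None:
                raise ValueError(f"rule 'substructure' needs a valid SMARTS, "
                                 f"got {self.smarts!r}")


def _sp3_fraction(mol: Chem.Mol) -> float:
    hyb = [a.GetHybridization() == Chem.HybridizationType.SP3 for a in mol.GetAtoms()]
    return float(np.mean(hyb))


def _base_labels(mols: Sequence[Chem.Mol], spec: TaskSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.rule == "substructure":
        patt = Chem.MolFromSmarts(spec.smarts)
        return np.array([float(m.HasSubstructMatch(patt)) for m in mols])
    if spec.rule == "aromatic_ring":
        return np.array([float(any(a.GetIsAromatic() for a in m.GetAtoms()))
                         for m in mols])
    if spec.rule == "sp3_fraction":
        thr = 0.5 if spec.threshold is None else spec.threshold
        return np.array([float(_sp3_fraction(m) >= thr) for m in mols])
    if spec.rule == "mol_weight":
        w = np.array([Descriptors.MolWt(m) for m in mols])
        thr = float(np.median(w)) if spec.threshold is None else spec.threshold
        return (w >= thr).astype(float)
    if spec.rule == "rotatable":
        r = np.array([Lipinski.NumRotatableBonds(m) for m in mols])
        thr = float(np.median(r)) if spec.threshold is None else spec.threshold
        return (r >= thr).astype(float)
    if spec.rule == "rare_quantile":
        fn = Descriptors.MolWt if spec.descriptor == "molwt" else Descriptors.TPSA
        w = np.array([fn(m) for m in mols])
        thr = np.quantile(w, 1.0 - spec.target_prevalence)
        return (w > thr).astype(float)
    if spec.rule == "random_rare":
        return (rng.random(len(mols)) < spec.target_prevalence).astype(float)
    raise AssertionError(spec.rule)


def assign_labels(smiles_list: Sequence[str], specs: Sequence[TaskSpec],
                  seed: int):
    """Evaluate each task rule, then apply seeded flip noise and missingness.
    Returns ``(labels, mask)`` of shape (n, c)."""
    if not specs:
        raise ValueError("specs must be non-empty")
    mols = [_parse_mol(s) for s in smiles_list]
    rng = np.random.default_rng(seed)
    n, c = len(mols), len(specs)
    labels = np.zeros((n, c))
    mask = np.ones((n, c))
    for j, spec in enumerate(specs):
        base = _base_labels(mols, spec, rng)
        if spec.noise > 0:
            flips = rng.random(n) < spec.noise
            base = np.where(flips, 1.0 - base, base)
        if spec.missing_rate > 0:
            missing = rng.random(n) < spec.missing_rate
            mask[missing, j] = 0.0
            base[missing] = 0.0
        labels[:, j] = base
    return labels, mask


def write_dataset_csv(smiles_list: Sequence[str], labels: np.ndarray,
                      mask: np.ndarray, task_names: Sequence[str], path) -> None:
    """Write the benchmark CSV format: header ``smiles,task1,...``; masked
    entries become empty cells.  Round-trips losslessly through the reader."""
    labels = np.asarray(labels, float)
    mask = np.asarray(mask, float)
    if not (len(smiles_list) == labels.shape[0] == mask.shape[0]):
        raise ValueError("smiles, labels and mask lengths disagree")
    if labels.shape[1] != len(task_names):
        raise ValueError("task_names length disagrees with label columns")
    data = {"smiles": list(smiles_list)}
    for j, name in enumerate(task_names):
        col = [("" if mask[i, j] == 0 else int(labels[i, j]))
               for i in range(len(smiles_list))]
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canned benchmark recipes


def default_benchmark(n: int = 600, seed: int = 0):
    """The standard 4-task synthetic benchmark: aromatic-ring, sp3-fraction
    and weight-threshold tasks at 5% flip noise, plus a learnable rare task
    (weight 98th percentile, prevalence ~2%, no noise).

    Returns ``(smiles, labels, mask, task_names, specs)``.
    """
    specs = [
        TaskSpec("aromatic", "aromatic_ring", noise=0.05),
        TaskSpec("sp3rich", "sp3_fraction", noise=0.05, threshold=0.5),
        TaskSpec("heavy", "mol_weight", noise=0.05),
        TaskSpec("rare_heavy", "rare_quantile", noise=0.0, target_prevalence=0.02),
    ]
    smiles = generate_molecules(n, seed)
    labels, mask = assign_labels(smiles, specs, seed + 1)
    return smiles, labels, mask, [s.name for s in specs], specs


def ladder_benchmark(n: int = 600, seed: int = 0):
    """Single weight-threshold task (median split, 2% flip noise) used to
    expose the information-level ladder: global features see the weight
    directly, element-only features must reconstruct it."""
    specs = [TaskSpec("heavy", "mol_weight", noise=0.02)]
    smiles = generate_molecules(n, seed)
    labels, mask = assign_labels(smiles, specs, seed + 1)
    return smiles, labels, mask, [s.name for s in specs], specs


def imbalance_benchmark(n: int = 2000, seed: int = 0):
    """Two common tasks plus a learnable rare task (prevalence ~2%) for the
    weighted-loss experiment.

    The rare label thresholds topological polar surface area at its 98th
    percentile: a distributed atomic signal rather than one of the level-5
    global inputs, and continuous enough for an accurate quantile.  The
    default size keeps a handful of rare positives in the 10% test split.
    """
    specs = [
        TaskSpec("aromatic", "aromatic_ring", noise=0.05),
        TaskSpec("sp3rich", "sp3_fraction", noise=0.05, threshold=0.5),
        TaskSpec("rare_polar", "rare_quantile", noise=0.0,
                 target_prevalence=0.02, descriptor="tpsa"),
    ]
    smiles = generate_molecules(n, seed)
    labels, mask = assign_labels(smiles, specs, seed + 1)
    return smiles, labels, mask, [s.name for s in specs], specs


RECIPES = {
    "default": default_benchmark,
    "ladder": ladder_benchmark,
    "imbalance": imbalance_benchmark,
}
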