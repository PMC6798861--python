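"""Dataset reading for benchmark-style CSV files.

Expected format: a header with one column named ``smiles``; every other
column is a binary task with values in {0, 1, empty}.  Empty cells mean the
label was not observed (mask 0).  Row order is preserved exactly as on disk —
the index-based split depends on it.  Unparseable SMILES rows are dropped
with a logged warning (or raise in strict mode).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import numpy as np
import pandas as pd

from .featurize import FeatureConfig, SmilesParseError, build_graph

logger = logging.getLogger("molgcn")


@dataclasses.dataclass
class Dataset:
    """An ordered, featurized dataset.

    ``records`` is the on-disk order of ``(smiles, labels, mask)`` triples
    that survived parsing; ``graphs`` are the corresponding featurized
    molecules.  ``fingerprint`` hashes the file content together with the
    featurization level, so runs can be tied to their exact inputs.
    """

    records: list
    graphs: list
    task_names: list
    path: str
    fingerprint: str
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.stack([r[1] for r in self.records])

    @property
    def mask(self) -> np.ndarray:
        return np.stack([r[2] for r in self.records])


def _coerce_label(value, row: int, col: str):
    """'' / NaN -> unobserved; otherwise must be 0 or 1."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0.0, 0.0
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return 0.0, 0.0
    try:
        f = float(s)
    except ValueError:
        raise ValueError(f"non-binary label {value!r} at row {row}, "
                         f"column {col!r}") from None
    if f not in (0.0, 1.0):
        raise ValueError(f"non-binary label {value!r} at row {row}, column {col!r}")
    return f, 1.0


def read_dataset_csv(path, config: FeatureConfig,
                     strict: bool = False) -> Dataset:
    """Read and featurize a benchmark CSV under ``config``.

    Raises if the ``smiles`` column is missing or a label is non-binary;
    unparseable SMILES rows are dropped with a warning unless ``strict``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: no 'smiles' column (found {list(df.columns)})")
    task_names = [c for c in df.columns if c != "smiles"]
    if not task_names:
        raise ValueError(f"{path}: no task columns besides 'smiles'")

    records, graphs = [], []
    n_dropped = 0
    smiles_col = df["smiles"].tolist()
    label_cols = [df[name].tolist() for name in task_names]
    for row_idx, smiles in enumerate(smiles_col):
        labels = np.zeros(len(task_names))
        mask = np.zeros(len(task_names))
        for j, name in enumerate(task_names):
            labels[j], mask[j] = _coerce_label(label_cols[j][row_idx], row_idx, name)
        try:
            graph = build_graph(smiles, config, labels=labels, mask=mask)
        except SmilesParseError:
            if strict:
                raise
            n_dropped += 1
            continue
        records.append((smiles, labels, mask))
        graphs.append(graph)
    if n_dropped:
        logger.warning("%s: dropped %d unparseable SMILES row(s)", path, n_dropped)

    hasher = hashlib.sha256()
    with open(path, "rb") as fh:
        hasher.update(fh.read())
    hasher.update(f"|level={config.level}".encode())
    return Dataset(records=records, graphs=graphs, task_names=task_names,
                   path=str(path), fingerprint=hasher.hexdigest(),
                   n_dropped=n_dropped)
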