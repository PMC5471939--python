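"""Reading, writing and merging labeled fingerprint datasets.

The canonical on-disk format is the PaDEL-Descriptor CSV dialect for
PubChem-type fingerprints: one identifier column followed by 881 binary
columns named ``PubchemFP0`` ... ``PubchemFP880``.  Labels travel in a
separate two-column CSV (``compound_id,label``).  Compound identity for
deduplication is string equality of canonicalized SMILES, delegated to
RDKit behind :func:`canonical_smiles`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three admissible compound labels.
LABELS = ("positive", "negative", "unlabeled")

#: Width of the PubChem-type substructure fingerprint.
DEFAULT_N_BITS = 881


@dataclass
class CompoundRecord:
    """A single compound: opaque identifier, optional structure key, label.

    Parameters
    ----------
    compound_id : str
        Non-empty identifier, unique within a dataset.
    label : str
        One of ``"positive"`` (hepatotoxicity concern), ``"negative"``
        (no concern) or ``"unlabeled"``.
    structure_key : str or None
        Canonical structure string (canonical SMILES).  Required only by
        structure-based deduplication.
    """

    compound_id: str
    label: str = "unlabeled"
    structure_key: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(
                f"label {self.label!r} for {self.compound_id!r} is not one of {LABELS}"
            )


@dataclass
class LabeledFingerprintDataset:
    """Ordered compound records plus their binary fingerprint matrix.

    ``X`` has one row per record and one column per fingerprint bit; every
    entry is 0 or 1.  Weighted (real-valued) feature matrices produced
    downstream are plain arrays, never stored here.
    """

    records: list[CompoundRecord]
    X: np.ndarray
    n_bits: int = DEFAULT_N_BITS

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[0] != len(self.records):
            raise ValueError(
                f"X has {X.shape[0]} rows but there are {len(self.records)} records"
            )
        if X.shape[1] != self.n_bits:
            raise ValueError(f"X has {X.shape[1]} columns, expected n_bits={self.n_bits}")
        if X.size and not np.isin(X, (0, 1)).all():
            bad = np.argwhere(~np.isin(X, (0, 1)))[0]
            raise ValueError(
                f"non-binary fingerprint value at row {bad[0]} (compound "
                f"{self.records[bad[0]].compound_id!r}), bit column {bad[1]}"
            )
        self.X = X.astype(np.uint8)
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound IDs: {dupes}")

    # -- convenience views -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def n_compounds(self) -> int:
        return len(self.records)

    def labeled_subset(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return ``(X, y, ids)`` for the labeled records only.

        ``y`` is 1 for positives and 0 for negatives; unlabeled records are
        dropped.
        """
        mask = self.labels != "unlabeled"
        y = (self.labels[mask] == "positive").astype(int)
        ids = [r.compound_id for r, m in zip(self.records, mask) if m]
        return self.X[mask], y, ids

    def subset(self, indices: Sequence[int]) -> "LabeledFingerprintDataset":
        idx = list(indices)
        return LabeledFingerprintDataset(
            records=[replace(self.records[i]) for i in idx],
            X=self.X[idx].copy(),
            n_bits=self.n_bits,
        )


# ---------------------------------------------------------------------------
# PaDEL-dialect fingerprint CSV
# ---------------------------------------------------------------------------

def read_padel_csv(path: str | Path, n_bits: int = DEFAULT_N_BITS) -> LabeledFingerprintDataset:
    """Read a PaDEL-Descriptor fingerprint CSV into an (unlabeled) dataset.

    The header must name one identifier column followed by exactly
    ``n_bits`` fingerprint columns; cell values may be ``0``/``1`` as
    integers or strings.  Any other value, a missing column, or a duplicate
    compound ID is a hard error naming the offending row or column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] != n_bits + 1:
        raise ValueError(
            f"{path}: expected 1 ID column + {n_bits} fingerprint columns, "
            f"found {df.shape[1]} columns"
        )
    id_col = df.columns[0]
    bit_cols = list(df.columns[1:])
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate compound IDs {dupes}")

    raw = df[bit_cols].to_numpy()
    X = np.zeros(raw.shape, dtype=np.uint8)
    valid = {"0": 0, "1": 1, "0.0": 0, "1.0": 1}
    for j, col in enumerate(bit_cols):
        for i, cell in enumerate(raw[:, j]):
            cell = str(cell).strip()
            if cell not in valid:
                raise ValueError(
                    f"{path}: non-binary value {cell!r} at row {i} "
                    f"(compound {ids[i]!r}), column {col!r}"
                )
            X[i, j] = valid[cell]
    records = [CompoundRecord(compound_id=c) for c in ids]
    return LabeledFingerprintDataset(records=records, X=X, n_bits=n_bits)


def write_padel_csv(ds: LabeledFingerprintDataset, path: str | Path) -> None:
    """Write the fingerprint matrix in the PaDEL CSV dialect (lossless)."""
    cols = [f"PubchemFP{j}" for j in range(ds.n_bits)]
    df = pd.DataFrame(ds.X.astype(int), columns=cols)
    df.insert(0, "Name", ds.ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def read_label_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``compound_id,label`` CSV into a mapping."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (compound_id,label)")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return _pairs_to_map(pairs)


def write_label_csv(ds: LabeledFingerprintDataset, path: str | Path) -> None:
    rows = [(r.compound_id, r.label) for r in ds.records if r.label != "unlabeled"]
    pd.DataFrame(rows, columns=["compound_id", "label"]).to_csv(path, index=False)


def _pairs_to_map(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for cid, label in pairs:
        if label not in ("positive", "negative"):
            raise ValueError(f"label {label!r} for {cid!r}: must be positive or negative")
        if cid in out and out[cid] != label:
            raise ValueError(f"conflicting labels assigned to {cid!r}: {out[cid]} vs {label}")
        out[cid] = label
    return out


def attach_labels(
    ds: LabeledFingerprintDataset,
    labels: Mapping[str, str] | Iterable[tuple[str, str]],
) -> LabeledFingerprintDataset:
    """Return a copy of ``ds`` with labels applied by compound ID.

    Compounds absent from ``labels`` remain unlabeled.  A key not present
    in the dataset, or the same ID assigned two different labels, is an
    error.
    """
    label_map = dict(labels) if isinstance(labels, Mapping) else _pairs_to_map(labels)
    known = set(ds.ids)
    missing = sorted(set(label_map) - known)
    if missing:
        raise KeyError(f"label keys not in dataset: {missing}")
    records = [
        replace(r, label=label_map.get(r.compound_id, r.label)) for r in ds.records
    ]
    return LabeledFingerprintDataset(records=records, X=ds.X.copy(), n_bits=ds.n_bits)


# ---------------------------------------------------------------------------
# SMILES
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES list: one structure per line, optional tab-separated ID.

    Returns ``(compound_id, smiles)`` pairs; lines without an explicit ID
    get a 1-based positional ID ``cmpd<i>``.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                out.append((parts[1].strip(), parts[0].strip()))
            else:
                out.append((f"cmpd{i}", parts[0]))
    return out


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string (RDKit canonical form).

    This is the single point where compound identity is defined: two
    compounds are duplicates iff their canonical SMILES are equal.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def assign_structure_keys(
    ds: LabeledFingerprintDataset,
    smiles: Mapping[str, str],
    canonicalize: bool = True,
) -> LabeledFingerprintDataset:
    """Attach structure keys (canonical SMILES) to records by compound ID."""
    records = []
    for r in ds.records:
        key = smiles.get(r.compound_id)
        if key is not None and canonicalize:
            key = canonical_smiles(key)
        records.append(replace(r, structure_key=key))
    return LabeledFingerprintDataset(records=records, X=ds.X.copy(), n_bits=ds.n_bits)


# ---------------------------------------------------------------------------
# Merging / deduplication
# ---------------------------------------------------------------------------

def merge_deduplicate(
    train: LabeledFingerprintDataset,
    other: LabeledFingerprintDataset,
) -> LabeledFingerprintDataset:
    """Clean an external set against a training set by structure identity.

    Removes from ``other`` (i) every record whose structure key occurs in
    ``train``, and (ii) every record whose structure key carries both a
    positive and a negative label within ``other`` (conservative handling
    of label contradictions: both sides are dropped).  All records of both
    datasets must carry a structure key.
    """
    for name, ds in (("train", train), ("other", other)):
        missing = [r.compound_id for r in ds.records if r.structure_key is None]
        if missing:
            raise ValueError(f"{name} records missing structure_key: {missing[:5]}...")

    train_keys = {r.structure_key for r in train.records}

    by_key_labels: dict[str, set[str]] = {}
    for r in other.records:
        if r.label != "unlabeled":
            by_key_labels.setdefault(r.structure_key, set()).add(r.label)
    conflicted = {k for k, ls in by_key_labels.items() if {"positive", "negative"} <= ls}

    keep = [
        i
        for i, r in enumerate(other.records)
        if r.structure_key not in train_keys and r.structure_key not in conflicted
    ]
    n_dropped = other.n_compounds - len(keep)
    if n_dropped:
        logger.info(
            "merge_deduplicate: dropped %d of %d records (%d train duplicates, "
            "%d label-conflicted keys)",
            n_dropped,
            other.n_compounds,
            sum(1 for r in other.records if r.structure_key in train_keys),
            len(conflicted),
        )
    return other.subset(keep)
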