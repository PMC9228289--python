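"""Molecule tables: reading, writing, and train/test partitioning.

A dataset is a flat table of molecules, each carrying six physicochemical /
topological descriptors (polarizability ``ae``, surface tension ``gamma``,
torsion energy ``te``, hydrogen-bond donor count ``hbd``, stretch energy
``se``, topological diameter ``td``), an observed activity on the decimal-log
scale (Log10 IC50), a train/test subset flag, and an outlier flag.  The
bundled GlyT1-inhibitor table (44 bicyclo((aryl)methyl)benzamides) ships as a
package fixture and is the reference dataset for the whole pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTOR_NAMES",
    "INTEGER_DESCRIPTORS",
    "MoleculeRecord",
    "QsarDataset",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "load_table",
    "write_table",
    "load_glyt1",
    "split",
    "kmeans_split",
]

#: Canonical descriptor order used everywhere downstream.
DESCRIPTOR_NAMES: tuple[str, ...] = ("ae", "gamma", "te", "hbd", "se", "td")

#: Descriptors that are counts and must be non-negative integers.
INTEGER_DESCRIPTORS: tuple[str, ...] = ("hbd", "td")

_REQUIRED_COLUMNS = ("id", *DESCRIPTOR_NAMES, "log10ic50", "subset")


class SchemaError(ValueError):
    """A required column is missing or a table layout is invalid."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class ValidationError(ValueError):
    """A table violates a dataset invariant (duplicate ids, bad flags...)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: id, named descriptors, observed activity and flags."""

    id: int
    descriptors: dict[str, float]
    activity: float
    subset: str = "train"
    outlier: bool = False

    def __post_init__(self) -> None:
        if tuple(self.descriptors) != DESCRIPTOR_NAMES:
            raise ValidationError(
                f"molecule {self.id}: descriptors must be exactly "
                f"{DESCRIPTOR_NAMES} in order, got {tuple(self.descriptors)}"
            )
        for name in INTEGER_DESCRIPTORS:
            v = self.descriptors[name]
            if v < 0 or v != int(v):
                raise ValidationError(
                    f"molecule {self.id}: {name}={v!r} must be a non-negative integer"
                )
        if not math.isfinite(self.activity):
            raise ValidationError(f"molecule {self.id}: non-finite activity")
        if self.subset not in ("train", "test"):
            raise ValidationError(
                f"molecule {self.id}: subset must be 'train' or 'test', got {self.subset!r}"
            )


@dataclass
class QsarDataset:
    """An ordered collection of molecule records sharing one descriptor set."""

    records: list[MoleculeRecord]
    descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate molecule id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.records]

    @property
    def X(self) -> pd.DataFrame:
        """Descriptor matrix (n × p) with molecule ids as the index."""
        return pd.DataFrame(
            [[r.descriptors[n] for n in self.descriptor_names] for r in self.records],
            index=pd.Index(self.ids, name="id"),
            columns=list(self.descriptor_names),
        )

    @property
    def y(self) -> pd.Series:
        """Observed Log10 IC50 activities, indexed by molecule id."""
        return pd.Series(
            [r.activity for r in self.records],
            index=pd.Index(self.ids, name="id"),
            name="log10ic50",
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.X.copy()
        frame["log10ic50"] = self.y
        frame["subset"] = [r.subset for r in self.records]
        frame["outlier"] = [int(r.outlier) for r in self.records]
        return frame.reset_index()

    def subset_dataset(self, flag: str) -> "QsarDataset":
        return QsarDataset(
            [r for r in self.records if r.subset == flag], self.descriptor_names
        )

    def to_json(self, path: str | Path) -> None:
        """Full-precision JSON export (lossless round trip)."""
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "records": [
                {
                    "id": r.id,
                    "descriptors": r.descriptors,
                    "activity": r.activity,
                    "subset": r.subset,
                    "outlier": r.outlier,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "QsarDataset":
        payload = json.loads(Path(path).read_text())
        records = [
            MoleculeRecord(
                id=int(r["id"]),
                descriptors={k: float(v) for k, v in r["descriptors"].items()},
                activity=float(r["activity"]),
                subset=r["subset"],
                outlier=bool(r["outlier"]),
            )
            for r in payload["records"]
        ]
        return cls(records, tuple(payload["descriptor_names"]))


def _parse_number(raw: object, row: object, column: str) -> float:
    """Parse a numeric cell, accepting Unicode minus and comma decimals."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    text = str(raw).strip().replace("−", "-").replace(",", ".")
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"row {row!r}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None


def load_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> QsarDataset:
    """Read a molecule table from CSV.

    Parameters
    ----------
    path
        CSV file with header ``id,ae,gamma,te,hbd,se,td,log10ic50,subset``
        (an ``outlier`` 0/1 column is optional).  A trailing ``*`` on an id
        marks a test-set molecule, as an alternative to the subset column.
    dialect
        Optional map from canonical column names to the names actually used
        in the file, e.g. ``{"ae": "polarizability"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (no header)") from None
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    raw.columns = [str(c).strip().lower() for c in raw.columns]

    for col in _REQUIRED_COLUMNS:
        if col == "subset" and col not in raw.columns:
            continue  # may be encoded by starred ids
        if col not in raw.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    records: list[MoleculeRecord] = []
    for _, row in raw.iterrows():
        id_text = str(row["id"]).strip()
        starred = id_text.endswith("*")
        if starred:
            id_text = id_text.rstrip("* ").strip()
        mol_id = int(_parse_number(id_text, row["id"], "id"))
        if "subset" in raw.columns:
            subset = str(row["subset"]).strip().lower()
        else:
            subset = "test" if starred else "train"
        outlier = False
        if "outlier" in raw.columns and not pd.isna(row["outlier"]):
            outlier = bool(int(_parse_number(row["outlier"], mol_id, "outlier")))
        descriptors = {
            name: _parse_number(row[name], mol_id, name) for name in DESCRIPTOR_NAMES
        }
        activity = _parse_number(row["log10ic50"], mol_id, "log10ic50")
        records.append(
            MoleculeRecord(mol_id, descriptors, activity, subset, outlier)
        )
    return QsarDataset(records)


def write_table(dataset: QsarDataset, path: str | Path) -> None:
    """Write a dataset in the same CSV dialect ``load_table`` reads.

    Numbers are written with :func:`repr` precision so a load→write→load
    round trip preserves every field exactly.
    """
    frame = dataset.to_frame()
    frame.to_csv(path, index=False)


def load_glyt1() -> QsarDataset:
    """The bundled 44-molecule GlyT1 inhibitor table.

    35 training molecules, 9 test molecules of which ids 1 and 32 are flagged
    outliers (confirmed independently by the leverage analysis in
    :mod:`qsarval.domain`).
    """
    with resources.as_file(
        resources.files("qsarval.data").joinpath("glyt1_table1.csv")
    ) as p:
        return load_table(p)


def split(
    dataset: QsarDataset, drop_outliers: bool = True
) -> tuple[QsarDataset, QsarDataset]:
    """Partition a dataset by its subset flags.

    With ``drop_outliers`` the records flagged as outliers are excluded from
    the returned test set (they belong to no partition).
    """
    train = dataset.subset_dataset("train")
    test = dataset.subset_dataset("test")
    if drop_outliers:
        test = QsarDataset(
            [r for r in test.records if not r.outlier], dataset.descriptor_names
        )
    if len(train) == 0:
        raise ValidationError("empty training partition")
    return train, test


def kmeans_split(
    dataset: QsarDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[QsarDataset, QsarDataset]:
    """Representative train/test split via k-means on standardized descriptors.

    The descriptor matrix is standardized, clustered into
    ``k = ceil(n * (1 - train_fraction))`` groups, and the record nearest each
    centroid becomes a test molecule; everything else trains.  Deterministic
    for a fixed seed.  This is a splitting utility: the bundled fixture uses
    its printed subset flags, not this procedure.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    from sklearn.cluster import KMeans

    n = len(dataset)
    k = math.ceil(n * (1.0 - train_fraction))
    if n < k or k < 1:
        raise ValidationError(f"cannot form {k} clusters from {n} records")
    X = dataset.X.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    test_idx: set[int] = set()
    for c in range(k):
        members = np.flatnonzero(km.labels_ == c)
        d = np.linalg.norm(Z[members] - km.cluster_centers_[c], axis=1)
        test_idx.add(int(members[int(np.argmin(d))]))
    train_records, test_records = [], []
    for i, rec in enumerate(dataset.records):
        flag = "test" if i in test_idx else "train"
        rec = MoleculeRecord(rec.id, rec.descriptors, rec.activity, flag, rec.outlier)
        (test_records if i in test_idx else train_records).append(rec)
    return (
        QsarDataset(train_records, dataset.descriptor_names),
        QsarDataset(test_records, dataset.descriptor_names),
    )
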