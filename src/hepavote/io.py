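"""Feature-table and label I/O.

Feature tables follow the PaDEL-Descriptor CSV dialect: a header row, a
first column holding the compound name/ID, and one column per fingerprint
bit / count / descriptor. Fingerprints are consumed precomputed — this
package never recomputes them from structures.

Compound alignment across tables is by ID intersection: compounds missing
from any block or from the label file are dropped (and the drop is logged),
mirroring how curated QSAR sets lose entries without a database identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("binary", "count", "continuous")

#: label vocabulary: hepatotoxicant (most-DILI) = 1, non-hepatotoxicant = 0
LABEL_TOKENS = {
    "1": 1,
    "0": 0,
    "most-DILI": 1,
    "no-DILI": 0,
}


@dataclass
class FeatureBlock:
    """One fingerprint or descriptor matrix with aligned compound IDs."""

    block_id: str
    kind: str
    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}; expected one of {KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.compound_ids):
            raise ValueError(
                f"block {self.block_id!r}: {n} rows but {len(self.compound_ids)} compound IDs"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"block {self.block_id!r}: {p} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError(f"block {self.block_id!r}: duplicate compound IDs")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"block {self.block_id!r}: duplicate feature names")
        if np.isnan(self.values).any():
            raise ValueError(f"block {self.block_id!r}: missing values are not supported")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError(f"binary block {self.block_id!r} contains non-binary value")
        if self.kind == "count":
            if (self.values < 0).any() or (self.values != np.round(self.values)).any():
                raise ValueError(
                    f"count block {self.block_id!r} contains negative or non-integer value"
                )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self, prefix: bool = False) -> pd.DataFrame:
        """Return the block as a DataFrame indexed by compound ID.

        With ``prefix=True`` columns are namespaced ``"<block_id>:<feature>"``
        so that blocks can be concatenated without collisions.
        """
        cols = (
            [f"{self.block_id}:{c}" for c in self.feature_names]
            if prefix
            else list(self.feature_names)
        )
        return pd.DataFrame(self.values, index=list(self.compound_ids), columns=cols)

    def subset(self, compound_ids: Sequence[str]) -> "FeatureBlock":
        """Restrict to the given compounds, in the given order."""
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        try:
            idx = [pos[c] for c in compound_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"compound {exc.args[0]!r} not in block {self.block_id!r}") from exc
        return FeatureBlock(
            block_id=self.block_id,
            kind=self.kind,
            compound_ids=list(compound_ids),
            feature_names=list(self.feature_names),
            values=self.values[idx],
        )


@dataclass
class LabeledDataset:
    """Aligned compound IDs, binary DILI labels and a keyed set of blocks."""

    compound_ids: list[str]
    labels: np.ndarray
    blocks: dict[str, FeatureBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.compound_ids),):
            raise ValueError("labels must be one {0,1} value per compound")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        for bid, block in self.blocks.items():
            if list(block.compound_ids) != list(self.compound_ids):
                raise ValueError(f"block {bid!r} is not aligned with the dataset compound order")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def matrix(self, block_ids: Iterable[str]) -> pd.DataFrame:
        """Column-wise concatenation of the named blocks (namespaced columns)."""
        frames = [self.blocks[b].to_frame(prefix=True) for b in block_ids]
        if not frames:
            raise ValueError("no blocks requested")
        return pd.concat(frames, axis=1)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        ids = [self.compound_ids[i] for i in indices]
        return LabeledDataset(
            compound_ids=ids,
            labels=self.labels[list(indices)],
            blocks={b: blk.subset(ids) for b, blk in self.blocks.items()},
        )


def read_feature_table(path: str | Path, block_id: str, kind: str) -> FeatureBlock:
    """Read one PaDEL-dialect CSV feature table into a validated block."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an ID column plus at least one feature column")
    ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in feature columns ({exc})") from exc
    return FeatureBlock(
        block_id=block_id,
        kind=kind,
        compound_ids=ids,
        feature_names=[str(c) for c in body.columns],
        values=values,
    )


def write_feature_table(block: FeatureBlock, path: str | Path) -> None:
    """Write a block back to the PaDEL CSV dialect (ID column named 'Name')."""
    df = block.to_frame()
    df.insert(0, "Name", list(block.compound_ids))
    fmt = "%.17g" if block.kind == "continuous" else "%d"
    df.to_csv(path, index=False, float_format=fmt)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column (id,label) CSV; labels are {0,1} or {no-DILI, most-DILI}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (id,label)")
    out: dict[str, int] = {}
    for cid, tok in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cid = str(cid)
        tok = str(tok).strip()
        if tok not in LABEL_TOKENS:
            raise ValueError(f"{path}: unknown label token {tok!r} for compound {cid!r}")
        if cid in out:
            raise ValueError(f"{path}: duplicate compound ID {cid!r}")
        out[cid] = LABEL_TOKENS[tok]
    return out


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"Name": list(labels.keys()), "label": [int(v) for v in labels.values()]}
    ).to_csv(path, index=False)


def extract_sdf_ids(path: str | Path, id_field: str = "PUBCHEM_COMPOUND_CID") -> list[str]:
    """Extract one compound ID per SDF record, in file order.

    The ID is taken from the named SDF data field when present (default:
    the PubChem CID field), otherwise from the molecule title line. This is
    a record-level text scan — no chemistry perception — so records whose
    connection tables are not parseable as molecules still yield their ID.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    if not text.strip():
        return []
    ids: list[str] = []
    records = text.split("$$$$")
    # trailing chunk after the last delimiter must be blank
    if records and records[-1].strip():
        raise ValueError(f"{path}: final SDF record is not terminated by '$$$$'")
    for rec in records[:-1]:
        lines = rec.lstrip("\n").split("\n")
        if not lines or not any(l.strip() for l in lines):
            raise ValueError(f"{path}: empty SDF record")
        title = lines[0].strip()
        field_value = None
        for i, line in enumerate(lines):
            if line.startswith(">") and f"<{id_field}>" in line:
                if i + 1 < len(lines):
                    field_value = lines[i + 1].strip()
                break
        ids.append(field_value if field_value else title)
    return ids


def assemble_dataset(
    blocks: Sequence[FeatureBlock], labels: Mapping[str, int]
) -> LabeledDataset:
    """Align blocks and labels on the intersection of compound IDs.

    Order follows the first block. Compounds absent from any block or from
    the labels are dropped with a log message; an empty intersection or a
    single surviving class is an error.
    """
    if not blocks:
        raise ValueError("at least one feature block is required")
    common = set(blocks[0].compound_ids) & set(labels)
    for blk in blocks[1:]:
        common &= set(blk.compound_ids)
    ordered = [c for c in blocks[0].compound_ids if c in common]
    if not ordered:
        raise ValueError("empty compound-ID intersection across blocks and labels")
    n_universe = len(set().union(*[set(b.compound_ids) for b in blocks], set(labels)))
    dropped = n_universe - len(ordered)
    if dropped:
        logger.info("assemble_dataset: dropped %d compounds not present everywhere", dropped)
    y = np.array([labels[c] for c in ordered], dtype=int)
    if y.min() == y.max():
        raise ValueError("single-class dataset after ID intersection")
    return LabeledDataset(
        compound_ids=ordered,
        labels=y,
        blocks={b.block_id: b.subset(ordered) for b in blocks},
    )
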