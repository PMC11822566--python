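"""Compound representation, fingerprints, and Tanimoto similarity.

Ligand-based virtual screening compares molecules through fixed-width binary
substructure fingerprints.  The Tanimoto index between two fingerprints is the
set-overlap ratio |A ∩ B| / |A ∪ B|: 1 means identical bit sets, 0 means no
shared substructure keys.  Everything downstream (decoy selection, classifier
features) operates on these bit vectors, so a precomputed feature-table path
is provided alongside SMILES parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "Compound",
    "SmilesParseError",
    "compute_fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "read_smiles_file",
    "read_compound_csv",
    "write_fingerprint_csv",
    "read_fingerprint_csv",
    "fingerprint_matrix",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, record_id: str | None = None):
        self.smiles = smiles
        self.record_id = record_id
        where = f" (record {record_id!r})" if record_id else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width binary substructure fingerprint.

    Bits are stored as a uint8 numpy array of 0/1.  Width must be positive;
    popcount is therefore bounded by the width.
    """

    bits: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("fingerprint must be a nonempty 1-D bit vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    @property
    def width(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @classmethod
    def from_on_bits(cls, on_bits: Iterable[int], width: int) -> "Fingerprint":
        bits = np.zeros(width, dtype=np.uint8)
        idx = np.fromiter(on_bits, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= width):
            raise ValueError("on-bit index out of range")
        bits[idx] = 1
        return cls(bits)

    def __eq__(self, other) -> bool:  # dataclass eq on arrays is ambiguous
        return isinstance(other, Fingerprint) and np.array_equal(self.bits, other.bits)

    def __hash__(self):
        return hash(self.bits.tobytes())


@dataclass
class Compound:
    """A compound with an identifier, structure and optional annotations.

    ``ob`` is oral bioavailability in percent (0–100); ``dl`` is a unitless
    drug-likeness score in [0, 1].  Both are read as annotations, never
    computed.  ``label`` is one of ``active`` / ``inactive`` / ``unknown``.
    """

    id: str
    smiles: str | None = None
    fingerprint: Fingerprint | None = None
    ob: float | None = None
    dl: float | None = None
    label: str = "unknown"
    score: float | None = field(default=None, compare=False)

    def featurize(self, width: int = 2048) -> Fingerprint:
        """Return the fingerprint, computing it from SMILES if needed."""
        if self.fingerprint is None:
            if self.smiles is None:
                raise ValueError(f"compound {self.id!r} has neither SMILES nor fingerprint")
            self.fingerprint = compute_fingerprint(self.smiles, width, record_id=self.id)
        return self.fingerprint


def compute_fingerprint(smiles: str, width: int = 2048, *, radius: int = 2,
                        record_id: str | None = None) -> Fingerprint:
    """Hashed circular (Morgan) substructure fingerprint of a SMILES string.

    Deterministic: identical SMILES always yield bitwise-identical vectors.
    Raises :class:`SmilesParseError` naming the offending record on invalid
    input.
    """
    if width <= 0:
        raise ValueError("fingerprint width must be positive")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, record_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    fp = gen.GetFingerprintAsNumPy(mol)
    return Fingerprint(np.asarray(fp, dtype=np.uint8))


def tanimoto(a: Fingerprint, b: Fingerprint, *, empty_value: float = 1.0) -> float:
    """Tanimoto index |a ∩ b| / |a ∪ b| between two equal-width fingerprints.

    Two all-zero fingerprints are identical objects, so the 0/0 case returns
    ``empty_value`` (1 by default; configurable).
    """
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return float(empty_value)
    return inter / union


def fingerprint_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into an (n, width) uint8 matrix; widths must agree."""
    if not fps:
        raise ValueError("empty fingerprint collection")
    widths = {fp.width for fp in fps}
    if len(widths) != 1:
        raise ValueError(f"inconsistent fingerprint widths: {sorted(widths)}")
    return np.stack([fp.bits for fp in fps])


def tanimoto_matrix(a: Sequence[Fingerprint], b: Sequence[Fingerprint],
                    *, empty_value: float = 1.0) -> np.ndarray:
    """All-pairs Tanimoto matrix, shape (len(a), len(b))."""
    A = fingerprint_matrix(a).astype(np.float64)
    B = fingerprint_matrix(b).astype(np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint width mismatch between collections")
    inter = A @ B.T
    union = A.sum(1)[:, None] + B.sum(1)[None, :] - inter
    out = np.full_like(inter, float(empty_value))
    np.divide(inter, union, out=out, where=union > 0)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_smiles_file(path, width: int | None = None) -> list[Compound]:
    """Read a .smi file: one record per line, ``SMILES<tab>id``.

    Fingerprints are computed eagerly when ``width`` is given.
    """
    compounds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{lineno}"
            c = Compound(id=cid, smiles=smiles)
            if width is not None:
                c.featurize(width)
            compounds.append(c)
    return compounds


def read_compound_csv(path) -> list[Compound]:
    """Read compounds from a CSV with header ``id,smiles[,ob,dl,label]``.

    Alternatively, bit columns ``bit0..bitN`` may replace ``smiles`` so the
    pipeline runs without a chemistry toolkit (precomputed feature tables).
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    bit_cols = [c for c in df.columns if c.startswith("bit")]
    compounds = []
    for _, row in df.iterrows():
        fp = None
        if bit_cols:
            fp = Fingerprint(row[bit_cols].to_numpy(dtype=np.uint8))
        compounds.append(Compound(
            id=str(row["id"]),
            smiles=row.get("smiles") if isinstance(row.get("smiles"), str) else None,
            fingerprint=fp,
            ob=float(row["ob"]) if "ob" in df.columns and pd.notna(row["ob"]) else None,
            dl=float(row["dl"]) if "dl" in df.columns and pd.notna(row["dl"]) else None,
            label=str(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else "unknown",
        ))
    return compounds


def write_fingerprint_csv(compounds: Sequence[Compound], path, *, width: int = 2048) -> None:
    """Cache a fingerprint matrix as CSV: id column + bit0..bitN columns."""
    mat = fingerprint_matrix([c.featurize(width) for c in compounds])
    df = pd.DataFrame(mat, columns=[f"bit{i}" for i in range(mat.shape[1])])
    df.insert(0, "id", [c.id for c in compounds])
    extra = {}
    if all(c.ob is not None for c in compounds):
        extra["ob"] = [c.ob for c in compounds]
    if all(c.dl is not None for c in compounds):
        extra["dl"] = [c.dl for c in compounds]
    for k, v in extra.items():
        df[k] = v
    df.to_csv(path, index=False)


def read_fingerprint_csv(path) -> list[Compound]:
    """Inverse of :func:`write_fingerprint_csv`."""
    return read_compound_csv(path)
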