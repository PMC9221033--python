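"""Sequence/PSSM/label I/O and per-residue featurization.

A protein is represented by a :class:`ProteinRecord` (sequence, 21-column
PSSM, optional 8-state secondary-structure label string). The model input is
an n x 42 matrix per protein: a 21-wide one-hot block over the amino-acid
alphabet (20 standard residues plus 'X' for unknown) concatenated with the 21
PSSM columns, optionally squashed through a logistic.

File dialects:

* FASTA for sequences and (in a parallel file sharing record ids) 8-state
  label strings;
* PSSM as whitespace-delimited text, one row per residue, exactly 21 numeric
  columns, '#' comment lines ignored;
* datasets as JSON Lines, one object per protein with keys ``id``,
  ``sequence``, ``pssm`` and optionally ``labels``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Canonical amino-acid order, frozen for reproducibility; 'X' (unknown) last.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)  # l = 21

# Ambiguous/rare residue codes folded into 'X'.
_NONSTANDARD = set("BZUOJ")


class SSAlphabet:
    """The eight DSSP states: 3_10 helix (G), alpha helix (H), pi helix (I),
    beta strand (E), beta bridge (B), beta turn (T), high-curvature loop (S),
    other/coil (L). Class indices 0..7 follow this order."""

    labels = "GHIEBTSL"
    index_of = {c: i for i, c in enumerate(labels)}

    @classmethod
    def to_indices(cls, labels: str) -> np.ndarray:
        try:
            return np.array([cls.index_of[c] for c in labels], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"label character {e.args[0]!r} outside the 8-state alphabet") from None

    @classmethod
    def to_string(cls, indices: Iterable[int]) -> str:
        return "".join(cls.labels[int(i)] for i in indices)


SS_ALPHABET = SSAlphabet()


def clean_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard residue codes (B, Z, U, O, J) to 'X'."""
    seq = seq.upper()
    if any(c in _NONSTANDARD for c in seq):
        bad = sorted({c for c in seq if c in _NONSTANDARD})
        logger.warning("record %s: mapping non-standard residue(s) %s to 'X'", record_id, bad)
        seq = "".join("X" if c in _NONSTANDARD else c for c in seq)
    return seq


@dataclasses.dataclass
class ProteinRecord:
    """One protein: id, sequence, n x 21 PSSM, optional 8-state label string."""

    id: str
    sequence: str
    pssm: np.ndarray
    labels: str | None = None

    def __post_init__(self) -> None:
        for pos, c in enumerate(self.sequence):
            if c not in AA_INDEX:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {c!r} at position {pos}"
                )
        self.pssm = np.asarray(self.pssm, dtype=np.float64)
        n = len(self.sequence)
        if self.pssm.shape != (n, N_AA):
            raise ValueError(
                f"record {self.id!r}: pssm shape {self.pssm.shape} does not match "
                f"sequence length {n} x {N_AA}"
            )
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError(
                    f"record {self.id!r}: labels length {len(self.labels)} != sequence length {n}"
                )
            SSAlphabet.to_indices(self.labels)  # validates alphabet

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def label_indices(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"record {self.id!r} carries no labels")
        return SSAlphabet.to_indices(self.labels)


def one_hot_encode(sequence: str) -> np.ndarray:
    """n x 21 one-hot matrix; 'X' maps to the last (unknown-residue) column."""
    out = np.zeros((len(sequence), N_AA))
    for i, c in enumerate(sequence):
        try:
            out[i, AA_INDEX[c]] = 1.0
        except KeyError:
            raise ValueError(f"invalid residue {c!r} at position {i}") from None
    return out


def build_features(record: ProteinRecord, pssm_transform: str = "raw") -> np.ndarray:
    """n x 42 input features: [one-hot | PSSM], PSSM raw or logistic-squashed."""
    if record.pssm.shape[0] != len(record.sequence):
        raise ValueError("pssm row count does not match sequence length")
    if pssm_transform == "raw":
        p = record.pssm
    elif pssm_transform == "logistic":
        p = 1.0 / (1.0 + np.exp(-record.pssm))
    else:
        raise ValueError(f"unknown pssm_transform {pssm_transform!r}")
    return np.concatenate([one_hot_encode(record.sequence), p], axis=1)


# ----------------------------------------------------------------- file I/O

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Order-preserving (id, sequence) pairs; sequences uppercased."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rid, seq in records:
        if not seq:
            raise ValueError(f"{path}: record {rid!r} has an empty sequence")
    return records


def read_pssm(path: str | Path) -> np.ndarray:
    """n x 21 matrix from whitespace-delimited text; '#' lines are comments."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != N_AA:
                raise ValueError(
                    f"{path}:{lineno}: expected {N_AA} columns, found {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric PSSM entry") from None
    return np.array(rows, dtype=np.float64).reshape(len(rows), N_AA)


def read_dataset(path: str | Path) -> list[ProteinRecord]:
    """Read a JSON-Lines dataset; empty file yields an empty list."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({e})") from None
            records.append(
                ProteinRecord(
                    id=obj["id"],
                    sequence=obj["sequence"],
                    pssm=np.array(obj["pssm"], dtype=np.float64).reshape(-1, N_AA),
                    labels=obj.get("labels"),
                )
            )
    return records


def write_dataset(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write JSON Lines; floats use shortest round-trip repr (lossless)."""
    with open(path, "w") as fh:
        for r in records:
            obj = {"id": r.id, "sequence": r.sequence, "pssm": r.pssm.tolist()}
            if r.labels is not None:
                obj["labels"] = r.labels
            fh.write(json.dumps(obj) + "\n")


def load_records_from_files(
    fasta: str | Path,
    pssm_dir: str | Path,
    labels_fasta: str | Path | None = None,
) -> list[ProteinRecord]:
    """Assemble records from a FASTA, a directory of <id>.pssm files, and an
    optional parallel label FASTA keyed by the same record ids."""
    label_map: dict[str, str] = {}
    if labels_fasta is not None:
        label_map = dict(read_fasta(labels_fasta))
    pssm_dir = Path(pssm_dir)
    out = []
    for rid, seq in read_fasta(fasta):
        seq = clean_sequence(seq, rid)
        pssm_path = pssm_dir / f"{rid}.pssm"
        if not pssm_path.exists():
            raise FileNotFoundError(f"no PSSM file for record {rid!r}: {pssm_path}")
        out.append(
            ProteinRecord(id=rid, sequence=seq, pssm=read_pssm(pssm_path),
                          labels=label_map.get(rid))
        )
    return out
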