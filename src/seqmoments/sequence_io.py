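"""Reading, validating, encoding, and synthesizing labeled DNA sequences.

Sequences are plain A/C/G/T strings with an identifier.  Input FASTA may
contain lowercase characters and IUPAC ambiguity codes; three policies
control what happens to non-ACGT characters:

``strict``
    any non-ACGT character aborts the read with the offending record id.
``strip``
    non-ACGT characters are removed (a count is kept per record).
``fail-record``
    offending records are skipped and reported; valid records are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"

#: Default base -> integer encoding.  Alphabetical, and deliberately nonzero
#: so that every sequence position carries mass into the moment sums.
DEFAULT_MAPPING: dict[str, int] = {"A": 1, "C": 2, "G": 3, "T": 4}

MIN_LENGTH = 4  # a 2x2 grid is the smallest supported reshape

POLICIES = ("strict", "strip", "fail-record")


class SequenceError(ValueError):
    """Raised on invalid sequence content or malformed input files."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over the alphabet {A, C, G, T}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < MIN_LENGTH:
            raise SequenceError(
                f"sequence {self.id!r} has length {len(self.bases)} < {MIN_LENGTH}"
            )
        invalid = set(self.bases) - set(ALPHABET)
        if invalid:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters {sorted(invalid)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse(self) -> "NucleotideSequence":
        return NucleotideSequence(id=self.id, bases=self.bases[::-1])


@dataclass(frozen=True)
class EncodedSequence:
    """Integer encoding of a sequence under an injective base->int mapping."""

    values: np.ndarray
    mapping: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LabeledDataset:
    """Parallel sequences and binary labels (1 = driver, 0 = passenger)."""

    samples: list[NucleotideSequence]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.samples) != len(self.labels):
            raise SequenceError(
                f"{len(self.samples)} samples but {len(self.labels)} labels"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise SequenceError(f"labels must be 0/1, got extra values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.samples)

    def require_both_classes(self) -> None:
        if not (np.any(self.labels == 0) and np.any(self.labels == 1)):
            raise SequenceError("dataset must contain both classes")


@dataclass
class ReadReport:
    """Bookkeeping from one FASTA read: stripped characters and skips."""

    n_records: int = 0
    stripped: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def validate_mapping(mapping: Mapping[str, int]) -> dict[str, int]:
    missing = set(ALPHABET) - set(mapping)
    if missing:
        raise SequenceError(f"mapping is missing bases {sorted(missing)}")
    values = [mapping[b] for b in ALPHABET]
    if len(set(values)) != 4:
        raise SequenceError("mapping must be injective over A,C,G,T")
    if any(v == 0 for v in values):
        raise SequenceError("mapping values must be nonzero")
    return {b: int(mapping[b]) for b in ALPHABET}


def read_fasta(
    path: str | Path,
    policy: str = "strict",
    report: ReadReport | None = None,
) -> list[NucleotideSequence]:
    """Read a FASTA file into validated sequences.

    Records are uppercased before validation.  See the module docstring for
    the three ambiguity policies.  Raises :class:`SequenceError` on a missing
    or empty file, on any bad character under ``strict``, and on records that
    fall below the minimum length after stripping.
    """
    if policy not in POLICIES:
        raise SequenceError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    if report is None:
        report = ReadReport()

    sequences: list[NucleotideSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        bases = str(record.seq).upper()
        invalid = [c for c in bases if c not in ALPHABET]
        if invalid:
            if policy == "strict":
                raise SequenceError(
                    f"record {record.id!r} in {path} contains "
                    f"{len(invalid)} non-ACGT character(s), e.g. {invalid[0]!r}"
                )
            if policy == "fail-record":
                report.skipped[record.id] = f"{len(invalid)} non-ACGT character(s)"
                logger.warning("skipping record %s: %d non-ACGT", record.id, len(invalid))
                continue
            # strip
            bases = "".join(c for c in bases if c in ALPHABET)
            report.stripped[record.id] = len(invalid)
            logger.info("stripped %d character(s) from record %s", len(invalid), record.id)
        if len(bases) < MIN_LENGTH:
            raise SequenceError(
                f"record {record.id!r} has only {len(bases)} valid base(s) "
                f"(minimum {MIN_LENGTH})"
            )
        sequences.append(NucleotideSequence(id=record.id, bases=bases))
        report.n_records += 1
    if not sequences and not report.skipped:
        raise SequenceError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(
    sequences: Iterable[NucleotideSequence], path: str | Path, width: int = 70
) -> None:
    """Write sequences to FASTA with fixed line wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table with labels in {0, 1}."""
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"label table not found: {path}")
    labels: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceError(f"{path}:{lineno}: expected 'id<TAB>label'")
            seq_id, raw = parts
            if raw not in ("0", "1"):
                raise SequenceError(f"{path}:{lineno}: label must be 0 or 1, got {raw!r}")
            labels[seq_id] = int(raw)
    if not labels:
        raise SequenceError(f"label table {path} is empty")
    return labels


def load_dataset(
    pos_fasta: str | Path | None = None,
    neg_fasta: str | Path | None = None,
    fasta: str | Path | None = None,
    label_table: str | Path | None = None,
    policy: str = "strict",
) -> LabeledDataset:
    """Build a labeled dataset from either two FASTA files or FASTA + labels."""
    if pos_fasta is not None and neg_fasta is not None:
        pos = read_fasta(pos_fasta, policy=policy)
        neg = read_fasta(neg_fasta, policy=policy)
        labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
        return LabeledDataset(samples=pos + neg, labels=labels)
    if fasta is not None and label_table is not None:
        seqs = read_fasta(fasta, policy=policy)
        table = read_label_table(label_table)
        missing = [s.id for s in seqs if s.id not in table]
        if missing:
            raise SequenceError(f"no label for record(s): {missing[:5]}")
        labels = np.array([table[s.id] for s in seqs], dtype=int)
        return LabeledDataset(samples=seqs, labels=labels)
    raise SequenceError(
        "provide either (pos_fasta, neg_fasta) or (fasta, label_table)"
    )


def encode(
    seq: NucleotideSequence, mapping: Mapping[str, int] | None = None
) -> EncodedSequence:
    """Substitute each base by its integer code, order preserved."""
    table = validate_mapping(mapping or DEFAULT_MAPPING)
    lut = np.zeros(128, dtype=np.int64)
    for base, value in table.items():
        lut[ord(base)] = value
    values = lut[np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)]
    return EncodedSequence(values=values, mapping=table)


#: Fixed 6-mer motif planted in positive-class synthetic sequences.
MOTIF = "GGCGGC"


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    length: int = 300,
    separation: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Generate a labeled synthetic dataset with tunable class separation.

    Positives are drawn from a base distribution shifted toward G/C by
    ``separation`` and carry a planted 6-mer motif at a random position with
    probability ``separation``; negatives are shifted toward A/T by the same
    amount.  ``separation=0`` gives two indistinguishable uniform classes;
    ``separation=1`` gives strongly separable classes.  Identical seeds give
    identical datasets.
    """
    if n_pos < 1 or n_neg < 1:
        raise SequenceError("n_pos and n_neg must be >= 1")
    if length < 20:
        raise SequenceError("length must be >= 20")
    if not 0.0 <= separation <= 1.0:
        raise SequenceError(f"separation must be in [0, 1], got {separation}")

    rng = np.random.default_rng(seed)
    # shift up to 0.15 of probability mass from each A/T base onto G/C
    shift = 0.15 * separation
    p_pos = np.array([0.25 - shift, 0.25 + shift, 0.25 + shift, 0.25 - shift])
    p_neg = np.array([0.25 + shift, 0.25 - shift, 0.25 - shift, 0.25 + shift])
    bases = np.array(list(ALPHABET))

    samples: list[NucleotideSequence] = []
    for i in range(n_pos):
        chars = rng.choice(bases, size=length, p=p_pos)
        if rng.random() < separation:
            start = rng.integers(0, length - len(MOTIF) + 1)
            chars[start : start + len(MOTIF)] = list(MOTIF)
        samples.append(NucleotideSequence(id=f"pos_{i}", bases="".join(chars)))
    for i in range(n_neg):
        chars = rng.choice(bases, size=length, p=p_neg)
        samples.append(NucleotideSequence(id=f"neg_{i}", bases="".join(chars)))

    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return LabeledDataset(samples=samples, labels=labels)
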