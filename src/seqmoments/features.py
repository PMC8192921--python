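"""Assembly of the fixed 102-slot feature vector and the design matrix.

Layout (in order):

* 3 source matrices — the sequence grid, PRIM, RPRIM — each summarized by
  raw, central, and Hahn moments at the ten fixed order pairs: 90 slots;
* frequency vector (4), forward position sums (4), reverse position
  sums (4): 12 slots.

The grid's Hahn basis uses the sequence's own side ``k``; PRIM/RPRIM use
the fixed 4x4 basis.  The length is 102 for every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import incidence, moments
from .sequence_io import (
    DEFAULT_MAPPING,
    ALPHABET,
    LabeledDataset,
    NucleotideSequence,
    encode,
    validate_mapping,
)

N_FEATURES = 102


@dataclass(frozen=True)
class FeaturizeConfig:
    """Everything that parameterizes the sequence -> vector map."""

    mapping: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MAPPING))
    prim_convention: str = "signed"
    hahn_a: float = 0.0
    hahn_b: float = 0.0

    def __post_init__(self) -> None:
        validate_mapping(self.mapping)
        if self.prim_convention not in incidence.PRIM_CONVENTIONS:
            raise ValueError(f"unknown PRIM convention {self.prim_convention!r}")


def feature_names() -> list[str]:
    """The 102 slot names, in serialization order."""
    names: list[str] = []
    for source in ("grid", "prim", "rprim"):
        for family in moments.FAMILIES:
            for a, b in moments.ORDER_PAIRS:
                names.append(f"{source}_{family}_m{a}{b}")
    for prefix in ("fv", "aapiv", "raapiv"):
        for base in ALPHABET:
            names.append(f"{prefix}_{base}")
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
assert len(FEATURE_NAMES) == N_FEATURES


def _moment_block(matrix, basis: moments.HahnBasis) -> np.ndarray:
    raw = moments.raw_moments(matrix)
    _, central = moments.central_moments(matrix)
    hahn = moments.hahn_moments(matrix, basis)
    return np.concatenate(
        [raw.coefficients, central.coefficients, hahn.coefficients]
    )


def featurize(
    seq: NucleotideSequence, config: FeaturizeConfig | None = None
) -> np.ndarray:
    """Map one sequence to its deterministic 102-slot feature vector."""
    config = config or FeaturizeConfig()
    grid = moments.reshape_to_grid(encode(seq, config.mapping))
    grid_basis = moments.build_hahn_basis(grid.side, config.hahn_a, config.hahn_b)
    pair_basis = moments.build_hahn_basis(4, config.hahn_a, config.hahn_b)

    p = incidence.prim(seq, convention=config.prim_convention)
    rp = incidence.rprim(seq, convention=config.prim_convention)

    vector = np.concatenate(
        [
            _moment_block(grid, grid_basis),
            _moment_block(p.entries, pair_basis),
            _moment_block(rp.entries, pair_basis),
            incidence.frequency_vector(seq).counts.astype(float),
            incidence.aapiv(seq).sums.astype(float),
            incidence.raapiv(seq).sums.astype(float),
        ]
    )
    if vector.shape != (N_FEATURES,):
        raise AssertionError(f"feature vector has shape {vector.shape}")
    if not np.all(np.isfinite(vector)):
        raise ValueError(f"non-finite feature for sequence {seq.id!r}")
    return vector


@dataclass
class FeatureMatrix:
    """Per-sample feature rows with parallel ids and binary labels."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.y), len(self.names)):
            raise ValueError(
                f"X has shape {self.X.shape}, expected "
                f"({len(self.y)}, {len(self.names)})"
            )
        if len(self.ids) != len(self.y):
            raise ValueError("ids and labels must be parallel")

    def __len__(self) -> int:
        return len(self.y)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.X, columns=list(self.names))
        frame.insert(0, "id", self.ids)
        frame.insert(1, "label", self.y)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        if "id" not in frame.columns or "label" not in frame.columns:
            raise ValueError(f"{path} is not a feature matrix CSV (id/label missing)")
        names = tuple(c for c in frame.columns if c not in ("id", "label"))
        return cls(
            X=frame[list(names)].to_numpy(dtype=float),
            y=frame["label"].to_numpy(dtype=int),
            ids=[str(v) for v in frame["id"]],
            names=names,
        )


def build_feature_matrix(
    data: LabeledDataset, config: FeaturizeConfig | None = None
) -> FeatureMatrix:
    """Featurize every sample, preserving dataset order and labels."""
    if len(data) == 0:
        raise ValueError("cannot featurize an empty dataset")
    config = config or FeaturizeConfig()
    rows = []
    for sample in data.samples:
        try:
            rows.append(featurize(sample, config))
        except Exception as exc:  # noqa: BLE001 - re-raise with the sample id
            raise ValueError(f"featurization failed for sample {sample.id!r}: {exc}") from exc
    return FeatureMatrix(
        X=np.vstack(rows), y=data.labels, ids=[s.id for s in data.samples]
    )
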