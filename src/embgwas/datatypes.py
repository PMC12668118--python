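"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "FeatureMatrix", "EmbeddingMatrix"]


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages plus variant metadata.

    ``dosages`` is an ``n_samples x n_variants`` float array with entries in
    ``[0, 2]``; missing genotypes are ``NaN``.  ``variants`` carries one row
    per variant with columns ``chrom, pos, id, ref, alt``.
    """

    sample_ids: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but "
                f"{self.dosages.shape[0]} dosage rows"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but "
                f"{self.dosages.shape[1]} dosage columns"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, ignoring missing entries."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class FeatureMatrix:
    """Per-image (or per-participant) raw feature vectors.

    ``participants`` maps each row to its participant id; for
    participant-level matrices it simply repeats ``sample_ids``.
    """

    sample_ids: list[str]
    values: np.ndarray
    participants: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids / values row mismatch")
        if self.participants is not None and len(self.participants) != len(
            self.sample_ids
        ):
            raise ValueError("participants / values row mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class EmbeddingMatrix:
    """Per-participant processed embeddings used as the GWAS phenotype."""

    sample_ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids / values row mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]
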