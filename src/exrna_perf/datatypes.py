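"""Core data containers for biofluid total-RNA-seq performance assessment.

The substrate of every statistic in this package is a gene-by-sample integer
count matrix whose features carry a small controlled annotation: whether the
feature is an endogenous gene or a member of one of the two synthetic spike-in
panels (ERCC, 92 RNAs, added before library prep; Sequin, 78 RNAs, added at
RNA isolation), its biotype, its chromosomal origin (nuclear / mitochondrial /
ribosomal), and a gene-body region class. Sample-level metadata records the
biofluid, the replicate structure, the original input volume and the spike
dilution factors — the quantities needed to turn read ratios into relative
RNA concentrations per millilitre of biofluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("endogenous", "spike_ercc", "spike_sequin")
BIOTYPES = ("protein_coding", "lncRNA", "miscRNA", "pseudogene", "other", "spike")
CHROM_CLASSES = ("nuclear", "mitochondrial", "rRNA", "spike")
REGION_CLASSES = ("exonic", "intronic", "intergenic", "not_applicable")

SPIKE_CLASSES = ("spike_ercc", "spike_sequin")

#: annotation table columns, in canonical order
ANNOTATION_COLUMNS = ("feature_class", "biotype", "chrom_class", "region_class")


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a feature annotation table.

    Parameters
    ----------
    annotation
        DataFrame indexed by ``feature_id`` with columns ``feature_class``,
        ``biotype``, ``chrom_class`` and ``region_class``.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if not annotation.index.is_unique:
        dup = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in annotation: {dup[:5]}")
    for col, allowed in (
        ("feature_class", FEATURE_CLASSES),
        ("biotype", BIOTYPES),
        ("chrom_class", CHROM_CLASSES),
        ("region_class", REGION_CLASSES),
    ):
        bad = set(annotation[col].unique()) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} values: {sorted(bad)}")
    spikes = annotation["feature_class"].isin(SPIKE_CLASSES)
    if not (annotation.loc[spikes, "biotype"] == "spike").all():
        raise ValidationError("spike features must carry biotype 'spike'")
    if not (annotation.loc[spikes, "chrom_class"] == "spike").all():
        raise ValidationError("spike features must carry chrom_class 'spike'")
    return annotation[list(ANNOTATION_COLUMNS)]


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with per-feature annotation.

    ``counts`` is a DataFrame (index: feature_id, columns: sample ids) of
    non-negative integers. ``annotation`` is indexed by the same feature ids.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = validate_annotation(self.annotation)
        counts = self.counts
        if not counts.index.is_unique:
            raise ValidationError("duplicate feature ids in count table")
        if not counts.columns.is_unique:
            raise ValidationError("duplicate sample ids in count table")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                raise ValidationError("non-integer count encountered")
            counts = counts.astype(np.int64)
        if counts.size and (counts.to_numpy() < 0).any():
            raise ValidationError("negative count encountered")
        unknown = counts.index.difference(self.annotation.index)
        if len(unknown):
            raise ValidationError(
                f"features absent from annotation: {unknown.tolist()[:5]}"
            )
        # keep only the annotation rows actually present, in count-table order
        self.annotation = self.annotation.loc[counts.index]
        self.counts = counts.astype(np.int64)

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column(self, sample: str) -> pd.Series:
        if sample not in self.counts.columns:
            raise KeyError(f"unknown sample: {sample!r}")
        return self.counts[sample]

    def feature_mask(self, feature_class: str | Sequence[str]) -> pd.Series:
        classes = (feature_class,) if isinstance(feature_class, str) else tuple(feature_class)
        return self.annotation["feature_class"].isin(classes)

    def subset_features(self, mask: pd.Series) -> "CountMatrix":
        return CountMatrix(self.counts.loc[mask], self.annotation.loc[mask])

    def endogenous(self) -> "CountMatrix":
        return self.subset_features(self.feature_mask("endogenous"))

    def spikes(self, mix: str | None = None) -> "CountMatrix":
        """Restrict to spike features; ``mix`` is 'ERCC' or 'Sequin'."""
        if mix is None:
            return self.subset_features(self.feature_mask(SPIKE_CLASSES))
        cls = _mix_to_class(mix)
        return self.subset_features(self.feature_mask(cls))

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.annotation.equals(other.annotation)


def _mix_to_class(mix: str) -> str:
    key = mix.strip().lower()
    if key == "ercc":
        return "spike_ercc"
    if key == "sequin":
        return "spike_sequin"
    raise KeyError(f"unknown spike mix: {mix!r} (expected 'ERCC' or 'Sequin')")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata needed for concentration estimation.

    ``input_volume`` is the ORIGINAL biofluid volume in microlitres (e.g.
    45 000 µl for urinary EVs concentrated from 45 ml, 200 µl for whole
    urine). ``ercc_dilution`` / ``sequin_dilution`` are dimensionless
    dilution factors of the spike stock (e.g. 1/25 000).
    """

    sample_id: str
    fluid: str
    replicate_group: str = ""
    replicate_level: str = "rna_isolation"  # or "library_prep"
    input_volume: float | None = None
    ercc_dilution: float | None = None
    sequin_dilution: float | None = None

    def __post_init__(self) -> None:
        if self.input_volume is not None and not self.input_volume > 0:
            raise ValidationError("input_volume must be > 0 µl")
        for name in ("ercc_dilution", "sequin_dilution"):
            d = getattr(self, name)
            if d is not None and not (0 < d <= 1):
                raise ValidationError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class SpikePanel:
    """One spike-in mix: ordered (spike_id, stock concentration) members.

    Stock concentrations are relative abundance units within the mix; only
    ratios matter downstream.
    """

    mix: str  # "ERCC" or "Sequin"
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        _mix_to_class(self.mix)
        ids = [sid for sid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate spike ids in {self.mix} panel")
        if any(c <= 0 for _, c in self.members):
            raise ValidationError("stock concentrations must be > 0")

    @property
    def spike_ids(self) -> list[str]:
        return [sid for sid, _ in self.members]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.members], dtype=float)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the assessment pipeline.

    Defaults follow the method's published operating point: genes are called
    detected at >= 4 counts, libraries are compared after subsampling to one
    million reads, spike fold changes are trusted from a mean of 10 counts,
    trueness deviations are judged against a 0.5 log2-unit band, and the
    count cutoff is chosen to remove at least 95% of single-positive noise.
    """

    detection_cutoff: int = 4
    subsample_depth: int = 1_000_000
    trueness_min_count: int = 10
    deviation_threshold: float = 0.5
    removal_target: float = 0.95
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.detection_cutoff, self.subsample_depth, self.trueness_min_count) <= 0:
            raise ValidationError("thresholds must be positive")
        if not self.deviation_threshold > 0:
            raise ValidationError("deviation_threshold must be positive")
        if not 0 < self.removal_target < 1:
            raise ValidationError("removal_target must lie in (0, 1)")


@dataclass(frozen=True)
class SpikeDesign:
    """Titration design: dilution factor per (mix, sample).

    The published design dilutes the two panels in opposing five-point
    geometric series (factor ~1.414 per step, 4-fold end to end) so that
    fold changes of known size exist within one experiment.
    """

    samples: tuple[str, ...]
    dilution: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mixes = {mix for mix, _ in self.dilution}
        for mix in mixes:
            _mix_to_class(mix)
            for s in self.samples:
                if (mix, s) not in self.dilution:
                    raise ValidationError(f"design missing dilution for ({mix}, {s})")
        if any(d <= 0 for d in self.dilution.values()):
            raise ValidationError("dilution factors must be > 0")

    @property
    def mixes(self) -> list[str]:
        return sorted({mix for mix, _ in self.dilution})

    def dilution_of(self, mix: str, sample: str) -> float:
        try:
            return self.dilution[(mix, sample)]
        except KeyError:
            raise KeyError(f"no dilution for mix {mix!r}, sample {sample!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mix": mix, "sample_id": s, "dilution": self.dilution[(mix, s)]}
            for mix in self.mixes
            for s in self.samples
        ]
        return pd.DataFrame(rows)
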