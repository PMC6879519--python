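"""Library composition summaries and gene-set overlap between samples.

Composition is summarised as fraction families: read mapping categories
(unique / multi / too short / unmapped — consumed from a pre-tagged upstream
tally, never computed from alignments here), chromosomal origin (nuclear,
mitochondrial, ribosomal), gene-body region (exonic / intronic / intergenic)
and gene biotype (computed over exonic endogenous counts). Each family sums
to one over its labels; families with zero total are reported as absent.

Gene-set overlap between two samples is reported as shared / unique detected
gene counts with the Jaccard index shared / (shared + unique_a + unique_b),
plus a per-side abundance table of the unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ValidationError

logger = logging.getLogger("exrna_perf")

READ_CATEGORIES = ("unique", "multi", "too_short", "unmapped")


@dataclass
class CompositionResult:
    """Per-sample fraction families; absent families are listed, not 0/0."""

    sample: str
    fractions: dict[str, dict[str, float]]  # family -> label -> fraction
    absent_families: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        rows = [
            {"family": fam, "label": lab, "fraction": frac}
            for fam, labs in self.fractions.items()
            for lab, frac in labs.items()
        ]
        return {"fractions": pd.DataFrame(rows, columns=["family", "label", "fraction"])}

    def summary(self) -> dict:
        return {
            "sample": self.sample,
            "fractions": self.fractions,
            "absent_families": self.absent_families,
        }

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "CompositionResult":
        return cls(
            sample=summary["sample"],
            fractions={k: dict(v) for k, v in summary["fractions"].items()},
            absent_families=list(summary["absent_families"]),
        )


def composition(
    cm: CountMatrix,
    sample: str,
    categories: pd.DataFrame | None = None,
) -> CompositionResult:
    """Fraction families of a sample's library.

    ``categories`` is an optional pre-tagged read-category tally (one row per
    sample, columns unique/multi/too_short/unmapped). Chromosome-origin and
    region fractions are computed over endogenous counts via the feature
    annotation; biotype fractions over exonic endogenous counts (falling back
    to all endogenous counts when no feature carries an exonic tag).
    """
    col = cm.endogenous().column(sample)
    ann = cm.endogenous().annotation
    fractions: dict[str, dict[str, float]] = {}
    absent: list[str] = []

    if categories is not None:
        if sample not in categories.index:
            raise KeyError(f"sample {sample!r} absent from read-category table")
        row = categories.loc[sample, list(READ_CATEGORIES)].astype(float)
        if (row < 0).any():
            raise ValidationError("read-category counts must be non-negative")
        _add_family(fractions, absent, "read_category", row)

    chrom = col.groupby(ann["chrom_class"], observed=True).sum()
    _add_family(fractions, absent, "chrom_class", chrom)

    region = col.groupby(ann["region_class"], observed=True).sum()
    region = region.drop(index="not_applicable", errors="ignore")
    _add_family(fractions, absent, "region_class", region)

    exonic = ann["region_class"] == "exonic"
    bio_col = col[exonic] if exonic.any() else col
    bio_ann = ann.loc[exonic, "biotype"] if exonic.any() else ann["biotype"]
    biotype = bio_col.groupby(bio_ann, observed=True).sum()
    _add_family(fractions, absent, "biotype", biotype)

    return CompositionResult(sample=sample, fractions=fractions, absent_families=absent)


def _add_family(fractions: dict, absent: list, name: str, counts: pd.Series) -> None:
    total = float(counts.sum())
    if total <= 0:
        absent.append(name)
        logger.warning("composition family %r has zero total; reported absent", name)
        return
    fractions[name] = {str(k): float(v) / total for k, v in counts.items()}


def top_n_consumption(cm: CountMatrix, sample: str, n: int = 20) -> float:
    """Fraction of endogenous reads consumed by the n most abundant genes.

    Ties at the boundary are broken by feature id so the statistic is
    deterministic. Spikes are excluded from both numerator and denominator.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    col = cm.endogenous().column(sample)
    total = int(col.sum())
    if total == 0:
        raise ValidationError(f"sample {sample!r} has no endogenous reads")
    ordered = col.sort_index().sort_values(ascending=False, kind="stable")
    return float(ordered.iloc[:n].sum()) / total


def percentile_coverage(per_base_coverage: np.ndarray) -> np.ndarray:
    """Average coverage within 100 equal-width bins of the rescaled gene body.

    Each base is treated as a uniform-coverage interval of the rescaled
    [0, 1) gene body, so bins shorter than one base average exactly the step
    function they overlap. The 100-bin profile is normalised to mean 1;
    constant input maps to all ones, all-zero input returns zeros (with a
    logged flag since normalisation is impossible).
    """
    vec = np.asarray(per_base_coverage, dtype=float)
    if vec.ndim != 1 or vec.size < 1:
        raise ValidationError("coverage must be a 1-D vector of length >= 1")
    if (vec < 0).any():
        raise ValidationError("coverage must be non-negative")
    length = vec.size
    # integral of the per-base step function from 0 to t (t in base units)
    cum = np.concatenate([[0.0], np.cumsum(vec)])

    def integral(t: np.ndarray) -> np.ndarray:
        idx = np.minimum(np.floor(t).astype(int), length - 1)
        return cum[idx] + (t - idx) * vec[idx]

    edges = np.linspace(0.0, float(length), 101)
    binned = np.diff(integral(edges)) / (length / 100.0)
    mean = binned.mean()
    if mean == 0:
        logger.warning("all-zero coverage vector; percentile profile is zeros")
        return np.zeros(100)
    return binned / mean


@dataclass
class OverlapResult:
    """Shared/unique detected-gene counts and the Jaccard index."""

    shared: int
    unique_a: int
    unique_b: int
    jaccard: float
    unique_gene_abundance: pd.DataFrame  # feature, which_side, count
    flagged_empty: bool = False  # both sets empty: Jaccard undefined, reported 0

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"unique_gene_abundance": self.unique_gene_abundance}

    def summary(self) -> dict:
        return {
            "shared": self.shared,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
            "jaccard": self.jaccard,
            "flagged_empty": self.flagged_empty,
        }

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "OverlapResult":
        return cls(
            shared=int(summary["shared"]),
            unique_a=int(summary["unique_a"]),
            unique_b=int(summary["unique_b"]),
            jaccard=float(summary["jaccard"]),
            unique_gene_abundance=tables["unique_gene_abundance"],
            flagged_empty=bool(summary["flagged_empty"]),
        )


def overlap(
    set_a: set[str],
    set_b: set[str],
    cm: CountMatrix | None = None,
    sample_a: str | None = None,
    sample_b: str | None = None,
) -> OverlapResult:
    """Overlap of two detected-gene sets: shared/unique counts and Jaccard.

    When a count matrix and sample ids are supplied, the abundance of each
    side's unique genes (in the sample where they were detected) is tabulated
    — unique genes are typically the low-abundance tail. Empty inputs are
    legal: with both sets empty the Jaccard index is undefined and reported
    as 0 with ``flagged_empty``.
    """
    shared_set = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a
    union = len(shared_set) + len(only_a) + len(only_b)
    flagged = union == 0
    jaccard = 0.0 if flagged else len(shared_set) / union
    rows = []
    if cm is not None and sample_a is not None and sample_b is not None:
        for feat in sorted(only_a):
            rows.append({"feature": feat, "which_side": "a", "count": int(cm.counts.at[feat, sample_a])})
        for feat in sorted(only_b):
            rows.append({"feature": feat, "which_side": "b", "count": int(cm.counts.at[feat, sample_b])})
    abundance = pd.DataFrame(rows, columns=["feature", "which_side", "count"])
    return OverlapResult(
        shared=len(shared_set),
        unique_a=len(only_a),
        unique_b=len(only_b),
        jaccard=jaccard,
        unique_gene_abundance=abundance,
        flagged_empty=flagged,
    )
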