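"""Replicate precision, depth subsampling, and the count-cutoff procedure.

Precision of the sequencing method is summarised from pairs of technical
replicates: for every gene detected in both replicates the absolute log2
count ratio is computed, and the area left of the empirical cumulative
distribution of those ratios — the ALC — is the single-number precision
statistic. For a non-negative variable that area equals the mean absolute
log2 ratio exactly; the median is reported alongside because "half of the
genes replicate within a fold change of 2^x" is the statistic's common
reading.

The detection cutoff is chosen from a single-positive / double-positive
analysis: a gene observed (count > 0) in exactly one of two replicates is
treated as noise, and the cutoff is the smallest count threshold that
removes at least a target share (default 95%) of those single positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ValidationError


def subsample_counts(cm: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Subsample every library to exactly ``depth`` reads without replacement.

    Each sample's reads are drawn multivariate-hypergeometrically across
    features, so column totals equal ``depth`` exactly and expectations are
    proportional to the input composition. Deterministic given ``seed``.

    Raises
    ------
    ValidationError
        If ``depth`` exceeds any library's total (all offenders listed).
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    totals = cm.library_sizes()
    short = totals[totals < depth]
    if len(short):
        raise ValidationError(
            "depth %d exceeds library total for sample(s): %s"
            % (depth, ", ".join(f"{s} ({t})" for s, t in short.items()))
        )
    children = np.random.SeedSequence(seed).spawn(len(cm.samples))
    out = {}
    for child, sample in zip(children, cm.samples):
        col = cm.counts[sample].to_numpy(dtype=np.int64)
        rng = np.random.default_rng(child)
        out[sample] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    sub = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return CountMatrix(sub, cm.annotation)


def log2_to_fold(x: float) -> float:
    """Convert a log2 ratio to a linear fold change (2**x)."""
    if not np.isfinite(x):
        raise ValidationError("log2 value must be finite")
    return float(2.0 ** x)


@dataclass
class PrecisionResult:
    """Replicate-pair concordance: absolute log2 ratios and the ALC."""

    sample_a: str
    sample_b: str
    cutoff: int
    ratios: np.ndarray  # |log2(k_a / k_b)| over retained genes
    alc: float  # area left of the empirical CDF == mean ratio
    median_ratio: float
    pearson_r: float  # on log2 counts of retained genes
    n_retained: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"ratios": pd.DataFrame({"abs_log2_ratio": self.ratios})}

    def summary(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "cutoff": self.cutoff,
            "n_retained": self.n_retained,
            "alc": self.alc,
            "alc_fold": log2_to_fold(self.alc),
            "median_ratio": self.median_ratio,
            "median_fold": log2_to_fold(self.median_ratio),
            "pearson_r": self.pearson_r,
        }

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "PrecisionResult":
        return cls(
            sample_a=summary["sample_a"],
            sample_b=summary["sample_b"],
            cutoff=int(summary["cutoff"]),
            ratios=tables["ratios"]["abs_log2_ratio"].to_numpy(dtype=float)
            if len(tables["ratios"])
            else np.array([]),
            alc=float(summary["alc"]),
            median_ratio=float(summary["median_ratio"]),
            pearson_r=float(summary["pearson_r"]),
            n_retained=int(summary["n_retained"]),
        )


def replicate_ratios(
    cm: CountMatrix, sample_a: str, sample_b: str, cutoff: int = 4
) -> PrecisionResult:
    """Absolute log2 count ratios between two replicates, and the ALC.

    Spike features are excluded. A gene is retained when its count reaches
    ``cutoff`` in BOTH replicates — the operational meaning of "reproducibly
    detected". The ALC (area left of the empirical CDF of the absolute
    ratios) equals their arithmetic mean; the Pearson correlation is taken
    on log2 counts of the retained genes.
    """
    endo = cm.endogenous()
    ka = endo.column(sample_a).to_numpy(dtype=float)
    kb = endo.column(sample_b).to_numpy(dtype=float)
    keep = (ka >= cutoff) & (kb >= cutoff)
    if not keep.any():
        raise ValidationError(
            f"no genes with count >= {cutoff} in both {sample_a} and {sample_b}"
        )
    la, lb = np.log2(ka[keep]), np.log2(kb[keep])
    ratios = np.abs(la - lb)
    if np.std(la) == 0 or np.std(lb) == 0:
        pearson = 1.0 if np.array_equal(la, lb) else float("nan")
    else:
        pearson = float(np.corrcoef(la, lb)[0, 1])
    return PrecisionResult(
        sample_a=sample_a,
        sample_b=sample_b,
        cutoff=cutoff,
        ratios=ratios,
        alc=float(np.mean(ratios)),
        median_ratio=float(np.median(ratios)),
        pearson_r=pearson,
        n_retained=int(keep.sum()),
    )


@dataclass
class FilterReport:
    """Single/double-positive removal fractions per candidate cutoff."""

    per_cutoff: pd.DataFrame  # cutoff, removed_single_positive_fraction, removed_double_positive_fraction
    chosen_cutoff: int
    n_single_positive: int
    n_double_positive: int
    flagged: bool = False  # True when no single positives were found

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"per_cutoff": self.per_cutoff}

    def summary(self) -> dict:
        return {
            "chosen_cutoff": self.chosen_cutoff,
            "n_single_positive": self.n_single_positive,
            "n_double_positive": self.n_double_positive,
            "flagged": self.flagged,
        }

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "FilterReport":
        return cls(
            per_cutoff=tables["per_cutoff"],
            chosen_cutoff=int(summary["chosen_cutoff"]),
            n_single_positive=int(summary["n_single_positive"]),
            n_double_positive=int(summary["n_double_positive"]),
            flagged=bool(summary["flagged"]),
        )


def single_positive_analysis(
    cm: CountMatrix,
    sample_a: str,
    sample_b: str,
    cutoffs: list[int] | range = range(1, 11),
    removal_target: float = 0.95,
) -> FilterReport:
    """Choose a detection cutoff from single/double-positive gene removal.

    Single positive: gene with count > 0 in exactly one replicate (noise).
    Double positive: count > 0 in both. For each candidate cutoff ``c`` the
    removed single-positive fraction is the share of single positives whose
    nonzero count is < c; the chosen cutoff is the smallest c whose removal
    reaches ``removal_target``. The double-positive column reports the share
    of double positives with min(count_a, count_b) < c, i.e. genes a
    both-replicates detection rule at c would drop.
    """
    cutoffs = sorted(int(c) for c in cutoffs)
    if not cutoffs or cutoffs[0] <= 0:
        raise ValidationError("cutoffs must be positive integers")
    endo = cm.endogenous()
    ka = endo.column(sample_a).to_numpy(dtype=np.int64)
    kb = endo.column(sample_b).to_numpy(dtype=np.int64)
    single = (ka > 0) != (kb > 0)
    double = (ka > 0) & (kb > 0)
    single_vals = np.where(ka[single] > 0, ka[single], kb[single])
    double_min = np.minimum(ka[double], kb[double])
    rows = []
    for c in cutoffs:
        rows.append(
            {
                "cutoff": c,
                "removed_single_positive_fraction": float(np.mean(single_vals < c))
                if len(single_vals)
                else float("nan"),
                "removed_double_positive_fraction": float(np.mean(double_min < c))
                if len(double_min)
                else float("nan"),
            }
        )
    per_cutoff = pd.DataFrame(rows)
    if len(single_vals) == 0:
        return FilterReport(
            per_cutoff=per_cutoff,
            chosen_cutoff=cutoffs[0],
            n_single_positive=0,
            n_double_positive=int(double.sum()),
            flagged=True,
        )
    meeting = per_cutoff[
        per_cutoff["removed_single_positive_fraction"] >= removal_target
    ]
    chosen = int(meeting["cutoff"].iloc[0]) if len(meeting) else cutoffs[-1]
    return FilterReport(
        per_cutoff=per_cutoff,
        chosen_cutoff=chosen,
        n_single_positive=int(single.sum()),
        n_double_positive=int(double.sum()),
        flagged=len(meeting) == 0,
    )


def detected_genes(cm: CountMatrix, sample: str, cutoff: int = 4) -> set[str]:
    """Feature ids (spikes excluded) with count >= cutoff in ``sample``."""
    endo = cm.endogenous()
    col = endo.column(sample)
    return set(col.index[col >= cutoff])


class PrecisionModel:
    """Replicate-precision analysis over a list of replicate pairs.

    Thin model wrapper: built from a count matrix and pair list, ``fit()``
    returns one :class:`PrecisionResult` per pair plus a cutoff scan.
    """

    def __init__(
        self,
        cm: CountMatrix,
        pairs: list[tuple[str, str]],
        cutoff: int = 4,
        cutoffs: range = range(1, 11),
        removal_target: float = 0.95,
    ):
        self.cm = cm
        self.pairs = [tuple(p) for p in pairs]
        self.cutoff = cutoff
        self.cutoffs = cutoffs
        self.removal_target = removal_target

    def fit(self) -> "PrecisionModelResult":
        results = [
            replicate_ratios(self.cm, a, b, cutoff=self.cutoff) for a, b in self.pairs
        ]
        filters = [
            single_positive_analysis(
                self.cm, a, b, cutoffs=self.cutoffs, removal_target=self.removal_target
            )
            for a, b in self.pairs
        ]
        return PrecisionModelResult(results, filters)


@dataclass
class PrecisionModelResult:
    pair_results: list[PrecisionResult]
    filter_reports: list[FilterReport]

    def summary(self) -> pd.DataFrame:
        rows = []
        for r, f in zip(self.pair_results, self.filter_reports):
            row = r.summary()
            row["chosen_cutoff"] = f.chosen_cutoff
            rows.append(row)
        return pd.DataFrame(rows)
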