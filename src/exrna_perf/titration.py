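"""Spike-in titration design and fold-change trueness statistics.

Two synthetic spike panels (ERCC and Sequin) are added to aliquots of one
RNA sample in opposing five-point geometric dilution series, so that between
any two aliquots every spike has a known, designed fold change (up to 4-fold
end to end, ~1.414-fold per step). Trueness — how close observed fold
changes come to the designed ones — is summarised three ways:

* per-spike deviation ``delta = observed - expected`` log2 fold change,
* an ordinary least-squares regression of observed on expected log2 fold
  change (slope and adjusted R^2; a perfect method gives slope 1),
* the fraction of spikes whose deviation stays within a threshold (default
  0.5 log2 units, i.e. the measurement is off by at most a factor 1.41),
  optionally binned by the designed fold-change magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import AnalysisConfig, CountMatrix, SpikeDesign, ValidationError
from .precision import subsample_counts


def expected_log2fc(design: SpikeDesign, mix: str, sample_a: str, sample_b: str) -> float:
    """Designed log2 fold change of ``mix`` spikes between two samples.

    Spike concentration is proportional to the dilution factor, so the
    expected fold change is ``log2(d_a / d_b)``; antisymmetric in the sample
    arguments.
    """
    d_a = design.dilution_of(mix, sample_a)
    d_b = design.dilution_of(mix, sample_b)
    return float(np.log2(d_a / d_b))


def observed_log2fc(
    cm: CountMatrix,
    mix: str,
    sample_a: str,
    sample_b: str,
    depth: int | None = None,
    seed: int = 0,
    min_count: int = 10,
) -> pd.DataFrame:
    """Observed per-spike log2 fold changes between two samples.

    When ``depth`` is given, both whole libraries are first subsampled to
    that equal depth (without replacement) before restricting to the spikes
    of ``mix``. Spikes with zero count in either sample cannot yield a fold
    change: they are flagged ``excluded_zero`` with NaN observed value rather
    than silently dropped. ``low_count_flag`` marks spikes whose mean count
    across the pair falls below ``min_count`` — fold changes of such spikes
    are unreliable.
    """
    for s in (sample_a, sample_b):
        if s not in cm.samples:
            raise KeyError(f"unknown sample: {s!r}")
    work = cm
    if depth is not None:
        pair = CountMatrix(cm.counts[[sample_a, sample_b]], cm.annotation)
        work = subsample_counts(pair, depth, seed)
    spikes = work.spikes(mix)
    if spikes.shape[0] == 0:
        raise ValidationError(f"no spikes of mix {mix!r} present")
    ka = spikes.column(sample_a).to_numpy(dtype=float)
    kb = spikes.column(sample_b).to_numpy(dtype=float)
    zero = (ka == 0) | (kb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.where(zero, np.nan, np.log2(ka / kb))
    mean_count = (ka + kb) / 2.0
    return pd.DataFrame(
        {
            "spike_id": spikes.features,
            "mix": mix,
            "count_a": ka.astype(int),
            "count_b": kb.astype(int),
            "observed_log2fc": obs,
            "mean_count": mean_count,
            "low_count_flag": mean_count < min_count,
            "excluded_zero": zero,
        }
    )


def fit_trueness(per_spike: pd.DataFrame) -> tuple[float, float]:
    """OLS of observed on expected log2 fold change, with intercept.

    Returns ``(slope, adjusted_r2)``; the adjusted R^2 carries the standard
    n-2 degrees-of-freedom correction. Requires at least 3 finite points and
    non-constant expected values.
    """
    data = per_spike[["expected_log2fc", "observed_log2fc"]].dropna()
    if len(data) < 3:
        raise ValidationError("fit_trueness needs at least 3 finite (E, O) points")
    e = data["expected_log2fc"].to_numpy(dtype=float)
    o = data["observed_log2fc"].to_numpy(dtype=float)
    if np.ptp(e) == 0:
        raise ValidationError("expected log2 fold changes are constant; slope undefined")
    model = sm.OLS(o, sm.add_constant(e)).fit()
    return float(model.params[1]), float(model.rsquared_adj)


def fraction_within(
    per_spike: pd.DataFrame,
    thresholds: list[float] = (0.5,),
    bin_by_expected: bool = False,
) -> pd.DataFrame:
    """Share of spikes whose |observed - expected| deviation is within tau.

    With ``bin_by_expected`` the fractions are computed per distinct
    magnitude of the designed fold change (|E| rounded to 3 decimals), as in
    a cumulative-deviation plot stratified by designed difference; otherwise
    a single pooled row per threshold is returned. Monotonically
    non-decreasing in tau.
    """
    data = per_spike[["expected_log2fc", "observed_log2fc"]].dropna()
    if data.empty:
        raise ValidationError("fraction_within requires a nonempty table")
    dev = (data["observed_log2fc"] - data["expected_log2fc"]).abs().to_numpy()
    abs_e = data["expected_log2fc"].abs().round(3).to_numpy()
    rows = []
    groups: list[tuple[str | float, np.ndarray]]
    if bin_by_expected:
        groups = [(val, dev[abs_e == val]) for val in np.unique(abs_e)]
    else:
        groups = [("pooled", dev)]
    for label, devs in groups:
        for tau in thresholds:
            rows.append(
                {
                    "abs_expected": label,
                    "threshold": float(tau),
                    "fraction_within": float(np.mean(devs <= tau)),
                    "n": int(len(devs)),
                }
            )
    return pd.DataFrame(rows)


def titration_pairs(
    design: SpikeDesign, pairing: str = "reference"
) -> list[tuple[str, str]]:
    """Sample pairs to populate the trueness analysis.

    ``reference``: every sample against the mid-dilution sample (default);
    ``adjacent``: consecutive titration steps; ``extreme``: first vs last.
    """
    s = list(design.samples)
    if pairing == "reference":
        ref = s[len(s) // 2]
        return [(x, ref) for x in s if x != ref]
    if pairing == "adjacent":
        return list(zip(s[:-1], s[1:]))
    if pairing == "extreme":
        return [(s[0], s[-1])]
    raise ValueError(f"unknown pairing mode: {pairing!r}")


@dataclass
class TruenessResult:
    """Per-spike expected/observed fold changes plus regression summaries."""

    per_spike: pd.DataFrame  # spike_id, mix, sample_pair, E, O, deviation, mean_count, low_count_flag
    fits: pd.DataFrame  # mix, slope, adjusted_r2, n
    fractions: pd.DataFrame  # abs_expected|pooled, threshold, fraction_within, n
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)  # zero-count spikes

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "per_spike": self.per_spike,
            "fits": self.fits,
            "fractions": self.fractions,
            "excluded": self.excluded,
        }

    def summary(self) -> dict:
        out: dict = {"n_spike_pairs": int(len(self.per_spike))}
        for row in self.fits.itertuples():
            out[f"slope_{row.mix}"] = row.slope
            out[f"adjusted_r2_{row.mix}"] = row.adjusted_r2
        pooled = self.fractions[self.fractions["abs_expected"] == "pooled"]
        for row in pooled.itertuples():
            out[f"fraction_within_{row.threshold:g}"] = row.fraction_within
        out["n_excluded_zero"] = int(len(self.excluded))
        return out

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "TruenessResult":
        return cls(
            per_spike=tables["per_spike"],
            fits=tables["fits"],
            fractions=tables["fractions"],
            excluded=tables.get("excluded", pd.DataFrame()),
        )


class TruenessModel:
    """Fold-change trueness assessment of a spike-in titration experiment.

    Built from a count matrix carrying both spike panels and the titration
    design; ``fit()`` computes per-spike expected and observed log2 fold
    changes over the chosen sample pairs, regresses observed on expected per
    mix, and tabulates the fraction of spikes within deviation thresholds.
    """

    def __init__(
        self,
        cm: CountMatrix,
        design: SpikeDesign,
        config: AnalysisConfig | None = None,
    ):
        self.cm = cm
        self.design = design
        self.config = config or AnalysisConfig()

    def fit(
        self,
        mixes: tuple[str, ...] | None = None,
        pairing: str = "reference",
        thresholds: tuple[float, ...] = (0.5, 1.0),
        depth: int | None = None,
        seed: int | None = None,
        bin_by_expected: bool = False,
    ) -> TruenessResult:
        mixes = tuple(mixes) if mixes else tuple(self.design.mixes)
        seed = self.config.random_seed if seed is None else seed
        pairs = titration_pairs(self.design, pairing)
        frames, excluded = [], []
        for mix in mixes:
            for a, b in pairs:
                obs = observed_log2fc(
                    self.cm,
                    mix,
                    a,
                    b,
                    depth=depth,
                    seed=seed,
                    min_count=self.config.trueness_min_count,
                )
                obs["sample_pair"] = f"{a}/{b}"
                obs["expected_log2fc"] = expected_log2fc(self.design, mix, a, b)
                excluded.append(obs[obs["excluded_zero"]])
                obs = obs[~obs["excluded_zero"]].copy()
                obs["deviation"] = obs["observed_log2fc"] - obs["expected_log2fc"]
                frames.append(obs)
        per_spike = pd.concat(frames, ignore_index=True).drop(columns=["excluded_zero"])
        excluded_df = pd.concat(excluded, ignore_index=True)
        fit_rows = []
        for mix in mixes:
            sub = per_spike[per_spike["mix"] == mix]
            slope, adj_r2 = fit_trueness(sub)
            fit_rows.append(
                {"mix": mix, "slope": slope, "adjusted_r2": adj_r2, "n": len(sub)}
            )
        fracs = fraction_within(per_spike, list(thresholds), bin_by_expected=False)
        if bin_by_expected:
            fracs = pd.concat(
                [fracs, fraction_within(per_spike, list(thresholds), bin_by_expected=True)],
                ignore_index=True,
            )
        return TruenessResult(
            per_spike=per_spike,
            fits=pd.DataFrame(fit_rows),
            fractions=fracs,
            excluded=excluded_df,
        )
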