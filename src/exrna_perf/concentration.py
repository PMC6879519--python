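"""Relative RNA concentration from the endogenous:spike read ratio.

A fixed amount of ERCC spike mix is added to each RNA eluate, so the ratio
of endogenous to spike reads in a library measures the endogenous RNA amount
relative to the spike amount, independent of sequencing depth. Correcting
that ratio for the spike dilution factor and the original biofluid input
volume yields a relative RNA concentration per millilitre of biofluid:

    rho = (endogenous reads / ERCC reads) * dilution / volume_ml

Only ratios between samples sharing the same spike stock are meaningful;
absolute molarity is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .datatypes import CountMatrix, SampleMeta, ValidationError


def endo_spike_ratio(cm: CountMatrix, sample: str, mix: str = "ERCC") -> float:
    """Total endogenous counts over total spike counts for one sample.

    The endogenous sum covers all non-spike features, including
    mitochondrial and rRNA genes. Zero spike reads signal failed spike
    recovery and raise rather than returning infinity.
    """
    endo = int(cm.endogenous().column(sample).sum())
    spike = int(cm.spikes(mix).column(sample).sum())
    if spike == 0:
        raise ValidationError(
            f"no {mix} spike reads in sample {sample!r}; spike recovery failed"
        )
    return endo / spike


def relative_concentration(ratio: float, meta: SampleMeta) -> float:
    """Relative RNA concentration per ml: ratio * dilution / volume_ml.

    ``meta.input_volume`` is the original biofluid volume in microlitres;
    ``meta.ercc_dilution`` the dimensionless spike dilution factor. Units are
    arbitrary but comparable across samples spiked from the same stock.
    """
    if meta.ercc_dilution is None:
        raise ValidationError(f"sample {meta.sample_id!r} has no ercc_dilution")
    if meta.input_volume is None:
        raise ValidationError(f"sample {meta.sample_id!r} has no input_volume")
    volume_ml = meta.input_volume / 1000.0
    return ratio * meta.ercc_dilution / volume_ml


@dataclass
class ConcentrationResult:
    """Per-sample relative RNA concentrations, scaled to a reference."""

    per_sample: pd.DataFrame  # sample_id, endo_reads, spike_reads, ratio, dilution, input_volume, relative_concentration, scaled_to_reference
    reference: str

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"per_sample": self.per_sample}

    def summary(self) -> dict:
        return {
            "reference": self.reference,
            "n_samples": int(len(self.per_sample)),
            "concentrations": dict(
                zip(
                    self.per_sample["sample_id"],
                    self.per_sample["relative_concentration"],
                )
            ),
        }

    @classmethod
    def from_report(cls, tables: dict, summary: dict) -> "ConcentrationResult":
        return cls(per_sample=tables["per_sample"], reference=summary["reference"])

    def concentration_of(self, sample: str) -> float:
        sel = self.per_sample.loc[self.per_sample["sample_id"] == sample]
        if sel.empty:
            raise KeyError(f"unknown sample: {sample!r}")
        return float(sel["relative_concentration"].iloc[0])


def fold_difference(result: ConcentrationResult, sample_a: str, sample_b: str) -> float:
    """Ratio of relative concentrations rho_a / rho_b."""
    rho_a = result.concentration_of(sample_a)
    rho_b = result.concentration_of(sample_b)
    if rho_b == 0:
        raise ValidationError(f"reference sample {sample_b!r} has zero concentration")
    return rho_a / rho_b


class ConcentrationModel:
    """Relative RNA concentration estimation across a sample set.

    Built from a count matrix and per-sample metadata; ``fit()`` computes
    the endogenous:ERCC ratio, corrects it for spike dilution and input
    volume, and scales to a reference sample (first sample by default).
    Samples lacking dilution or volume metadata are skipped with a note.
    """

    def __init__(self, cm: CountMatrix, meta: Mapping[str, SampleMeta], mix: str = "ERCC"):
        self.cm = cm
        self.meta = meta
        self.mix = mix

    def fit(self, reference: str | None = None) -> ConcentrationResult:
        rows = []
        for sample in self.cm.samples:
            m = self.meta.get(sample)
            if m is None or m.ercc_dilution is None or m.input_volume is None:
                continue
            ratio = endo_spike_ratio(self.cm, sample, mix=self.mix)
            rho = relative_concentration(ratio, m)
            rows.append(
                {
                    "sample_id": sample,
                    "endo_reads": int(self.cm.endogenous().column(sample).sum()),
                    "spike_reads": int(self.cm.spikes(self.mix).column(sample).sum()),
                    "ratio": ratio,
                    "dilution": m.ercc_dilution,
                    "input_volume": m.input_volume,
                    "relative_concentration": rho,
                }
            )
        if not rows:
            raise ValidationError("no sample has both ercc_dilution and input_volume")
        per_sample = pd.DataFrame(rows)
        reference = reference or per_sample["sample_id"].iloc[0]
        result = ConcentrationResult(per_sample=per_sample, reference=reference)
        rho_ref = result.concentration_of(reference)
        per_sample["scaled_to_reference"] = per_sample["relative_concentration"] / rho_ref
        return result
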