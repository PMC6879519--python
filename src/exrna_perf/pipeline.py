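"""One-shot assessment pipeline combining every stage into a report bundle.

``assess`` runs, on one dataset: spike titration trueness (when a titration
design is supplied), relative concentration (for samples with volume and
dilution metadata), replicate precision and the count-cutoff scan (for the
given replicate pairs), composition per sample, and detected-gene overlap per
pair. Stages whose required metadata is absent are skipped with a logged
reason. Outputs are per-stage TSV reports plus one combined ``assess.json``;
contradictory configuration (e.g. a subsampling depth exceeding the smallest
library) is rejected before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .composition import composition, overlap, top_n_consumption
from .concentration import ConcentrationModel
from .datatypes import AnalysisConfig, CountMatrix, SampleMeta, SpikeDesign, ValidationError
from .io import write_report
from .precision import detected_genes, replicate_ratios, single_positive_analysis, subsample_counts
from .titration import TruenessModel

logger = logging.getLogger("exrna_perf")


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, input digests, seed, version.

    The manifest carries wall-clock timestamps and is therefore run metadata;
    reproducibility of a rerun is judged on the analysis outputs, which are
    bit-identical given the same inputs, config and seed.
    """

    subcommand: str
    config: dict
    input_digests: dict[str, str]
    seed: int
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, outdir: Path) -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def assess(
    cm: CountMatrix,
    outdir: str | Path,
    config: AnalysisConfig | None = None,
    design: SpikeDesign | None = None,
    meta: Mapping[str, SampleMeta] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    categories: pd.DataFrame | None = None,
    depth: int | None = None,
    manifest: RunManifest | None = None,
) -> dict:
    """Run all applicable stages and write a combined report bundle.

    ``depth``: optional equal-depth subsampling applied to the whole matrix
    before any statistic (checked against the smallest library up front).
    Returns the combined summary dict (also written as ``assess.json``).
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if depth is not None:
        smallest = int(cm.library_sizes().min())
        if depth > smallest:
            raise ValidationError(
                f"subsample depth {depth} exceeds smallest library ({smallest})"
            )
        cm = subsample_counts(cm, depth, config.random_seed)

    combined: dict = {"config": config.__dict__, "depth": depth, "stages": {}}

    # -- trueness ----------------------------------------------------------
    if design is not None and all(s in cm.samples for s in design.samples):
        mixes = [
            mix for mix in design.mixes if cm.spikes(mix).counts.to_numpy().sum() > 0
        ]
        if mixes:
            if len(mixes) < len(design.mixes):
                logger.info("trueness restricted to mixes with reads: %s", mixes)
            res = TruenessModel(cm, design, config).fit(
                mixes=tuple(mixes),
                thresholds=(config.deviation_threshold, 2 * config.deviation_threshold),
            )
            write_report(res, outdir / "trueness")
            combined["stages"]["trueness"] = res.summary()
        else:
            logger.info("trueness skipped: no spike reads")
    else:
        logger.info("trueness skipped: no titration design for these samples")

    # -- concentration -----------------------------------------------------
    if meta:
        try:
            res = ConcentrationModel(cm, meta).fit()
            write_report(res, outdir / "concentration")
            combined["stages"]["concentration"] = res.summary()
        except ValidationError as exc:
            logger.info("concentration skipped: %s", exc)
    else:
        logger.info("concentration skipped: no sample metadata")

    # -- precision & filtering ----------------------------------------------
    if pairs:
        prec, filt = {}, {}
        for a, b in pairs:
            r = replicate_ratios(cm, a, b, cutoff=config.detection_cutoff)
            f = single_positive_analysis(
                cm, a, b, removal_target=config.removal_target
            )
            write_report(r, outdir / "precision" / f"{a}__{b}")
            write_report(f, outdir / "filter_scan" / f"{a}__{b}")
            prec[f"{a}/{b}"] = r.summary()
            filt[f"{a}/{b}"] = f.summary()
        combined["stages"]["precision"] = prec
        combined["stages"]["filter_scan"] = filt
    else:
        logger.info("precision/filter skipped: no replicate pairs")

    # -- composition ---------------------------------------------------------
    comp = {}
    for s in cm.samples:
        res = composition(cm, s, categories=categories)
        write_report(res, outdir / "composition" / s)
        summ = res.summary()
        summ["top20_consumption"] = top_n_consumption(cm, s, 20)
        comp[s] = summ
    combined["stages"]["composition"] = comp

    # -- overlap --------------------------------------------------------------
    if pairs:
        ov = {}
        for a, b in pairs:
            res = overlap(
                detected_genes(cm, a, config.detection_cutoff),
                detected_genes(cm, b, config.detection_cutoff),
                cm,
                a,
                b,
            )
            write_report(res, outdir / "overlap" / f"{a}__{b}")
            ov[f"{a}/{b}"] = res.summary()
        combined["stages"]["overlap"] = ov

    with open(outdir / "assess.json", "w") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    if manifest is not None:
        manifest.write(outdir)
    return combined


def _default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
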