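"""Readers and writers for the package's plain-text interchange formats.

All tables are UTF-8, tab-separated. The count matrix is features row-wise
with a header row of sample ids; the feature annotation is a separate sidecar
table so the same counts can be re-annotated. Stage results are written as a
directory of TSV tables plus a machine-readable ``summary.json``; re-reading
reproduces integers bit-identically and reals to at least 12 significant
digits (floats are serialised at full precision).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Type, TypeVar

import pandas as pd
import yaml

from .datatypes import (
    ANNOTATION_COLUMNS,
    AnalysisConfig,
    CountMatrix,
    SampleMeta,
    SpikeDesign,
    SpikePanel,
    ValidationError,
)

logger = logging.getLogger("exrna_perf")

T = TypeVar("T")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a feature annotation sidecar table (first column feature_id)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    first = ann.columns[0]
    return ann.set_index(first).rename_axis("feature_id")


def read_count_matrix(path: str | Path, annotation_path: str | Path) -> CountMatrix:
    """Read a TSV count table plus its annotation sidecar into a CountMatrix.

    Unknown features (present in counts, absent from annotation) raise;
    extra annotation rows are ignored with a logged warning.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    annotation = read_annotation(annotation_path)
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(
            f"features absent from annotation: {missing.tolist()[:5]}"
        )
    extra = annotation.index.difference(counts.index)
    if len(extra):
        logger.warning(
            "annotation has %d features not in the count table; ignored", len(extra)
        )
    return CountMatrix(counts, annotation.loc[counts.index])


def write_count_matrix(cm: CountMatrix, path: str | Path, annotation_path: str | Path) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")
    cm.annotation.rename_axis("feature_id").to_csv(annotation_path, sep="\t")


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read sample metadata from YAML (list of mappings) or TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
    else:
        df = pd.read_csv(path, sep="\t")
        records = df.to_dict(orient="records")
    metas: dict[str, SampleMeta] = {}
    for rec in records:
        rec = {k: (None if _is_na(v) else v) for k, v in rec.items()}
        meta = SampleMeta(**rec)
        metas[meta.sample_id] = meta
    return metas


def _is_na(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def read_spike_panels(path: str | Path) -> dict[str, SpikePanel]:
    """Read spike panels from a TSV with columns spike_id, mix, stock_concentration."""
    df = pd.read_csv(path, sep="\t")
    panels = {}
    for mix, grp in df.groupby("mix", sort=True):
        members = tuple(zip(grp["spike_id"].astype(str), grp["stock_concentration"].astype(float)))
        panels[str(mix)] = SpikePanel(mix=str(mix), members=members)
    return panels


def write_spike_panels(panels: dict[str, SpikePanel], path: str | Path) -> None:
    rows = [
        {"spike_id": sid, "mix": p.mix, "stock_concentration": conc}
        for p in panels.values()
        for sid, conc in p.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spike_design(path: str | Path) -> SpikeDesign:
    """Read a titration design TSV with columns mix, sample_id, dilution."""
    df = pd.read_csv(path, sep="\t")
    samples = tuple(dict.fromkeys(df["sample_id"].astype(str)))
    dilution = {
        (str(r.mix), str(r.sample_id)): float(r.dilution) for r in df.itertuples()
    }
    return SpikeDesign(samples=samples, dilution=dilution)


def write_spike_design(design: SpikeDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# Generic stage-result reports: TSV tables + JSON summary
# ---------------------------------------------------------------------------


def write_report(result: Any, path: str | Path) -> None:
    """Write a stage result as TSV tables plus a key/value ``summary.json``.

    ``result`` must expose ``tables() -> dict[str, DataFrame]`` and
    ``summary() -> dict``. Empty tables produce header-only files.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables().items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(result.summary()), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(cls: Type[T], path: str | Path) -> T:
    """Reconstruct a stage result written by :func:`write_report`.

    ``cls`` must expose ``from_report(tables, summary)``.
    """
    outdir = Path(path)
    with open(outdir / "summary.json") as fh:
        summary = json.load(fh)
    tables = {
        p.stem: pd.read_csv(p, sep="\t") for p in sorted(outdir.glob("*.tsv"))
    }
    return cls.from_report(tables, summary)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj
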