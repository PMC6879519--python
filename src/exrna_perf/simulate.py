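"""Synthetic count data with the structure the assessment statistics assume.

Three generators cover the experiments the pipeline analyses:

* spike panels and an opposing five-point titration (92 ERCC + 78 Sequin
  spikes, dilution factor ~1.414 per step, 4-fold end to end) layered on a
  constant endogenous background, with optional Poisson or negative-binomial
  count noise — exercises the trueness statistics with known expected fold
  changes;
* replicate biofluid libraries from a :class:`BiofluidProfile` — a shared
  true expression vector per gene with biofluid-specific biotype and
  chromosome-origin read fractions (matched exactly in expectation by
  iterative proportional fitting), negative-binomial replicate noise, and a
  planted population of low-count "single-positive" noise genes — exercises
  the precision, filtering and composition statistics;
* sample sets with planted relative RNA concentrations, spiked at known
  dilution — exercises the concentration estimator by parameter recovery.

Every generator records a :class:`SimulationTruth` next to its counts so
tests can compare estimates against the planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    SampleMeta,
    SpikeDesign,
    SpikePanel,
    ValidationError,
)
from .titration import expected_log2fc

#: the published opposing five-point dilution series
SEQUIN_DILUTIONS = (1 / 15000, 1 / 21277, 1 / 30000, 1 / 42433, 1 / 60000)
ERCC_DILUTIONS = (1 / 100000, 1 / 70721, 1 / 50000, 1 / 35461, 1 / 25000)


@dataclass
class BiofluidProfile:
    """Generative profile of one biofluid's small-input total-RNA library.

    ``biotype_weights`` and ``chrom_weights`` are target READ fractions;
    ``abundance_shape`` is the (log-mean, log-sd) of the per-gene log-normal
    expression; ``single_positive_rate`` is the share of genes emitted as
    1-3-count noise in exactly one replicate; ``dispersion`` maps replicate
    level to negative-binomial overdispersion (RNA-isolation replicates are
    noisier than library-prep replicates).
    """

    name: str
    n_genes: int
    biotype_weights: dict[str, float]
    chrom_weights: dict[str, float]
    abundance_shape: tuple[float, float] = (0.0, 1.5)
    single_positive_rate: float = 0.15
    dispersion: dict[str, float] = field(
        default_factory=lambda: {"rna_isolation": 0.05, "library_prep": 0.01}
    )

    def __post_init__(self) -> None:
        for weights in (self.biotype_weights, self.chrom_weights):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"weights must sum to 1, got {total}")
        if any(d < 0 for d in self.dispersion.values()):
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.single_positive_rate < 1:
            raise ValidationError("single_positive_rate must lie in [0, 1)")


#: mitochondria-heavy platelet-rich plasma, protein-coding-dominated
#: platelet-free plasma, and gene-rich urine
PRESET_PROFILES: dict[str, BiofluidProfile] = {
    "ePRP": BiofluidProfile(
        name="ePRP",
        n_genes=6000,
        biotype_weights={
            "protein_coding": 0.40,
            "pseudogene": 0.35,
            "lncRNA": 0.10,
            "miscRNA": 0.10,
            "other": 0.05,
        },
        chrom_weights={"nuclear": 0.20, "mitochondrial": 0.77, "rRNA": 0.03},
    ),
    "ePFP": BiofluidProfile(
        name="ePFP",
        n_genes=8000,
        biotype_weights={
            "protein_coding": 0.70,
            "lncRNA": 0.12,
            "miscRNA": 0.08,
            "pseudogene": 0.06,
            "other": 0.04,
        },
        chrom_weights={"nuclear": 0.85, "mitochondrial": 0.08, "rRNA": 0.07},
    ),
    "urine": BiofluidProfile(
        name="urine",
        n_genes=12000,
        biotype_weights={
            "protein_coding": 0.55,
            "lncRNA": 0.20,
            "miscRNA": 0.10,
            "pseudogene": 0.10,
            "other": 0.05,
        },
        chrom_weights={"nuclear": 0.90, "mitochondrial": 0.05, "rRNA": 0.05},
    ),
}


@dataclass
class SimulationTruth:
    """Planted parameters recorded alongside every generated dataset."""

    seed: int
    design: SpikeDesign | None = None
    expected_log2fc: dict[tuple[str, str, str], float] | None = None  # (mix, a, b)
    true_concentration: dict[str, float] | None = None
    biotype_fractions: dict[str, float] | None = None
    chrom_fractions: dict[str, float] | None = None
    expected_counts: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        if self.design is not None:
            out["design"] = self.design.to_frame().to_dict(orient="records")
        if self.expected_log2fc is not None:
            out["expected_log2fc"] = {
                f"{mix}:{a}/{b}": v for (mix, a, b), v in self.expected_log2fc.items()
            }
        for name in ("true_concentration", "biotype_fractions", "chrom_fractions"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


def default_titration_design(sample_prefix: str = "T") -> SpikeDesign:
    """The published opposing five-point titration design."""
    samples = tuple(f"{sample_prefix}{i + 1}" for i in range(5))
    dilution: dict[tuple[str, str], float] = {}
    for s, d_seq, d_ercc in zip(samples, SEQUIN_DILUTIONS, ERCC_DILUTIONS):
        dilution[("Sequin", s)] = d_seq
        dilution[("ERCC", s)] = d_ercc
    return SpikeDesign(samples=samples, dilution=dilution)


def make_spike_panels(
    n_ercc: int = 92,
    n_sequin: int = 78,
    dynamic_range_log2: float = 6.0,
    seed: int = 0,
) -> tuple[SpikePanel, SpikePanel]:
    """Synthetic ERCC-like and Sequin-like panels with log-spaced stocks.

    Stock concentrations are evenly log2-spaced over ``dynamic_range_log2``
    units; panel sizes default to the real panels (92 + 78 = 170 spikes).
    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    if n_ercc <= 0 or n_sequin <= 0:
        raise ValidationError("panel sizes must be positive")

    def _panel(mix: str, prefix: str, n: int) -> SpikePanel:
        if n == 1:
            concs = np.array([1.0])
        else:
            concs = 2.0 ** np.linspace(0.0, dynamic_range_log2, n)
        members = tuple(
            (f"{prefix}_{i + 1:03d}", float(c)) for i, c in enumerate(concs)
        )
        return SpikePanel(mix=mix, members=members)

    return _panel("ERCC", "ERCC", n_ercc), _panel("Sequin", "SEQUIN", n_sequin)


def _spike_annotation(panel: SpikePanel) -> pd.DataFrame:
    cls = "spike_ercc" if panel.mix.lower() == "ercc" else "spike_sequin"
    return pd.DataFrame(
        {
            "feature_class": cls,
            "biotype": "spike",
            "chrom_class": "spike",
            "region_class": "not_applicable",
        },
        index=pd.Index(panel.spike_ids, name="feature_id"),
    )


def _noisy_counts(
    mu: np.ndarray, noise: str, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if noise == "none":
        return np.rint(mu).astype(np.int64)  # half-to-even, deterministic
    if noise == "poisson" or (noise == "nb" and dispersion == 0):
        return rng.poisson(mu).astype(np.int64)
    if noise == "nb":
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        return rng.poisson(lam).astype(np.int64)
    raise ValidationError(f"unknown noise model: {noise!r}")


def make_titration(
    design: SpikeDesign | None = None,
    panels: tuple[SpikePanel, SpikePanel] | None = None,
    library_size: int = 1_000_000,
    noise: str = "poisson",
    dispersion: float = 0.0,
    seed: int = 0,
    n_endogenous: int = 2000,
    spike_fraction: float = 0.05,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate the opposing-dilution titration experiment.

    All samples share one endogenous background (the titration aliquots come
    from a single RNA pool); each spike's expected count is proportional to
    its stock concentration times the sample's dilution factor, scaled so
    that each mix consumes ``spike_fraction`` of the library at its highest
    dilution factor. ``noise='none'`` rounds expectations half-to-even;
    ``'poisson'`` and ``'nb'`` (gamma-Poisson with the given overdispersion)
    sample counts.
    """
    if library_size <= 0:
        raise ValidationError("library_size must be positive")
    design = design or default_titration_design()
    if panels is None:
        panels = make_spike_panels(seed=seed)
    rng = np.random.default_rng(seed)

    endo_ids = [f"TITR_G{i + 1:05d}" for i in range(n_endogenous)]
    x = rng.lognormal(mean=0.0, sigma=1.5, size=n_endogenous)
    endo_budget = library_size * (1.0 - 2 * spike_fraction)
    endo_mu = endo_budget * x / x.sum()

    mu_blocks = {s: [endo_mu] for s in design.samples}
    feature_ids = list(endo_ids)
    ann_blocks = [
        pd.DataFrame(
            {
                "feature_class": "endogenous",
                "biotype": "protein_coding",
                "chrom_class": "nuclear",
                "region_class": "exonic",
            },
            index=pd.Index(endo_ids, name="feature_id"),
        )
    ]
    for panel in panels:
        conc = panel.concentrations
        d_max = max(design.dilution_of(panel.mix, s) for s in design.samples)
        kappa = spike_fraction * library_size / (conc.sum() * d_max)
        for s in design.samples:
            d = design.dilution_of(panel.mix, s)
            mu_blocks[s].append(kappa * conc * d)
        feature_ids.extend(panel.spike_ids)
        ann_blocks.append(_spike_annotation(panel))

    counts = {}
    for s in design.samples:
        mu = np.concatenate(mu_blocks[s])
        counts[s] = _noisy_counts(mu, noise, dispersion, rng)
    annotation = pd.concat(ann_blocks)
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id")),
        annotation,
    )
    exp = {
        (mix, a, b): expected_log2fc(design, mix, a, b)
        for mix in design.mixes
        for a in design.samples
        for b in design.samples
        if a != b
    }
    truth = SimulationTruth(seed=seed, design=design, expected_log2fc=exp)
    return cm, truth


def _ipf_gene_weights(
    base: np.ndarray,
    chrom: np.ndarray,
    biotype: np.ndarray,
    chrom_weights: dict[str, float],
    biotype_weights: dict[str, float],
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Rescale gene weights so chromosome and biotype READ fractions match
    the planted targets exactly (iterative proportional fitting on the
    chrom x biotype cell totals)."""
    chroms = sorted(chrom_weights)
    biotypes = sorted(biotype_weights)
    ci = pd.Categorical(chrom, categories=chroms).codes
    bi = pd.Categorical(biotype, categories=biotypes).codes
    cell = np.zeros((len(chroms), len(biotypes)))
    np.add.at(cell, (ci, bi), base)
    row_t = np.array([chrom_weights[c] for c in chroms])
    col_t = np.array([biotype_weights[b] for b in biotypes])
    m = cell.copy()
    for _ in range(max_iter):
        rows = m.sum(axis=1)
        m *= np.where(rows > 0, row_t / np.where(rows > 0, rows, 1.0), 0.0)[:, None]
        cols = m.sum(axis=0)
        m *= np.where(cols > 0, col_t / np.where(cols > 0, cols, 1.0), 0.0)[None, :]
        err = max(
            np.abs(m.sum(axis=1) - row_t).max(), np.abs(m.sum(axis=0) - col_t).max()
        )
        if err < tol:
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(cell > 0, m / np.where(cell > 0, cell, 1.0), 0.0)
    return base * scale[ci, bi]


def _profile_expression(
    profile: BiofluidProfile, rng: np.random.Generator, prefix: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene annotation and normalised expected read shares for one profile.

    Chromosome classes get realistic GENE counts (mitochondrial and rRNA
    genes are few, so mito-heavy fluids concentrate reads on a handful of
    genes, as real platelet-rich plasma does); read fractions are then
    matched to the profile's planted weights exactly.
    """
    n_real = profile.n_genes - round(profile.single_positive_rate * profile.n_genes)
    n_mito = max(10, int(0.005 * n_real)) if profile.chrom_weights.get("mitochondrial", 0) > 0 else 0
    n_rrna = max(5, int(0.003 * n_real)) if profile.chrom_weights.get("rRNA", 0) > 0 else 0
    chrom = np.array(
        ["mitochondrial"] * n_mito
        + ["rRNA"] * n_rrna
        + ["nuclear"] * (n_real - n_mito - n_rrna)
    )
    biotypes = sorted(profile.biotype_weights)
    probs = np.array([profile.biotype_weights[b] for b in biotypes])
    biotype = rng.choice(biotypes, size=n_real, p=probs / probs.sum())
    loc, scale = profile.abundance_shape
    base = rng.lognormal(mean=loc, sigma=scale, size=n_real)
    weights = _ipf_gene_weights(
        base, chrom, biotype, profile.chrom_weights, profile.biotype_weights
    )
    ids = [f"{prefix}_G{i + 1:05d}" for i in range(n_real)]
    ann = pd.DataFrame(
        {
            "feature_class": "endogenous",
            "biotype": biotype,
            "chrom_class": chrom,
            "region_class": "exonic",
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return ann, weights / weights.sum()


def make_replicates(
    profile: BiofluidProfile,
    n_replicates: int = 2,
    library_size: int = 1_000_000,
    seed: int = 0,
    replicate_level: str = "rna_isolation",
    sample_prefix: str | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate technical replicates of one biofluid library.

    Replicates share a true expression vector; counts are negative-binomial
    with the profile's dispersion for ``replicate_level`` (Poisson when 0).
    A planted fraction of genes are single-positive noise: 1-3 counts in
    exactly one replicate, zero elsewhere.
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates")
    if replicate_level not in profile.dispersion:
        raise ValidationError(f"profile has no dispersion for {replicate_level!r}")
    rng = np.random.default_rng(seed)
    prefix = sample_prefix or profile.name
    ann, shares = _profile_expression(profile, rng, prefix)
    mu = library_size * shares
    dispersion = profile.dispersion[replicate_level]
    samples = [f"{prefix}_rep{i + 1}" for i in range(n_replicates)]
    cols = {
        s: _noisy_counts(mu, "nb" if dispersion > 0 else "poisson", dispersion, rng)
        for s in samples
    }

    n_noise = round(profile.single_positive_rate * profile.n_genes)
    if n_noise:
        noise_ids = [f"{prefix}_N{i + 1:05d}" for i in range(n_noise)]
        which = rng.integers(0, n_replicates, size=n_noise)
        vals = rng.integers(1, 4, size=n_noise)
        for j, s in enumerate(samples):
            noise_col = np.where(which == j, vals, 0)
            cols[s] = np.concatenate([cols[s], noise_col])
        noise_ann = pd.DataFrame(
            {
                "feature_class": "endogenous",
                "biotype": "other",
                "chrom_class": "nuclear",
                "region_class": "exonic",
            },
            index=pd.Index(noise_ids, name="feature_id"),
        )
        ann = pd.concat([ann, noise_ann])

    cm = CountMatrix(pd.DataFrame(cols, index=ann.index), ann)
    truth = SimulationTruth(
        seed=seed,
        biotype_fractions=dict(profile.biotype_weights),
        chrom_fractions=dict(profile.chrom_weights),
        expected_counts=pd.DataFrame({"mu": mu}, index=ann.index[: len(mu)]),
    )
    return cm, truth


def make_concentration_samples(
    metas: list[SampleMeta],
    true_concentration: dict[str, float],
    panel: SpikePanel | None = None,
    library_size: int = 1_000_000,
    spike_scale: float = 2500.0,
    n_genes: int = 2000,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate samples with planted relative RNA concentrations.

    Each sample's endogenous read weight is proportional to its true
    concentration times its input volume (ml); its ERCC read weight to
    ``spike_scale`` times its dilution factor. Counts are a Poisson draw at
    ``library_size`` expected reads, so the endogenous:spike ratio corrected
    for dilution and volume recovers concentration ratios.
    """
    if panel is None:
        panel, _ = make_spike_panels(seed=seed)
    rng = np.random.default_rng(seed)
    endo_ids = [f"CONC_G{i + 1:05d}" for i in range(n_genes)]
    x = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    x /= x.sum()
    conc_shares = panel.concentrations / panel.concentrations.sum()

    cols = {}
    for meta in metas:
        c = true_concentration[meta.sample_id]
        if meta.input_volume is None or meta.ercc_dilution is None:
            raise ValidationError(f"sample {meta.sample_id!r} lacks volume or dilution")
        endo_w = c * (meta.input_volume / 1000.0)
        spike_w = spike_scale * meta.ercc_dilution
        total = endo_w + spike_w
        mu = np.concatenate(
            [
                library_size * (endo_w / total) * x,
                library_size * (spike_w / total) * conc_shares,
            ]
        )
        cols[meta.sample_id] = rng.poisson(mu).astype(np.int64)

    ann = pd.concat(
        [
            pd.DataFrame(
                {
                    "feature_class": "endogenous",
                    "biotype": "protein_coding",
                    "chrom_class": "nuclear",
                    "region_class": "exonic",
                },
                index=pd.Index(endo_ids, name="feature_id"),
            ),
            _spike_annotation(panel),
        ]
    )
    cm = CountMatrix(pd.DataFrame(cols, index=ann.index), ann)
    truth = SimulationTruth(seed=seed, true_concentration=dict(true_concentration))
    return cm, truth


def make_assessment_dataset(
    seed: int = 0, library_size: int = 1_300_000
) -> dict:
    """One combined dataset exercising every pipeline stage.

    Five titration samples (T1-T5, both spike panels, Poisson noise) plus
    replicate pairs of three biofluid presets (ePRP, ePFP, urine) carrying
    ERCC spikes, merged over a common feature universe (absent features are
    zero). Returns counts, design, per-sample metadata, replicate pairs and
    the simulation truths.
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)]
    design = default_titration_design()
    panels = make_spike_panels(seed=seeds[0])
    titr_cm, titr_truth = make_titration(
        design, panels, library_size=library_size, noise="poisson", seed=seeds[0]
    )
    ercc_panel = panels[0]

    blocks = [titr_cm]
    truths = {"titration": titr_truth}
    metas: dict[str, SampleMeta] = {}
    pairs: list[tuple[str, str]] = []
    for i, name in enumerate(("ePRP", "ePFP", "urine")):
        profile = PRESET_PROFILES[name]
        rep_cm, rep_truth = make_replicates(
            profile, n_replicates=2, library_size=library_size, seed=seeds[i + 1]
        )
        # add ERCC spikes (5% of the library) so concentration can run
        rng = np.random.default_rng(seeds[i + 1] + 1)
        spike_mu = 0.05 * library_size * ercc_panel.concentrations / ercc_panel.concentrations.sum()
        spike_counts = {
            s: rng.poisson(spike_mu).astype(np.int64) for s in rep_cm.samples
        }
        spike_cm = CountMatrix(
            pd.DataFrame(
                spike_counts, index=pd.Index(ercc_panel.spike_ids, name="feature_id")
            ),
            _spike_annotation(ercc_panel),
        )
        merged = CountMatrix(
            pd.concat([rep_cm.counts, spike_cm.counts]),
            pd.concat([rep_cm.annotation, spike_cm.annotation]),
        )
        blocks.append(merged)
        truths[name] = rep_truth
        pairs.append(tuple(rep_cm.samples[:2]))
        for j, s in enumerate(rep_cm.samples):
            metas[s] = SampleMeta(
                sample_id=s,
                fluid=name,
                replicate_group=name,
                replicate_level="rna_isolation",
                input_volume=200.0,
                ercc_dilution=1 / 25000,
            )

    counts = pd.concat([b.counts for b in blocks], axis=1).fillna(0).astype(np.int64)
    annotation = pd.concat([b.annotation for b in blocks])
    annotation = annotation[~annotation.index.duplicated(keep="first")]
    cm = CountMatrix(counts, annotation.loc[counts.index])
    for s in design.samples:
        metas[s] = SampleMeta(
            sample_id=s,
            fluid="ePFP",
            replicate_group="titration",
            input_volume=200.0,
            ercc_dilution=design.dilution_of("ERCC", s),
            sequin_dilution=design.dilution_of("Sequin", s),
        )
    return {
        "counts": cm,
        "design": design,
        "meta": metas,
        "pairs": pairs,
        "truths": truths,
        "panels": panels,
    }
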