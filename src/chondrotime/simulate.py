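"""Synthetic replicated time-course expression data with planted profiles.

The generator emulates a small chondrogenic-differentiation style microarray
experiment: 6 weekly time points, 2 replicate arrays each, log2 intensities.
Every probe gets a baseline level drawn once (so a dominant "general level"
component exists), an optional planted time trend, and additive Gaussian
array noise.  Planted trends come in four classes matching the four temporal
subgroups the selection procedure reports:

* ``sustained_increase`` / ``sustained_decrease`` — linear in the time-point
  index, scaled so the peak-to-trough amplitude equals ``effect_size``;
* ``transient_peak`` / ``transient_dip`` — a symmetric triangular excursion
  over the interior time points, zero at both endpoints, amplitude
  ``effect_size``;
* ``flat`` — no trend (the null class).

A truth table records each probe's class, effect size and gene symbol (a
configurable fraction of probes is left unannotatable), enabling recovery
experiments against the selection pipeline.  Companion generators emit GMT
gene-set collections with optional planted enrichment and qPCR plates with
known fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .io import TimeCourseDesign
from .qpcr import QpcrPlate

__all__ = [
    "PROFILE_CLASSES",
    "PlantedBlock",
    "SimulationConfig",
    "profile_curve",
    "generate_dataset",
    "generate_genesets",
    "generate_qpcr",
]

PROFILE_CLASSES = (
    "flat",
    "sustained_increase",
    "sustained_decrease",
    "transient_peak",
    "transient_dip",
)


@dataclass(frozen=True)
class PlantedBlock:
    """A block of probes sharing one planted temporal profile."""

    profile_class: str
    n_probes: int
    effect_size: float  # log2 units, peak-to-trough amplitude

    def __post_init__(self) -> None:
        if self.profile_class not in PROFILE_CLASSES:
            raise ValueError(
                f"unknown profile_class {self.profile_class!r}; "
                f"choose from {PROFILE_CLASSES}"
            )
        if self.n_probes < 0:
            raise ValueError("n_probes must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.profile_class == "flat" and self.effect_size != 0:
            raise ValueError("flat blocks must have effect_size = 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of one synthetic experiment.

    Defaults mirror a 6-week, duplicate-array design with between-probe
    baseline spread (2.0 log2 units) well above replicate noise (0.25 log2
    units) and a quarter of probes unannotatable.
    """

    n_probes: int = 20_000
    n_timepoints: int = 6
    n_replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    planted: tuple[PlantedBlock, ...] = field(default_factory=tuple)
    frac_unannotated: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.n_replicates < 2:
            raise ValueError(
                "n_replicates must be >= 2: the replicate-based significance "
                "filter requires replication at every time point"
            )
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.frac_unannotated <= 1.0:
            raise ValueError("frac_unannotated must lie in [0, 1]")
        n_planted = sum(b.n_probes for b in self.planted)
        if n_planted > self.n_probes:
            raise ValueError(
                f"planted blocks cover {n_planted} probes but n_probes={self.n_probes}"
            )

    @classmethod
    def from_dict(cls, spec: dict) -> "SimulationConfig":
        spec = dict(spec)
        blocks = tuple(PlantedBlock(**b) for b in spec.pop("planted", []))
        return cls(planted=blocks, **spec)


def profile_curve(
    profile_class: str, n_timepoints: int, effect_size: float
) -> np.ndarray:
    """Expected deviation from baseline at each time point (log2 units)."""
    if profile_class not in PROFILE_CLASSES:
        raise ValueError(f"unknown profile_class {profile_class!r}")
    t = np.arange(n_timepoints, dtype=float)
    if profile_class == "flat":
        return np.zeros(n_timepoints)
    if profile_class in ("sustained_increase", "sustained_decrease"):
        ramp = t / (n_timepoints - 1) - 0.5  # -1/2 .. +1/2
        curve = effect_size * ramp
        return curve if profile_class == "sustained_increase" else -curve
    # transient: symmetric triangle, zero at both endpoints
    centre = (n_timepoints - 1) / 2.0
    tri = np.maximum(0.0, 1.0 - np.abs(t - centre) / centre)
    tri = tri / tri.max() * effect_size
    return tri if profile_class == "transient_peak" else -tri


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TimeCourseDesign, pd.Series, pd.DataFrame]:
    """Simulate one experiment.

    Returns ``(expression, design, annotation, truth)``: a probes x samples
    log2 matrix, the replicated design, a probe -> gene-symbol Series (<NA>
    for unannotatable probes) and the truth table (``profile_class``,
    ``effect_size``, ``gene_symbol`` per probe).  Identical config (the seed
    included) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T, R = config.n_probes, config.n_timepoints, config.n_replicates

    classes = np.full(n, "flat", dtype=object)
    effects = np.zeros(n)
    start = 0
    for block in config.planted:
        stop = start + block.n_probes
        classes[start:stop] = block.profile_class
        effects[start:stop] = block.effect_size
        start = stop

    curves = {
        (cls, eff): profile_curve(cls, T, eff)
        for cls, eff in set(zip(classes, effects))
    }
    trend = np.vstack([curves[(c, e)] for c, e in zip(classes, effects)])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    design = TimeCourseDesign.from_layout(T, R)
    sample_tp = design.timepoint_of().to_numpy()
    mean_profile = baseline[:, None] + trend  # probes x timepoints
    noise = rng.normal(0.0, config.noise_sd, size=(n, T * R))
    values = mean_profile[:, sample_tp] + noise

    digits = max(6, len(str(n)))
    probe_ids = pd.Index(
        [f"PROBE_{i + 1:0{digits}d}" for i in range(n)], name="probe_id"
    )
    em = pd.DataFrame(values, index=probe_ids, columns=design.sample_ids)

    symbols = np.array([f"GENE{i + 1:06d}" for i in range(n)], dtype=object)
    n_unannotated = int(round(config.frac_unannotated * n))
    unannotated = rng.choice(n, size=n_unannotated, replace=False)
    symbols[unannotated] = None

    truth = pd.DataFrame(
        {
            "profile_class": classes,
            "effect_size": effects,
            "gene_symbol": symbols,
        },
        index=probe_ids,
    )
    annotation = truth["gene_symbol"].astype("string")
    return em, design, annotation, truth


def generate_genesets(
    truth: pd.DataFrame,
    n_sets: int,
    enrichment_factor: float,
    seed: int,
    set_size: int = 50,
    n_enriched: int | None = None,
) -> GeneSetCollection:
    """Random gene sets over the annotated genes of a truth table.

    ``n_enriched`` sets (default: a fifth of ``n_sets`` when the factor
    exceeds 1) oversample genes of planted non-flat probes with sampling
    weight ``enrichment_factor``; the rest ("decoy" sets) draw uniformly.
    With ``enrichment_factor = 1`` all sets are plain random draws.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    annotated = truth[truth["gene_symbol"].notna()]
    if annotated.empty:
        raise ValueError("truth table has no annotated genes")
    genes = annotated["gene_symbol"].to_numpy(dtype=object)
    planted = (annotated["profile_class"] != "flat").to_numpy()

    if n_enriched is None:
        n_enriched = 0 if enrichment_factor == 1 else max(1, n_sets // 5)
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    set_size = min(set_size, genes.size)

    rng = np.random.default_rng(seed)
    weights = np.where(planted, enrichment_factor, 1.0)
    weights = weights / weights.sum()
    uniform = np.full(genes.size, 1.0 / genes.size)

    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        enriched = i < n_enriched
        name = f"{'enriched' if enriched else 'decoy'}_{i + 1:02d}"
        members = rng.choice(
            genes, size=set_size, replace=False, p=weights if enriched else uniform
        )
        sets[name] = tuple(sorted(members))
        descriptions[name] = (
            "oversamples planted-profile genes" if enriched else "uniform random draw"
        )
    return GeneSetCollection(sets, descriptions)


def generate_qpcr(
    n_targets: int,
    fold_changes,
    ct_ref: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> QpcrPlate:
    """Simulate a qPCR plate whose expected 2^-ddCt equals ``fold_changes``.

    Each target gene gets triplicate (by default) Ct values in a calibrator
    sample (``baseline``) and a ``treated`` sample whose target Ct is
    shifted by -log2(fold change); the reference gene ``REF`` sits at
    ``ct_ref`` cycles in both samples.  Gaussian noise of ``noise_sd``
    cycles is added per well.
    """
    fcs = np.asarray(fold_changes, dtype=float)
    if fcs.ndim != 1 or fcs.size == 0:
        raise ValueError("fold_changes must be a non-empty 1-D sequence")
    if (fcs <= 0).any():
        raise ValueError("all fold_changes must be positive")
    if fcs.size == 1:
        fcs = np.repeat(fcs, n_targets)
    if fcs.size != n_targets:
        raise ValueError(
            f"got {fcs.size} fold changes for {n_targets} targets"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-2.0, 2.0, size=n_targets)
    rows = []

    def add(target: str, sample: str, level: float) -> None:
        for r in range(1, n_replicates + 1):
            rows.append(
                (target, sample, r, level + rng.normal(0.0, noise_sd))
            )

    for i in range(n_targets):
        target = f"T{i + 1:02d}"
        base_ct = ct_ref + offsets[i]
        add(target, "baseline", base_ct)
        add(target, "treated", base_ct - np.log2(fcs[i]))
    add("REF", "baseline", ct_ref)
    add("REF", "treated", ct_ref)

    data = pd.DataFrame(rows, columns=["target", "sample", "replicate", "ct"])
    return QpcrPlate(data=data, reference_gene="REF", calibrator="baseline")
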