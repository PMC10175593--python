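"""Synthetic four-block sensor panels with known ground truth.

The generator emulates the statistical structure the fusion analysis
assumes: nonnegative gas/taste sensor responses whose class means
differ only on a small set of planted variables, a sparse color-number
histogram for the electronic eye, and smooth NIR spectra built from a
linear baseline plus Gaussian peaks, some of which carry
class-dependent amplitudes. Each sample is measured in replicate and
the replicates are averaged into the analysis matrix, as the
instruments' protocols do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    AUTHENTIC,
    AUTHENTIC_SPECIES,
    COUNTERFEIT,
    FusionDataset,
    LabelTable,
    SensorBlock,
    assemble_dataset,
)
from .data_model import DataError
from .preprocessing import average_replicates

EN_SENSORS = ("W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S")
ET_SENSORS = ("Sourness", "Bitterness", "Astringency", "Aftertaste-B",
              "Aftertaste-A", "Umami")


@dataclass(frozen=True)
class SimConfig:
    """Panel-generation settings.

    Effect size ``delta`` is the spread of class means on a planted
    variable in units of the single-replicate noise standard deviation.
    Defaults mirror the study design: 4 classes x 20 samples, blocks of
    10 / 6 / 65 variables plus a 2075-point NIR grid spanning
    12,000-4,000 cm^-1, 3 replicates per sample.
    """

    n_per_class: int = 20
    classes: tuple[str, ...] = ("FU", "FP", "FD", "FUS")
    replicates: int = 3
    delta: float = 3.0

    en_vars: int = 10
    en_informative: int = 5
    et_vars: int = 6
    et_informative: int = 3
    ee_vars: int = 65
    ee_informative: int = 10

    nir_points: int = 2075
    nir_max_wavenumber: float = 12_000.0
    nir_min_wavenumber: float = 4_000.0
    nir_peaks: int = 12
    nir_informative_peaks: int = 5
    nir_peak_width: float = 120.0       # Gaussian sigma, cm^-1
    nir_noise_sd: float = 0.01
    nir_peak_amplitude: float = 0.5

    en_noise_sd: float = 1.0
    et_noise_sd: float = 1.0
    ee_noise_sd: float = 1.0
    en_baseline: float = 10.0
    et_baseline: float = 10.0
    ee_baseline: float = 8.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise DataError("delta must be >= 0")
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")
        for p, k, tag in ((self.en_vars, self.en_informative, "EN"),
                          (self.et_vars, self.et_informative, "ET"),
                          (self.ee_vars, self.ee_informative, "EE")):
            if k > p:
                raise DataError(f"{tag}: more planted variables than variables")
        if self.nir_informative_peaks > self.nir_peaks:
            raise DataError("NIR: more informative peaks than peaks")
        if self.nir_peak_width <= 0:
            raise DataError("NIR peak width must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated panel."""

    informative: dict[str, tuple[int, ...]]     # per-block variable indices
    class_means: dict[str, np.ndarray]          # per-block (g, p) mean table
    nir_peak_centers: tuple[float, ...] = ()
    nir_informative_centers: tuple[float, ...] = ()
    seed: int = 0


def _class_levels(classes: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    """Per-class offsets with unit spread.

    The counterfeit class(es) take the extreme offsets (random sign),
    the authentic congeners share the remaining levels in random order:
    a counterfeit of a different species is more distinct from every
    authentic class than the authentic classes are from each other,
    which keeps planted variables discriminative for both the species
    and the authenticity task.
    """
    g = len(classes)
    levels = np.linspace(-0.5, 0.5, g)
    by_magnitude = np.argsort(-np.abs(levels))
    fake = [k for k, c in enumerate(classes) if c not in AUTHENTIC_SPECIES]
    real = [k for k, c in enumerate(classes) if c in AUTHENTIC_SPECIES]
    out = np.empty(g)
    out[rng.permutation(fake).tolist()] = levels[by_magnitude[: len(fake)]]
    out[rng.permutation(real).tolist()] = levels[by_magnitude[len(fake):]]
    return out


def _sensor_block(
    source: str,
    var_names: tuple[str, ...],
    n_informative: int,
    baseline: float,
    noise_sd: float,
    cfg: SimConfig,
    labels: list[str],
    sample_ids: list[str],
    rng: np.random.Generator,
    sparse: bool = False,
) -> tuple[SensorBlock, tuple[int, ...], np.ndarray]:
    """One intelligent-sensor block with replicate rows averaged."""
    p = len(var_names)
    g = len(cfg.classes)
    informative = tuple(sorted(rng.choice(p, size=n_informative, replace=False).tolist()))
    class_index = {c: k for k, c in enumerate(cfg.classes)}
    means = np.zeros((g, p))
    if sparse:
        # sparse histogram: most bins sit near zero, a few carry signal
        means += 0.05 * baseline
        means[:, informative] = baseline
    else:
        means += baseline
    for j in informative:
        means[:, j] += cfg.delta * noise_sd * _class_levels(cfg.classes, rng)

    rep_ids, rep_rows, rep_map = [], [], {}
    for sid, lab in zip(sample_ids, labels):
        sample_level = means[class_index[lab]]
        ids = [f"{sid}-{r + 1}" for r in range(cfg.replicates)]
        rep_map[sid] = ids
        for rid in ids:
            row = sample_level + rng.normal(0.0, noise_sd, size=p)
            rep_ids.append(rid)
            rep_rows.append(np.clip(row, 0.0, None))   # responses are nonnegative
    reps = SensorBlock(source=source, sample_ids=tuple(rep_ids),
                       var_names=var_names, values=np.vstack(rep_rows))
    return average_replicates(reps, rep_map), informative, means


def generate_nir(
    cfg: SimConfig,
    labels: list[str],
    sample_ids: list[str],
    rng: np.random.Generator,
) -> tuple[SensorBlock, tuple[int, ...], np.ndarray, tuple[float, ...], tuple[float, ...]]:
    """Smooth synthetic spectra: baseline + Gaussian peaks + noise.

    Informative grid points lie within one FWHM of a peak whose
    amplitude is class-dependent.
    """
    grid = np.linspace(cfg.nir_max_wavenumber, cfg.nir_min_wavenumber, cfg.nir_points)
    margin = 2 * cfg.nir_peak_width
    lo, hi = cfg.nir_min_wavenumber + margin, cfg.nir_max_wavenumber - margin
    centers = np.sort(rng.uniform(lo, hi, size=cfg.nir_peaks))[::-1]
    if not ((centers >= cfg.nir_min_wavenumber) & (centers <= cfg.nir_max_wavenumber)).all():
        raise DataError("peak centers must lie within the wavenumber grid")
    informative_peaks = np.sort(
        rng.choice(cfg.nir_peaks, size=cfg.nir_informative_peaks, replace=False))
    g = len(cfg.classes)
    class_index = {c: k for k, c in enumerate(cfg.classes)}

    # per-class amplitude for every peak; informative peaks spread by delta
    base_amp = np.full(cfg.nir_peaks, cfg.nir_peak_amplitude)
    amp = np.tile(base_amp, (g, 1))
    for jp in informative_peaks:
        amp[:, jp] += cfg.delta * cfg.nir_noise_sd * _class_levels(cfg.classes, rng)

    shapes = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / cfg.nir_peak_width) ** 2)
    baseline = 0.1 + 0.05 * (grid - grid.min()) / (grid.max() - grid.min())
    class_means = amp @ shapes + baseline          # (g, p)

    rep_ids, rep_rows, rep_map = [], [], {}
    for sid, lab in zip(sample_ids, labels):
        level = class_means[class_index[lab]]
        ids = [f"{sid}-{r + 1}" for r in range(cfg.replicates)]
        rep_map[sid] = ids
        for rid in ids:
            rep_ids.append(rid)
            rep_rows.append(level + rng.normal(0.0, cfg.nir_noise_sd, size=cfg.nir_points))
    var_names = tuple(f"{w:.2f}" for w in grid)
    reps = SensorBlock(source="NIR", sample_ids=tuple(rep_ids),
                       var_names=var_names, values=np.vstack(rep_rows))
    block = average_replicates(reps, rep_map)

    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * cfg.nir_peak_width
    informative_centers = centers[informative_peaks]
    mask = np.zeros(cfg.nir_points, dtype=bool)
    for c in informative_centers:
        mask |= np.abs(grid - c) <= fwhm
    informative = tuple(int(j) for j in np.flatnonzero(mask))
    return (block, informative, class_means,
            tuple(float(c) for c in centers),
            tuple(float(c) for c in informative_centers))


def generate_panel(
    cfg: SimConfig | None = None,
    *,
    task: str = "species",
    blocks: tuple[str, ...] = ("EN", "ET", "EE", "NIR"),
) -> tuple[FusionDataset, GroundTruth]:
    """Generate an aligned multi-block panel plus its ground truth.

    The same seed and config always reproduce the same panel.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    g = len(cfg.classes)
    n = g * cfg.n_per_class
    sample_ids = [f"S{i + 1}" for i in range(n)]
    species = [cfg.classes[i // cfg.n_per_class] for i in range(n)]
    authenticity = [AUTHENTIC if s in AUTHENTIC_SPECIES else COUNTERFEIT for s in species]
    labels = LabelTable(sample_ids=tuple(sample_ids),
                        authenticity=tuple(authenticity),
                        species=tuple(species))

    made: list[SensorBlock] = []
    informative: dict[str, tuple[int, ...]] = {}
    class_means: dict[str, np.ndarray] = {}
    nir_centers: tuple[float, ...] = ()
    nir_inf_centers: tuple[float, ...] = ()

    if "EN" in blocks:
        blk, inf, mu = _sensor_block(
            "EN", EN_SENSORS[: cfg.en_vars], cfg.en_informative, cfg.en_baseline,
            cfg.en_noise_sd, cfg, species, sample_ids, rng)
        made.append(blk); informative["EN"] = inf; class_means["EN"] = mu
    if "ET" in blocks:
        blk, inf, mu = _sensor_block(
            "ET", ET_SENSORS[: cfg.et_vars], cfg.et_informative, cfg.et_baseline,
            cfg.et_noise_sd, cfg, species, sample_ids, rng)
        made.append(blk); informative["ET"] = inf; class_means["ET"] = mu
    if "EE" in blocks:
        names = tuple(f"cnv{1500 + 40 * j}" for j in range(cfg.ee_vars))
        blk, inf, mu = _sensor_block(
            "EE", names, cfg.ee_informative, cfg.ee_baseline,
            cfg.ee_noise_sd, cfg, species, sample_ids, rng, sparse=True)
        made.append(blk); informative["EE"] = inf; class_means["EE"] = mu
    if "NIR" in blocks:
        blk, inf, mu, nir_centers, nir_inf_centers = generate_nir(
            cfg, species, sample_ids, rng)
        made.append(blk); informative["NIR"] = inf; class_means["NIR"] = mu

    dataset = assemble_dataset(made, labels, task)
    truth = GroundTruth(
        informative=informative,
        class_means=class_means,
        nir_peak_centers=nir_centers,
        nir_informative_centers=nir_inf_centers,
        seed=cfg.seed,
    )
    return dataset, truth
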