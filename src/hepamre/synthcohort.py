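"""Synthetic study inputs with the statistical structure the analysis assumes.

Generates (i) proteome profiles with log-normal inter-animal variability and
a two-cluster pathway-level structure, (ii) damped plane shear-wave fields
with prescribed per-frequency shear wave speed and penetration rate plus
complex Gaussian noise, (iii) uniform-uptake PET phantoms with known
dose/decay metadata, and (iv) whole-cohort bundles with a truth record
sufficient to score every downstream estimate.  The forward wave model is a
superposition of damped plane waves — the same local model the inversion
assumes — with amplitude ~ exp(-kappa'' s), phase 2*pi*f/SWS * s and
kappa'' = f/PR along the propagation coordinate s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .liverkin.model import ProteomeProfile, ReferenceModelSpec, build_reference_model
from .petsuv import PETInput
from .waveinv import N_PHASE_OFFSETS, PhaseOffsetSeries, WaveFieldSet, wrap_phase

__all__ = [
    "SyntheticTruth",
    "CohortConfig",
    "CohortBundle",
    "gen_proteomes",
    "gen_wavefield",
    "phase_encode",
    "gen_pet_phantom",
    "gen_cohort",
    "liver_mask",
]

# Pathway-level multiplicative shifts defining the two metabolic clusters:
# cluster 1 has the more active fatty-acid / ketone metabolism, cluster 2 the
# higher biosynthetic (gluconeogenic, lipogenic, cholesterogenic) capacity.
DEFAULT_CLUSTER_SPEC: dict[str, float] = {
    "fatty_acid_uptake": 0.2,
    "triglyceride_synthesis": 0.2,
    "lipid_droplet_turnover": 0.2,
    "beta_oxidation": 0.2,
    "ketone_body_synthesis": 0.2,
    "vldl_synthesis": 0.2,
    "gluconeogenesis": -0.2,
    "fatty_acid_synthesis": -0.2,
    "cholesterol_synthesis": -0.2,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery scoring."""

    seed: int
    cluster_labels: tuple[int, ...] = ()
    true_sws_per_freq: Mapping[float, float] = field(default_factory=dict)
    true_pr: float | None = None
    true_abundance_means: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    noise_cv: float = 0.0
    snr: float | None = None

    def __post_init__(self):
        if any(v <= 0 for v in self.true_sws_per_freq.values()):
            raise ValueError("true SWS values must be positive")
        if self.true_pr is not None and self.true_pr <= 0:
            raise ValueError("true PR must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def _lognormal_around(rng: np.random.Generator, mean: np.ndarray, cv: float, size):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.broadcast_to(mean, size).copy()
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def gen_proteomes(
    n_samples: int,
    cluster_spec: Mapping[str, float] | None = None,
    cv: float = 0.1,
    seed: int = 0,
    model: ReferenceModelSpec | None = None,
) -> tuple[list[ProteomeProfile], SyntheticTruth]:
    """Per-sample enzyme abundance ratios with two-cluster structure.

    Samples alternate between clusters 1 and 2.  An enzyme of a pathway with
    effect ``e`` has cluster means 1+e (cluster 1) and 1-e (cluster 2); every
    other enzyme has mean 1.  Abundances are i.i.d. log-normal around the
    cluster mean with common coefficient of variation ``cv``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    model = model or build_reference_model()
    spec = dict(DEFAULT_CLUSTER_SPEC if cluster_spec is None else cluster_spec)
    pathways = set(r.pathway for r in model.reactions)
    unknown = sorted(set(spec) - pathways)
    if unknown:
        raise ValueError(f"cluster_spec names unknown pathway(s): {unknown}")
    if any(abs(e) >= 1 for e in spec.values()):
        raise ValueError("pathway effects must lie in (-1, 1)")
    enzymes = sorted({r.enzyme for r in model.reactions})
    enzyme_pathway = {r.enzyme: r.pathway for r in model.reactions}
    cluster_means = {}
    for label, sign in ((1, +1.0), (2, -1.0)):
        cluster_means[label] = {
            e: 1.0 + sign * spec.get(enzyme_pathway[e], 0.0) for e in enzymes
        }
    rng = np.random.default_rng(seed)
    labels = tuple(1 + (i % 2) for i in range(n_samples))
    profiles = []
    for i, label in enumerate(labels):
        means = np.array([cluster_means[label][e] for e in enzymes])
        draws = _lognormal_around(rng, means, cv, means.shape)
        profiles.append(
            ProteomeProfile(
                sample_id=f"S{i + 1:02d}",
                ratios=dict(zip(enzymes, draws.tolist())),
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        cluster_labels=labels,
        true_abundance_means=cluster_means,
        noise_cv=cv,
    )
    return profiles, truth


def gen_wavefield(
    shape: tuple[int, int, int] = (2, 48, 48),
    spacing_mm: tuple[float, float, float] = (5.0, 2.0, 2.0),
    frequencies_hz: Sequence[float] = (40.0, 50.0, 60.0, 70.0, 80.0),
    sws_true: float | Mapping[float, float] = 1.6,
    pr_true: float = 1.0,
    directions: Sequence[tuple[float, float]] = ((1.0, 0.0), (-1.0, 0.0)),
    snr: float | None = None,
    seed: int = 0,
    encoding_directions: Sequence[str] = ("HF",),
) -> tuple[WaveFieldSet, SyntheticTruth]:
    """Superposed damped plane waves at the requested SWS(f) and PR.

    ``directions`` are in-plane propagation unit vectors (x, y); the
    propagation coordinate starts at zero on the entry side of the field of
    view so the noiseless amplitude at distance s is exp(-kappa'' s) with
    kappa'' = f/PR (``pr_true=numpy.inf`` switches attenuation off).  Complex
    white Gaussian noise is added at the stated power SNR.
    """
    if pr_true <= 0:
        raise ValueError("true PR must be positive")
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacing must be positive")
    if len(directions) == 0:
        raise ValueError("at least one propagation direction required")
    sws_map = (
        dict(sws_true)
        if isinstance(sws_true, Mapping)
        else {float(f): float(sws_true) for f in frequencies_hz}
    )
    if any(c <= 0 for c in sws_map.values()):
        raise ValueError("true SWS must be positive")
    nz, ny, nx = shape
    y = np.arange(ny) * spacing_mm[1] * 1e-3
    x = np.arange(nx) * spacing_mm[2] * 1e-3
    yy, xx = np.meshgrid(y, x, indexing="ij")
    rng = np.random.default_rng(seed)
    fields = np.zeros((len(frequencies_hz), len(encoding_directions), nz, ny, nx), complex)
    for fi, f in enumerate(frequencies_hz):
        c = sws_map[float(f)]
        kappa = 0.0 if np.isinf(pr_true) else f / pr_true
        k_rad = 2.0 * np.pi * f / c
        slice_field = np.zeros((ny, nx), complex)
        for dx, dy in directions:
            norm = np.hypot(dx, dy)
            s = (xx * dx + yy * dy) / norm
            s = s - s.min()
            slice_field += np.exp(1j * k_rad * s) * np.exp(-kappa * s)
        for ei in range(len(encoding_directions)):
            fields[fi, ei] = slice_field  # same in-plane pattern in each slice
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("SNR must be positive")
        p_sig = np.mean(np.abs(fields) ** 2)
        sigma = np.sqrt(p_sig / snr / 2.0)
        noise = sigma * (
            rng.standard_normal(fields.shape) + 1j * rng.standard_normal(fields.shape)
        )
        fields = fields + noise
    wfs = WaveFieldSet(
        fields=fields,
        frequencies_hz=tuple(float(f) for f in frequencies_hz),
        voxel_spacing_mm=tuple(float(s) for s in spacing_mm),
        encoding_directions=tuple(encoding_directions),
    )
    truth = SyntheticTruth(
        seed=seed,
        true_sws_per_freq=sws_map,
        true_pr=None if np.isinf(pr_true) else float(pr_true),
        snr=snr,
    )
    return wfs, truth


def phase_encode(wfs: WaveFieldSet, amplitude_rad: float = 1.0) -> list[PhaseOffsetSeries]:
    """Synthesise wrapped phase-offset series from a complex field set.

    Offset t of the cycle holds wrap(Re(u * exp(2j*pi*t/8)) * amplitude_rad);
    for amplitudes that stay below pi the temporal-harmonic extraction is the
    exact inverse up to the amplitude scaling.
    """
    if not np.all(np.isfinite(wfs.fields)):
        raise ValueError("wave field contains non-finite values")
    out = []
    t = np.arange(N_PHASE_OFFSETS)
    phases = np.exp(2j * np.pi * t / N_PHASE_OFFSETS)
    for fi, f in enumerate(wfs.frequencies_hz):
        for ei, enc in enumerate(wfs.encoding_directions):
            u = wfs.fields[fi, ei]
            images = np.stack(
                [wrap_phase(np.real(u * ph) * amplitude_rad) for ph in phases]
            )
            out.append(
                PhaseOffsetSeries(
                    images=images,
                    frequency_hz=f,
                    direction=enc,
                    voxel_spacing_mm=wfs.voxel_spacing_mm,
                )
            )
    return out


def gen_pet_phantom(
    shape: tuple[int, int, int] = (2, 48, 48),
    uptake_kbq_per_ml: float | np.ndarray = 2.0,
    weight_kg: float = 3.0,
    injected_mbq: float = 6.0,
    delay_min: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PETInput:
    """Uniform (or user-shaped) activity phantom with carried-over metadata."""
    if weight_kg <= 0 or injected_mbq <= 0:
        raise ValueError("dose and weight must be positive")
    if delay_min < 0:
        raise ValueError("delay must be non-negative")
    activity = np.broadcast_to(np.asarray(uptake_kbq_per_ml, dtype=float), shape).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = np.clip(activity + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return PETInput(
        activity_kbq_per_ml=activity,
        weight_kg=weight_kg,
        injected_dose_mbq=injected_mbq,
        delay_min=delay_min,
    )


def liver_mask(shape: tuple[int, int, int], margin: int = 10) -> np.ndarray:
    """Elliptical in-plane ROI clear of the field-of-view borders."""
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ry, rx = ny / 2.0 - margin, nx / 2.0 - margin
    ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return np.broadcast_to(ellipse, shape).copy()


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the rabbit study: 19 animals, PET in a 10-animal subset,
    vibration frequencies 40-80 Hz, cohort-level SWS/PR/SUV/weight/glucose
    moments matching the published descriptive statistics, and a two-cluster
    proteome structure.  ``pr_cluster_effect_sd`` separates the two metabolic
    clusters' mean PR by that many PR standard deviations.
    """

    n_samples: int = 19
    cluster_spec: Mapping[str, float] | None = None
    abundance_cv: float = 0.1
    frequencies_hz: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0)
    shape: tuple[int, int, int] = (2, 48, 48)
    spacing_mm: tuple[float, float, float] = (5.0, 2.0, 2.0)
    snr: float | None = 20.0
    with_imaging: bool = False
    pet_subset: int = 10
    sws_mean: float = 1.59
    sws_sd: float = 0.10
    pr_mean: float = 0.99
    pr_sd: float = 0.11
    pr_cluster_effect_sd: float = 0.0
    suv_mean: float = 2.72
    suv_sd: float = 0.27
    weight_mean_kg: float = 3.23
    weight_sd_kg: float = 0.26
    bg_mean_mg_dl: float = 153.0
    bg_sd_mg_dl: float = 24.0
    delay_min: float = 30.0


@dataclass(frozen=True)
class CohortBundle:
    proteomes: list[ProteomeProfile]
    cohort: pd.DataFrame  # per-animal id, weight, bg, true sws/pr/suv, cluster
    truth: SyntheticTruth
    wavefields: dict[str, WaveFieldSet]
    pet_inputs: dict[str, PETInput]
    masks: dict[str, np.ndarray]
    config: CohortConfig


def gen_cohort(n: int | None = None, config: CohortConfig | None = None, seed: int = 0):
    """One consistent synthetic study bundle (proteomes, truth, images).

    Per-sample true SWS and PR are drawn around the cohort means; when
    ``pr_cluster_effect_sd`` is non-zero the PR means of the two metabolic
    clusters are separated by that many SD, tying viscosity to metabolism as
    the analysis probes.  Imaging (wave fields and PET phantoms) is only
    synthesised when ``config.with_imaging`` is set; the truth record always
    suffices for statistics-level recovery tests.
    """
    config = config or CohortConfig()
    if n is not None and n != config.n_samples:
        config = CohortConfig(**{**config.__dict__, "n_samples": int(n)})
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    profiles, ptruth = gen_proteomes(
        config.n_samples,
        cluster_spec=config.cluster_spec,
        cv=config.abundance_cv,
        seed=int(rng.integers(2**31 - 1)),
    )
    labels = np.array(ptruth.cluster_labels)
    sws = rng.normal(config.sws_mean, config.sws_sd, config.n_samples)
    offset = 0.5 * config.pr_cluster_effect_sd * config.pr_sd
    pr_mu = np.where(labels == 1, config.pr_mean - offset, config.pr_mean + offset)
    pr = rng.normal(pr_mu, config.pr_sd)
    sws = np.clip(sws, 0.5, None)
    pr = np.clip(pr, 0.2, None)
    suv = np.clip(rng.normal(config.suv_mean, config.suv_sd, config.n_samples), 0.1, None)
    weight = np.clip(
        rng.normal(config.weight_mean_kg, config.weight_sd_kg, config.n_samples), 1.0, None
    )
    bg = np.clip(
        rng.normal(config.bg_mean_mg_dl, config.bg_sd_mg_dl, config.n_samples), 30.0, None
    )
    pet_members = [p.sample_id for p in profiles[: config.pet_subset]]
    cohort = pd.DataFrame(
        {
            "id": [p.sample_id for p in profiles],
            "weight_kg": weight,
            "bg_mg_dl": bg,
            "sws_m_s": sws,
            "pr_m_s": pr,
            "suv": [
                s if p.sample_id in pet_members else np.nan
                for s, p in zip(suv, profiles)
            ],
            "cluster": labels,
        }
    )
    wavefields: dict[str, WaveFieldSet] = {}
    pet_inputs: dict[str, PETInput] = {}
    masks: dict[str, np.ndarray] = {}
    if config.with_imaging:
        for i, p in enumerate(profiles):
            wfs, _ = gen_wavefield(
                shape=config.shape,
                spacing_mm=config.spacing_mm,
                frequencies_hz=config.frequencies_hz,
                sws_true=float(sws[i]),
                pr_true=float(pr[i]),
                snr=config.snr,
                seed=int(rng.integers(2**31 - 1)),
            )
            wavefields[p.sample_id] = wfs
            masks[p.sample_id] = liver_mask(config.shape)
            if p.sample_id in pet_members:
                dose = 75.0 * weight[i] / 3.23
                d = 2.0 ** (-config.delay_min / 109.77)
                activity = suv[i] * dose * d / weight[i]
                pet_inputs[p.sample_id] = gen_pet_phantom(
                    shape=config.shape,
                    uptake_kbq_per_ml=activity,
                    weight_kg=float(weight[i]),
                    injected_mbq=dose,
                    delay_min=config.delay_min,
                )
    truth = SyntheticTruth(
        seed=seed,
        cluster_labels=ptruth.cluster_labels,
        true_abundance_means=ptruth.true_abundance_means,
        noise_cv=config.abundance_cv,
        snr=config.snr,
    )
    return CohortBundle(
        proteomes=profiles,
        cohort=cohort,
        truth=truth,
        wavefields=wavefields,
        pet_inputs=pet_inputs,
        masks=masks,
        config=config,
    )
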