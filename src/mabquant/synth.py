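"""Synthetic native SCX-HPLC-MS run generator with known ground truth.

Each simulated component (one intact proteoform) elutes as a Gaussian
chromatographic peak and is ionised into a Gaussian charge-state envelope;
every scan then contains one centroid per (component, charge) at the
theoretical [M+zH]z+ m/z, perturbed by ppm-level m/z jitter and mean-one
lognormal multiplicative intensity noise, plus Poisson-rate baseline noise
centroids.  Class-dependent retention behaviour is emulated the way a pH
gradient cation exchanger separates charge variants: sialylated glycoforms
elute earlier than the main peak, oligomannose slightly later, and each
C-terminal lysine adds a basic shift to later retention times.

The generator is the ground-truth oracle for the quantitation and
deconvolution code: fractions, masses, and retention centers are recorded in
a :class:`TruthManifest`, and total simulated ion current per component is
conserved (area = fraction x global scale) at zero noise.

What it does not emulate: isotopic fine structure (the unresolved envelope is
subsumed in a single centroid per charge, consistent with average-mass
bookkeeping), chromatographic tailing/fronting, adducts, and detector
saturation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .chem import PROTON_MASS
from .msio import MsRun, Scan
from .proteoforms import Proteoform, build_library, rituximab_chains
from .quant import theoretical_mz

__all__ = [
    "SimComponent",
    "SimConfig",
    "TruthManifest",
    "simulate_run",
    "preset_glycoform_panel",
    "preset_rituximab_like",
    "GLYCOFORM_RT_OFFSETS",
    "binomial_galactose_profile",
]

#: Default retention-time offsets (minutes) of glycoform classes relative to
#: the main peak of their lysine-variant group, emulating the observed
#: earlier elution of mono-/di-sialylated species and later elution of
#: oligomannose on a pH-gradient SCX separation.
GLYCOFORM_RT_OFFSETS = {
    "main": 0.0,
    "monosialylated": -0.68,
    "disialylated": -1.35,
    "oligomannose": +0.21,
    "afucosylated": 0.0,
}


@dataclass(frozen=True)
class SimComponent:
    """One simulated proteoform: mass, abundance, elution, charging."""

    label: str
    mass: float  # Da (average-mass domain)
    fraction: float
    rt_center: float  # minutes
    rt_sigma: float = 0.15  # minutes
    z_center: float = 26.0
    z_sigma: float = 2.0


@dataclass
class SimConfig:
    """Full description of a synthetic run; same seed -> identical arrays."""

    components: list[SimComponent]
    run_length: float = 16.0  # minutes
    scan_interval: float = 2.0  # seconds
    resolution: float = 17500.0
    mz_range: tuple[float, float] = (2500.0, 8000.0)
    noise_cv: float = 0.0  # multiplicative intensity noise, coefficient of variation
    mz_jitter_ppm: float = 0.0
    baseline_rate: float = 0.0  # expected baseline noise centroids per scan
    baseline_intensity: float = 1.0
    total_ion_current: float = 1.0e6  # global scale: summed area of all components
    seed: int = 0

    def __post_init__(self):
        if self.scan_interval <= 0:
            raise ValueError("scan interval must be positive")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions sum to {total!r}, not 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthManifest:
    """Ground truth of a simulated run, for closing the recovery loop."""

    components: list[dict]
    seed: int
    config_hash: str

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def true_fractions(self) -> dict[str, float]:
        return {c["label"]: c["fraction"] for c in self.components}


def _charge_weights(comp: SimComponent) -> tuple[np.ndarray, np.ndarray]:
    z_lo = max(1, int(np.floor(comp.z_center - 3 * comp.z_sigma)))
    z_hi = int(np.ceil(comp.z_center + 3 * comp.z_sigma))
    zs = np.arange(z_lo, z_hi + 1)
    w = np.exp(-0.5 * ((zs - comp.z_center) / comp.z_sigma) ** 2)
    return zs, w / w.sum()


def simulate_run(config: SimConfig) -> tuple[MsRun, TruthManifest]:
    """Generate an in-memory MS1 run plus its ground-truth manifest.

    Per scan k and component i the deposited ion current (per minute) is
    ``F_i * S * N(t_k; rt_i, sigma_i)`` split over the charge envelope, so
    that the trapezoid-integrated EICC area of component i equals ``F_i * S``
    (S = total_ion_current) up to Gaussian-truncation edge effects, which are
    negligible for rt_sigma >> scan interval.
    """
    rng = np.random.default_rng(config.seed)
    dt_min = config.scan_interval / 60.0
    times = np.arange(0.0, config.run_length, dt_min)
    lo_mz, hi_mz = config.mz_range
    log_sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    scans = []
    per_component = [
        (c, *_charge_weights(c)) for c in config.components
    ]
    for t in times:
        mzs, intens = [], []
        for comp, zs, wz in per_component:
            elution = np.exp(-0.5 * ((t - comp.rt_center) / comp.rt_sigma) ** 2) / (
                comp.rt_sigma * np.sqrt(2 * np.pi)
            )
            amplitude = comp.fraction * config.total_ion_current * elution
            if amplitude * dt_min < 1e-12 * config.total_ion_current:
                continue
            mz = (comp.mass + zs * PROTON_MASS) / zs
            if config.mz_jitter_ppm > 0:
                mz = mz * (1.0 + config.mz_jitter_ppm * 1e-6 * rng.standard_normal(zs.size))
            inten = amplitude * wz
            if config.noise_cv > 0:
                inten = inten * np.exp(
                    log_sigma * rng.standard_normal(zs.size) - 0.5 * log_sigma**2
                )
            keep = (mz >= lo_mz) & (mz <= hi_mz)
            mzs.append(mz[keep])
            intens.append(inten[keep])
        if config.baseline_rate > 0:
            n_noise = rng.poisson(config.baseline_rate)
            if n_noise:
                mzs.append(rng.uniform(lo_mz, hi_mz, n_noise))
                intens.append(
                    rng.exponential(config.baseline_intensity, n_noise)
                )
        if mzs:
            mz = np.concatenate(mzs)
            inten = np.concatenate(intens)
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        # merge coincident centroids so the m/z axis stays strictly ascending
        if mz.size > 1 and np.any(np.diff(mz) == 0):
            uniq, starts = np.unique(mz, return_index=True)
            inten = np.add.reduceat(inten, starts)
            mz = uniq
        scans.append(Scan(rt=float(t), mz=mz, intensity=inten))
    run = MsRun(scans=scans, metadata={"resolution": config.resolution, "synthetic": 1})
    manifest = TruthManifest(
        components=[
            {
                "label": c.label,
                "mass": c.mass,
                "fraction": c.fraction,
                "rt_center": c.rt_center,
            }
            for c in config.components
        ],
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    return run, manifest


# ---------------------------------------------------------------------------
# Presets


def binomial_galactose_profile(level_pct: float) -> dict[str, float]:
    """Relative weights of the main fucosylated ladder at a galactosylation level.

    Galactose occupancy over the four antenna sites of the glycan pair is
    modelled as Binomial(4, p) with ``p = level_pct / 100``; the weighted
    site-occupancy of the resulting ladder G0F/G0F .. G2F/G2F equals the
    requested level exactly.
    """
    from math import comb

    p = level_pct / 100.0
    weights = {g: comb(4, g) * p**g * (1 - p) ** (4 - g) for g in range(5)}
    labels = {
        0: "A2G0F/A2G0F",
        1: "A2G0F/A2G1F",
        2: "A2G1F/A2G1F",
        3: "A2G1F/A2G2F",
        4: "A2G2F/A2G2F",
    }
    return {labels[g]: w for g, w in weights.items()}


_PANEL_PAIRS = [
    "A2G0F/A2G0F",
    "A2G0F/A2G1F",
    "A2G1F/A2G1F",
    "A2G1F/A2G2F",
    "A2G2F/A2G2F",
    "M5/M5",
    "A2G0F/A2G0",
    "A2S1G0F/A2G0F",
    "A2S2G0F/A2G0F",
]


def panel_library(lysine_variants=(0,)) -> list[Proteoform]:
    """The glycoform panel library used by the presets (rituximab chains)."""
    return build_library(rituximab_chains(), _PANEL_PAIRS, lysine_variants=lysine_variants)


def _class_offset(pair_label: str) -> float:
    if "S2" in pair_label:
        return GLYCOFORM_RT_OFFSETS["disialylated"]
    if "S1" in pair_label:
        return GLYCOFORM_RT_OFFSETS["monosialylated"]
    if pair_label.startswith("M5"):
        return GLYCOFORM_RT_OFFSETS["oligomannose"]
    return GLYCOFORM_RT_OFFSETS["main"]


def _group_fractions(
    galactosylation_pct: float,
    m5m5_pct: float,
    afucosylated_pct: float,
    sialylated_pct: float,
) -> dict[str, float]:
    """Per-glycoform fractions within one lysine-variant group (sum 1)."""
    minor = {
        "M5/M5": m5m5_pct / 100.0,
        "A2G0F/A2G0": afucosylated_pct / 100.0,
        "A2S1G0F/A2G0F": sialylated_pct / 100.0 * 2 / 3,
        "A2S2G0F/A2G0F": sialylated_pct / 100.0 * 1 / 3,
    }
    main_total = 1.0 - sum(minor.values())
    main = binomial_galactose_profile(galactosylation_pct)
    fractions = {k: v * main_total for k, v in main.items()}
    fractions.update(minor)
    return fractions


def preset_glycoform_panel(
    galactosylation_pct: float = 32.67,
    m5m5_pct: float = 0.45,
    afucosylated_pct: float = 0.44,
    sialylated_pct: float = 2.24,
    rt_center: float = 11.06,
    seed: int = 0,
    noise_cv: float = 0.0,
    mz_jitter_ppm: float = 0.0,
) -> tuple[SimConfig, list[Proteoform]]:
    """Single-lysine-variant panel with configurable class levels.

    Defaults reproduce an originator-like profile (galactosylation level,
    M5/M5, afucosylated, and sialylated class fractions in percent); pass
    e.g. (23.86, 2.30, 4.28, 0.79) for a copy-product-like profile.
    """
    library = panel_library(lysine_variants=(0,))
    by_pair = {p.glycan_labels[0]: p for p in library}
    fractions = _group_fractions(
        galactosylation_pct, m5m5_pct, afucosylated_pct, sialylated_pct
    )
    components = []
    for pair_label, fraction in fractions.items():
        prot = by_pair[pair_label]
        components.append(
            SimComponent(
                label=prot.label,
                mass=prot.mass.avg,
                fraction=fraction,
                rt_center=rt_center + _class_offset(pair_label),
            )
        )
    config = SimConfig(
        components=components,
        seed=seed,
        noise_cv=noise_cv,
        mz_jitter_ppm=mz_jitter_ppm,
    )
    return config, library


#: Retention-time centers of the 0K/1K/2K groups in the three-group preset;
#: each C-terminal lysine adds a basic shift towards later elution.
KVARIANT_RT_CENTERS = {0: 9.5, 1: 11.0, 2: 12.5}

#: Per-group class levels of the three-group preset (percent): galactosylation,
#: M5/M5, afucosylated, sialylated.
KVARIANT_CLASS_LEVELS = {
    0: (25.52, 3.24, 4.28, 0.79),
    1: (22.85, 1.07, 4.28, 0.79),
    2: (22.77, 0.93, 4.28, 0.79),
}


def preset_rituximab_like(
    group_weights: dict[int, float] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    mz_jitter_ppm: float = 0.0,
) -> tuple[SimConfig, list[Proteoform]]:
    """Copy-product-like preset: three C-terminal-lysine ladders (0K/1K/2K).

    Groups elute 1.5 min apart (+128.17 Da mass spacing); within each group
    the glycoform panel elutes with its class retention offsets, the 0K group
    carrying more oligomannose and slightly higher galactosylation than the
    1K/2K groups.
    """
    if group_weights is None:
        group_weights = {0: 0.5, 1: 0.3, 2: 0.2}
    total = sum(group_weights.values())
    library = panel_library(lysine_variants=tuple(sorted(group_weights)))
    by_key = {(p.lysine_count, p.glycan_labels[0]): p for p in library}
    components = []
    for k, weight in sorted(group_weights.items()):
        fractions = _group_fractions(*KVARIANT_CLASS_LEVELS[k])
        for pair_label, fraction in fractions.items():
            prot = by_key[(k, pair_label)]
            components.append(
                SimComponent(
                    label=prot.label,
                    mass=prot.mass.avg,
                    fraction=fraction * weight / total,
                    rt_center=KVARIANT_RT_CENTERS[k] + _class_offset(pair_label),
                )
            )
    config = SimConfig(
        components=components,
        seed=seed,
        noise_cv=noise_cv,
        mz_jitter_ppm=mz_jitter_ppm,
    )
    return config, library
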