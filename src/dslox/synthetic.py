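"""Synthetic labelled spectra and volumes emulating two-setup oximetry studies.

The in vivo datasets the method was developed on are not publicly
deposited, so this module generates data with the same statistical
structure: two vis-OCT "setups" that differ by a smooth systemic spectral
bias, rats ventilated through sequences of oxygenation states (normoxia,
step-wise hypoxia, hyperoxia, CO2 challenge), pulse-oximeter spO2 labels
per state, and depth-resolved backscattering spectra computed by the
Beer's-law forward model at the vessel bottom (full double-pass lumen
path) and centre (half path), degraded by speckle-like multiplicative
noise, additive noise and a per-sample heteroscedastic noise factor that
emulates vignetting-driven SNR loss.

Default sample counts mirror the two studies: setup 1 contributes 849
training and 248 testing spectra (4 rats, 6 states), setup 2 contributes
1930 training and 254 testing spectra (8 rats, 5 states) -- 2779 train /
502 test in total, split by rat so no animal appears in both splits.

Label noise is injected by computing each spectrum at an sO2 value
jittered around the recorded label: the label's conditional standard
deviation given the spectrum is then known per sample, which is what the
calibration tests exercise.  The per-sample noise factor also attenuates
the (deeper) bottom spectrum, so the noise level is identifiable from the
input -- emulating how low-SNR peripheral A-lines lose deep signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .blood_optics import (
    BloodOpticalCoefficients,
    ForwardModelParams,
    forward_spectrum,
    load_blood_coefficients,
)
from .preprocessing import WindowBank, normalize_batch

__all__ = [
    "VentilationState",
    "NoiseModel",
    "SyntheticDatasetConfig",
    "VesselSpec",
    "VolumeGeometry",
    "SyntheticVolume",
    "BAND_COLUMNS",
    "default_states",
    "sample_labels",
    "generate_spectral_dataset",
    "generate_two_regime_dataset",
    "generate_volume",
]

BAND_COLUMNS = [f"band{i:02d}" for i in range(28)]

LABEL_LO, LABEL_HI = 0.5, 1.0


@dataclass(frozen=True)
class VentilationState:
    """One ventilation condition with its systemic spO2 distribution."""

    name: str
    spo2_mean: float
    spo2_sd: float

    def __post_init__(self) -> None:
        if not LABEL_LO <= self.spo2_mean <= LABEL_HI:
            raise ValueError("spo2_mean must lie in [0.5, 1.0]")
        if self.spo2_sd < 0:
            raise ValueError("spo2_sd must be non-negative")


def default_states(setup: int) -> Tuple[VentilationState, ...]:
    """Ventilation sequences of the two emulated studies.

    Setup 1: normoxia followed by five step-wise hypoxia challenges
    (inspired O2 reduced 21% -> 9%).  Setup 2: normoxia, hyperoxia
    (100% O2), 5% CO2 challenge, hypoxia (10% O2), return to normoxia.
    Means follow pulse-oximeter readings typical of these challenges
    (hypoxia ~70%, normoxia ~80-95%, hyperoxia ~98%).
    """
    if setup == 1:
        return (
            VentilationState("normoxia", 0.95, 0.02),
            VentilationState("hypoxia-step-1", 0.90, 0.02),
            VentilationState("hypoxia-step-2", 0.86, 0.02),
            VentilationState("hypoxia-step-3", 0.80, 0.02),
            VentilationState("hypoxia-step-4", 0.72, 0.02),
            VentilationState("hypoxia-step-5", 0.64, 0.02),
        )
    if setup == 2:
        return (
            VentilationState("normoxia", 0.80, 0.03),
            VentilationState("hyperoxia", 0.98, 0.01),
            VentilationState("co2-challenge", 0.85, 0.03),
            VentilationState("hypoxia", 0.70, 0.03),
            VentilationState("normoxia-return", 0.80, 0.03),
        )
    raise ValueError("setup must be 1 or 2")


@dataclass(frozen=True)
class NoiseModel:
    """Spectral and label noise applied to generated samples.

    Attributes
    ----------
    multiplicative_speckle_shape : float
        Gamma shape of unit-mean per-band multiplicative speckle noise
        (relative sd = 1/sqrt(shape)); 0 disables.
    additive_sd : float
        Additive Gaussian noise sd as a fraction of the band mean.
    heteroscedastic_scale : float
        Per-sample noise factor h ~ U(1, 1 + scale); scales both the
        additive noise and the label jitter (vignetting emulation).
    label_jitter_sd : float
        Base sd of the sO2 used to synthesize the spectrum around the
        recorded label; per-sample sd is ``label_jitter_sd * h``.
    low_snr_bottom_attenuation : float
        The bottom spectrum is scaled by exp(-g * (h - 1)); makes the
        per-sample noise level identifiable from the input.
    """

    multiplicative_speckle_shape: float = 2000.0
    additive_sd: float = 0.02
    heteroscedastic_scale: float = 1.0
    label_jitter_sd: float = 0.02
    low_snr_bottom_attenuation: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "multiplicative_speckle_shape",
            "additive_sd",
            "heteroscedastic_scale",
            "label_jitter_sd",
            "low_snr_bottom_attenuation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def off(cls) -> "NoiseModel":
        """Completely noiseless configuration."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Study-level configuration; identical config + seed -> identical data."""

    n_rats_per_setup: Dict[int, int] = field(default_factory=lambda: {1: 4, 2: 8})
    states_per_setup: Dict[int, Tuple[VentilationState, ...]] = field(
        default_factory=lambda: {1: default_states(1), 2: default_states(2)}
    )
    train_totals: Dict[int, int] = field(default_factory=lambda: {1: 849, 2: 1930})
    test_totals: Dict[int, int] = field(default_factory=lambda: {1: 248, 2: 254})
    noise: NoiseModel = field(default_factory=NoiseModel)
    # per-setup smooth multiplicative spectral bias exp(c1*u + c2*u^2),
    # u = (lam - mean)/span: "systemic spectral bias" between the setups
    bias_coefficients: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {1: (0.0, 0.0), 2: (0.25, -0.20)}
    )
    # forward-model truth
    z_bottom_mm: float = 0.1  # double-pass through a ~50 um lumen
    w_true: float = 0.12
    amplitude: float = 1.0
    alpha_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for setup, states in self.states_per_setup.items():
            if len(states) == 0:
                raise ValueError(f"setup {setup} has an empty state list")
        for setup in self.n_rats_per_setup:
            if self.n_rats_per_setup[setup] < 2:
                raise ValueError("need >= 2 rats per setup for a by-rat split")

    @classmethod
    def small(cls, seed: int = 0, n_per_cell: int = 8, **kw) -> "SyntheticDatasetConfig":
        """Scaled-down configuration for fast tests; same structure."""
        cfg = cls(seed=seed, **kw)
        train = {s: n_per_cell * (cfg.n_rats_per_setup[s] - 1) * len(cfg.states_per_setup[s])
                 for s in cfg.n_rats_per_setup}
        test = {s: n_per_cell * len(cfg.states_per_setup[s]) for s in cfg.n_rats_per_setup}
        return replace(cfg, train_totals=train, test_totals=test)


def _allocate(total: int, n_cells: int) -> np.ndarray:
    """Spread ``total`` across ``n_cells`` as evenly as possible."""
    base, rem = divmod(total, n_cells)
    counts = np.full(n_cells, base, dtype=int)
    counts[:rem] += 1
    return counts


def _draw_labels(rng: np.random.Generator, state: VentilationState, n: int) -> np.ndarray:
    if state.spo2_sd == 0:
        return np.full(n, state.spo2_mean)
    a = (LABEL_LO - state.spo2_mean) / state.spo2_sd
    b = (LABEL_HI - state.spo2_mean) / state.spo2_sd
    return truncnorm.rvs(a, b, loc=state.spo2_mean, scale=state.spo2_sd, size=n, random_state=rng)


def sample_labels(config: SyntheticDatasetConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw per-spectrum spO2 labels for every rat/setup/state cell.

    Returns a frame with columns rat, setup, state, split, label; the
    last rat of each setup is the held-out test animal (split by rat).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows: List[dict] = []
    for setup in sorted(config.n_rats_per_setup):
        states = config.states_per_setup[setup]
        n_rats = config.n_rats_per_setup[setup]
        train_rats = list(range(1, n_rats))  # last rat held out
        test_rats = [n_rats]
        for split, rats, total in (
            ("train", train_rats, config.train_totals[setup]),
            ("test", test_rats, config.test_totals[setup]),
        ):
            cells = [(r, s) for r in rats for s in states]
            counts = _allocate(total, len(cells))
            for (rat, state), n in zip(cells, counts):
                labels = _draw_labels(rng, state, n)
                for lab in labels:
                    rows.append(
                        dict(rat=rat, setup=setup, state=state.name, split=split, label=lab)
                    )
    return pd.DataFrame(rows)


def _bias_profile(lam: np.ndarray, coeffs: Tuple[float, float]) -> np.ndarray:
    c1, c2 = coeffs
    span = lam[-1] - lam[0]
    u = (lam - lam.mean()) / span
    return np.exp(c1 * u + c2 * u**2)


def _synthesize_spectra(
    labels: np.ndarray,
    h: np.ndarray,
    bias: np.ndarray,
    rng: np.random.Generator,
    config: SyntheticDatasetConfig,
    coeffs: BloodOpticalCoefficients,
    lam: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward-model bottom/centre/top spectra for a batch of labels.

    Returns the (n, 28) normalized inputs and the per-sample effective
    label-noise sd (``label_jitter_sd * h``).
    """
    nm = config.noise
    n = labels.size
    jitter_sd = nm.label_jitter_sd * h
    so2_actual = np.clip(labels + rng.normal(0.0, 1.0, n) * jitter_sd, 0.0, 1.0)

    mu_ox = coeffs.mu_a(lam, True) + config.w_true * coeffs.mu_s(lam, True)
    mu_de = coeffs.mu_a(lam, False) + config.w_true * coeffs.mu_s(lam, False)
    mu = np.outer(so2_actual, mu_ox) + np.outer(1.0 - so2_actual, mu_de)  # (n, 14)
    wall = np.sqrt(config.amplitude * lam ** (-config.alpha_true))

    spectra = {}
    for depth, z in (("bottom", config.z_bottom_mm),
                     ("centre", config.z_bottom_mm / 2.0),
                     ("top", config.z_bottom_mm / 4.0)):
        s = wall * np.exp(-mu * z) * bias
        if depth == "bottom" and nm.low_snr_bottom_attenuation > 0:
            s = s * np.exp(-nm.low_snr_bottom_attenuation * (h - 1.0))[:, None]
        if nm.multiplicative_speckle_shape > 0:
            shape = nm.multiplicative_speckle_shape / h[:, None] ** 2
            s = s * rng.gamma(shape, 1.0 / shape)
        if nm.additive_sd > 0:
            sd = nm.additive_sd * h[:, None] * s.mean(axis=1, keepdims=True)
            s = np.clip(s + rng.normal(0.0, 1.0, s.shape) * sd, 1e-12, None)
        spectra[depth] = s
    x = normalize_batch(spectra["bottom"], spectra["centre"], spectra["top"])
    return x, jitter_sd


def generate_spectral_dataset(
    config: SyntheticDatasetConfig,
    coeffs: Optional[BloodOpticalCoefficients] = None,
    bank: Optional[WindowBank] = None,
) -> pd.DataFrame:
    """Generate the full labelled two-setup spectral table.

    Columns: 28 normalized band intensities (``band00`` ... ``band27``),
    ``label`` (spO2 fraction), ``setup``, ``rat``, ``state``, ``split``,
    ``noise_factor`` (per-sample h) and ``noise_sd`` (effective label sd).
    """
    coeffs = coeffs or load_blood_coefficients()
    bank = bank or WindowBank()
    lam = bank.centres_nm
    coeffs.require_coverage(lam[0], lam[-1])

    labels_df = sample_labels(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    nm = config.noise

    parts = []
    for setup, group in labels_df.groupby("setup", sort=True):
        bias = _bias_profile(lam, config.bias_coefficients.get(setup, (0.0, 0.0)))
        labels = group["label"].to_numpy()
        h = 1.0 + rng.uniform(0.0, 1.0, labels.size) * nm.heteroscedastic_scale
        x, jitter_sd = _synthesize_spectra(labels, h, bias, rng, config, coeffs, lam)
        part = pd.DataFrame(x, columns=BAND_COLUMNS, index=group.index)
        part["noise_factor"] = h
        part["noise_sd"] = jitter_sd
        parts.append(part)
    out = pd.concat([labels_df, pd.concat(parts).sort_index()], axis=1)
    return out


def generate_two_regime_dataset(
    n_per_regime: int = 800,
    sds: Tuple[float, float] = (0.02, 0.08),
    seed: int = 0,
    coeffs: Optional[BloodOpticalCoefficients] = None,
) -> pd.DataFrame:
    """Two-noise-regime benchmark for heteroscedastic-uncertainty recovery.

    Labels are uniform on [0.6, 1.0]; regime r spectra carry label jitter
    of sd ``sds[r]`` together with proportionally stronger spectral noise
    and bottom-signal attenuation, making the regime identifiable from
    the input.  Adds a ``regime`` column (0 = low noise, 1 = high noise)
    and the standard band/label columns.
    """
    coeffs = coeffs or load_blood_coefficients()
    bank = WindowBank()
    lam = bank.centres_nm
    base = SyntheticDatasetConfig(seed=seed)
    nm = base.noise
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    bias = _bias_profile(lam, (0.0, 0.0))

    frames = []
    for regime, sd in enumerate(sds):
        labels = rng.uniform(0.6, 1.0, n_per_regime)
        h = np.full(n_per_regime, sd / nm.label_jitter_sd)
        x, jitter_sd = _synthesize_spectra(labels, h, bias, rng, base, coeffs, lam)
        df = pd.DataFrame(x, columns=BAND_COLUMNS)
        df["label"] = labels
        df["regime"] = regime
        df["noise_sd"] = jitter_sd
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["split"] = "train"
    # hold out a by-row test split (no rat structure here)
    test_idx = rng.choice(len(out), size=len(out) // 5, replace=False)
    out.loc[test_idx, "split"] = "test"
    return out


# ---------------------------------------------------------------------------
# Synthetic 3-D volumes


@dataclass(frozen=True)
class VesselSpec:
    """A horizontal ribbon vessel in the en face plane."""

    row: int  # centre row (y index)
    diameter_um: float = 50.0
    top_depth_um: float = 40.0
    so2: float = 0.9


@dataclass(frozen=True)
class VolumeGeometry:
    nx: int = 48
    ny: int = 48
    nz: int = 160
    dz_um: float = 1.0
    pixel_um: float = 10.0
    vessels: Tuple[VesselSpec, ...] = (VesselSpec(row=24),)
    vessel_gain: float = 25.0  # vessel signal amplitude over the noise floor
    lumen_backscatter: float = 0.1  # blood backscatter relative to the wall peaks
    vignetting: float = 0.0  # peripheral signal multiplier drop (0 = none)
    noise_floor: float = 0.02
    additive_sd: float = 0.0


@dataclass(frozen=True)
class SyntheticVolume:
    """Per-band intensity volume plus ground-truth geometry."""

    bands: np.ndarray  # (ny, nx, nz, n_bands)
    depth_axis_um: np.ndarray
    lam_grid: np.ndarray
    mask: np.ndarray  # (ny, nx) vessel mask
    bottom_wall_depth_um: np.ndarray  # (ny, nx), nan outside mask
    so2_map: np.ndarray  # (ny, nx), nan outside mask
    surface_index: np.ndarray  # (ny, nx) retinal surface depth index
    snr_map: np.ndarray  # (ny, nx) relative signal multiplier

    def enface_projection(self) -> np.ndarray:
        """Mean-over-depth, mean-over-band intensity image."""
        return self.bands.mean(axis=(2, 3))


def generate_volume(
    geometry: VolumeGeometry,
    seed: int = 0,
    coeffs: Optional[BloodOpticalCoefficients] = None,
    config: Optional[SyntheticDatasetConfig] = None,
) -> SyntheticVolume:
    """Build a per-band intensity volume with ribbon vessels.

    In-vessel A-lines carry a bright top/bottom wall peak and a lumen
    signal following the forward model with a double-pass path
    ``2 * (z - top)``; the background carries a noise floor; an optional
    vignetting ramp scales peripheral columns down.
    """
    geom = geometry
    coeffs = coeffs or load_blood_coefficients()
    config = config or SyntheticDatasetConfig(noise=NoiseModel.off())
    bank = WindowBank()
    lam = bank.centres_nm
    depth = np.arange(geom.nz) * geom.dz_um
    rng = np.random.default_rng(seed)

    mu_ox = coeffs.mu_a(lam, True) + config.w_true * coeffs.mu_s(lam, True)
    mu_de = coeffs.mu_a(lam, False) + config.w_true * coeffs.mu_s(lam, False)
    wall_spec = np.sqrt(config.amplitude * lam ** (-config.alpha_true))

    bands = np.full((geom.ny, geom.nx, geom.nz, lam.size), geom.noise_floor)
    mask = np.zeros((geom.ny, geom.nx), dtype=bool)
    wall_depth = np.full((geom.ny, geom.nx), np.nan)
    so2_map = np.full((geom.ny, geom.nx), np.nan)

    for ves in geom.vessels:
        half = int(round(ves.diameter_um / 2.0 / geom.pixel_um))
        rows = np.arange(max(0, ves.row - half), min(geom.ny, ves.row + half + 1))
        top = ves.top_depth_um
        bottom = top + ves.diameter_um
        if bottom + 20.0 > depth[-1]:
            raise ValueError("vessel bottom wall exceeds the depth range")
        mu = ves.so2 * mu_ox + (1.0 - ves.so2) * mu_de  # (nb,)
        in_lumen = (depth >= top) & (depth <= bottom)
        z_eff_mm = 2.0 * np.clip(depth - top, 0.0, None) * 1e-3
        profile = geom.lumen_backscatter * np.where(
            in_lumen[:, None], wall_spec * np.exp(-np.outer(z_eff_mm, mu)), 0.0
        )
        # wall peaks: bright scattering layers at the top and bottom walls
        for wall_z, amp in ((top, 2.0), (bottom, 1.5)):
            peak = amp * np.exp(-0.5 * ((depth - wall_z) / 3.0) ** 2)
            att = np.exp(-np.outer(np.full_like(depth, 2.0 * (wall_z - top) * 1e-3), mu))
            profile = profile + peak[:, None] * wall_spec * att
        for r in rows:
            bands[r, :, :, :] += geom.vessel_gain * profile[None, :, :]
            mask[r, :] = True
            wall_depth[r, :] = bottom
            so2_map[r, :] = ves.so2

    snr = np.ones((geom.ny, geom.nx))
    if geom.vignetting > 0:
        x = np.linspace(-1.0, 1.0, geom.nx)
        snr *= 1.0 - geom.vignetting * x[None, :] ** 2
        bands *= snr[:, :, None, None]
    if geom.additive_sd > 0:
        bands = np.clip(
            bands + rng.normal(0.0, geom.additive_sd, bands.shape), 0.0, None
        )
    surface = np.zeros((geom.ny, geom.nx), dtype=int)
    return SyntheticVolume(
        bands=bands,
        depth_axis_um=depth,
        lam_grid=lam,
        mask=mask,
        bottom_wall_depth_um=wall_depth,
        so2_map=so2_map,
        surface_index=surface,
        snr_map=snr,
    )
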