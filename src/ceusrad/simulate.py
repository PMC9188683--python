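"""Synthetic dual-view CEUS cine generator with known kinetic ground truth.

Clinical CEUS loops of focal liver lesions are not publicly available, so
every downstream stage of the pipeline is exercised on simulated loops
that emulate the salient physics of a bolus examination:

* log-compressed contrast frames driven by pixel-wise bolus wash-in /
  wash-out kinetics (log-normal arterial bolus plus a delayed sigmoid
  plateau emulating the overlapping portal phase);
* a lesion with kinetics distinct from the surrounding parenchyma
  (earlier onset and higher peak for the malignant phenotype, plus
  per-pixel kinetic jitter producing spatially heterogeneous enhancement
  — a simulator convention for end-to-end ML tests, not a clinical claim);
* multiplicative, spatially correlated gamma speckle;
* intermittent motion: small rigid in-plane shifts applied jointly to
  both panes, and occasional "out-of-plane" frames whose texture is
  replaced by an independent speckle draw.

The generator is fully reproducible from its seed and returns, next to
the cine, a :class:`GroundTruth` carrying the noiseless per-pixel TIC
field, the true appearance/peak times, the lesion mask and the list of
large-motion frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Cine, LesionAnnotation, log_compress_values


@dataclasses.dataclass
class SimConfig:
    """Study-condition defaults for the cine simulator.

    The defaults emulate a ~60 s liver CEUS recording covering wash-in,
    peak enhancement and the beginning of wash-out, with the arterial
    bolus peaking around 30 s in parenchyma and the portal plateau
    setting in around 35-45 s.
    """

    n_frames: int = 60
    height: int = 256
    width: int = 256
    frame_rate: float = 1.0            # Hz
    spacing_mm: float = 0.5            # mm per pixel, isotropic
    dynamic_range_db: float = 60.0
    gray_max: float = 255.0

    lesion_center: tuple[int, int] | None = None   # defaults to grid center
    lesion_radius: int = 30                        # px

    # parenchyma kinetics (linear relative power)
    bg_amplitude: float = 0.30
    bg_onset_s: float = 14.0
    bg_mu: float = float(np.log(24.0))             # log-normal shape
    bg_sigma: float = 0.50
    plateau_amplitude: float = 0.15
    plateau_onset_s: float = 40.0
    plateau_width_s: float = 6.0

    # lesion kinetics
    lesion_amplitude: float = 0.55
    lesion_onset_s: float = 12.0
    lesion_mu: float = float(np.log(22.0))
    lesion_sigma: float = 0.50
    kinetic_jitter: float = 0.0        # sd of per-pixel jitter on mu/sigma/onset

    baseline_power: float = 1e-4       # pre-contrast echo floor

    # speckle
    speckle_shape: float = 4.0         # gamma shape; mean fixed at 1
    speckle_corr_px: float = 1.5       # spatial correlation length (0 = off)
    speckle_on: bool = True

    # motion
    shift_sd_px: float = 0.0           # per-frame rigid shift sd (0 = off)
    large_motion_prob: float = 0.0     # out-of-plane dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames / self.frame_rate < 60.0:
            raise ValueError("recording must cover at least 60 s")
        if self.lesion_center is None:
            self.lesion_center = (self.height // 2, self.width // 2)
        cy, cx = self.lesion_center
        r = self.lesion_radius
        if not (r <= cy < self.height - r and r <= cx < self.width - r):
            raise ValueError("lesion must lie inside the grid")
        for name in ("bg_amplitude", "lesion_amplitude", "frame_rate",
                     "spacing_mm", "dynamic_range_db"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Noise-free reference quantities for one simulated lesion."""

    lesion_mask: np.ndarray            # H x W bool
    label: str
    clean_field: np.ndarray            # T x H x W noiseless linear power
    tic_lesion: np.ndarray             # lesion-mean noiseless TIC
    tic_parenchyma: np.ndarray
    times: np.ndarray
    appearance_time_s: float           # first 10%-of-peak crossing, lesion TIC
    peak_time_s: float                 # argmax of lesion TIC
    large_motion_frames: list[int]
    ref_frame: int


def bolus_tic(
    t: np.ndarray | float,
    amplitude: float,
    onset_s: float,
    mu: float,
    sigma: float,
    plateau: float = 0.0,
    plateau_onset_s: float = 40.0,
    plateau_width_s: float = 6.0,
) -> np.ndarray:
    """Forward TIC model: log-normal bolus plus delayed sigmoid plateau.

    The bolus term is a log-normal density in ``t - onset_s`` rescaled so
    its peak equals *amplitude*; its mode sits at
    ``onset_s + exp(mu - sigma**2)``.  The plateau term is a logistic ramp
    emulating portal-phase inflow.  Output is zero for ``t <= onset_s``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=np.float64)
    tau = t - onset_s
    out = np.zeros_like(tau)
    pos = tau > 0
    tau_p = tau[pos]
    log_pdf = -((np.log(tau_p) - mu) ** 2) / (2 * sigma**2) - np.log(tau_p)
    mode = np.exp(mu - sigma**2)
    log_pdf_mode = -((np.log(mode) - mu) ** 2) / (2 * sigma**2) - np.log(mode)
    out[pos] = amplitude * np.exp(log_pdf - log_pdf_mode)
    if plateau > 0:
        sig = plateau / (1.0 + np.exp(-(t - plateau_onset_s) / plateau_width_s))
        out = np.where(tau > 0, out + sig, out)
    return out


def _disk_mask(h: int, w: int, center: tuple[int, int], radius: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _speckle_field(rng: np.random.Generator, shape, gamma_shape, corr_px) -> np.ndarray:
    """Multiplicative unit-mean speckle, spatially low-pass filtered."""
    field = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=shape)
    if corr_px > 0:
        field = gaussian_filter(field, sigma=corr_px)
        field /= field.mean()
    return field


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer rigid shift with edge replication."""
    if dy == 0 and dx == 0:
        return img
    pad_y = abs(dy)
    pad_x = abs(dx)
    padded = np.pad(img, ((pad_y, pad_y), (pad_x, pad_x)), mode="edge")
    h, w = img.shape
    return padded[pad_y - dy:pad_y - dy + h, pad_x - dx:pad_x - dx + w]


def generate_cine(config: SimConfig) -> tuple[Cine, GroundTruth, LesionAnnotation]:
    """Simulate one dual-view cine loop with known ground truth."""
    rng = np.random.default_rng(config.seed)
    T, H, W = config.n_frames, config.height, config.width
    times = np.arange(T) / config.frame_rate
    lesion = _disk_mask(H, W, config.lesion_center, config.lesion_radius)

    # --- per-pixel kinetic parameter maps ---------------------------------
    onset = np.full((H, W), config.bg_onset_s)
    mu = np.full((H, W), config.bg_mu)
    sigma = np.full((H, W), config.bg_sigma)
    amp = np.full((H, W), config.bg_amplitude)
    onset[lesion] = config.lesion_onset_s
    mu[lesion] = config.lesion_mu
    sigma[lesion] = config.lesion_sigma
    amp[lesion] = config.lesion_amplitude
    if config.kinetic_jitter > 0:
        n_les = int(lesion.sum())
        j = config.kinetic_jitter
        mu[lesion] += rng.normal(0, j, n_les)
        sigma[lesion] *= np.exp(rng.normal(0, j, n_les))
        onset[lesion] += rng.normal(0, 2.0 * j / 0.3, n_les).clip(-5, 5)

    # --- noiseless linear-power field -------------------------------------
    tau = times[:, None, None] - onset[None]
    pos = tau > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_tau = np.where(pos, np.log(np.where(pos, tau, 1.0)), 0.0)
        log_pdf = -((log_tau - mu[None]) ** 2) / (2 * sigma[None] ** 2) - log_tau
        mode = np.exp(mu - sigma**2)
        log_pdf_mode = -((np.log(mode) - mu) ** 2) / (2 * sigma**2) - np.log(mode)
        bolus = amp[None] * np.exp(log_pdf - log_pdf_mode[None])
    field = np.where(pos, bolus, 0.0)
    if config.plateau_amplitude > 0:
        sig = config.plateau_amplitude / (
            1.0 + np.exp(-(times - config.plateau_onset_s) / config.plateau_width_s)
        )
        field = np.where(pos, field + sig[:, None, None], field)
    field = field + config.baseline_power
    clean = np.clip(field, 0.0, 1.0)

    tic_lesion = clean[:, lesion].mean(axis=1)
    tic_par = clean[:, ~lesion].mean(axis=1)
    peak_idx = int(np.argmax(tic_lesion))
    app_idx = int(np.argmax(tic_lesion >= 0.1 * tic_lesion.max()))

    # --- speckle ----------------------------------------------------------
    ceus_lin = clean.copy()
    if config.speckle_on:
        speckle = _speckle_field(
            rng, (T, H, W), config.speckle_shape, config.speckle_corr_px
        )
        ceus_lin = np.clip(clean * speckle, 0.0, 1.0)

    # --- B-mode pane: static echo texture ---------------------------------
    bmode_base = _speckle_field(rng, (H, W), config.speckle_shape, 2.0)
    # give the lesion a mild B-mode contrast so the pane is anatomical
    bmode_base = bmode_base * np.where(lesion, 0.7, 1.0)
    bmode_base = 40.0 + 150.0 * bmode_base / bmode_base.max()

    # --- motion -----------------------------------------------------------
    shifts = np.zeros((T, 2), dtype=int)
    if config.shift_sd_px > 0:
        shifts = np.round(rng.normal(0, config.shift_sd_px, (T, 2))).astype(int)
    large = np.zeros(T, dtype=bool)
    if config.large_motion_prob > 0:
        large = rng.random(T) < config.large_motion_prob
    ref_frame = peak_idx
    shifts[ref_frame] = 0
    large[ref_frame] = False
    large_frames = [int(i) for i in np.flatnonzero(large)]

    bmode = np.empty((T, H, W))
    for i in range(T):
        if large[i]:
            # out-of-plane: independent texture in both panes
            alt = _speckle_field(rng, (H, W), config.speckle_shape, 2.0)
            bmode[i] = 40.0 + 150.0 * alt / alt.max()
            ceus_lin[i] = np.clip(
                (config.baseline_power + tic_par[i])
                * _speckle_field(rng, (H, W), config.speckle_shape,
                                 config.speckle_corr_px),
                0.0, 1.0,
            )
        else:
            bmode[i] = _shift2d(bmode_base, *shifts[i])
            ceus_lin[i] = _shift2d(ceus_lin[i], *shifts[i])

    ceus_gray = log_compress_values(
        ceus_lin, config.dynamic_range_db, config.gray_max
    )

    cine = Cine(
        bmode=bmode,
        ceus=ceus_gray,
        times=times,
        spacing_mm=(config.spacing_mm, config.spacing_mm),
        dynamic_range_db=config.dynamic_range_db,
        gray_max=config.gray_max,
    )
    truth = GroundTruth(
        lesion_mask=lesion,
        label="unknown",
        clean_field=clean,
        tic_lesion=tic_lesion,
        tic_parenchyma=tic_par,
        times=times,
        appearance_time_s=float(times[app_idx]),
        peak_time_s=float(times[peak_idx]),
        large_motion_frames=large_frames,
        ref_frame=ref_frame,
    )
    annotation = LesionAnnotation(
        masks={ref_frame: lesion.copy()}, ref_frame=ref_frame, label="unknown"
    )
    return cine, truth, annotation


# ---------------------------------------------------------------------------
# Cohorts for end-to-end ML tests
# ---------------------------------------------------------------------------

def malignant_config(base: SimConfig, seed: int, rng: np.random.Generator) -> SimConfig:
    """Malignant phenotype: earlier onset, higher peak, heterogeneous kinetics."""
    return dataclasses.replace(
        base,
        seed=seed,
        lesion_onset_s=float(np.clip(rng.normal(7.0, 1.0), 5.0, 10.0)),
        lesion_amplitude=float(np.clip(rng.normal(0.85, 0.05), 0.6, 0.99)),
        lesion_mu=float(np.log(rng.uniform(20.0, 24.0))),
        lesion_radius=int(rng.integers(max(8, base.lesion_radius - 6),
                                       base.lesion_radius + 7)),
        kinetic_jitter=0.25,
    )


def benign_config(base: SimConfig, seed: int, rng: np.random.Generator) -> SimConfig:
    """Benign phenotype: later onset, lower peak, homogeneous kinetics."""
    return dataclasses.replace(
        base,
        seed=seed,
        lesion_onset_s=float(np.clip(rng.normal(13.0, 1.0), 11.0, 16.0)),
        lesion_amplitude=float(np.clip(rng.normal(0.45, 0.05), 0.3, 0.6)),
        lesion_mu=float(np.log(rng.uniform(22.0, 26.0))),
        lesion_radius=int(rng.integers(max(8, base.lesion_radius - 6),
                                       base.lesion_radius + 7)),
        kinetic_jitter=0.0,
    )


def generate_cohort(
    n_lesions: int,
    malignant_fraction: float = 0.6,
    base_config: SimConfig | None = None,
    seed: int = 0,
) -> list[tuple[Cine, GroundTruth, LesionAnnotation]]:
    """Generate a labelled cohort of simulated lesions.

    The class split defaults to malignant-majority, mirroring the
    imbalance typical of at-risk liver cohorts.  Labels are attached to
    both the ground truth and the annotations.
    """
    if base_config is None:
        base_config = SimConfig()
    rng = np.random.default_rng(seed)
    n_mal = int(round(n_lesions * malignant_fraction))
    labels = ["malignant"] * n_mal + ["benign"] * (n_lesions - n_mal)
    out = []
    for i, label in enumerate(labels):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = (malignant_config if label == "malignant" else benign_config)(
            base_config, sub_seed, rng
        )
        cine, truth, ann = generate_cine(cfg)
        truth.label = label
        ann.label = label
        out.append((cine, truth, ann))
    return out
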