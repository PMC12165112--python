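"""Synthetic data generators for every stage of the pipeline.

Three generators with known ground truth:

* TIRF fields — diffraction-limited Gaussian spots on a uniform background
  with optional Poisson shot noise and Gaussian read noise, so that the
  image-quantification stage can be tested against an exact spot list.
* Spike-in dilution series — log–log linear TFI response with optional
  Langmuir capture saturation and a healthy-donor matrix baseline, the
  oracle for the calibration stage.
* Patient cohorts — samples from high-risk smoker (HRS), limited-stage (LS)
  and extensive-stage (ES) groups with log-normal per-marker TFI, a latent
  SCLC molecular subtype drawn with configurable prevalences, and
  subtype-dependent marker elevation, the oracle for cutoff derivation and
  classification.

Every generator is a pure function of (config, seed): repeated calls are
bit-identical.  Randomness is split into named substreams derived from the
master seed so that, e.g., adding fields to a well does not perturb the
draws of earlier fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import TIRFField

__all__ = [
    "FieldSimConfig",
    "FieldGroundTruth",
    "WellSimResult",
    "SpikeSeriesConfig",
    "CohortSimConfig",
    "simulate_field",
    "simulate_well",
    "simulate_spikein_series",
    "simulate_cohort",
    "default_cohort_config",
    "SCLC_GROUPS",
    "SUBTYPES",
    "DEFAULT_MARKERS",
]

#: Marker panel: three subtype transcription factors measured as exosomal
#: mRNA, plus DLL3 measured both as exosomal mRNA and as tEV membrane protein.
DEFAULT_MARKERS = (
    "ASCL1",
    "NEUROD1",
    "POU2F3",
    "DLL3_exo_mRNA",
    "DLL3_tEV_mProtein",
)

SCLC_GROUPS = ("LS", "ES")
SUBTYPES = ("A", "N", "P", "I")

# Substream tags mixed into the SeedSequence so each random purpose gets an
# independent, reproducible stream.
_STREAM_COUNT = 0
_STREAM_POSITION = 1
_STREAM_AMPLITUDE = 2
_STREAM_NOISE = 3
_STREAM_SPIKE = 4
_STREAM_COHORT = 5


def _stream(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, *extra]))


# ---------------------------------------------------------------------------
# TIRF fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSimConfig:
    """Parameters of one simulated TIRF field.

    Defaults emulate a 512 px × 512 px EMCCD frame covering an
    80 µm × 80 µm surface (0.15625 µm/px) with a ~1.3 px Gaussian PSF.
    Spot count per field is Poisson; integrated spot brightness (arbitrary
    fluorescence units) is log-normal.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.15625
    psf_sigma_px: float = 1.3
    spot_count_mean: float = 40.0
    amplitude_log10_mean: float = 3.0
    amplitude_log10_sd: float = 0.3
    background_level: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    #: When > 0, spots are placed by rejection sampling so that no two centers
    #: are closer than this (the "non-overlapping regime" used by oracle tests).
    min_separation_px: float = 0.0
    #: Keep spot centers at least this far from every image border.
    border_margin_px: float = 0.0

    def validate(self) -> None:
        h, w = self.image_size_px
        if h < 1 or w < 1:
            raise ValueError(f"image_size_px must be positive, got {self.image_size_px}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.spot_count_mean < 0:
            raise ValueError("spot_count_mean must be non-negative")
        if self.amplitude_log10_sd < 0 or self.read_noise_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        for v in (
            self.pixel_size_um,
            self.psf_sigma_px,
            self.spot_count_mean,
            self.amplitude_log10_mean,
            self.amplitude_log10_sd,
            self.background_level,
            self.read_noise_sd,
        ):
            if not math.isfinite(v):
                raise ValueError("all scale parameters must be finite")

    @property
    def field_extent_um(self) -> tuple[float, float]:
        h, w = self.image_size_px
        return (h * self.pixel_size_um, w * self.pixel_size_um)


@dataclass(frozen=True)
class FieldGroundTruth:
    """Injected spots of one simulated field: (x_px, y_px, integrated amplitude)."""

    spots: tuple[tuple[float, float, float], ...]

    @property
    def true_field_tfi(self) -> float:
        return float(sum(a for _, _, a in self.spots))

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def _place_spots(
    rng_pos: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
) -> list[tuple[float, float]]:
    h, w = shape
    lo_x, hi_x = margin, w - 1 - margin
    lo_y, hi_y = margin, h - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("border_margin_px leaves no room for spots")
    if min_sep <= 0:
        xs = rng_pos.uniform(lo_x, hi_x, n)
        ys = rng_pos.uniform(lo_y, hi_y, n)
        return list(zip(xs.tolist(), ys.tolist()))
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        x = rng_pos.uniform(lo_x, hi_x)
        y = rng_pos.uniform(lo_y, hi_y)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in placed):
            placed.append((x, y))
    if len(placed) < n:
        raise RuntimeError(
            f"could not place {n} spots with min separation {min_sep} px; "
            "reduce density or separation"
        )
    return placed


def _render_spot(img: np.ndarray, x: float, y: float, amplitude: float, sigma: float) -> None:
    # Windowed rendering: the Gaussian is negligible beyond ~8 sigma.
    h, w = img.shape
    r = int(math.ceil(8 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    peak = amplitude / (2 * math.pi * sigma**2)
    img[y0:y1, x0:x1] += peak * np.outer(gy, gx)


def simulate_field(
    cfg: FieldSimConfig,
    seed: int,
    field_index: int = 0,
    channel: str = "",
) -> tuple[TIRFField, FieldGroundTruth]:
    """Simulate one TIRF field.

    Pixel values are ``background + Σ Gaussian spots`` with, when enabled,
    Poisson shot noise on the expected count and additive Gaussian read
    noise, clipped at zero.  Returns the field together with the exact list
    of injected spots.
    """
    cfg.validate()
    h, w = cfg.image_size_px

    n = int(_stream(seed, _STREAM_COUNT).poisson(cfg.spot_count_mean))
    centers = _place_spots(
        _stream(seed, _STREAM_POSITION), n, (h, w), cfg.border_margin_px, cfg.min_separation_px
    )
    amplitudes = 10.0 ** _stream(seed, _STREAM_AMPLITUDE).normal(
        cfg.amplitude_log10_mean, cfg.amplitude_log10_sd, n
    )

    expected = np.full((h, w), float(cfg.background_level))
    for (x, y), a in zip(centers, amplitudes):
        _render_spot(expected, x, y, float(a), cfg.psf_sigma_px)

    rng_noise = _stream(seed, _STREAM_NOISE)
    if cfg.shot_noise:
        pixels = rng_noise.poisson(expected).astype(float)
    else:
        pixels = expected.copy()
    if cfg.read_noise_sd > 0:
        pixels += rng_noise.normal(0.0, cfg.read_noise_sd, (h, w))
    np.clip(pixels, 0.0, None, out=pixels)

    truth = FieldGroundTruth(
        spots=tuple((float(x), float(y), float(a)) for (x, y), a in zip(centers, amplitudes))
    )
    fld = TIRFField(
        pixels=pixels,
        pixel_size_um=cfg.pixel_size_um,
        field_index=field_index,
        channel=channel,
    )
    return fld, truth


@dataclass(frozen=True)
class WellSimResult:
    """All fields of one simulated well plus per-field substream seeds."""

    fields: tuple[TIRFField, ...]
    truths: tuple[FieldGroundTruth, ...]
    field_seeds: tuple[int, ...]

    @property
    def true_well_tfi(self) -> float:
        return float(sum(t.true_field_tfi for t in self.truths))

    @property
    def true_spot_count(self) -> int:
        return int(sum(t.n_spots for t in self.truths))

    def __iter__(self):
        return iter(zip(self.fields, self.truths))


def simulate_well(
    cfg: FieldSimConfig,
    n_fields: int = 100,
    seed: int = 0,
    channel: str = "",
) -> WellSimResult:
    """Simulate one well as ``n_fields`` independent TIRF fields.

    Per-field seeds are derived from the master seed through a scrambled
    SeedSequence offset, are recorded in the result, and are distinct.
    """
    if n_fields < 1:
        raise ValueError(f"n_fields must be >= 1, got {n_fields}")
    base = int(np.random.SeedSequence([int(seed)]).generate_state(1, np.uint32)[0])
    field_seeds = tuple((base + i) % 2**31 for i in range(n_fields))
    fields: list[TIRFField] = []
    truths: list[FieldGroundTruth] = []
    for i, fs in enumerate(field_seeds):
        fld, tr = simulate_field(cfg, fs, field_index=i, channel=channel)
        fields.append(fld)
        truths.append(tr)
    return WellSimResult(tuple(fields), tuple(truths), field_seeds)


# ---------------------------------------------------------------------------
# Spike-in calibration series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeSeriesConfig:
    """Spike-in dilution series: tumor-cell EVs spiked into a constant
    healthy-donor EV matrix at the listed concentrations (particles/mL).

    Expected response::

        TFI(C) = baseline + 10**intercept * C_eff**slope,
        C_eff  = C * K / (C + K)      (Langmuir capture saturation)

    i.e. log–log linear below the half-saturation concentration ``K`` with a
    roll-off above it; ``saturation_k = inf`` disables saturation.  Replicate
    noise is log-normal on the spike signal; the blank (zero spike) is the
    healthy-donor matrix baseline.
    """

    concentrations: tuple[float, ...]
    response_slope: float = 1.0
    response_intercept_log10: float = -3.0
    saturation_k: float = math.inf
    baseline_tfi_mean: float = 0.0
    baseline_tfi_sd: float = 0.0
    replicate_log10_sd: float = 0.05
    replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if len(self.concentrations) == 0:
            raise ValueError("concentrations must be non-empty")
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be sorted strictly ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.baseline_tfi_mean < 0 or self.baseline_tfi_sd < 0:
            raise ValueError("baseline parameters must be non-negative")
        if self.saturation_k <= 0:
            raise ValueError("saturation_k must be positive (inf to disable)")


def expected_spike_tfi(cfg: SpikeSeriesConfig, concentration: float) -> float:
    """Noise-free expected TFI at one spiked concentration."""
    c = float(concentration)
    if math.isinf(cfg.saturation_k):
        c_eff = c
    else:
        c_eff = c * cfg.saturation_k / (c + cfg.saturation_k)
    return cfg.baseline_tfi_mean + 10.0**cfg.response_intercept_log10 * c_eff**cfg.response_slope


def simulate_spikein_series(cfg: SpikeSeriesConfig) -> pd.DataFrame:
    """Simulate a calibration table.

    Returns a tidy frame with columns ``concentration, replicate, tfi``;
    blank (healthy-donor matrix only) replicates carry concentration 0.
    """
    cfg.validate()
    rng = _stream(cfg.seed, _STREAM_SPIKE)
    rows: list[tuple[float, int, float]] = []
    for r in range(cfg.replicates):
        blank = cfg.baseline_tfi_mean
        if cfg.baseline_tfi_sd > 0:
            blank += rng.normal(0.0, cfg.baseline_tfi_sd)
        rows.append((0.0, r, max(blank, 0.0)))
    for c in cfg.concentrations:
        signal = expected_spike_tfi(cfg, c) - cfg.baseline_tfi_mean
        for r in range(cfg.replicates):
            noise = 10.0 ** rng.normal(0.0, cfg.replicate_log10_sd) if cfg.replicate_log10_sd > 0 else 1.0
            baseline = cfg.baseline_tfi_mean
            if cfg.baseline_tfi_sd > 0:
                baseline += rng.normal(0.0, cfg.baseline_tfi_sd)
            rows.append((float(c), r, max(baseline + signal * noise, 0.0)))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "tfi"])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Multi-marker cohort with latent SCLC subtype.

    Per-sample log10 TFI across markers is multivariate normal with
    group/marker means (``log10_tfi_mean[group][marker]``), per-marker sd and
    a shared inter-marker correlation matrix; SCLC samples (LS/ES) draw a
    latent subtype from ``subtype_prevalence`` over (A, N, P, I) and receive
    the additive log10 shifts of ``subtype_shift_log10[subtype][marker]``.
    Control (HRS) samples receive no subtype shift.
    """

    n_per_group: Mapping[str, int]
    markers: tuple[str, ...] = DEFAULT_MARKERS
    log10_tfi_mean: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)
    log10_tfi_sd: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)
    subtype_prevalence: tuple[float, float, float, float] = (0.539, 0.197, 0.211, 0.053)
    subtype_shift_log10: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)
    inter_marker_corr: np.ndarray | None = None
    control_group: str = "HRS"
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must be non-empty")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be non-negative")
        prev = np.asarray(self.subtype_prevalence, dtype=float)
        if prev.shape != (4,) or np.any(prev < 0):
            raise ValueError("subtype_prevalence must be 4 non-negative probabilities")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_prevalence must sum to 1 within 1e-9")
        corr = self.corr_matrix()
        if corr.shape != (len(self.markers),) * 2:
            raise ValueError("inter_marker_corr shape must match marker count")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("inter_marker_corr must be symmetric")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
            raise ValueError("inter_marker_corr must be positive semi-definite")
        for group in self.n_per_group:
            for m in self.markers:
                if self.sd(group, m) < 0:
                    raise ValueError("all log10 TFI sds must be >= 0")

    def corr_matrix(self) -> np.ndarray:
        if self.inter_marker_corr is None:
            return np.eye(len(self.markers))
        return np.asarray(self.inter_marker_corr, dtype=float)

    def mean(self, group: str, marker: str) -> float:
        return float(self.log10_tfi_mean.get(group, {}).get(marker, 0.0))

    def sd(self, group: str, marker: str) -> float:
        return float(self.log10_tfi_sd.get(group, {}).get(marker, 0.0))

    def shift(self, subtype: str, marker: str) -> float:
        return float(self.subtype_shift_log10.get(subtype, {}).get(marker, 0.0))


def default_cohort_config(
    seed: int = 0,
    n_per_group: Mapping[str, int] | None = None,
    subtype_shift_defining: float = 0.8,
    subtype_shift_dll3: float = 0.5,
) -> CohortSimConfig:
    """Cohort configuration emulating the study conditions.

    Group sizes default to 45 high-risk smokers, 33 limited-stage and 43
    extensive-stage SCLC samples.  HRS log10-TFI means put the control
    distributions at the magnitudes of the assay's readout; SCLC groups share
    the transcription-factor baseline (subtype shifts carry that signal) and
    show elevated DLL3 Exo-mRNA in both stages and DLL3 tEV-mProtein mainly
    in extensive stage.  Subtype shifts: +0.8 log10 on the defining
    transcription factor, +0.5 log10 on DLL3 Exo-mRNA for subtypes A and N.
    """
    if n_per_group is None:
        n_per_group = {"HRS": 45, "LS": 33, "ES": 43}
    hrs_means = {
        "ASCL1": 3.55,
        "NEUROD1": 4.05,
        "POU2F3": 4.70,
        "DLL3_exo_mRNA": 4.60,
        "DLL3_tEV_mProtein": 4.95,
    }
    means = {
        "HRS": dict(hrs_means),
        "LS": {**hrs_means, "DLL3_exo_mRNA": 5.00, "DLL3_tEV_mProtein": 5.00},
        "ES": {**hrs_means, "DLL3_exo_mRNA": 5.00, "DLL3_tEV_mProtein": 5.20},
    }
    sds = {g: {m: 0.25 for m in DEFAULT_MARKERS} for g in ("HRS", "LS", "ES")}
    shifts = {
        "A": {"ASCL1": subtype_shift_defining, "DLL3_exo_mRNA": subtype_shift_dll3},
        "N": {"NEUROD1": subtype_shift_defining, "DLL3_exo_mRNA": subtype_shift_dll3},
        "P": {"POU2F3": subtype_shift_defining},
        "I": {},
    }
    k = len(DEFAULT_MARKERS)
    corr = np.full((k, k), 0.2)
    np.fill_diagonal(corr, 1.0)
    return CohortSimConfig(
        n_per_group=dict(n_per_group),
        markers=DEFAULT_MARKERS,
        log10_tfi_mean=means,
        log10_tfi_sd=sds,
        subtype_shift_log10=shifts,
        inter_marker_corr=corr,
        seed=seed,
    )


def simulate_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """Simulate a cohort table.

    Returns a frame with ``sample_id, group, latent_subtype`` followed by one
    TFI column per marker.  ``latent_subtype`` is ``"none"`` for control
    samples.
    """
    cfg.validate()
    rng = _stream(cfg.seed, _STREAM_COHORT)
    markers = list(cfg.markers)
    corr = cfg.corr_matrix()
    rows = []
    counter = 0
    for group in cfg.n_per_group:
        n = int(cfg.n_per_group[group])
        if n == 0:
            continue
        mu = np.array([cfg.mean(group, m) for m in markers])
        sd = np.array([cfg.sd(group, m) for m in markers])
        cov = corr * np.outer(sd, sd)
        # eigh factorization tolerates semi-definite covariances (e.g. sd = 0)
        log10_tfi = rng.multivariate_normal(mu, cov, size=n, method="eigh")
        is_sclc = group != cfg.control_group
        if is_sclc:
            subtypes = rng.choice(SUBTYPES, size=n, p=np.asarray(cfg.subtype_prevalence))
            for i, st in enumerate(subtypes):
                log10_tfi[i] += np.array([cfg.shift(str(st), m) for m in markers])
        else:
            subtypes = np.array(["none"] * n)
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:05d}",
                    "group": group,
                    "latent_subtype": str(subtypes[i]),
                    **{m: float(10.0 ** log10_tfi[i, j]) for j, m in enumerate(markers)},
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "latent_subtype", *markers])
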