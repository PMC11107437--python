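"""Seeded synthetic imaging data with the statistical structure the
analysis assumes.

No per-cell raw data accompany the study this pipeline reimplements, so
verification is done end-to-end on simulated recordings: a wide-field
340/385 nm Fura-2 movie, confocal RNAscope stacks displaced by a known
similarity misalignment, an ROI label image, intra-day negative-control
intensities, and the generating ground truth.

Population model (per probe channel), applied to each cultured cell:

* a cell is a neuron with probability ``fraction_neurons``; only neurons
  depolarize to KCl and only neurons can express the probe or respond to
  its agonist;
* a neuron expresses the probe's mRNA with probability
  ``fraction_expressing``; expression is lognormal (median
  ``expression_median``, log-sd ``expression_sigma``) — the bimodal
  positive/negative pattern seen in situ;
* expressing neurons respond to the agonist unless silenced
  (``p_silent_expressor`` -> mRNA-positive / function-negative cells), and
  non-expressing neurons may still respond (``p_responder_nonexpressor``
  -> function-positive / mRNA-negative cells); responder AUC is lognormal
  (median ``auc_median``, log-sd ``auc_sigma``) — response magnitudes are
  positive and right-skewed;
* within co-positive cells, expression and AUC are jointly lognormal; the
  latent (log-log) correlation is *calibrated in closed form*
  (mixture-moment algebra over the union clusters, including the ~2.3%
  functional false-positive cluster at the origin) so that the expected
  raw-scale Pearson correlation of (measured intensity, measured AUC) over
  the pipeline's union set equals ``true_correlation``.

Calcium responses use a single-exponential rise (tau 3 s) to a plateau for
the application, then exponential decay (tau 20 s); the amplitude is
scaled so the trapezoidal area of the noiseless kernel on the acquisition
grid over the 60 s scoring window equals the cell's true AUC.  Pixels
follow a Poisson photon + Gaussian read noise camera model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calcium import (AUC_SPAN, ApplicationWindow, RatioTrace, default_schedule,
                      validate_schedule)
from .registration import SimilarityTransform

#: one-sided tail beyond mean + 2*SD of a Gaussian — the functional
#: false-positive rate induced by the thresholding rule
FUNCTIONAL_FP_RATE = float(norm.sf(2.0))


@dataclass(frozen=True)
class ChannelParams:
    """Expression/response population model for one probe channel.

    Expression among expressors and AUC among responders are both
    lognormal: per-cell mRNA content and response magnitudes are
    right-skewed, strictly positive, and span a continuum from near the
    detection floor to bright/strong — there is no gap between "weak
    positives" and background, which is what makes the thresholded union
    statistically well behaved.
    """

    name: str
    agonist: str
    fraction_expressing: float = 0.35
    p_silent_expressor: float = 0.0
    p_responder_nonexpressor: float = 0.0
    true_correlation: float = 0.43
    expression_median: float = 150.0
    expression_sigma: float = 0.8      # lognormal log-sd (or sd, family="normal")
    auc_median: float = 25.0           # ratio*s, responder AUC median
    auc_sigma: float = 0.7             # lognormal log-sd (or sd, family="normal")
    family: str = "lognormal"          # marginal family: lognormal | normal

    def validate(self) -> None:
        for f in ("fraction_expressing", "p_silent_expressor", "p_responder_nonexpressor"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if not -1.0 <= self.true_correlation <= 1.0:
            raise ValueError(f"true_correlation must be in [-1, 1], got {self.true_correlation}")
        for f in ("expression_median", "expression_sigma", "auc_median", "auc_sigma"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0, got {getattr(self, f)}")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"family must be 'lognormal' or 'normal', got {self.family!r}")

    def expression_moments(self) -> tuple[float, float]:
        """(mean, variance) of expression among expressors."""
        if self.family == "normal":
            return self.expression_median, self.expression_sigma ** 2
        s = self.expression_sigma
        m = self.expression_median * np.exp(s * s / 2.0)
        return m, m * m * (np.exp(s * s) - 1.0)

    def auc_moments(self) -> tuple[float, float]:
        """(mean, variance) of AUC among responders."""
        if self.family == "normal":
            return self.auc_median, self.auc_sigma ** 2
        s = self.auc_sigma
        m = self.auc_median * np.exp(s * s / 2.0)
        return m, m * m * (np.exp(s * s) - 1.0)


def default_channels() -> tuple[ChannelParams, ChannelParams]:
    return (
        ChannelParams(name="trpa1", agonist="aitc", true_correlation=0.43),
        ChannelParams(name="trpv1", agonist="capsaicin", true_correlation=0.19),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic experiment (see module docstring)."""

    n_cells: int = 500
    fraction_neurons: float = 0.85
    channels: tuple[ChannelParams, ...] = field(default_factory=default_channels)
    schedule: tuple[ApplicationWindow, ...] = field(
        default_factory=lambda: tuple(default_schedule()))
    frame_rate: float = 1.0
    duration: float | None = None          # s; default: schedule end + 20
    noise_sd: float = 0.02                 # trace-level ratio noise
    baseline_ratio: float = 0.8
    kcl_amplitude: float = 0.8
    rise_tau: float = 3.0
    decay_tau: float = 20.0
    # geometry
    widefield_shape: tuple[int, int] = (512, 512)
    confocal_shape: tuple[int, int] = (512, 512)
    n_planes: int = 21
    cell_radius: float = 4.0
    min_separation: float = 11.0
    margin: float = 30.0
    transform: SimilarityTransform = field(
        default_factory=lambda: SimilarityTransform(3.0, (12.0, -7.0), 1.03))
    # camera / staining model
    wf_background: tuple[float, float] = (150.0, 200.0)   # 340, 385 nm counts
    wf_cell_brightness: float = 1800.0
    read_noise_sd: float = 3.0
    confocal_background: float = 20.0
    trans_background: float = 1000.0
    trans_contrast: tuple[float, float] = (300.0, 60.0)   # mean, sd per cell
    dapi_intensity: float = 500.0
    # negative controls
    n_controls: int = 50
    control_mean: float = 0.5
    control_sd: float = 1.2
    intensity_noise_sd: float = 0.3        # table-level measurement noise
    photon_noise: str = "poisson"          # poisson | gaussian (approximation)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be positive, got {self.n_cells}")
        if not 0.0 <= self.fraction_neurons <= 1.0:
            raise ValueError(f"fraction_neurons must be in [0, 1], got {self.fraction_neurons}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for nm, shape in (("widefield_shape", self.widefield_shape),
                          ("confocal_shape", self.confocal_shape)):
            if len(shape) != 2 or min(shape) <= 0:
                raise ValueError(f"{nm} must be two positive integers, got {shape}")
        if self.n_planes < 1:
            raise ValueError(f"n_planes must be >= 1, got {self.n_planes}")
        if self.cell_radius <= 0:
            raise ValueError(f"cell_radius must be > 0, got {self.cell_radius}")
        if self.n_controls < 3:
            raise ValueError(f"n_controls must be >= 3, got {self.n_controls}")
        if self.photon_noise not in ("poisson", "gaussian"):
            raise ValueError(
                f"photon_noise must be 'poisson' or 'gaussian', got {self.photon_noise!r}")
        validate_schedule(list(self.schedule))
        names = [cp.name for cp in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        sched_agonists = {w.agonist for w in self.schedule}
        for cp in self.channels:
            cp.validate()
            if cp.agonist not in sched_agonists:
                raise ValueError(
                    f"channel {cp.name}: agonist {cp.agonist!r} not in schedule")

    @property
    def record_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        return max(w.end for w in self.schedule) + 20.0

    def times(self) -> np.ndarray:
        n = int(round(self.record_duration * self.frame_rate))
        return np.arange(n, dtype=float) / self.frame_rate


def auc_noise_sd(noise_sd: float, span: float = AUC_SPAN,
                 baseline_span: float = 5.0, frame_rate: float = 1.0) -> float:
    """Standard deviation of the measured AUC induced by white trace noise.

    Two terms: trapezoidal integration of per-sample noise (weights 1/2 at
    the window ends) and the baseline estimate error, which enters scaled
    by the window length.
    """
    h = 1.0 / frame_rate
    n = int(round(span * frame_rate))  # intervals
    w2 = (n - 1) + 2 * 0.25            # sum of squared trapezoid weights * h^2
    var = noise_sd ** 2 * (h * h * w2 + span ** 2 / (baseline_span * frame_rate))
    return float(np.sqrt(var))


def discordance_from_counts(both: int, rnascope_only: int, functional_only: int,
                            neither: int,
                            fp_rate: float = FUNCTIONAL_FP_RATE) -> dict[str, float]:
    """Invert observed category counts into latent generator rates.

    The thresholding rule converts a known fraction ``fp_rate`` of
    function-negative cells into apparent responders (mRNA-positive
    non-responders appear as double positives, blanks as function-only), so
    latent class probabilities must be slightly different from the observed
    breakdown for the *expected observed* counts to match it.  This solves
    the linear forward model for the latent rates.
    """
    q = fp_rate
    r_lat = rnascope_only / (1 - q)
    b_lat = both - q * r_lat
    n_lat = neither / (1 - q)
    f_lat = functional_only - q * n_lat
    if min(b_lat, f_lat) < 0:
        raise ValueError("counts are inconsistent with the false-positive model")
    total = b_lat + r_lat + f_lat + n_lat
    return {
        "fraction_expressing": (b_lat + r_lat) / total,
        "p_silent_expressor": r_lat / (b_lat + r_lat),
        "p_responder_nonexpressor": f_lat / (f_lat + n_lat),
    }


def within_correlation(cp: ChannelParams,
                       fp_rate: float = FUNCTIONAL_FP_RATE,
                       intensity_noise_var: float = 0.0,
                       auc_noise_var: float = 0.0) -> float:
    """Calibrated within-class latent correlation for one channel.

    Solves the mixture-moment equation so the expected raw-scale Pearson
    correlation of (measured intensity, measured AUC) over the union set
    equals ``cp.true_correlation``.  Union clusters: co-positive cells
    (latent correlation rho_l, the unknown), mRNA-positive non-responders,
    responders without mRNA, and the functional false positives of the
    ``neither`` class (at the origin).  Measurement noise variances are
    added to the mixture variances so the calibration compensates the
    attenuation they cause.  For lognormal marginals the raw-scale
    within-class covariance is ``m_x * m_y * (exp(rho_l * sx * sy) - 1)``;
    for normal marginals it is ``rho_l * sx * sy``.  Clips (with a
    warning) when the target is unattainable for the configured
    discordance geometry.
    """
    fe, sil, rn = (cp.fraction_expressing, cp.p_silent_expressor,
                   cp.p_responder_nonexpressor)
    p = np.array([
        fe * (1 - sil),            # both
        fe * sil,                  # rnascope_only
        (1 - fe) * rn,             # functional_only
        fp_rate * (1 - fe) * (1 - rn),  # false positives from 'neither'
    ])
    if p.sum() <= 0:
        return 0.0
    w = p / p.sum()
    m_x, v_x = cp.expression_moments()
    m_y, v_y = cp.auc_moments()
    mx = np.array([m_x, m_x, 0.0, 0.0])
    my = np.array([m_y, 0.0, m_y, 0.0])
    vx = np.array([v_x, v_x, 0.0, 0.0])
    vy = np.array([v_y, 0.0, v_y, 0.0])
    mxb = float(w @ mx)
    myb = float(w @ my)
    var_x = float(w @ (vx + (mx - mxb) ** 2)) + intensity_noise_var
    var_y = float(w @ (vy + (my - myb) ** 2)) + auc_noise_var
    between = float(w @ ((mx - mxb) * (my - myb)))
    target_cov = cp.true_correlation * np.sqrt(var_x * var_y)
    sx, sy = cp.expression_sigma, cp.auc_sigma
    if w[0] == 0 or sx * sy == 0:
        if abs(target_cov - between) > 1e-9 * max(1.0, abs(target_cov)):
            warnings.warn(
                f"channel {cp.name}: no co-positive population to carry the "
                "correlation target; generated correlation is fixed by the "
                "cluster geometry", UserWarning)
        return 0.0
    c_w = (target_cov - between) / w[0]   # within-class covariance needed
    if cp.family == "normal":
        rho_l = c_w / (sx * sy)
    else:
        arg = 1.0 + c_w / (m_x * m_y)
        rho_l = np.log(arg) / (sx * sy) if arg > 0 else -np.inf
    if not -1.0 <= rho_l <= 1.0:
        warnings.warn(
            f"channel {cp.name}: union correlation target "
            f"{cp.true_correlation:.3g} unattainable for this discordance "
            f"geometry (needed latent correlation {rho_l:.3g}); "
            "clipping to +/-1", UserWarning)
        rho_l = float(np.clip(rho_l, -1.0, 1.0))
    return float(rho_l)


# ---------------------------------------------------------------------------
# ground truth


def sample_ground_truth(config: SynthConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the latent per-cell table: identity, expression, true AUCs."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_neurons = int(round(config.fraction_neurons * n))
    is_neuron = np.zeros(n, dtype=bool)
    is_neuron[:n_neurons] = True

    df = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "is_neuron": is_neuron,
        "kcl_responsive": is_neuron.copy(),
    })
    s_auc = auc_noise_sd(config.noise_sd, frame_rate=config.frame_rate)
    for cp in config.channels:
        rho_w = within_correlation(
            cp, intensity_noise_var=config.intensity_noise_sd ** 2,
            auc_noise_var=s_auc ** 2)
        expressing = is_neuron & (rng.random(n) < cp.fraction_expressing)
        resp_if_expr = rng.random(n) >= cp.p_silent_expressor
        resp_if_not = rng.random(n) < cp.p_responder_nonexpressor
        responder = is_neuron & np.where(expressing, resp_if_expr, resp_if_not)

        z_e = rng.standard_normal(n)
        z_a = rho_w * z_e + np.sqrt(max(0.0, 1 - rho_w ** 2)) * rng.standard_normal(n)
        if cp.family == "normal":
            expr_vals = np.maximum(cp.expression_median + cp.expression_sigma * z_e, 0.0)
            auc_vals = np.maximum(cp.auc_median + cp.auc_sigma * z_a, 1e-9)
        else:
            expr_vals = cp.expression_median * np.exp(cp.expression_sigma * z_e)
            auc_vals = cp.auc_median * np.exp(cp.auc_sigma * z_a)
        expression = np.where(expressing, expr_vals, 0.0)
        auc = np.where(responder, auc_vals, 0.0)

        df[f"expression_{cp.name}"] = expression
        df[f"expressing_{cp.name}"] = expressing
        df[f"responder_{cp.name}"] = responder
        df[f"true_auc_{cp.agonist}"] = auc
    return df


def place_cells(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement of cell centroids with a minimum
    separation, inside the field margin.  Returns (n, 2) (x, y) positions."""
    h, w = config.widefield_shape
    lo_x, hi_x = config.margin, w - 1 - config.margin
    lo_y, hi_y = config.margin, h - 1 - config.margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("margin leaves no room for cell placement in widefield_shape")
    pts = np.empty((config.n_cells, 2))
    n_placed = 0
    d2 = config.min_separation ** 2
    max_tries = 4000 * config.n_cells
    tries = 0
    while n_placed < config.n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {config.n_cells} cells with min_separation "
                f"{config.min_separation} in widefield_shape {config.widefield_shape}")
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        head = pts[:n_placed]
        if n_placed and np.min((head[:, 0] - x) ** 2 + (head[:, 1] - y) ** 2) < d2:
            continue
        pts[n_placed] = (x, y)
        n_placed += 1
    return pts


def label_image(shape: tuple[int, int], centroids: np.ndarray,
                radius: float | np.ndarray) -> np.ndarray:
    """Paint disk ROIs (label = cell index + 1) onto a zero background."""
    lab = np.zeros(shape, dtype=np.int32)
    radii = np.broadcast_to(np.asarray(radius, dtype=float), (len(centroids),))
    h, w = shape
    for i, ((cx, cy), r) in enumerate(zip(centroids, radii)):
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        lab[y0:y1, x0:x1][mask] = i + 1
    return lab


# ---------------------------------------------------------------------------
# trace model


def response_kernel(times: np.ndarray, start: float, duration: float,
                    rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-plateau response: exponential rise during the application,
    exponential decay after washout."""
    t = np.asarray(times, dtype=float) - start
    k = np.zeros_like(t)
    during = (t >= 0) & (t <= duration)
    k[during] = 1.0 - np.exp(-t[during] / rise_tau)
    after = t > duration
    peak = 1.0 - np.exp(-duration / rise_tau)
    k[after] = peak * np.exp(-(t[after] - duration) / decay_tau)
    return k


def kernel_window_area(times: np.ndarray, window: ApplicationWindow,
                       rise_tau: float, decay_tau: float,
                       span: float = AUC_SPAN) -> float:
    """Trapezoidal area of the unit kernel over the AUC scoring window on
    the acquisition grid — the normalization that makes rendered traces
    integrate back to their true AUC exactly."""
    sel = (times >= window.start) & (times <= window.start + span)
    k = response_kernel(times[sel], window.start, window.duration, rise_tau, decay_tau)
    return float(np.trapezoid(k, times[sel]))


def trace_matrix(ground_truth: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    """Noiseless (n_cells, n_frames) ratio matrix for all cells."""
    times = config.times()
    out = np.full((len(ground_truth), times.size), config.baseline_ratio)
    for w in config.schedule:
        k = response_kernel(times, w.start, w.duration, config.rise_tau, config.decay_tau)
        if w.agonist.lower() == "kcl":
            amp = np.where(ground_truth["kcl_responsive"].to_numpy(), config.kcl_amplitude, 0.0)
        else:
            col = f"true_auc_{w.agonist}"
            if col not in ground_truth.columns:
                continue
            area = kernel_window_area(times, w, config.rise_tau, config.decay_tau)
            amp = ground_truth[col].to_numpy() / area
        out += amp[:, None] * k[None, :]
    return out


def render_trace(cell, schedule, noise_sd: float, seed=None,
                 duration: float | None = None, frame_rate: float = 1.0,
                 baseline_ratio: float = 0.8, kcl_amplitude: float = 0.8,
                 rise_tau: float = 3.0, decay_tau: float = 20.0) -> RatioTrace:
    """Render one cell's ratio trace from its ground-truth row.

    ``cell`` is a mapping with ``true_auc_<agonist>`` entries and
    ``kcl_responsive``; ``seed`` may be an integer or a Generator.
    """
    schedule = list(schedule)
    validate_schedule(schedule)
    if duration is None:
        duration = max(w.end for w in schedule) + 20.0
    times = np.arange(int(round(duration * frame_rate)), dtype=float) / frame_rate
    ratio = np.full_like(times, baseline_ratio)
    for w in schedule:
        k = response_kernel(times, w.start, w.duration, rise_tau, decay_tau)
        if w.agonist.lower() == "kcl":
            amp = kcl_amplitude if bool(cell["kcl_responsive"]) else 0.0
        else:
            key = f"true_auc_{w.agonist}"
            if key not in cell:
                continue
            area = kernel_window_area(times, w, rise_tau, decay_tau)
            amp = float(cell[key]) / area
        ratio += amp * k
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)
    cid = int(cell["cell_id"]) if "cell_id" in cell else 0
    return RatioTrace(cell_id=cid, times=times, ratio=ratio, roi_area=0)


# ---------------------------------------------------------------------------
# table-level fast path


def sample_measurements(config: SynthConfig,
                        rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell measured values without rendering images.

    Emulates what the imaging pipeline measures — AUC with integration +
    baseline noise, intensity with measurement noise floored at zero — for
    fast statistical tests of the classification and correlation stages.
    Returns ``(cells, negative_controls)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gt = sample_ground_truth(config, rng)
    s_auc = auc_noise_sd(config.noise_sd, frame_rate=config.frame_rate)
    out = gt[["cell_id", "is_neuron", "kcl_responsive"]].copy()
    out["kcl_pass"] = gt["kcl_responsive"]
    for cp in config.channels:
        out[f"auc_{cp.agonist}"] = (gt[f"true_auc_{cp.agonist}"]
                                    + rng.normal(0.0, s_auc, len(gt)))
        meas = gt[f"expression_{cp.name}"] + rng.normal(
            0.0, config.intensity_noise_sd, len(gt))
        out[f"intensity_{cp.name}"] = np.clip(meas, 0.0, None)
    controls = np.clip(
        rng.normal(config.control_mean, config.control_sd, config.n_controls), 0.0, None)
    return out, controls


# ---------------------------------------------------------------------------
# image rendering


@dataclass
class SyntheticDataset:
    """In-memory synthetic experiment: everything the pipeline consumes,
    plus the generating truth for verification."""

    config: SynthConfig
    ground_truth: pd.DataFrame
    centroids_widefield: np.ndarray
    movie: np.ndarray                 # (t, 2, y, x) uint16; channel 0=340, 1=385
    times: np.ndarray
    roi_labels: np.ndarray            # wide-field frame, label = cell_id
    widefield_trans: np.ndarray
    confocal: dict[str, np.ndarray]   # probe/dapi name -> (z, y, x) uint16
    confocal_trans: np.ndarray
    negative_controls: np.ndarray
    transform: SimilarityTransform    # true confocal -> widefield mapping

    def write(self, outdir) -> None:
        from . import io as _io
        _io.write_dataset(self, outdir)


def _poisson_camera(rng: np.random.Generator, lam: np.ndarray,
                    read_sd: float, model: str = "poisson") -> np.ndarray:
    """Photon + read noise.  ``model='gaussian'`` uses the mean/variance-
    matched normal approximation to the Poisson photon count, accurate at
    the >100-count background levels simulated here and ~4x faster."""
    if model == "gaussian":
        z = rng.standard_normal(lam.shape)
        img = lam + np.sqrt(lam + read_sd * read_sd) * z
    else:
        img = rng.poisson(lam).astype(np.float64)
        if read_sd > 0:
            img += rng.normal(0.0, read_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Render the full synthetic experiment (deterministic in config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = sample_ground_truth(config, rng)
    n = config.n_cells

    centroids = place_cells(config, rng)
    labels_wf = label_image(config.widefield_shape, centroids, config.cell_radius)
    tf = config.transform
    centroids_conf = tf.inverse().apply_points(centroids)
    labels_conf = label_image(config.confocal_shape, centroids_conf,
                              config.cell_radius / tf.scale)

    ratios = trace_matrix(gt, config)          # (n, T)
    times = config.times()
    n_t = times.size
    b340, b385 = config.wf_background
    bright = config.wf_cell_brightness

    movie = np.empty((n_t, 2) + tuple(config.widefield_shape), dtype=np.uint16)
    lut385 = np.zeros(n + 1)
    lut385[1:] = bright
    lam385 = b385 + lut385[labels_wf]
    lut340 = np.zeros(n + 1)
    for t in range(n_t):
        lut340[1:] = bright * ratios[:, t]
        lam340 = b340 + lut340[labels_wf]
        movie[t, 0] = _poisson_camera(rng, lam340, config.read_noise_sd, config.photon_noise)
        movie[t, 1] = _poisson_camera(rng, lam385, config.read_noise_sd, config.photon_noise)

    # transmitted-light pair for registration (same per-cell contrast in
    # both frames; the confocal one is drawn at the transformed positions)
    contrast = rng.normal(*config.trans_contrast, size=n)
    lut = np.zeros(n + 1)
    lut[1:] = contrast
    trans_wf = _poisson_camera(
        rng, config.trans_background + lut[labels_wf], config.read_noise_sd,
        config.photon_noise)
    trans_conf = _poisson_camera(
        rng, config.trans_background + lut[labels_conf], config.read_noise_sd,
        config.photon_noise)

    # confocal stacks: soma intensity proportional to expression (the
    # perikaryal signal is dense enough that discrete puncta merge).  The
    # soma is drawn slightly larger than the ROI disk: ROIs are adapted to
    # lie inside the cell boundary, so every transferred ROI pixel samples
    # the plateau rather than the soma edge.
    soma_labels = label_image(config.confocal_shape, centroids_conf,
                              (config.cell_radius + 0.8) / tf.scale)
    confocal: dict[str, np.ndarray] = {}
    cbg = config.confocal_background
    for cp in config.channels:
        lut_e = np.zeros(n + 1)
        lut_e[1:] = gt[f"expression_{cp.name}"].to_numpy()
        lam_plane = cbg + lut_e[soma_labels]
        stack = np.empty((config.n_planes,) + tuple(config.confocal_shape),
                         dtype=np.uint16)
        for p in range(config.n_planes):
            stack[p] = _poisson_camera(rng, lam_plane, config.read_noise_sd, config.photon_noise)
        confocal[cp.name] = stack

    lut_d = np.zeros(n + 1)
    lut_d[1:] = config.dapi_intensity
    labels_nuc = label_image(config.confocal_shape, centroids_conf,
                             config.cell_radius / tf.scale / 2.0)
    lam_dapi = cbg + lut_d[labels_nuc]
    dapi = np.empty((config.n_planes,) + tuple(config.confocal_shape), dtype=np.uint16)
    for p in range(config.n_planes):
        dapi[p] = _poisson_camera(rng, lam_dapi, config.read_noise_sd, config.photon_noise)
    confocal["dapi"] = dapi

    controls = np.clip(
        rng.normal(config.control_mean, config.control_sd, config.n_controls), 0.0, None)

    return SyntheticDataset(
        config=config, ground_truth=gt, centroids_widefield=centroids,
        movie=movie, times=times, roi_labels=labels_wf,
        widefield_trans=trans_wf, confocal=confocal, confocal_trans=trans_conf,
        negative_controls=controls, transform=tf,
    )


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    if "channels" in d:
        d["channels"] = tuple(
            cp if isinstance(cp, ChannelParams) else ChannelParams(**cp)
            for cp in d["channels"])
    if "schedule" in d:
        d["schedule"] = tuple(
            w if isinstance(w, ApplicationWindow) else ApplicationWindow(**w)
            for w in d["schedule"])
    if "transform" in d and not isinstance(d["transform"], SimilarityTransform):
        t = d["transform"]
        d["transform"] = SimilarityTransform(
            rotation_deg=float(t.get("rotation_deg", 0.0)),
            translation=tuple(t.get("translation", (0.0, 0.0))),
            scale=float(t.get("scale", 1.0)))
    for key in ("widefield_shape", "confocal_shape", "wf_background",
                "trans_contrast"):
        if key in d:
            d[key] = tuple(d[key])
    return SynthConfig(**d)


def correlation_recovery_config(true_correlation: float = 0.43,
                                trpv1_correlation: float = 0.19,
                                n_cells: int = 500, seed: int = 0,
                                **overrides) -> SynthConfig:
    """Benchmark condition for correlation recovery through the pipeline.

    Every gated neuron expresses both probes and responds to both agonists
    (the single-population analog of a co-transfected cell line), with
    modest-CV lognormal marginals.  This isolates the measurement chain —
    rendering, ratio extraction, registration, ROI transfer, intensity
    quantification, union selection — from population-structure effects:
    the union is the whole coupled population, so the recovered Pearson R
    is Fisher-consistent and can be compared against its nominal
    confidence interval.  Marginals are bivariate normal with moderate CV
    (far from zero, so positivity is never clipped in practice); with the
    realistic bimodal default population the thresholded union's R has
    super-Fisher variance (see docs/methods.md).
    """
    channels = (
        ChannelParams(name="trpa1", agonist="aitc", fraction_expressing=1.0,
                      true_correlation=true_correlation, family="normal",
                      expression_median=150.0, expression_sigma=25.0,
                      auc_median=25.0, auc_sigma=5.0),
        ChannelParams(name="trpv1", agonist="capsaicin", fraction_expressing=1.0,
                      true_correlation=trpv1_correlation, family="normal",
                      expression_median=150.0, expression_sigma=25.0,
                      auc_median=25.0, auc_sigma=5.0),
    )
    return SynthConfig(n_cells=n_cells, channels=channels, seed=seed, **overrides)


def study_emulation_config(counts: dict[str, dict[str, int]],
                           n_gated: int = 890,
                           fraction_neurons: float = 0.85,
                           seed: int = 0, **overrides) -> SynthConfig:
    """Config whose expected observed category counts match a published
    breakdown.

    ``counts`` maps channel name -> {'both', 'rnascope_only',
    'functional_only'} observed counts; the remainder up to ``n_gated`` is
    'neither'.  Cell number is scaled so the expected KCl-gated population
    equals ``n_gated``.
    """
    base = {cp.name: cp for cp in default_channels()}
    channels = []
    for name, c in counts.items():
        neither = n_gated - c["both"] - c["rnascope_only"] - c["functional_only"]
        rates = discordance_from_counts(c["both"], c["rnascope_only"],
                                        c["functional_only"], neither)
        channels.append(replace(base[name], **rates))
    n_cells = int(round(n_gated / fraction_neurons))
    overrides.setdefault("widefield_shape", (640, 640))
    overrides.setdefault("confocal_shape", (640, 640))
    return SynthConfig(n_cells=n_cells, fraction_neurons=fraction_neurons,
                       channels=tuple(channels), seed=seed, **overrides)
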