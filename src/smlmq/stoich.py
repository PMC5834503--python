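"""Completeness-of-labeling analysis of homo-oligomeric counting standards.

The workflow quantifies how completely a 24-subunit ferritin (FtnA)
oligomer is decorated with fluorophores:

1.  Single-fluorophore calibration — blink amplitudes (baseline-to-peak)
    are extracted from ROI intensity traces and their histogram fitted with
    a log-normal density

        f(x) = 1 / (x σ √(2π)) · exp(−(ln x − µ)² / (2σ²)),

    giving (µ, σ) of one fluorophore's integrated intensity.
2.  Fully-labeled model — with degree of labeling p and n subunits, the
    number of fluorophores per oligomer is Binomial(n, p); the intensity
    density of a k-labeled oligomer is the k-fold self-convolution of the
    single-fluorophore log-normal, and the observable mixture is
    Σ_k P(k)·conv_k for k ≥ 1 (unlabeled oligomers produce no spot and are
    excluded, with renormalization).
3.  Completeness — 100 · median(measured oligomer intensities) /
    median(fully-labeled mixture), with a bootstrap CI over the measured
    set and a sensitivity band from the uncertainty of p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .core_io import IntensityTrace

__all__ = [
    "BlinkEvent",
    "LogNormalParams",
    "LabelingModel",
    "IntensityDistribution",
    "CompletenessResult",
    "extract_blinks",
    "collect_blink_amplitudes",
    "fit_single_fluorophore",
    "SingleFluorophoreCalibrator",
    "oligomer_intensity",
    "default_grid",
    "kfold_convolution",
    "mixture_distribution",
    "completeness",
]


@dataclass(frozen=True)
class BlinkEvent:
    trace_id: str
    start_frame: int
    end_frame: int
    amplitude: float  # baseline-to-peak AD counts

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("blink amplitude must be > 0")


@dataclass(frozen=True)
class LogNormalParams:
    """Parameters of ln(intensity): location µ and scale σ."""

    mu: float
    sigma: float
    mu_err: float = float("nan")
    sigma_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def cdf(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import ndtr

        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = ndtr((np.log(x[pos]) - self.mu) / self.sigma)
        return out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = (
            1.0
            / (x[pos] * self.sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-((np.log(x[pos]) - self.mu) ** 2) / (2.0 * self.sigma**2))
        )
        return out

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


@dataclass(frozen=True)
class LabelingModel:
    """Binomial subunit labeling of an n-mer with calibrated fluorophores.

    ``dol`` is the degree of labeling (binomial success probability p),
    ``dol_sd`` its uncertainty used for the sensitivity band.
    """

    dol: float
    single: LogNormalParams
    n_subunits: int = 24
    dol_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dol <= 1.0:
            raise ValueError("dol must be in [0, 1]")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")

    def state_probabilities(self) -> np.ndarray:
        """P(k), k = 0..n, of carrying k fluorophores."""
        return binom.pmf(np.arange(self.n_subunits + 1), self.n_subunits, self.dol)


@dataclass
class IntensityDistribution:
    """Density over AD counts on a uniform grid (nodes at i·step)."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.density = np.asarray(self.density, float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must align")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.step)

    @property
    def mean(self) -> float:
        return float((self.grid * self.density).sum() * self.step / self.mass)

    def cdf(self, x: np.ndarray | None = None) -> np.ndarray:
        """Trapezoid cumulative distribution, optionally at query points."""
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        c = c / c[-1]
        if x is None:
            return c
        return np.interp(np.asarray(x, float), self.grid, c)

    @property
    def median(self) -> float:
        c = self.cdf()
        return float(np.interp(0.5, c, self.grid))


@dataclass
class CompletenessResult:
    percent: float
    ci_low: float
    ci_high: float
    dol_band_low: float
    dol_band_high: float
    median_measured: float
    median_model: float


# ---------------------------------------------------------------------------
# blink extraction and calibration


def extract_blinks(
    trace: IntensityTrace,
    window: int = 100,
    min_blinks: int = 2,
    k_sigma: float = 3.0,
    min_sep_frames: int = 3,
) -> list[BlinkEvent] | None:
    """Step-like blink events in the last ``window`` frames of a trace.

    The local baseline is the median of the window and the noise scale its
    MAD; frames rising more than ``k_sigma``·noise above baseline form
    events (runs closer than ``min_sep_frames`` are merged).  Traces with
    fewer than ``min_blinks`` events are rejected (returns None); the
    amplitude of an event is its peak minus the baseline.
    """
    counts = trace.counts
    if len(counts) < window:
        raise ValueError("trace shorter than the blink window")
    seg = counts[-window:]
    baseline = float(np.median(seg))
    noise = 1.4826 * float(np.median(np.abs(seg - baseline)))
    noise = max(noise, 1e-9)
    above = seg > baseline + k_sigma * noise
    events = []
    runs = _runs(above)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_sep_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    offset = len(counts) - window
    for s, e in merged:
        amp = float(seg[s:e].max() - baseline)
        events.append(BlinkEvent(trace.trace_id, offset + s, offset + e, amp))
    if len(events) < min_blinks:
        return None
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def collect_blink_amplitudes(
    traces: list[IntensityTrace], **kwargs
) -> np.ndarray:
    """Amplitudes from all traces that pass the ≥2-blink selection."""
    amps = []
    for t in traces:
        events = extract_blinks(t, **kwargs)
        if events is not None:
            amps.extend(ev.amplitude for ev in events)
    return np.asarray(amps, float)


def fit_single_fluorophore(
    amplitudes: np.ndarray, bin_ad: float = 100.0, min_amplitudes: int = 50
) -> LogNormalParams:
    """Least-squares log-normal fit of the binned amplitude histogram.

    Amplitudes are binned at ``bin_ad`` AD counts and converted to relative
    frequencies; the predicted relative frequency of a bin is the log-normal
    probability mass over the bin (CDF difference, so the fit is unbiased
    even when bins are wide relative to the distribution), fitted by
    nonlinear least squares.  Initial values come from the closed-form ML
    estimates (mean and SD of ln amplitude).
    """
    amplitudes = np.asarray(amplitudes, float)
    amplitudes = amplitudes[amplitudes > 0]
    if len(amplitudes) < min_amplitudes:
        raise ValueError(f"need >= {min_amplitudes} amplitudes, got {len(amplitudes)}")
    loga = np.log(amplitudes)
    mu0, sigma0 = float(loga.mean()), float(loga.std(ddof=1))
    if sigma0 < 1e-6:
        raise ValueError("degenerate amplitude distribution (zero spread)")
    edges = np.arange(0.0, amplitudes.max() + 2 * bin_ad, bin_ad)
    hist, edges = np.histogram(amplitudes, bins=edges)
    rel = hist / hist.sum()
    lefts = edges[:-1]

    def model(left, mu, sigma):
        p = LogNormalParams(mu, max(sigma, 1e-9))
        return p.cdf(left + bin_ad) - p.cdf(left)

    try:
        popt, pcov = curve_fit(
            model, lefts, rel, p0=[mu0, sigma0],
            bounds=([0.0, 1e-3], [np.inf, 10.0]), maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"log-normal fit did not converge (n={len(amplitudes)}): {exc}"
        ) from None
    errs = np.sqrt(np.diag(pcov))
    return LogNormalParams(float(popt[0]), float(popt[1]), float(errs[0]), float(errs[1]))


class SingleFluorophoreCalibrator(BaseEstimator):
    """fit(amplitudes) -> single-fluorophore log-normal in ``params_``."""

    def __init__(self, bin_ad: float = 100.0, min_amplitudes: int = 50):
        self.bin_ad = bin_ad
        self.min_amplitudes = min_amplitudes

    def fit(self, X: np.ndarray, y=None) -> "SingleFluorophoreCalibrator":
        self.params_ = fit_single_fluorophore(X, self.bin_ad, self.min_amplitudes)
        self.mu_ = self.params_.mu
        self.sigma_ = self.params_.sigma
        return self


# ---------------------------------------------------------------------------
# oligomer intensities and the mixture model


def oligomer_intensity(
    trace: IntensityTrace,
    baseline_window: int = 100,
    subtract_baseline: bool = True,
    baseline_quantile: float = 0.2,
) -> float:
    """Integrated ROI intensity of the second frame (index 1).

    At that point all fluorophores of the oligomer are still on.  The
    per-trace baseline, estimated as a low quantile of the last
    ``baseline_window`` frames (robust against the sparse blink pulses that
    occupy that window), is subtracted by default.
    """
    if trace.n_frames < 2:
        raise ValueError("trace must have >= 2 frames")
    value = float(trace.counts[1])
    if subtract_baseline:
        value -= float(np.quantile(trace.counts[-baseline_window:], baseline_quantile))
    return value


def default_grid(single: LogNormalParams, step_ad: float = 10.0) -> np.ndarray:
    """Uniform grid wide enough for a 24-fold convolution support.

    Nodes sit at integer multiples of the step (x_i = i·h) so that discrete
    convolution is exactly lattice-aligned: x_i + x_j lands on a node.
    """
    upper = 40.0 * np.exp(single.mu + 3.0 * single.sigma)
    n = int(np.ceil(upper / step_ad))
    return np.arange(n) * step_ad


def _single_density(single: LogNormalParams, grid: np.ndarray) -> np.ndarray:
    d = single.pdf(grid)
    step = grid[1] - grid[0]
    return d / (d.sum() * step)  # exact unit mass on the grid


def _convolutions(
    single: LogNormalParams, k_max: int, grid: np.ndarray, max_mass_loss: float = 1e-4
) -> list[np.ndarray]:
    """Densities of conv_1..conv_k_max by recursive discrete convolution."""
    step = grid[1] - grid[0]
    base = _single_density(single, grid)
    out = [base]
    for k in range(2, k_max + 1):
        c = signal.fftconvolve(out[-1], base)[: len(grid)] * step
        c = np.clip(c, 0.0, None)
        lost = 1.0 - c.sum() * step
        if lost > max_mass_loss:
            raise ValueError(
                f"grid too short for {k}-fold convolution (mass loss {lost:.2e})"
            )
        out.append(c)
    return out


def kfold_convolution(
    single: LogNormalParams, k: int, grid: np.ndarray | None = None
) -> IntensityDistribution:
    """Density of the sum of k independent single-fluorophore intensities."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if grid is None:
        grid = default_grid(single)
    return IntensityDistribution(grid, _convolutions(single, k, grid)[k - 1])


def mixture_distribution(
    model: LabelingModel, grid: np.ndarray | None = None
) -> IntensityDistribution:
    """Binomial mixture Σ_k P(k)·conv_k over the observable states k ≥ 1.

    Unlabeled oligomers (k = 0) produce no selectable spot, so the mixture
    is renormalized over k ≥ 1.
    """
    if grid is None:
        grid = default_grid(model.single)
    probs = model.state_probabilities()
    convs = _convolutions(model.single, model.n_subunits, grid)
    density = np.zeros_like(grid)
    for k in range(1, model.n_subunits + 1):
        density += probs[k] * convs[k - 1]
    density /= 1.0 - probs[0]
    step = grid[1] - grid[0]
    density /= density.sum() * step
    return IntensityDistribution(grid, density)


def completeness(
    measured_intensities: np.ndarray,
    model: LabelingModel,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_measurements: int = 30,
) -> CompletenessResult:
    """Labeling completeness: measured vs fully-labeled median, in percent.

    completeness = 100 · median(measured) / median(mixture(model)).  The
    95% CI is a percentile bootstrap over the measured set; the dol band
    re-evaluates the model median at p ± dol_sd.
    """
    measured = np.asarray(measured_intensities, float)
    if len(measured) < min_measurements:
        raise ValueError(f"need >= {min_measurements} measured intensities")
    grid = default_grid(model.single)
    med_model = mixture_distribution(model, grid).median
    med_meas = float(np.median(measured))
    percent = 100.0 * med_meas / med_model

    rng = np.random.default_rng(seed)
    boot = np.median(
        rng.choice(measured, size=(n_bootstrap, len(measured)), replace=True), axis=1
    )
    ci = 100.0 * np.percentile(boot, [2.5, 97.5]) / med_model

    band = [percent, percent]
    if model.dol_sd > 0:
        for i, p in enumerate(
            (min(1.0, model.dol + model.dol_sd), max(1e-6, model.dol - model.dol_sd))
        ):
            alt = LabelingModel(p, model.single, model.n_subunits)
            band[i] = 100.0 * med_meas / mixture_distribution(alt, grid).median
        band.sort()
    return CompletenessResult(
        percent=float(percent),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        dol_band_low=float(band[0]),
        dol_band_high=float(band[1]),
        median_measured=med_meas,
        median_model=float(med_model),
    )
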