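"""Unconfined-compression viscoelastic analysis.

A cylindrical specimen is compressed in successive ramp-hold steps
(protocol: four steps of 5% strain, 1 s ramps, 3 min holds).  From the
force–displacement–time record the analysis derives:

* engineering stress σ = F / (π (d/2)²) in kPa and strain
  ε = displacement / thickness (compression positive);
* the Young's modulus E and intercept C from the linear fit
  σ_eq = E ε + C over the per-step equilibrium stresses;
* the instantaneous/equilibrium modulus ratio R_s = σ_max / σ_eq per
  step, an index of rate-dependent stiffening; and
* the bi-exponential stress-relaxation fit per hold,
  σ(t) = a1 exp(−t/τ_fast) + a2 exp(−t/τ_slow) + b,
  with τ_fast < τ_slow enforced by reordering after the fit.

Equilibrium stress is estimated as the mean of the final 10% of each
hold (configurable); bi-exponential fits use a multistart nonlinear
least-squares scheme because such fits are initialization-sensitive.
Each hold is fitted independently (no Boltzmann superposition of
previous steps) — a deliberate simplification matching per-step
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import RelaxationTrace


class SegmentationError(ValueError):
    """Raised when the displacement record does not match the protocol."""


@dataclass
class StepSegment:
    """One ramp-hold step of a compression trace.

    ``time_hold`` is re-zeroed at the start of the hold; ``strain_level``
    is the cumulative strain during the hold plateau.
    """

    step_index: int
    ramp_window: tuple[float, float]
    hold_window: tuple[float, float]
    strain_level: float
    time_hold: np.ndarray
    stress_hold: np.ndarray       # kPa
    stress_ramp: np.ndarray       # kPa
    def __post_init__(self) -> None:
        if not 0 < self.strain_level < 1:
            raise ValueError("strain_level must be in (0, 1)")
        if not np.all(np.isfinite(self.stress_hold)):
            raise ValueError("stress must be finite")


@dataclass
class RelaxationFit:
    """Bi-exponential hold fit with diagnostics."""

    a1: float
    a2: float
    tau_fast: float
    tau_slow: float
    b: float
    residual_norm: float
    converged: bool
    degenerate: bool = False
    aic_2exp: float = np.nan
    aic_1exp: float = np.nan
    preferred_model: str = "2exp"


@dataclass
class ViscoFit:
    """Per-specimen summary: linear modulus plus per-step quantities."""

    E: float                       # kPa
    C: float                       # kPa
    E_stderr: float
    strain_levels: list[float] = field(default_factory=list)
    sigma_max: list[float] = field(default_factory=list)
    sigma_eq: list[float] = field(default_factory=list)
    rs: list[float] = field(default_factory=list)
    relaxation: list[RelaxationFit] = field(default_factory=list)
    relaxation_joint: RelaxationFit | None = None

    @property
    def rs_mean(self) -> float:
        return float(np.mean(self.rs)) if self.rs else np.nan


# --------------------------------------------------------------------------
# conversions and segmentation
# --------------------------------------------------------------------------

def to_stress_strain(trace: RelaxationTrace) -> tuple[np.ndarray, np.ndarray]:
    """(stress kPa, strain) from force (N) and displacement (mm).

    σ = F / A with A = π(d/2)² ; ε = displacement / thickness.
    Compression is positive throughout.
    """
    area_m2 = np.pi * (trace.specimen_diameter / 2 * 1e-3) ** 2
    stress_kpa = trace.force / area_m2 / 1e3
    strain = trace.displacement / trace.specimen_thickness
    return stress_kpa, strain


def segment_steps(trace: RelaxationTrace, n_steps: int = 4) -> list[StepSegment]:
    """Split a staircase trace into ramp-hold steps.

    Ramps are located by displacement-rate thresholding (20% of the peak
    rate); the hold of each step runs from the ramp's end to the next
    ramp's start.  A detected ramp count different from ``n_steps`` is an
    error that lists the detected ramp times.
    """
    t = trace.time
    rate = np.gradient(trace.displacement, t)
    peak = np.max(np.abs(rate))
    if peak <= 0:
        raise SegmentationError("displacement is constant: no ramps detected")
    on = np.abs(rate) > 0.2 * peak
    # contiguous True regions
    edges = np.diff(on.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if on[0]:
        starts.insert(0, 0)
    if on[-1]:
        ends.append(len(on))
    ramps = list(zip(starts, ends))
    if len(ramps) != n_steps:
        times = [f"{t[s]:.2f}s" for s, _ in ramps]
        raise SegmentationError(
            f"detected {len(ramps)} ramps (expected {n_steps}); ramp starts: {times}"
        )
    stress, _ = to_stress_strain(trace)
    segments: list[StepSegment] = []
    for i, (s, e) in enumerate(ramps):
        hold_end = ramps[i + 1][0] if i + 1 < len(ramps) else len(t)
        if hold_end <= e:
            raise SegmentationError(f"step {i + 1}: hold window is empty")
        plateau = float(np.median(trace.displacement[e:hold_end]))
        segments.append(
            StepSegment(
                step_index=i + 1,
                ramp_window=(float(t[s]), float(t[e - 1])),
                hold_window=(float(t[e]), float(t[hold_end - 1])),
                strain_level=plateau / trace.specimen_thickness,
                time_hold=t[e:hold_end] - t[e],
                stress_hold=stress[e:hold_end],
                stress_ramp=stress[s:e],
            )
        )
    return segments


# --------------------------------------------------------------------------
# per-step quantities
# --------------------------------------------------------------------------

def equilibrium_stress(segment: StepSegment, window_frac: float = 0.1) -> float:
    """Mean stress over the final ``window_frac`` of the hold."""
    n = segment.stress_hold.size
    k = max(1, int(round(window_frac * n)))
    return float(segment.stress_hold[-k:].mean())


def modulus_ratio(
    segment: StepSegment,
    window_frac: float = 0.1,
    sigma_max_source: str = "ramp_peak",
) -> tuple[float, float, float]:
    """(R_s, σ_max, σ_eq) for one step.

    ``sigma_max_source`` chooses the instantaneous stress: the peak over
    ramp plus hold (``ramp_peak``) or the first hold sample
    (``hold_start``); at 1 s ramps the two differ negligibly.
    """
    if sigma_max_source == "ramp_peak":
        pool = np.concatenate([segment.stress_ramp, segment.stress_hold])
        sigma_max = float(pool.max()) if pool.size else float(segment.stress_hold.max())
    elif sigma_max_source == "hold_start":
        sigma_max = float(segment.stress_hold[0])
    else:
        raise ValueError(f"unknown sigma_max_source {sigma_max_source!r}")
    sigma_eq = equilibrium_stress(segment, window_frac)
    if sigma_eq <= 0:
        raise ValueError("equilibrium stress must be positive")
    return sigma_max / sigma_eq, sigma_max, sigma_eq


def fit_youngs_modulus(
    segments: list[StepSegment], window_frac: float = 0.1
) -> tuple[float, float, float]:
    """(E, C, stderr of E): OLS of equilibrium stress on strain level."""
    if len(segments) < 2:
        raise ValueError("need at least 2 steps for a stress-strain fit")
    eps = np.array([s.strain_level for s in segments])
    sig = np.array([equilibrium_stress(s, window_frac) for s in segments])
    res = stats.linregress(eps, sig)
    return float(res.slope), float(res.intercept), float(res.stderr)


# --------------------------------------------------------------------------
# bi-exponential relaxation fit
# --------------------------------------------------------------------------

def _biexp(t: np.ndarray, a1: float, a2: float, tf: float, ts: float, b: float) -> np.ndarray:
    return a1 * np.exp(-t / tf) + a2 * np.exp(-t / ts) + b


def _aic(rss: float, n: int, k: int, scale: float) -> float:
    # floor keeps noiseless fits (rss ~ machine eps) comparable
    rss = max(rss, 1e-24 * max(scale, 1e-300) * n)
    return n * np.log(rss / n) + 2 * k


def fit_relaxation(
    segment: StepSegment,
    window_frac: float = 0.1,
    compare_single_exp: bool = True,
) -> RelaxationFit:
    """Fit σ(t) = a1·e^(−t/τ_fast) + a2·e^(−t/τ_slow) + b to the hold.

    Multistart scheme: b starts at the equilibrium stress; the excess
    σ_max − b is split {0.25, 0.5, 0.75} between the exponentials; τ
    starts are log-spaced over [0.01, 1] × hold duration, crossed
    pairwise with τ_fast < τ_slow.  The best residual wins, ties broken
    by the smaller τ_slow.  a1, a2, b are bounded non-negative; negative
    amplitudes would indicate mis-segmentation, not relaxation.

    A degenerate result (vanishing amplitude or τ_fast ≈ τ_slow) is
    flagged, and an optional single-exponential fit provides an
    AIC-based parsimony comparison.
    """
    t = segment.time_hold
    y = segment.stress_hold
    T = float(t[-1] - t[0]) if t.size > 1 else 1.0
    b0 = equilibrium_stress(segment, window_frac)
    excess = max(float(y[0]) - b0, 1e-9 * max(abs(b0), 1.0))
    taus = np.array([0.01, 0.1, 1.0]) * T
    tau_pairs = [(tf, ts) for i, tf in enumerate(taus) for ts in taus[i + 1:]]
    lo = np.array([0.0, 0.0, 1e-4 * T, 1e-4 * T, 0.0])
    hi = np.array([np.inf, np.inf, 100 * T, 100 * T, np.inf])

    def residual(p: np.ndarray) -> np.ndarray:
        return _biexp(t, *p) - y

    best = None
    for split in (0.25, 0.5, 0.75):
        for tf, ts in tau_pairs:
            p0 = np.clip([split * excess, (1 - split) * excess, tf, ts, b0], lo, hi)
            try:
                sol = optimize.least_squares(residual, p0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or sol.cost < best.cost - 1e-15 or (
                abs(sol.cost - best.cost) <= 1e-15 and max(sol.x[2], sol.x[3]) < max(best.x[2], best.x[3])
            ):
                best = sol
    if best is None:
        return RelaxationFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)

    a1, a2, tf, ts, b = best.x
    if tf > ts:
        a1, a2, tf, ts = a2, a1, ts, tf
    rss = float(2 * best.cost)
    total_amp = a1 + a2
    degenerate = bool(total_amp > 0 and (min(a1, a2) < 1e-3 * total_amp or ts / max(tf, 1e-300) < 1.2))
    fit = RelaxationFit(
        a1=float(a1), a2=float(a2), tau_fast=float(tf), tau_slow=float(ts), b=float(b),
        residual_norm=float(np.sqrt(rss)), converged=bool(best.success), degenerate=degenerate,
    )
    if compare_single_exp:
        scale = float(np.mean(y**2))
        fit.aic_2exp = _aic(rss, t.size, 5, scale)

        def res1(p: np.ndarray) -> np.ndarray:
            return p[0] * np.exp(-t / p[1]) + p[2] - y

        best1 = None
        for tau in taus:
            try:
                sol = optimize.least_squares(
                    res1, [excess, tau, b0],
                    bounds=([0.0, 1e-4 * T, 0.0], [np.inf, 100 * T, np.inf]),
                    method="trf",
                )
            except Exception:
                continue
            if best1 is None or sol.cost < best1.cost:
                best1 = sol
        if best1 is not None:
            fit.aic_1exp = _aic(float(2 * best1.cost), t.size, 3, scale)
            if fit.aic_1exp < fit.aic_2exp:
                fit.preferred_model = "1exp"
    return fit


def fit_relaxation_joint(
    segments: list[StepSegment],
    per_step_fits: list[RelaxationFit] | None = None,
    window_frac: float = 0.1,
) -> RelaxationFit:
    """Joint hold fit sharing τ_fast and τ_slow across all steps.

    The time constants are material properties of the specimen, so the
    per-specimen estimate pools every hold (per-step amplitudes and
    offsets stay free: 3 n + 2 parameters).  Initialized from the
    per-step multistart fits, amplitude-weighted for the shared τ.
    """
    if not segments:
        raise ValueError("need at least one segment")
    if per_step_fits is None:
        per_step_fits = [fit_relaxation(s, window_frac, compare_single_exp=False) for s in segments]
    amps = np.array([max(f.a1 + f.a2, 1e-12) for f in per_step_fits])
    w = amps / amps.sum()
    tf0 = float(np.sum(w * [f.tau_fast for f in per_step_fits]))
    ts0 = float(np.sum(w * [f.tau_slow for f in per_step_fits]))
    if tf0 >= ts0:
        tf0, ts0 = 0.5 * ts0, ts0
    T = max(float(s.time_hold[-1]) for s in segments)
    n_seg = len(segments)

    p0 = np.empty(2 + 3 * n_seg)
    p0[0], p0[1] = tf0, ts0
    for i, f in enumerate(per_step_fits):
        p0[2 + 3 * i: 5 + 3 * i] = (max(f.a1, 0.0), max(f.a2, 0.0), max(f.b, 0.0))
    lo = np.zeros_like(p0)
    hi = np.full_like(p0, np.inf)
    lo[:2] = 1e-4 * T
    hi[:2] = 100 * T

    def residual(p: np.ndarray) -> np.ndarray:
        tf, ts = p[0], p[1]
        out = []
        for i, s in enumerate(segments):
            a1, a2, b = p[2 + 3 * i: 5 + 3 * i]
            out.append(_biexp(s.time_hold, a1, a2, tf, ts, b) - s.stress_hold)
        return np.concatenate(out)

    sol = optimize.least_squares(residual, np.clip(p0, lo, hi), bounds=(lo, hi), method="trf")
    tf, ts = float(sol.x[0]), float(sol.x[1])
    a1s = sol.x[2::3].copy()
    a2s = sol.x[3::3].copy()
    if tf > ts:
        tf, ts = ts, tf
        a1s, a2s = a2s, a1s
    total = float(a1s.sum() + a2s.sum())
    degenerate = bool(
        total > 0 and (min(a1s.sum(), a2s.sum()) < 1e-3 * total or ts / max(tf, 1e-300) < 1.2)
    )
    return RelaxationFit(
        a1=float(a1s.sum()), a2=float(a2s.sum()), tau_fast=tf, tau_slow=ts,
        b=float(sol.x[4::3].sum()), residual_norm=float(np.sqrt(2 * sol.cost)),
        converged=bool(sol.success), degenerate=degenerate,
    )


def analyze_trace(
    trace: RelaxationTrace,
    n_steps: int = 4,
    window_frac: float = 0.1,
    sigma_max_source: str = "ramp_peak",
    fit_holds: bool = True,
) -> ViscoFit:
    """Full per-specimen analysis: segmentation, E, R_s and hold fits."""
    segments = segment_steps(trace, n_steps=n_steps)
    E, C, stderr = fit_youngs_modulus(segments, window_frac)
    out = ViscoFit(E=E, C=C, E_stderr=stderr)
    for seg in segments:
        rs, smax, seq = modulus_ratio(seg, window_frac, sigma_max_source)
        out.strain_levels.append(seg.strain_level)
        out.sigma_max.append(smax)
        out.sigma_eq.append(seq)
        out.rs.append(rs)
        if fit_holds:
            out.relaxation.append(fit_relaxation(seg))
    if fit_holds:
        out.relaxation_joint = fit_relaxation_joint(segments, out.relaxation, window_frac)
    return out
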