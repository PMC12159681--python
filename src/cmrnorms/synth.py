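"""Seeded generators emulating the data structures the pipeline consumes.

Each generator is a pure function of its parameters and an explicit seed:

* :func:`gen_study_aggregates` — study-level (n, mean, SD) triples drawn
  from a two-level normal model: true study means θᵢ ~ N(μ, τ²) and
  individual values ~ N(θᵢ, σ²); the reported mean/SD are the *sample*
  statistics of the nᵢ draws, mimicking what publications print.
* :func:`gen_lms_population` — measurements sampled through the inverse
  LMS transform X = M·(1 + L·S·z)^(1/L), z ~ N(0,1), so the LMS z-scores
  of the output are exactly the drawn z's.
* :func:`gen_flow_pair` — a smooth systolic velocity waveform (half-sine
  upstroke, exponential decay) and a copy delayed by Δx / PWV, optionally
  with multiplicative Gaussian noise.
* :func:`gen_fractal_image` — rasterized test shapes (line, Koch curve,
  square boundary, filled square) of known fractal dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cmrnorms.formulas import AortaPathPair, FlowCurve
from cmrnorms.registry import StudySummary

__all__ = ["PopulationSpec", "gen_study_aggregates", "gen_lms_population",
           "gen_flow_pair", "gen_fractal_image"]


@dataclass(frozen=True)
class PopulationSpec:
    """Two-level normal population for simulated meta-analyses."""

    mu: float
    sigma_within: float
    tau: float = 0.0
    k_studies: int = 10
    n_range: tuple[int, int] = (200, 200)
    parameter_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not 2 <= self.n_range[0] <= self.n_range[1]:
            raise ValueError("n_range must satisfy 2 <= min <= max")


def gen_study_aggregates(spec: PopulationSpec) -> list[StudySummary]:
    """Simulate k studies' published (n, mean, SD) aggregates."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.k_studies):
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        theta = rng.normal(spec.mu, spec.tau) if spec.tau > 0 else spec.mu
        x = rng.normal(theta, spec.sigma_within, size=n)
        out.append(StudySummary(study_id=f"sim{i:03d}",
                                parameter_id=spec.parameter_id,
                                n=n, mean=float(np.mean(x)),
                                sd=float(np.std(x, ddof=1))))
    return out


def gen_lms_population(L: float, M: float, S: float, n: int,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample n measurements from an LMS distribution by inverse transform.

    Returns ``(values, z_scores, rejection_rate)``.  Draws with an
    infeasible Box–Cox argument (1 + L·S·z ≤ 0) are rejected and redrawn;
    for published pediatric parameter ranges the rejection rate is zero.
    """
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be positive")
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    zs = np.empty(n)
    rejected = 0
    filled = 0
    while filled < n:
        z = rng.standard_normal(n - filled)
        if abs(L) < 1e-7:
            x = M * np.exp(S * z)
            ok = np.ones_like(z, dtype=bool)
        else:
            base = 1.0 + L * S * z
            ok = base > 0
            x = np.where(ok, M * np.abs(base) ** (1.0 / L), np.nan)
        rejected += int((~ok).sum())
        take = int(ok.sum())
        values[filled:filled + take] = x[ok]
        zs[filled:filled + take] = z[ok]
        filled += take
    return values, zs, rejected / (n + rejected)


def _waveform(t_ms: np.ndarray, onset_ms: float, upstroke_ms: float = 80.0,
              peak: float = 100.0, decay_ms: float = 250.0) -> np.ndarray:
    """Half-sine systolic upstroke followed by exponential decay, zero baseline."""
    v = np.zeros_like(t_ms)
    rise = (t_ms >= onset_ms) & (t_ms < onset_ms + upstroke_ms)
    v[rise] = peak * np.sin(0.5 * np.pi * (t_ms[rise] - onset_ms) / upstroke_ms)
    fall = t_ms >= onset_ms + upstroke_ms
    v[fall] = peak * np.exp(-(t_ms[fall] - onset_ms - upstroke_ms) / decay_ms)
    return v


def gen_flow_pair(true_pwv: float, delta_x: float, dt: float = 5.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  cycle_ms: float = 1000.0, onset_ms: float = 150.0,
                  upstroke_ms: float = 80.0) -> AortaPathPair:
    """Proximal/distal flow-curve pair with a known transit delay.

    The distal waveform is the proximal template delayed by
    Δt = Δx / PWV (in ms); ``noise_sd`` adds multiplicative Gaussian
    noise of that fractional amplitude.
    """
    if min(true_pwv, delta_x, dt) <= 0:
        raise ValueError("true_pwv, delta_x and dt must be positive")
    delay_ms = delta_x / true_pwv * 1000.0
    if delay_ms < dt:
        warnings.warn(f"delay {delay_ms:.2f} ms is below the sampling interval "
                      f"{dt} ms (sub-sample shift)", stacklevel=2)
    t = np.arange(0.0, cycle_ms, dt)
    rng = np.random.default_rng(seed)
    curves = []
    for name, onset in (("proximal", onset_ms), ("distal", onset_ms + delay_ms)):
        v = _waveform(t, onset, upstroke_ms=upstroke_ms)
        if noise_sd > 0:
            v = v * (1.0 + rng.normal(0.0, noise_sd, size=v.size))
        curves.append(FlowCurve(times=t, velocities=v, site=name))
    return AortaPathPair(proximal=curves[0], distal=curves[1], delta_x=delta_x)


def _koch_segments(iterations: int) -> np.ndarray:
    """Vertex list of the Koch curve on the unit interval."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])  # +60 deg
    for _ in range(iterations):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3.0
            p1, p3 = a + d, a + 2 * d
            p2 = p1 + rot @ d
            new.extend([p1, p2, p3, b])
        pts = np.array(new)
    return pts


def _raster_polyline(pts: np.ndarray, size: int, margin: int = 2) -> np.ndarray:
    """Rasterize a polyline into a size×size binary image by dense sampling."""
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = float(np.max(hi - lo)) or 1.0
    scale = (size - 1 - 2 * margin) / span
    img = np.zeros((size, size), dtype=bool)
    for a, b in zip(pts[:-1], pts[1:]):
        npts = max(int(np.ceil(np.linalg.norm(b - a) * scale * 2)), 2)
        lam = np.linspace(0.0, 1.0, npts)[:, None]
        xy = (a + lam * (b - a) - lo) * scale + margin
        cols = np.clip(np.round(xy[:, 0]).astype(int), 0, size - 1)
        rows = np.clip(np.round(xy[:, 1]).astype(int), 0, size - 1)
        img[rows, cols] = True
    return img


def gen_fractal_image(kind: str, iterations: int = 5, size_px: int = 512,
                      seed: int = 0) -> np.ndarray:
    """Binary raster of a shape of known fractal dimension.

    ``line`` (FD 1), ``koch`` (FD ln4/ln3 ≈ 1.262), ``square_boundary``
    (FD 1) and ``filled_square`` (FD 2).  ``seed`` is accepted for
    interface symmetry; the shapes are deterministic.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    if kind == "line":
        img = np.zeros((size_px, size_px), dtype=bool)
        img[size_px // 2, 2:-2] = True
        return img
    if kind == "koch":
        return _raster_polyline(_koch_segments(iterations), size_px)
    if kind == "square_boundary":
        img = np.zeros((size_px, size_px), dtype=bool)
        m = size_px // 8
        img[m:-m, m] = img[m:-m, -m] = True
        img[m, m:-m] = img[-m, m:-m + 1] = True
        return img
    if kind == "filled_square":
        img = np.zeros((size_px, size_px), dtype=bool)
        m = size_px // 8
        img[m:-m, m:-m] = True
        return img
    raise ValueError(f"unknown shape kind {kind!r}")
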