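"""Clinical derivation formulas for quantitative CMR.

Pure-arithmetic helpers (body surface area, indexing, area–length atrial
volumes, sphericity, distensibility, ECV, T2*-derived quantities), the
threshold-based grading rules used in reporting, and two signal/image
operations: foot-to-foot transit-time estimation for pulse wave velocity
and box-counting fractal dimension of binary trabeculation masks.

Unit conventions: areas in cm² and lengths in cm give volumes in mL;
distensibility is reported in 10⁻³ mmHg⁻¹; PWV in m/s with path length in
metres and transit time in milliseconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FlowCurve", "AortaPathPair", "BiplaneGeometry", "RelaxometryInput",
    "bsa", "index_value", "atrial_volume_monoplane",
    "atrial_volume_biplane_ellipsoid", "atrial_volume_biplane_calibrated",
    "sphericity_index", "distensibility", "transit_time", "pwv",
    "ecv", "synthetic_hct", "r2star", "iron_concentration", "grade_iron",
    "stage_aortic_stenosis", "classify_diastolic",
    "box_counting_fd", "summarize_fd_stack",
]


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class FlowCurve:
    """Uniformly sampled velocity-time curve at one aortic site."""

    times: np.ndarray          # ms
    velocities: np.ndarray     # cm/s
    site: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if t.size < 10 or t.size != v.size:
            raise ValueError("need >= 10 matching (time, velocity) samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("sampling must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class AortaPathPair:
    """Proximal/distal flow curves with the centerline path length between them."""

    proximal: FlowCurve
    distal: FlowCurve
    delta_x: float             # m

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("centerline path length must be positive")
        if abs(self.proximal.dt - self.distal.dt) > 1e-9:
            raise ValueError("proximal and distal sampling rates must match")


@dataclass(frozen=True)
class BiplaneGeometry:
    """Atrial areas and lengths from the four- and two-chamber views (cm², cm)."""

    area_4ch: float
    area_2ch: float
    length_4ch: float
    length_2ch: float

    def __post_init__(self) -> None:
        if min(self.length_4ch, self.length_2ch) <= 0:
            raise ValueError("cavity lengths must be positive")
        if min(self.area_4ch, self.area_2ch) < 0:
            raise ValueError("areas must be non-negative")


@dataclass(frozen=True)
class RelaxometryInput:
    """Pre/post-contrast T1 times (ms) of myocardium and blood, plus hematocrit."""

    t1_myo_native: float
    t1_myo_post: float
    t1_blood_native: float
    t1_blood_post: float
    hematocrit: float
    t2star: float | None = None

    def __post_init__(self) -> None:
        for name in ("t1_myo_native", "t1_myo_post", "t1_blood_native", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.t2star is not None and self.t2star <= 0:
            raise ValueError("t2star must be positive")


# ------------------------------------------------------------ body size

def bsa(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m².

    DuBois: 0.007184·h^0.725·w^0.425 (default; the dominant convention in
    the normative cohort literature).  Mosteller: sqrt(h·w/3600).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    raise ValueError(f"unknown BSA formula {formula!r}")


def index_value(value: float, bsa_m2: float) -> float:
    """Index a parameter to body surface area (value / BSA)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    return value / bsa_m2


# ------------------------------------------------------- atrial volumes

def atrial_volume_monoplane(area: float, length: float) -> float:
    """Monoplane area-length volume 8A²/(3πL) (area cm², length cm -> mL)."""
    if length <= 0:
        raise ValueError("length must be positive")
    return 8.0 * area ** 2 / (3.0 * math.pi * length)


def atrial_volume_biplane_ellipsoid(g: BiplaneGeometry,
                                    length_rule: str = "shortest") -> float:
    """Biplane ellipsoid area-length volume (8/3π)·A1·A2/L.

    ``length_rule='shortest'`` uses the shorter of the two cavity lengths
    (the pediatric convention); ``'mean'`` averages them.
    """
    if length_rule == "shortest":
        L = min(g.length_4ch, g.length_2ch)
    elif length_rule == "mean":
        L = 0.5 * (g.length_4ch + g.length_2ch)
    else:
        raise ValueError(f"unknown length rule {length_rule!r}")
    return 8.0 * g.area_4ch * g.area_2ch / (3.0 * math.pi * L)


def atrial_volume_biplane_calibrated(g: BiplaneGeometry) -> float:
    """Calibrated biplane volume 0.848·A4·A2 / mean(L2, L4).

    The empirical constant 0.848 is numerically almost identical to
    8/(3π) = 0.8488; both variants are kept because published cohorts
    report either.
    """
    return 0.848 * g.area_4ch * g.area_2ch / (0.5 * (g.length_2ch + g.length_4ch))


def sphericity_index(edv_ml: float, length_4ch_cm: float) -> float:
    """LV sphericity: EDV over the volume of a sphere of diameter = 4ch length."""
    if length_4ch_cm <= 0:
        raise ValueError("length must be positive")
    return edv_ml / ((4.0 * math.pi / 3.0) * (length_4ch_cm / 2.0) ** 3)


# ---------------------------------------------------- vessel stiffness

def distensibility(a_max: float, a_min: float, p_max: float, p_min: float) -> float:
    """Aortic distensibility (Amax − Amin)/(Amin·ΔP) in 10⁻³ mmHg⁻¹.

    The area ratio makes the result independent of the area unit.
    """
    if a_min <= 0:
        raise ValueError("minimal area must be positive")
    if p_max <= p_min:
        raise ValueError("pulse pressure must be positive (p_max > p_min)")
    return 1000.0 * (a_max - a_min) / (a_min * (p_max - p_min))


def _foot_upslope_intersect(curve: FlowCurve, snr_min: float = 4.0) -> float:
    """Foot of the systolic upstroke: baseline ∩ 20–80% upslope regression line.

    The baseline is the median of pre-peak samples below 10% normalized
    amplitude; the upslope is fit by least squares to the contiguous run of
    rising samples between 20% and 80% amplitude immediately preceding the
    systolic peak.
    """
    t, v = curve.times, curve.velocities
    ipk = int(np.argmax(v))
    vmin = float(np.min(v[: ipk + 1])) if ipk > 0 else float(np.min(v))
    amp = float(v[ipk] - vmin)
    noise = float(np.std(v[: max(ipk // 4, 2)])) or 1e-12
    if ipk == 0 or amp <= 0 or amp < snr_min * noise:
        raise ValueError(f"no detectable systolic upstroke on {curve.site or 'curve'}")
    a = (v - vmin) / amp
    pre = np.arange(ipk + 1)
    base_idx = pre[a[pre] < 0.10]
    baseline = float(np.median(v[base_idx])) if base_idx.size else vmin
    ab = (v - baseline) / (v[ipk] - baseline)
    band = [i for i in pre if 0.20 <= ab[i] <= 0.80]
    if not band:
        raise ValueError("no samples on the 20-80% upstroke band")
    # earliest contiguous run ending before the peak
    runs, cur = [], [band[0]]
    for i in band[1:]:
        if i == cur[-1] + 1:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    runs.append(cur)
    run = runs[0]
    if len(run) < 2:
        run = max(runs, key=len)
    if len(run) < 2:
        raise ValueError("upstroke too steep to regress (fewer than 2 band samples)")
    slope, intercept, *_ = stats.linregress(t[run], v[run])
    if slope <= 0:
        raise ValueError("upslope regression is not rising")
    return (baseline - intercept) / slope


def _foot_upslope_midpoint(curve: FlowCurve) -> float:
    """Time at 50% amplitude on the upstroke, linearly interpolated."""
    t, v = curve.times, curve.velocities
    ipk = int(np.argmax(v))
    vmin = float(np.min(v[: ipk + 1])) if ipk > 0 else float(np.min(v))
    amp = v[ipk] - vmin
    if ipk == 0 or amp <= 0:
        raise ValueError("no systolic upstroke")
    half = vmin + 0.5 * amp
    above = np.nonzero(v[: ipk + 1] >= half)[0]
    i = int(above[0])
    if i == 0:
        return float(t[0])
    f = (half - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def transit_time(pair: AortaPathPair, method: str = "upslope_intersect") -> float:
    """Foot-to-foot transit time Δt (ms) between proximal and distal curves.

    ``upslope_intersect``: per curve, the foot is the intersection of the
    pre-systolic baseline with the least-squares line through the 20–80%
    amplitude samples of the systolic upstroke.  ``upslope_midpoint``: the
    50%-amplitude time on the upstroke.  A negative Δt is returned but
    flagged with a warning.
    """
    if method == "upslope_intersect":
        foot = _foot_upslope_intersect
    elif method == "upslope_midpoint":
        foot = _foot_upslope_midpoint
    else:
        raise ValueError(f"unknown transit-time method {method!r}")
    dt = foot(pair.distal) - foot(pair.proximal)
    if dt < 0:
        warnings.warn(f"negative transit time ({dt:.2f} ms): distal foot "
                      "precedes proximal foot", stacklevel=2)
    return float(dt)


def pwv(pair: AortaPathPair, method: str = "upslope_intersect") -> float:
    """Pulse wave velocity Δx/Δt in m/s (Δx in m, Δt estimated in ms)."""
    dt_ms = transit_time(pair, method=method)
    if dt_ms <= 0:
        raise ValueError(
            f"transit time {dt_ms:.3f} ms is not positive; cannot form PWV")
    return pair.delta_x / (dt_ms / 1000.0)


# -------------------------------------------------------- relaxometry

def ecv(r: RelaxometryInput) -> float:
    """Extracellular volume fraction from pre/post-contrast T1 and hematocrit.

    ECV = (1 − Hct) · ΔR1_myo / ΔR1_blood with R1 = 1/T1.
    """
    dr1_myo = 1.0 / r.t1_myo_post - 1.0 / r.t1_myo_native
    dr1_blood = 1.0 / r.t1_blood_post - 1.0 / r.t1_blood_native
    if dr1_blood == 0:
        raise ValueError("blood ΔR1 is zero; contrast has not changed blood T1")
    return (1.0 - r.hematocrit) * dr1_myo / dr1_blood


def synthetic_hct(t1_blood_native: float,
                  calibration: tuple[float, float]) -> float:
    """Hematocrit estimated from native blood T1 via a site-specific calibration.

    ``calibration = (slope, intercept)`` applies on the R1 scale:
    Hct = slope·(1000/T1) + intercept with T1 in ms.  No default
    coefficients are shipped — the regression is scanner- and
    sequence-specific and must be established locally.  The result is
    clipped into (0, 1) with a warning.
    """
    if t1_blood_native <= 0:
        raise ValueError("native blood T1 must be positive")
    if calibration is None:
        raise ValueError("a site-specific (slope, intercept) calibration is required")
    slope, intercept = calibration
    hct = slope * (1000.0 / t1_blood_native) + intercept
    if not 0.0 < hct < 1.0:
        warnings.warn(f"synthetic hematocrit {hct:.3f} outside (0,1); clipping",
                      stacklevel=2)
        hct = min(max(hct, 1e-6), 1.0 - 1e-6)
    return hct


def r2star(t2star_ms: float) -> float:
    """Relaxation rate R2* = 1000/T2* in s⁻¹ (T2* in ms)."""
    if t2star_ms <= 0:
        raise ValueError("T2* must be positive")
    return 1000.0 / t2star_ms


def iron_concentration(t2star_ms: float) -> float:
    """Cardiac iron concentration [Fe] = 45·(T2*)^−1.22 in mg/g dry weight."""
    if t2star_ms <= 0:
        raise ValueError("T2* must be positive")
    return 45.0 * t2star_ms ** -1.22


#: (field tag) -> (severe upper bound, overload upper bound); boundaries
#: belong to the milder neighbour is False: ">20 normal" makes 20 overload.
_IRON_THRESHOLDS = {"1.5": (10.0, 20.0), "3": (5.5, 12.0)}


def grade_iron(t2star_ms: float, field: str = "1.5") -> str:
    """Iron-overload grade from myocardial T2*.

    At 1.5T: normal > 20 ms, overload 10–20 ms, severe < 10 ms; at 3T the
    cutoffs are 12 and 5.5 ms.  A value exactly on a cutoff takes the more
    severe of the two neighbouring classes only when the printed inequality
    is strict for the milder one (">20" means 20 itself is overload;
    "10-20" is closed, so 10 is overload, not severe).
    """
    if t2star_ms <= 0:
        raise ValueError("T2* must be positive")
    key = str(field).rstrip("T").rstrip("t")
    key = {"1.5": "1.5", "3": "3", "3.0": "3"}.get(key)
    if key is None:
        raise ValueError(f"unknown field strength {field!r}; use 1.5 or 3")
    severe_hi, overload_hi = _IRON_THRESHOLDS[key]
    if t2star_ms > overload_hi:
        return "normal"
    if t2star_ms >= severe_hi:
        return "overload"
    return "severe"


# ------------------------------------------------------------- grading

def stage_aortic_stenosis(v_max: float | None = None,
                          orifice_area: float | None = None,
                          area_bsa: float | None = None) -> tuple[str, list[str]]:
    """Aortic-stenosis stage from peak velocity and/or orifice area.

    Velocity (m/s): mild 2.0–2.9, moderate 3.0–3.9, severe ≥ 4, very
    severe ≥ 5.  Orifice area ≤ 1.0 cm² (or ≤ 0.6 cm²/m² indexed) is
    severe.  The worst stage across supplied criteria is returned together
    with qualifier strings.
    """
    if v_max is None and orifice_area is None and area_bsa is None:
        raise ValueError("supply at least one criterion (v_max, orifice_area, area_bsa)")
    order = ["none", "mild", "moderate", "severe"]
    stage = "none"
    qualifiers: list[str] = []

    def worsen(s: str) -> None:
        nonlocal stage
        if order.index(s) > order.index(stage):
            stage = s

    if v_max is not None:
        if v_max >= 5.0:
            worsen("severe")
            qualifiers.append("very severe (v_max >= 5 m/s)")
        elif v_max >= 4.0:
            worsen("severe")
        elif v_max >= 3.0:
            worsen("moderate")
        elif v_max >= 2.0:
            worsen("mild")
    if orifice_area is not None and orifice_area <= 1.0:
        worsen("severe")
        qualifiers.append("orifice area <= 1.0 cm^2")
    if area_bsa is not None and area_bsa <= 0.6:
        worsen("severe")
        qualifiers.append("indexed orifice area <= 0.6 cm^2/m^2")
    if v_max is not None and stage == "severe" and v_max < 4.0:
        qualifiers.append("low-flow/low-gradient pattern (v_max < 4 m/s at rest)")
    return stage, qualifiers


def classify_diastolic(mdt_ms: float, ea_ratio: float,
                       mdt_normal: tuple[float, float] = (150.0, 220.0)
                       ) -> frozenset[str]:
    """Diastolic-function classes consistent with mitral MDT and E/A ratio.

    The printed rule table distinguishes: normal (MDT 150–220 ms, E/A
    1–2), type 1 impaired relaxation (MDT increased, E/A < 1), type 2
    pseudonormal (MDT normal, E/A 1–2) and type 3 restrictive (MDT
    decreased, E/A > 2).  Normal and pseudonormal are indistinguishable
    from these two numbers alone, so a *set* of consistent classes is
    returned rather than a forced guess.
    """
    lo, hi = mdt_normal
    mdt_state = "decreased" if mdt_ms < lo else "increased" if mdt_ms > hi else "normal"
    out: set[str] = set()
    if mdt_state == "normal" and lo <= mdt_ms <= hi and 1.0 <= ea_ratio <= 2.0:
        out |= {"normal", "type2"}
    if mdt_state == "increased" and ea_ratio < 1.0:
        out.add("type1")
    if mdt_state == "decreased" and ea_ratio > 2.0:
        out.add("type3")
    if not out:
        out.add("indeterminate")
    return frozenset(out)


# ------------------------------------------------- fractal dimension

def box_counting_fd(image: np.ndarray,
                    box_sizes: list[int] | None = None,
                    region: np.ndarray | None = None) -> float:
    """Box-counting fractal dimension of a binary 2-D mask.

    Counts occupied boxes on fixed-origin grids of the given sizes
    (default: dyadic sizes from 2 px up to a quarter of the shorter image
    side) and returns minus the slope of log(count) against log(size).
    """
    img = np.asarray(image).astype(bool)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D array")
    if region is not None:
        img = img & np.asarray(region).astype(bool)
    if not img.any():
        raise ValueError("image contains no foreground pixels")
    if box_sizes is None:
        side = min(img.shape)
        box_sizes, s = [], 2
        while s <= side // 4:
            box_sizes.append(s)
            s *= 2
    box_sizes = sorted(set(int(s) for s in box_sizes))
    if len(box_sizes) < 3:
        raise ValueError("need at least 3 box sizes")
    if box_sizes[-1] < 2 * box_sizes[0]:
        raise ValueError("box sizes must span at least one octave")

    counts = []
    h, w = img.shape
    for s in box_sizes:
        hh, ww = -(-h // s) * s, -(-w // s) * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = img
        blocks = padded.reshape(hh // s, s, ww // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, *_ = stats.linregress(np.log(box_sizes), np.log(counts))
    return float(-slope)


def summarize_fd_stack(fds: list[float]) -> dict[str, float]:
    """Global and maximal-apical FD summaries of a base-to-apex slice stack.

    Global FD is the mean over all slices; maximal apical FD is the
    maximum over the apical half of the stack (the middle slice of an
    odd-length stack is discounted).
    """
    if not fds:
        raise ValueError("empty stack")
    n = len(fds)
    apical = fds[(n + 1) // 2:] if n % 2 else fds[n // 2:]
    return {
        "global_fd": float(np.mean(fds)),
        "max_apical_fd": float(np.max(apical)) if apical else float(fds[-1]),
    }
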