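"""Relative-error-exponent arithmetic for numerical-trust maps.

Every measured or computed scalar carries two integers alongside its
floating-point value: the magnitude exponent ``e = floor(log2 |x|)`` and
the relative-error exponent ``r = floor(log2 Dx)``, where ``Dx`` is the
variable's relative error.  Rather than carrying actual error values
(which cannot be known at run time), each arithmetic operation propagates
``r`` by a worst-case first-order rule:

=============  =======================================
operation      relative-error exponent of the result
=============  =======================================
x + y          max(ex + rx, ey + ry) - e(x+y)
x * y          max(rx, ry, rx + ry)
1 / x          rx
exp(x)         ex + rx
sqrt(x)        rx - 1
sin(x)         e(cos(x) * x / sin(x)) + rx
=============  =======================================

Division decomposes into multiplication and inversion.  Three extension
rules are derived by the same first-order method (they are needed by the
power-law dispersion coefficients and the wind-frame rotation and are not
part of the original six): ``x**b`` (exact exponent b) propagates
``r = floor(log2 |b|) + rx``, ``cos(x)`` mirrors the sine rule with
amplification ``-sin(x) * x / cos(x)``, and negation preserves ``r``.

Initialisation combines a measurement error with a floating-point
representation class: ``r`` starts at the maximum of
``floor(log2 rel_measurement_error)`` and the class constant (-20 for
single precision, -50 for double).

Conventions for degenerate cases: ``exponent(0)`` is the sentinel
:data:`E_MIN`; any exact zero result of addition, or a vanishing sine /
cosine, saturates ``r`` to :data:`R_MAX` — the result has no trustworthy
relative accuracy.  All ``r`` values are clamped to [R_MIN, R_MAX] and
are always integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "E_MIN", "R_MAX", "R_MIN",
    "TrackedValue", "ErrorSpec",
    "exponent", "relative_error", "track", "exact",
    "t_add", "t_sub", "t_neg", "t_mul", "t_inv", "t_div",
    "t_exp", "t_sqrt", "t_sin", "t_cos", "t_pow",
    "tracked_plume_point", "tracked_multipuff_point", "tracked_field",
    "DEFAULT_INPUT_SPECS",
]

#: Sentinel magnitude exponent of zero (below the smallest subnormal double).
E_MIN = -1075
#: Saturation ceiling for the relative-error exponent.
R_MAX = 64
#: Saturation floor for the relative-error exponent.
R_MIN = -1075

_CLASS_R = {"single": -20, "double": -50}


def exponent(x: float) -> int:
    """floor(log2 |x|); :data:`E_MIN` for x == 0."""
    if x == 0.0 or not math.isfinite(x):
        return E_MIN
    return math.frexp(abs(x))[1] - 1


def relative_error(value: float, abs_error: float) -> float:
    """Relative error |abs_error / value| of a scalar measurement."""
    if value == 0.0:
        raise ZeroDivisionError("relative error undefined for a zero value")
    return abs(abs_error / value)


def _clamp(r: float) -> int:
    return int(min(max(r, R_MIN), R_MAX))


@dataclass(frozen=True)
class TrackedValue:
    """A scalar plus the integer exponent of its relative error."""

    value: float
    r: int

    @property
    def e(self) -> int:
        """Magnitude exponent floor(log2 |value|)."""
        return exponent(self.value)

    def __repr__(self) -> str:  # compact: value (r=...)
        return f"TrackedValue({self.value!r}, r={self.r})"


@dataclass(frozen=True)
class ErrorSpec:
    """How to initialise a tracked input.

    Exactly one of ``rel_measurement_error`` / ``abs_measurement_error``
    may be nonzero; the relative form suits quantities whose error is a
    fixed fraction (e.g. a bearing with constant relative error 1/360),
    the absolute form suits instrument resolutions.
    """

    precision_class: str = "double"
    rel_measurement_error: float = 0.0
    abs_measurement_error: float = 0.0

    def __post_init__(self) -> None:
        if self.precision_class not in _CLASS_R:
            raise ValueError("precision_class must be 'single' or 'double'")
        if self.rel_measurement_error < 0 or self.abs_measurement_error < 0:
            raise ValueError("measurement errors must be >= 0")
        if self.rel_measurement_error and self.abs_measurement_error:
            raise ValueError("give a relative or an absolute error, not both")


def track(value: float, spec: ErrorSpec | None = None) -> TrackedValue:
    """Wrap a measured value; ``r`` = max(measurement, representation) exponent."""
    spec = spec or ErrorSpec()
    rel = spec.rel_measurement_error
    if spec.abs_measurement_error:
        rel = relative_error(value, spec.abs_measurement_error)
    r = _CLASS_R[spec.precision_class]
    if rel > 0.0:
        r = max(r, exponent(rel))
    return TrackedValue(float(value), _clamp(r))


def exact(value: float, precision_class: str = "double") -> TrackedValue:
    """A constant known exactly up to its representation class."""
    return TrackedValue(float(value), _CLASS_R[precision_class])


# ---------------------------------------------------------------------------
# propagation rules
# ---------------------------------------------------------------------------


def t_add(a: TrackedValue, b: TrackedValue) -> TrackedValue:
    value = a.value + b.value
    if value == 0.0:
        return TrackedValue(value, R_MAX)
    terms = [x.e + x.r for x in (a, b) if x.value != 0.0]
    if not terms:  # both operands zero yet sum nonzero cannot happen
        return TrackedValue(value, R_MAX)
    return TrackedValue(value, _clamp(max(terms) - exponent(value)))


def t_neg(a: TrackedValue) -> TrackedValue:
    return TrackedValue(-a.value, a.r)


def t_sub(a: TrackedValue, b: TrackedValue) -> TrackedValue:
    return t_add(a, t_neg(b))


def t_mul(a: TrackedValue, b: TrackedValue) -> TrackedValue:
    return TrackedValue(a.value * b.value, _clamp(max(a.r, b.r, a.r + b.r)))


def t_inv(a: TrackedValue) -> TrackedValue:
    if a.value == 0.0:
        raise ZeroDivisionError("inversion of a tracked zero")
    return TrackedValue(1.0 / a.value, a.r)


def t_div(a: TrackedValue, b: TrackedValue) -> TrackedValue:
    return t_mul(a, t_inv(b))


def t_exp(a: TrackedValue) -> TrackedValue:
    try:
        value = math.exp(a.value)
    except OverflowError:
        return TrackedValue(math.inf, R_MAX)
    return TrackedValue(value, _clamp(a.e + a.r))


def t_sqrt(a: TrackedValue) -> TrackedValue:
    if a.value < 0.0:
        raise ValueError("square root of a negative tracked value")
    return TrackedValue(math.sqrt(a.value), _clamp(a.r - 1))


def t_sin(a: TrackedValue) -> TrackedValue:
    s = math.sin(a.value)
    if s == 0.0:
        return TrackedValue(s, R_MAX)
    amp = math.cos(a.value) * a.value / s
    return TrackedValue(s, _clamp(exponent(amp) + a.r))


def t_cos(a: TrackedValue) -> TrackedValue:
    c = math.cos(a.value)
    if c == 0.0:
        return TrackedValue(c, R_MAX)
    amp = -math.sin(a.value) * a.value / c
    return TrackedValue(c, _clamp(exponent(amp) + a.r))


def t_pow(a: TrackedValue, b: float) -> TrackedValue:
    """x**b for an exact real exponent b (first-order: error scales by |b|)."""
    if a.value <= 0.0 and b != int(b):
        raise ValueError("non-integer power of a non-positive tracked value")
    value = a.value ** b
    return TrackedValue(value, _clamp(exponent(b) + a.r))


# ---------------------------------------------------------------------------
# tracked evaluation of the dispersion models
# ---------------------------------------------------------------------------

#: Input error assumptions: sensor-grade wind instruments (speed resolution
#: 0.01 m/s; direction error 1 degree, i.e. constant relative error 1/360);
#: source term and geometry exact to double precision.
DEFAULT_INPUT_SPECS: dict[str, ErrorSpec] = {
    "wind_speed": ErrorSpec(abs_measurement_error=0.01),
    "wind_direction": ErrorSpec(rel_measurement_error=1.0 / 360.0),
    "release_rate": ErrorSpec(),
}

_DEG = math.pi / 180.0


def _tracked_frame(theta: TrackedValue, dx: TrackedValue, dy: TrackedValue):
    """Rotate a source-relative offset into the (downwind, crosswind) frame."""
    alpha = t_mul(t_add(theta, exact(180.0)), exact(_DEG))
    s, c = t_sin(alpha), t_cos(alpha)
    x_down = t_add(t_mul(dx, s), t_mul(dy, c))
    y_cross = t_sub(t_mul(dx, c), t_mul(dy, s))
    return x_down, y_cross


def _tracked_gauss(arg_num: TrackedValue, sigma: TrackedValue) -> TrackedValue:
    """exp(-arg_num / (2 sigma^2)) in tracked arithmetic."""
    denom = t_mul(exact(2.0), t_mul(sigma, sigma))
    return t_exp(t_neg(t_div(arg_num, denom)))


def tracked_plume_point(scenario, state, x: float, y: float, z: float = 0.0,
                        t: float = 0.0,
                        specs: dict[str, ErrorSpec] | None = None) -> TrackedValue:
    """Evaluate the plume equation at one point entirely in tracked arithmetic."""
    specs = {**DEFAULT_INPUT_SPECS, **(specs or {})}
    speed, bearing = scenario.wind.at(t)
    theta = track(bearing, specs["wind_direction"])
    v = track(speed, specs["wind_speed"])
    q = track(scenario.source.rate_at(t), specs["release_rate"])
    dx = exact(x - scenario.source.x)
    dy = exact(y - scenario.source.y)
    x_down, y_cross = _tracked_frame(theta, dx, dy)
    if x_down.value <= 0.0 or q.value == 0.0:
        return TrackedValue(0.0, R_MAX)
    sy = t_mul(exact(state.a1), t_pow(x_down, state.b1))
    sz = t_mul(exact(state.a2), t_pow(x_down, state.b2))
    base = t_div(q, t_mul(exact(2.0 * math.pi), t_mul(v, t_mul(sy, sz))))
    horiz = _tracked_gauss(t_mul(y_cross, y_cross), sy)
    zm = exact((z - scenario.source.height) ** 2)
    zp = exact((z + scenario.source.height) ** 2)
    vert = t_add(_tracked_gauss(zm, sz), _tracked_gauss(zp, sz))
    conc = t_mul(base, t_mul(horiz, vert))
    if scenario.lam > 0.0:
        conc = t_mul(conc, t_exp(t_neg(t_mul(exact(scenario.lam), exact(t)))))
    return conc


def _tracked_advection(scenario, tstart: float, t: float,
                       specs: dict[str, ErrorSpec]):
    """Tracked puff center offset and travel distance under step winds."""
    dx = exact(0.0)
    dy = exact(0.0)
    dist = exact(0.0)
    samples = scenario.wind.samples
    for j, (ts, speed, bearing) in enumerate(samples):
        seg_lo = ts if j > 0 else -math.inf
        seg_hi = samples[j + 1][0] if j + 1 < len(samples) else math.inf
        lo, hi = max(tstart, seg_lo), min(t, seg_hi)
        if hi <= lo:
            continue
        dt = exact(hi - lo)
        v = track(speed, specs["wind_speed"])
        theta = track(bearing, specs["wind_direction"])
        alpha = t_mul(t_add(theta, exact(180.0)), exact(_DEG))
        step = t_mul(v, dt)
        dist = t_add(dist, step)
        dx = t_add(dx, t_mul(step, t_sin(alpha)))
        dy = t_add(dy, t_mul(step, t_cos(alpha)))
    return dx, dy, dist


def tracked_multipuff_point(scenario, state, x: float, y: float, z: float = 0.0,
                            t: float = 0.0, t0: float = 0.0,
                            specs: dict[str, ErrorSpec] | None = None) -> TrackedValue:
    """Evaluate the multi-puff sum at one point in tracked arithmetic.

    Considerably slower than the vectorised float path; intended for
    modest grids and puff counts.
    """
    from .dispersion import emit_puffs

    specs = {**DEFAULT_INPUT_SPECS, **(specs or {})}
    total: TrackedValue | None = None
    norm = exact((2.0 * math.pi) ** 1.5)
    for p in emit_puffs(scenario.source, scenario.dt_release, (t0, t)):
        if p.q == 0.0:
            continue
        dx, dy, dist = _tracked_advection(scenario, p.tstart, t, specs)
        if dist.value <= 0.0:
            continue
        q = track(p.q, specs["release_rate"])
        sxy = t_mul(exact(state.a1), t_pow(dist, state.b1))
        sz = t_mul(exact(state.a2), t_pow(dist, state.b2))
        base = t_div(q, t_mul(norm, t_mul(sxy, t_mul(sxy, sz))))
        ox = t_sub(exact(x - p.xs), dx)
        oy = t_sub(exact(y - p.ys), dy)
        horiz = t_mul(_tracked_gauss(t_mul(ox, ox), sxy),
                      _tracked_gauss(t_mul(oy, oy), sxy))
        zm = exact((z - p.zs) ** 2)
        zp = exact((z + p.zs) ** 2)
        vert = t_add(_tracked_gauss(zm, sz), _tracked_gauss(zp, sz))
        contrib = t_mul(base, t_mul(horiz, vert))
        if scenario.lam > 0.0:
            contrib = t_mul(contrib, t_exp(t_neg(
                t_mul(exact(scenario.lam), exact(t - p.tstart)))))
        total = contrib if total is None else t_add(total, contrib)
    if total is None or total.value == 0.0:
        return TrackedValue(0.0 if total is None else total.value, R_MAX)
    return total


def tracked_field(model: str, scenario, state, grid_x, grid_y, t: float,
                  z: float = 0.0, t0: float = 0.0,
                  specs: dict[str, ErrorSpec] | None = None):
    """Concentration and relative-error-exponent maps on a rectangular grid.

    Parameters
    ----------
    model : "plume" or "multipuff"
    grid_x, grid_y : 1-D coordinate arrays; the field is evaluated on their
        Cartesian product.

    Returns
    -------
    (conc, r) : two arrays of shape (len(grid_y), len(grid_x)); ``conc`` in
        kg/m^3, ``r`` the integer relative-error exponent.  Deterministic
        for fixed inputs.
    """
    if model not in ("plume", "multipuff"):
        raise ValueError("model must be 'plume' or 'multipuff'")
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    conc = np.zeros((gy.size, gx.size))
    rmap = np.zeros((gy.size, gx.size), dtype=int)
    for i, yy in enumerate(gy):
        for j, xx in enumerate(gx):
            if model == "plume":
                tv = tracked_plume_point(scenario, state, xx, yy, z, t, specs)
            else:
                tv = tracked_multipuff_point(scenario, state, xx, yy, z, t, t0, specs)
            conc[i, j] = tv.value
            rmap[i, j] = tv.r
    return conc, rmap
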