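"""Two-compartment kinetics of nuclear-cytoplasmic tRNA exchange.

The cell is modelled as two well-mixed pools — nucleus and cytoplasm —
connected by first-order fluxes across the nuclear envelope with rate
constants ``k_in`` (import, min^-1) and ``k_out`` (export, min^-1).  The
plasma membrane is impermeable, so total tracer is conserved:

    V_N * C_N(t) + V_C * Cbar_C(t) = const.

Transport inside each compartment is fast compared with envelope
transport, so the cytoplasmic spatial profile keeps a fixed shape and the
spatially averaged cytoplasmic concentration is proportional to the
perinuclear one, ``Cbar_C = w * C_C`` with ``0 < w <= 1``.  Under these
assumptions the nuclear mass balance

    dC_N/dt = k_in * C_C - k_out * C_N

is linear with relaxation time ``tau = 1 / (k_out + (phi/w) * k_in)``
(``phi = V_N/V_C``), and the fluorescence intensity ratio
``FIR = C_N/C_C`` starting from an all-cytoplasmic tracer follows the
closed form

    FIR(t) = (1 - exp(-t/tau)) / (k_out/k_in + (phi/w) * exp(-t/tau)).

``phi`` and ``w`` enter only through the composite ``c = phi/w``; the
module accepts either the composite or full geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "CompartmentGeometry",
    "CompartmentState",
    "RampSegment",
    "RateSchedule",
    "FIRSeries",
    "DegenerateModelError",
    "fir_closed_form",
    "steady_state_fir",
    "time_constant",
    "simulate_compartments",
    "fir_from_state",
]

#: Composite geometry factor phi/w that makes the full-nutrition fitted
#: rate constants and time constant mutually consistent
#: (1 / (0.32 + 0.32*0.30) = 2.40 min).
DEFAULT_COMPOSITE_GEOMETRY = 0.32


class DegenerateModelError(ValueError):
    """Raised when the kinetic model has no finite, well-defined solution."""


@dataclass(frozen=True)
class RateConstants:
    """First-order nuclear import/export rate constants, per minute."""

    k_in: float
    k_out: float

    def __post_init__(self) -> None:
        if self.k_in < 0 or self.k_out < 0:
            raise ValueError(
                f"rate constants must be nonnegative, got "
                f"(k_in={self.k_in}, k_out={self.k_out})"
            )

    def to_dict(self) -> dict:
        return {"k_in": self.k_in, "k_out": self.k_out}


@dataclass(frozen=True)
class CompartmentGeometry:
    """Nucleus/cytoplasm volumes and the cytoplasmic uniformity factor.

    Parameters
    ----------
    V_N, V_C
        Compartment volumes (any common unit).
    w
        Ratio of spatially averaged to perinuclear cytoplasmic
        concentration; 1 for a uniform cytoplasm, < 1 when concentration
        decays away from the nucleus.
    """

    V_N: float
    V_C: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.V_N <= 0 or self.V_C <= 0:
            raise ValueError("compartment volumes must be positive")
        if not 0 < self.w <= 1:
            raise ValueError(f"uniformity factor w must be in (0, 1], got {self.w}")

    @property
    def phi(self) -> float:
        """Nucleus-to-cytoplasm volume ratio V_N/V_C."""
        return self.V_N / self.V_C

    @property
    def c(self) -> float:
        """Composite factor phi/w appearing in the closed-form FIR."""
        return self.phi / self.w

    @classmethod
    def from_composite(cls, c: float = DEFAULT_COMPOSITE_GEOMETRY) -> "CompartmentGeometry":
        """Geometry with a given phi/w (unit cytoplasm volume, w = 1)."""
        if c <= 0:
            raise ValueError(f"composite geometry factor must be positive, got {c}")
        return cls(V_N=c, V_C=1.0, w=1.0)

    def to_dict(self) -> dict:
        return {"V_N": self.V_N, "V_C": self.V_C, "w": self.w}


@dataclass(frozen=True)
class CompartmentState:
    """Concentrations of both pools at one instant.

    ``C_C`` is the perinuclear cytoplasmic concentration (the quantity
    entering FIR); ``C_bar_C`` the cytoplasmic spatial average.
    """

    t: float
    C_N: float
    C_C: float
    C_bar_C: float

    def __post_init__(self) -> None:
        if self.C_N < 0 or self.C_C < 0 or self.C_bar_C < 0:
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class RampSegment:
    """One schedule segment: at ``start`` the rates move to ``target``.

    ``transition='step'`` switches instantaneously; ``'linear'`` ramps
    linearly over ``duration`` minutes from whatever the rates were at
    ``start``.
    """

    start: float
    target: RateConstants
    transition: Literal["step", "linear"] = "step"
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.transition == "linear" and self.duration <= 0:
            raise ValueError("linear ramp requires duration > 0")
        if self.transition not in ("step", "linear"):
            raise ValueError(f"unknown transition {self.transition!r}")


class RateSchedule:
    """Piecewise rate-constant program k_in(t), k_out(t).

    Built from an initial :class:`RateConstants` plus ordered
    :class:`RampSegment` entries.  The canonical media-switch protocol —
    rates moving linearly over 25 minutes between their values in the old
    and new medium — is one linear segment.
    """

    def __init__(self, initial: RateConstants, segments: Sequence[RampSegment] = ()):
        starts = [s.start for s in segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        self.initial = initial
        self.segments = tuple(segments)

    @classmethod
    def constant(cls, rates: RateConstants) -> "RateSchedule":
        return cls(rates, ())

    @classmethod
    def media_switch(
        cls,
        before: RateConstants,
        after: RateConstants,
        switch_time: float = 0.0,
        ramp_duration: float = 25.0,
    ) -> "RateSchedule":
        """Linear ramp between two nutritional states over ``ramp_duration`` min."""
        return cls(before, (RampSegment(switch_time, after, "linear", ramp_duration),))

    def rates_at(self, t: float) -> RateConstants:
        current = self.initial
        for seg in self.segments:
            if t < seg.start:
                break
            if seg.transition == "step" or t >= seg.start + seg.duration:
                current = seg.target
            else:
                f = (t - seg.start) / seg.duration
                current = RateConstants(
                    current.k_in + f * (seg.target.k_in - current.k_in),
                    current.k_out + f * (seg.target.k_out - current.k_out),
                )
                break
        return current

    def breakpoints(self) -> list[float]:
        """Times where k(t) is non-smooth (segment starts and ramp ends)."""
        pts: list[float] = []
        for seg in self.segments:
            pts.append(seg.start)
            if seg.transition == "linear":
                pts.append(seg.start + seg.duration)
        return pts


@dataclass
class FIRSeries:
    """Time-stamped nuclear/cytoplasmic fluorescence intensity ratio."""

    times: np.ndarray
    fir: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None
    provenance: Literal["simulated", "extracted"] = "simulated"
    sigma: np.ndarray | None = field(default=None)  # optional per-point SD

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fir = np.asarray(self.fir, dtype=float)
        if self.times.shape != self.fir.shape:
            raise ValueError("times and fir must have the same shape")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at t >= 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(self.fir < 0):
            raise ValueError("FIR values must be nonnegative")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times, "fir": self.fir})
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "extracted") -> "FIRSeries":
        df = pd.read_csv(path)
        if not {"time_min", "fir"} <= set(df.columns):
            raise ValueError("FIR CSV requires columns time_min, fir")
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(
            times=df["time_min"].to_numpy(),
            fir=df["fir"].to_numpy(),
            provenance=provenance,  # type: ignore[arg-type]
            sigma=sigma,
        )


# ---------------------------------------------------------------------------
# Closed-form model
# ---------------------------------------------------------------------------

def _composite(geom: CompartmentGeometry | float) -> float:
    return geom.c if isinstance(geom, CompartmentGeometry) else float(geom)


def time_constant(rates: RateConstants, geom: CompartmentGeometry | float) -> float:
    """Relaxation time tau = 1/(k_out + (phi/w) k_in), in minutes."""
    c = _composite(geom)
    denom = rates.k_out + c * rates.k_in
    if denom <= 0:
        raise DegenerateModelError("k_out + (phi/w) k_in must be positive")
    return 1.0 / denom


def steady_state_fir(rates: RateConstants) -> float:
    """Asymptotic FIR, k_in/k_out."""
    if rates.k_out == 0:
        raise DegenerateModelError(
            "k_out = 0 gives unbounded nuclear accumulation (no finite FIR_inf)"
        )
    return rates.k_in / rates.k_out


def fir_closed_form(
    rates: RateConstants,
    geom: CompartmentGeometry | float,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """FIR(t) for constant rates and an all-cytoplasmic start.

    FIR(t) = (1 - e^{-t/tau}) / (k_out/k_in + (phi/w) e^{-t/tau}).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if rates.k_in == 0 and rates.k_out == 0:
        raise DegenerateModelError("k_in = k_out = 0: no transport at all")
    if rates.k_in == 0:
        # nucleus never loads; FIR stays 0
        return np.zeros_like(t) if t.ndim else 0.0
    c = _composite(geom)
    tau = time_constant(rates, c)
    decay = np.exp(-t / tau)
    out = (1.0 - decay) / (rates.k_out / rates.k_in + c * decay)
    return out if t.ndim else float(out)


def fir_from_state(state: CompartmentState) -> float:
    """FIR = C_N / C_C of one compartment state."""
    if state.C_C <= 0:
        raise ZeroDivisionError("cytoplasmic concentration is zero; FIR undefined")
    return state.C_N / state.C_C


# ---------------------------------------------------------------------------
# ODE simulation (constant or time-varying rates)
# ---------------------------------------------------------------------------

def simulate_compartments(
    schedule: RateSchedule | RateConstants,
    geom: CompartmentGeometry | float,
    init: CompartmentState,
    times: Iterable[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[CompartmentState]:
    """Integrate dC_N/dt = k_in(t) C_C - k_out(t) C_N on a time grid.

    The closed cell conserves ``V_N C_N + V_C Cbar_C`` and the cytoplasm
    keeps its profile shape (``Cbar_C = w C_C``), so C_C is eliminated
    algebraically and only C_N is integrated.  Ramp breakpoints are hit
    exactly by segment-wise integration, so the adaptive stepper never
    smears a rate discontinuity.
    """
    if isinstance(schedule, RateConstants):
        schedule = RateSchedule.constant(schedule)
    if isinstance(geom, CompartmentGeometry):
        V_N, V_C, w = geom.V_N, geom.V_C, geom.w
    else:
        V_N, V_C, w = float(geom), 1.0, 1.0

    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        return []
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.isclose(init.C_bar_C, w * init.C_C, rtol=1e-6, atol=1e-12):
        raise ValueError("initial state violates C_bar_C = w * C_C")

    total = V_N * init.C_N + V_C * init.C_bar_C  # conserved tracer amount

    def C_C_of(C_N: float | np.ndarray):
        return (total - V_N * np.asarray(C_N)) / (V_C * w)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        r = schedule.rates_at(t)
        return [r.k_in * C_C_of(y[0]) - r.k_out * y[0]]

    t0, t_end = init.t, times[-1]
    if times[0] < t0:
        raise ValueError("grid starts before the initial state's time")
    cuts = sorted({t0, t_end, *[b for b in schedule.breakpoints() if t0 < b < t_end]})

    C_N_grid = np.empty_like(times)
    y0 = [init.C_N]
    for a, b in zip(cuts, cuts[1:]):
        mask = (times >= a) & (times <= b)
        sol = solve_ivp(
            rhs, (a, b), y0, method="RK45",
            t_eval=times[mask], rtol=rtol, atol=atol, dense_output=True,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        C_N_grid[mask] = sol.y[0]
        y0 = [float(sol.sol(b)[0])]
    if times[0] == t0:
        C_N_grid[0] = init.C_N

    states = []
    for t, C_N in zip(times, C_N_grid):
        C_C = float(C_C_of(C_N))
        states.append(CompartmentState(t=float(t), C_N=float(C_N), C_C=C_C, C_bar_C=w * C_C))
    return states


def initial_state_from_fir(
    fir0: float, geom: CompartmentGeometry | float, t: float = 0.0, C_C: float = 1.0
) -> CompartmentState:
    """Compartment state with a prescribed FIR (e.g. a measured pre-switch value)."""
    if fir0 < 0:
        raise ValueError("initial FIR must be nonnegative")
    w = geom.w if isinstance(geom, CompartmentGeometry) else 1.0
    return CompartmentState(t=t, C_N=fir0 * C_C, C_C=C_C, C_bar_C=w * C_C)


# ---------------------------------------------------------------------------
# JSON serialization helpers
# ---------------------------------------------------------------------------

def schedule_to_dict(schedule: RateSchedule) -> dict:
    return {
        "initial": schedule.initial.to_dict(),
        "segments": [
            {
                "start": s.start,
                "target": s.target.to_dict(),
                "transition": s.transition,
                "duration": s.duration,
            }
            for s in schedule.segments
        ],
    }


def schedule_from_dict(d: dict) -> RateSchedule:
    return RateSchedule(
        RateConstants(**d["initial"]),
        tuple(
            RampSegment(
                start=s["start"],
                target=RateConstants(**s["target"]),
                transition=s.get("transition", "step"),
                duration=s.get("duration", 0.0),
            )
            for s in d.get("segments", ())
        ),
    )


def save_json(obj: RateConstants | CompartmentGeometry | RateSchedule, path: str | Path) -> None:
    if isinstance(obj, RateSchedule):
        payload: dict = {"type": "RateSchedule", **schedule_to_dict(obj)}
    else:
        payload = {"type": type(obj).__name__, **obj.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_json(path: str | Path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("type")
    if kind == "RateConstants":
        return RateConstants(**d)
    if kind == "CompartmentGeometry":
        return CompartmentGeometry(**d)
    if kind == "RateSchedule":
        return schedule_from_dict(d)
    raise ValueError(f"unknown serialized type {kind!r}")
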