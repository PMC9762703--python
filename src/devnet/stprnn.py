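"""Bi-stable short-term-plasticity recurrent network (STP-RNN) of developing CA1.

A Wilson-Cowan-type mean-field model of a pyramidal-cell (P) and an
interneuron (I) population whose synapses carry short-term depression
(resource x) and facilitation (utilization u), giving a 10-dimensional
system: two rates A_P, A_I and (x, u) for each of the four connections
PP, IP, PI, II (second index = presynaptic population):

    τ_i dA_i/dt = -A_i + f_i(J_iP u_iP x_iP A_P - J_iI u_iI x_iI A_I + e_i)
    dx_ij/dt    = (1 - x_ij)/τ_r,j - u_ij x_ij A_j
    du_ij/dt    = (U - u_ij)/τ_f,j + U (1 - u_ij) A_j

with a threshold-linear response f_i(h) = G_i·max(h - θ_i, 0). With the
default parameters (inhibitory GABA, non-zero spontaneous pyramidal
activity) the network is bi-stable: a stable silent fixed point at
(0, 0) Hz coexists with a stable active state, separated by an unstable
fixed point. "Freezing" the synaptic variables at a state of interest
yields a 2D rate system whose fixed-point layout exposes the fast dynamics
(amplification domain, transient attractors) that generate simulated
network bursts (simNBs) and the internal deadline for silent-to-active
transitions.

The module provides fixed-step RK4 simulation of pulse protocols, full-10D
and frozen-2D fixed-point finding with linear stability, operating-regime
classification (ISN / Non-ISN / unstable) over the rate plane, transition
matrices, the inter-pulse-interval deadline scan, synaptic-strength scaling
experiments, and the mono-stable model variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "StpRnnParams",
    "PulsedInput",
    "Trajectory",
    "FixedPointRecord",
    "FrozenStpRnn",
    "RegimeMap",
    "TransitionScan",
    "DeadlineResult",
    "make_variant",
    "response",
    "derivatives",
    "integrate",
    "stationary_stp",
    "find_fixed_points",
    "freeze",
    "classify_regime",
    "regime_map",
    "pulse_experiment",
    "transition_matrix",
    "deadline_scan",
    "scaling_experiment",
]

# state vector layout
STATE_NAMES = ("A_P", "A_I", "x_PP", "x_IP", "x_PI", "x_II",
               "u_PP", "u_IP", "u_PI", "u_II")


@dataclass(frozen=True)
class StpRnnParams:
    """Model constants. Defaults parameterize the second-postnatal-week
    network: inhibitory GABA (J_I > 0) and bi-stable spontaneous dynamics."""

    tau_P: float = 0.015     # s, P rate relaxation
    tau_I: float = 0.0075    # s, I rate relaxation
    J_P: float = 6.5         # glutamatergic efficacy (J_PP = J_IP)
    J_I: float = 3.0         # GABAergic efficacy (J_II = J_PI); < 0 = excitatory
    tau_r_P: float = 3.0     # s, depression recovery, presynaptic P
    tau_r_I: float = 2.5     # s, depression recovery, presynaptic I
    tau_f_P: float = 0.4     # s, facilitation, presynaptic P
    tau_f_I: float = 0.4     # s, facilitation, presynaptic I
    U_P: float = 0.8         # release-probability analog, presynaptic P
    U_I: float = 0.8
    theta_P: float = 0.22    # activity threshold
    theta_I: float = 0.53
    G_P: float = 1.0         # gain
    G_I: float = 1.0
    e_P: float = 0.0         # baseline external input
    e_I: float = 0.0


def make_variant(kind: str) -> StpRnnParams:
    """The three parameterizations: the bi-stable default ('STP-RNN'),
    'Mono-RNNi' (θ_P = -0.18, inhibitory GABA, mono-stable) and 'Mono-RNNe'
    (θ_P = -0.3, θ_I = -0.1, J_I = -1.5, excitatory GABA, mono-stable)."""
    if kind == "STP-RNN":
        return StpRnnParams()
    if kind == "Mono-RNNi":
        return StpRnnParams(theta_P=-0.18)
    if kind == "Mono-RNNe":
        return StpRnnParams(theta_P=-0.3, theta_I=-0.1, J_I=-1.5)
    raise ValueError(f"unknown model variant {kind!r}")


def response(h: float, theta: float, gain: float) -> float:
    """Threshold-linear rate response, continuous at the threshold."""
    return gain * (h - theta) if h > theta else 0.0


def derivatives(state, p: StpRnnParams, e_P: float = 0.0, e_I: float = 0.0):
    """Right-hand side of the 10D system (returns a tuple, plain floats)."""
    AP, AI, xPP, xIP, xPI, xII, uPP, uIP, uPI, uII = state
    hP = p.J_P * uPP * xPP * AP - p.J_I * uPI * xPI * AI + e_P
    hI = p.J_P * uIP * xIP * AP - p.J_I * uII * xII * AI + e_I
    fP = p.G_P * (hP - p.theta_P) if hP > p.theta_P else 0.0
    fI = p.G_I * (hI - p.theta_I) if hI > p.theta_I else 0.0
    return (
        (-AP + fP) / p.tau_P,
        (-AI + fI) / p.tau_I,
        (1.0 - xPP) / p.tau_r_P - uPP * xPP * AP,
        (1.0 - xIP) / p.tau_r_P - uIP * xIP * AP,
        (1.0 - xPI) / p.tau_r_I - uPI * xPI * AI,
        (1.0 - xII) / p.tau_r_I - uII * xII * AI,
        (p.U_P - uPP) / p.tau_f_P + p.U_P * (1.0 - uPP) * AP,
        (p.U_P - uIP) / p.tau_f_P + p.U_P * (1.0 - uIP) * AP,
        (p.U_I - uPI) / p.tau_f_I + p.U_I * (1.0 - uPI) * AI,
        (p.U_I - uII) / p.tau_f_I + p.U_I * (1.0 - uII) * AI,
    )


def drives(state, p: StpRnnParams, e_P: float = 0.0, e_I: float = 0.0) -> tuple[float, float]:
    """Summed inputs (h_P, h_I) at a state."""
    AP, AI, xPP, xIP, xPI, xII, uPP, uIP, uPI, uII = state
    hP = p.J_P * uPP * xPP * AP - p.J_I * uPI * xPI * AI + e_P
    hI = p.J_P * uIP * xIP * AP - p.J_I * uII * xII * AI + e_I
    return hP, hI


def silent_state(p: StpRnnParams):
    return (0.0, 0.0, 1.0, 1.0, 1.0, 1.0, p.U_P, p.U_P, p.U_I, p.U_I)


@dataclass
class PulsedInput:
    """Rectangular input pulses: list of (time s, duration s, e_P, e_I)."""

    pulses: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pulses = sorted(self.pulses)
        for (t0, d0, *_), (t1, *_rest) in zip(pulses, pulses[1:]):
            if t0 + d0 > t1:
                raise ValueError("pulses must not overlap")
        self.pulses = pulses

    def at(self, t: float) -> tuple[float, float]:
        for t0, dur, eP, eI in self.pulses:
            if t0 <= t < t0 + dur:
                return eP, eI
        return 0.0, 0.0


@dataclass
class Trajectory:
    t: np.ndarray
    states: np.ndarray           # (n, 10)
    h_P: np.ndarray
    h_I: np.ndarray
    inputs: np.ndarray           # (n, 2)

    @property
    def total_rate(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]


def _rk4_step(s, p, eP, eI, dt):
    k1 = derivatives(s, p, eP, eI)
    s2 = tuple(si + 0.5 * dt * ki for si, ki in zip(s, k1))
    k2 = derivatives(s2, p, eP, eI)
    s3 = tuple(si + 0.5 * dt * ki for si, ki in zip(s, k2))
    k3 = derivatives(s3, p, eP, eI)
    s4 = tuple(si + dt * ki for si, ki in zip(s, k3))
    k4 = derivatives(s4, p, eP, eI)
    return tuple(si + dt / 6.0 * (a + 2 * b + 2 * c + d)
                 for si, a, b, c, d in zip(s, k1, k2, k3, k4))


def _sanitize(s, p: StpRnnParams):
    """Enforce state bounds; tiny numerical undershoots are clipped, real
    violations raise."""
    AP, AI = s[0], s[1]
    if AP < -1e-9 or AI < -1e-9:
        raise FloatingPointError("negative rate beyond numerical tolerance")
    out = [max(AP, 0.0), max(AI, 0.0)]
    for x in s[2:6]:
        out.append(min(max(x, 1e-12), 1.0))
    for u, U in zip(s[6:], (p.U_P, p.U_P, p.U_I, p.U_I)):
        out.append(min(max(u, U), 1.0))
    if not all(math.isfinite(v) for v in out):
        raise FloatingPointError("non-finite state during integration")
    return tuple(out)


def integrate(p: StpRnnParams, protocol: PulsedInput, total_time: float,
              dt: float = 2e-4, initial_state=None,
              record_every: int = 1) -> Trajectory:
    """Fixed-step RK4 integration of the 10D system under a pulse protocol."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = tuple(float(v) for v in (initial_state if initial_state is not None
                                 else silent_state(p)))
    n_steps = int(round(total_time / dt))
    ts, states, hps, his, inputs = [], [], [], [], []
    for k in range(n_steps + 1):
        t = k * dt
        eP, eI = protocol.at(t)
        if k % record_every == 0:
            hP, hI = drives(s, p, eP, eI)
            ts.append(t)
            states.append(s)
            hps.append(hP)
            his.append(hI)
            inputs.append((eP, eI))
        if k < n_steps:
            s = _sanitize(_rk4_step(s, p, eP, eI, dt), p)
    return Trajectory(np.array(ts), np.array(states), np.array(hps),
                      np.array(his), np.array(inputs))


# ---------------------------------------------------------------------------
# steady-state synaptic variables and fixed points

def stationary_stp(A: float, U: float, tau_f: float, tau_r: float) -> tuple[float, float]:
    """Steady-state facilitation u* and depression x* for presynaptic rate A:
    u* = U(1 + τ_f A)/(1 + U τ_f A), x* = 1/(1 + τ_r u* A)."""
    if A < 0:
        raise ValueError("rate must be non-negative")
    u = U * (1.0 + tau_f * A) / (1.0 + U * tau_f * A)
    x = 1.0 / (1.0 + tau_r * u * A)
    return u, x


def _ux(A, U, tau_f, tau_r):
    """Vectorized product u*·x* as a function of presynaptic rate."""
    A = np.asarray(A, dtype=float)
    u = U * (1.0 + tau_f * A) / (1.0 + U * tau_f * A)
    x = 1.0 / (1.0 + tau_r * u * A)
    return u * x


@dataclass
class FixedPointRecord:
    rates: tuple[float, float]            # (A_P, A_I)
    state: tuple                          # full 10D state
    stable: bool
    eigenvalues: np.ndarray
    system: str                           # 'full' or 'frozen'

    @property
    def is_silent(self) -> bool:
        return abs(self.rates[0]) < 1e-9 and abs(self.rates[1]) < 1e-9


def _full_state_at(AP: float, AI: float, p: StpRnnParams):
    uP, xP = stationary_stp(AP, p.U_P, p.tau_f_P, p.tau_r_P)
    uI, xI = stationary_stp(AI, p.U_I, p.tau_f_I, p.tau_r_I)
    return (AP, AI, xP, xP, xI, xI, uP, uP, uI, uI)


def _jacobian(p: StpRnnParams, state, e_P=0.0, e_I=0.0, h: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of the 10D right-hand side."""
    state = np.asarray(state, dtype=float)
    J = np.empty((10, 10))
    for j in range(10):
        sp, sm = state.copy(), state.copy()
        sp[j] += h
        sm[j] -= h
        fp = derivatives(tuple(sp), p, e_P, e_I)
        fm = derivatives(tuple(sm), p, e_P, e_I)
        J[:, j] = (np.array(fp) - np.array(fm)) / (2 * h)
    return J


def find_fixed_points(p: StpRnnParams, e_P: float = 0.0, e_I: float = 0.0,
                      rate_max: float = 200.0, n_seeds: int = 24,
                      residual_tol: float = 1e-9) -> list[FixedPointRecord]:
    """All steady states of the 10D system.

    The STP equations are eliminated with their closed-form steady states,
    leaving two rate equations whose threshold-linear regions (each
    population above/below threshold) are enumerated: the fully subthreshold
    region is checked in closed form, single-population regions are solved
    by bracketed root finding, and the both-active region by damped Newton
    iterations from a grid of seeds. Solutions are deduplicated, verified to
    residual < ``residual_tol`` on the full 10D right-hand side, and
    classified by the eigenvalues of the 10D Jacobian.
    """
    sols: list[tuple[float, float]] = []

    def hP_of(AP, AI):
        return (p.J_P * _ux(AP, p.U_P, p.tau_f_P, p.tau_r_P) * AP
                - p.J_I * _ux(AI, p.U_I, p.tau_f_I, p.tau_r_I) * AI + e_P)

    def hI_of(AP, AI):
        return (p.J_P * _ux(AP, p.U_P, p.tau_f_P, p.tau_r_P) * AP
                - p.J_I * _ux(AI, p.U_I, p.tau_f_I, p.tau_r_I) * AI + e_I)

    # region (off, off)
    if hP_of(0.0, 0.0) <= p.theta_P and hI_of(0.0, 0.0) <= p.theta_I:
        sols.append((0.0, 0.0))

    # region (on, off): A_I = 0
    def gP(AP):
        return -AP + p.G_P * (hP_of(AP, 0.0) - p.theta_P)

    for lo, hi in _brackets(gP, 1e-9, rate_max, 400):
        AP = optimize.brentq(gP, lo, hi, xtol=1e-13)
        if AP > 1e-9 and hI_of(AP, 0.0) <= p.theta_I:
            sols.append((AP, 0.0))

    # region (off, on): A_P = 0
    def gI(AI):
        return -AI + p.G_I * (hI_of(0.0, AI) - p.theta_I)

    for lo, hi in _brackets(gI, 1e-9, rate_max, 400):
        AI = optimize.brentq(gI, lo, hi, xtol=1e-13)
        if AI > 1e-9 and hP_of(0.0, AI) <= p.theta_P:
            sols.append((0.0, AI))

    # region (on, on)
    def gPI(v):
        AP, AI = v
        return [-AP + p.G_P * (hP_of(AP, AI) - p.theta_P),
                -AI + p.G_I * (hI_of(AP, AI) - p.theta_I)]

    seeds = np.geomspace(0.05, rate_max, n_seeds)
    for sp in seeds:
        for si in seeds:
            res = optimize.root(gPI, [sp, si], method="hybr",
                                options={"xtol": 1e-13})
            if not res.success:
                continue
            AP, AI = res.x
            if AP > 1e-9 and AI > 1e-9 and \
               hP_of(AP, AI) > p.theta_P and hI_of(AP, AI) > p.theta_I:
                sols.append((float(AP), float(AI)))

    # deduplicate
    uniq: list[tuple[float, float]] = []
    for s in sols:
        if not any(abs(s[0] - u[0]) < 1e-6 and abs(s[1] - u[1]) < 1e-6 for u in uniq):
            uniq.append(s)

    records = []
    for AP, AI in sorted(uniq):
        state = _full_state_at(AP, AI, p)
        resid = max(abs(v) for v in derivatives(state, p, e_P, e_I))
        # rate equations carry a 1/tau factor; scale the tolerance accordingly
        if resid > residual_tol / min(p.tau_P, p.tau_I):
            continue
        eig = np.linalg.eigvals(_jacobian(p, state, e_P, e_I))
        records.append(FixedPointRecord((AP, AI), state,
                                        bool(np.max(eig.real) < 0), eig, "full"))
    return records


def _brackets(fn, lo, hi, n):
    xs = np.linspace(lo, hi, n)
    vals = np.array([fn(x) for x in xs])
    out = []
    for i in range(n - 1):
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            out.append((xs[i], xs[i + 1]))
    return out


def spontaneous_fixed_points(p: StpRnnParams) -> dict[str, FixedPointRecord]:
    """Convenience: the stable silent / active spontaneous fixed points."""
    fps = find_fixed_points(p)
    out: dict[str, FixedPointRecord] = {}
    for fp in fps:
        if fp.is_silent and fp.stable:
            out["silent"] = fp
        elif fp.stable and fp.rates[0] > 0:
            if "active" not in out or fp.rates[0] > out["active"].rates[0]:
                out["active"] = fp
    return out


# ---------------------------------------------------------------------------
# frozen (2D) system

@dataclass
class FrozenStpRnn:
    """Rate dynamics with synaptic efficacies frozen at a reference state:
    J^frz_ij = J_ij · u_ij · x_ij evaluated at that state."""

    params: StpRnnParams
    J_PP: float
    J_IP: float
    J_PI: float
    J_II: float

    def rhs(self, AP: float, AI: float, e_P: float = 0.0, e_I: float = 0.0):
        p = self.params
        hP = self.J_PP * AP - self.J_PI * AI + e_P
        hI = self.J_IP * AP - self.J_II * AI + e_I
        return ((-AP + response(hP, p.theta_P, p.G_P)) / p.tau_P,
                (-AI + response(hI, p.theta_I, p.G_I)) / p.tau_I)

    def jacobian(self, active_P: bool, active_I: bool) -> np.ndarray:
        p = self.params
        gP = p.G_P if active_P else 0.0
        gI = p.G_I if active_I else 0.0
        return np.array([
            [(-1.0 + gP * self.J_PP) / p.tau_P, -gP * self.J_PI / p.tau_P],
            [gI * self.J_IP / p.tau_I, (-1.0 - gI * self.J_II) / p.tau_I],
        ])

    def fixed_points(self, e_P: float = 0.0, e_I: float = 0.0) -> list[FixedPointRecord]:
        """All fixed points of the piecewise-linear 2D system, found in
        closed form per threshold region."""
        p = self.params
        cands: list[tuple[float, float, bool, bool]] = []
        # (off, off)
        if e_P <= p.theta_P and e_I <= p.theta_I:
            cands.append((0.0, 0.0, False, False))
        # (on, off)
        den = 1.0 - p.G_P * self.J_PP
        if abs(den) > 1e-12:
            AP = p.G_P * (e_P - p.theta_P) / den
            if AP > 1e-12 and self.J_IP * AP + e_I <= p.theta_I:
                cands.append((AP, 0.0, True, False))
        # (off, on)
        den = 1.0 + p.G_I * self.J_II
        if abs(den) > 1e-12:
            AI = p.G_I * (e_I - p.theta_I) / den
            if AI > 1e-12 and -self.J_PI * AI + e_P <= p.theta_P:
                cands.append((0.0, AI, False, True))
        # (on, on)
        M = np.array([[1.0 - p.G_P * self.J_PP, p.G_P * self.J_PI],
                      [-p.G_I * self.J_IP, 1.0 + p.G_I * self.J_II]])
        b = np.array([p.G_P * (e_P - p.theta_P), p.G_I * (e_I - p.theta_I)])
        if abs(np.linalg.det(M)) > 1e-12:
            AP, AI = np.linalg.solve(M, b)
            hP = self.J_PP * AP - self.J_PI * AI + e_P
            hI = self.J_IP * AP - self.J_II * AI + e_I
            if AP > 1e-12 and AI > 1e-12 and hP > p.theta_P and hI > p.theta_I:
                cands.append((float(AP), float(AI), True, True))
        records = []
        for AP, AI, actP, actI in cands:
            eig = np.linalg.eigvals(self.jacobian(actP, actI))
            records.append(FixedPointRecord((AP, AI), (AP, AI),
                                            bool(np.max(eig.real) < 0), eig,
                                            "frozen"))
        return records


def freeze(p: StpRnnParams, state) -> FrozenStpRnn:
    """Freeze the synaptic variables of a 10D state into a 2D rate system."""
    _, _, xPP, xIP, xPI, xII, uPP, uIP, uPI, uII = state
    return FrozenStpRnn(p,
                        J_PP=p.J_P * uPP * xPP, J_IP=p.J_P * uIP * xIP,
                        J_PI=p.J_I * uPI * xPI, J_II=p.J_I * uII * xII)


# ---------------------------------------------------------------------------
# operating regimes

def classify_regime(point: tuple[float, float], p: StpRnnParams) -> str:
    """Operating regime of a candidate fixed point (A_I, A_P) with synaptic
    variables at their stationary values.

    'isn': the pyramidal subsystem alone is unstable (G_P·J_PP·u*x* > 1 with
    A_I clamped) but feedback inhibition stabilizes the 2x2 frozen Jacobian;
    'non_isn': stable with a self-stable pyramidal subsystem; 'unstable'
    otherwise. For excitatory GABA (J_I < 0) the ISN notion is undefined and
    the labels reduce to {'non_isn', 'unstable'} (stable vs not).
    """
    AI, AP = point
    if AP < 0 or AI < 0:
        raise ValueError("rates must be non-negative")
    frz = freeze(p, _full_state_at(AP, AI, p))
    jac = frz.jacobian(AP > 0, AI > 0)
    tr, det = jac[0, 0] + jac[1, 1], jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
    overall_stable = (tr < 0) and (det > 0)
    if p.J_I < 0:
        return "non_isn" if overall_stable else "unstable"
    exc_unstable = (AP > 0) and (p.G_P * frz.J_PP > 1.0)
    if exc_unstable and overall_stable:
        return "isn"
    if (not exc_unstable) and overall_stable:
        return "non_isn"
    return "unstable"


@dataclass
class RegimeMap:
    A_I: np.ndarray
    A_P: np.ndarray
    labels: np.ndarray          # (n_AP, n_AI) strings
    areas: dict[str, float]     # Hz^2, by cell counting

    @property
    def isn_ap_range(self) -> float:
        """Maximal extent of pyramidal rates over which the ISN regime is
        available (Hz)."""
        rows = (self.labels == "isn").any(axis=1)
        if not rows.any():
            return 0.0
        ap = self.A_P[rows]
        return float(ap.max() - ap.min())


def regime_map(p: StpRnnParams, ai_max: float = 50.0, ap_max: float = 50.0,
               resolution: int = 201) -> RegimeMap:
    """Classify every grid point of the (A_I, A_P) plane; FP-domain areas by
    cell counting. Vectorized via the 2x2 trace/determinant criterion."""
    if resolution < 50:
        raise ValueError("resolution must be at least 50")
    A_I = np.linspace(0.0, ai_max, resolution)
    A_P = np.linspace(0.0, ap_max, resolution)
    AI, AP = np.meshgrid(A_I, A_P)           # labels[i, j] ~ (A_P[i], A_I[j])
    uxP = _ux(AP, p.U_P, p.tau_f_P, p.tau_r_P)
    uxI = _ux(AI, p.U_I, p.tau_f_I, p.tau_r_I)
    gP = np.where(AP > 0, p.G_P, 0.0)
    gI = np.where(AI > 0, p.G_I, 0.0)
    j11 = (-1.0 + gP * p.J_P * uxP) / p.tau_P
    j12 = -gP * p.J_I * uxI / p.tau_P
    j21 = gI * p.J_P * uxP / p.tau_I
    j22 = (-1.0 - gI * p.J_I * uxI) / p.tau_I
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    stable = (tr < 0) & (det > 0)
    labels = np.full(AP.shape, "unstable", dtype=object)
    if p.J_I < 0:
        labels[stable] = "non_isn"
    else:
        exc_unstable = (AP > 0) & (p.G_P * p.J_P * uxP > 1.0)
        labels[stable & exc_unstable] = "isn"
        labels[stable & ~exc_unstable] = "non_isn"
    cell = (A_I[1] - A_I[0]) * (A_P[1] - A_P[0])
    areas = {name: float((labels == name).sum()) * cell
             for name in ("isn", "non_isn", "unstable")}
    return RegimeMap(A_I, A_P, labels, areas)


# ---------------------------------------------------------------------------
# pulse experiments

@dataclass
class PulseOutcome:
    outcome: str                 # 'to_silent' | 'to_active' | 'undecided'
    simnb: bool
    simnb_size: float            # max of A_P + A_I after the pulse
    trajectory: Trajectory


def _near(state, fp: FixedPointRecord, eps: float) -> bool:
    return max(abs(a - b) for a, b in zip(state, fp.state)) < eps


def _run_with_exit(p, s, settle_time, dt, fps, eps, record=False):
    """Integrate after a pulse with early exit once the state has converged
    to one of the spontaneous fixed points."""
    n_steps = int(round(settle_time / dt))
    check_every = max(int(round(0.05 / dt)), 1)
    peak = s[0] + s[1]
    states = [s] if record else None
    for k in range(n_steps):
        s = _sanitize(_rk4_step(s, p, 0.0, 0.0, dt), p)
        total = s[0] + s[1]
        if total > peak:
            peak = total
        if record:
            states.append(s)
        if k % check_every == 0:
            name = _converged(s, p, fps, eps)
            if name is not None:
                return s, f"to_{name}", peak, states
    name = _converged(s, p, fps, eps)
    if name is not None:
        return s, f"to_{name}", peak, states
    return s, "undecided", peak, states


def _converged(s, p: StpRnnParams, fps, eps):
    """Name of the spontaneous fixed point the state has converged to, or
    None. Besides full-state proximity, a state with both rates at zero and
    both drives subthreshold is already in the silent point's basin: with no
    further input the rates stay at zero and the synaptic variables relax
    monotonically to rest."""
    for name, fp in fps.items():
        if _near(s, fp, eps):
            return name
    if "silent" in fps and s[0] < 1e-6 and s[1] < 1e-6:
        hP, hI = drives(s, p)
        if hP < p.theta_P and hI < p.theta_I:
            return "silent"
    return None


def pulse_experiment(p: StpRnnParams, start: str = "silent",
                     e_PC: float = 0.25, e_IN: float = 0.25,
                     pulse_duration: float = 0.020, settle_time: float = 20.0,
                     dt: float = 2e-4, eps: float = 1e-3,
                     initial_state=None,
                     fps: dict[str, FixedPointRecord] | None = None) -> PulseOutcome:
    """Apply one 20-ms excitatory pulse from a spontaneous fixed point (or a
    caller-supplied state) and classify the asymptotic outcome.

    A simNB is flagged when the post-offset peak of A_P + A_I exceeds both
    its value at input offset and twice the active fixed point's total rate
    (supra-amplification: the network transiently overshoots what the input
    itself drove).
    """
    if e_PC < 0 or e_IN < 0:
        raise ValueError("pulse amplitudes must be non-negative")
    if fps is None:
        fps = spontaneous_fixed_points(p)
    if initial_state is not None:
        s = tuple(float(v) for v in initial_state)
    else:
        if start not in fps:
            raise ValueError(f"no spontaneous {start!r} fixed point")
        s = fps[start].state
    # pulse
    n_pulse = int(round(pulse_duration / dt))
    pulse_states = [s]
    for _ in range(n_pulse):
        s = _sanitize(_rk4_step(s, p, e_PC, e_IN, dt), p)
        pulse_states.append(s)
    offset_total = s[0] + s[1]
    s_end, outcome, peak, post_states = _run_with_exit(
        p, s, settle_time, dt, fps, eps)
    active_total = (fps["active"].rates[0] + fps["active"].rates[1]
                    if "active" in fps else 0.0)
    simnb = peak > offset_total + 1e-9 and peak > 2.0 * active_total
    all_states = np.array(pulse_states)
    traj = Trajectory(np.arange(len(all_states)) * dt, all_states,
                      np.zeros(len(all_states)), np.zeros(len(all_states)),
                      np.zeros((len(all_states), 2)))
    return PulseOutcome(outcome, bool(simnb), float(peak), traj)


@dataclass
class TransitionScan:
    e_PC: np.ndarray
    e_IN: np.ndarray
    outcomes: np.ndarray        # (n_ePC, n_eIN) strings
    simnb: np.ndarray           # boolean flags
    simnb_size: np.ndarray


def transition_matrix(p: StpRnnParams, start: str, e_PC_grid: np.ndarray,
                      e_IN_grid: np.ndarray, settle_time: float = 20.0,
                      dt: float = 2e-4) -> TransitionScan:
    """Pulse-outcome matrix over a grid of input amplitudes."""
    e_PC_grid = np.asarray(e_PC_grid, dtype=float)
    e_IN_grid = np.asarray(e_IN_grid, dtype=float)
    if len(e_PC_grid) < 2 or len(e_IN_grid) < 2:
        raise ValueError("grids need at least two points")
    fps = spontaneous_fixed_points(p)
    outcomes = np.empty((len(e_PC_grid), len(e_IN_grid)), dtype=object)
    flags = np.zeros(outcomes.shape, dtype=bool)
    sizes = np.zeros(outcomes.shape)
    for i, ep in enumerate(e_PC_grid):
        for j, ei in enumerate(e_IN_grid):
            r = pulse_experiment(p, start, ep, ei, settle_time=settle_time,
                                 dt=dt, fps=fps)
            outcomes[i, j] = r.outcome
            flags[i, j] = r.simnb
            sizes[i, j] = r.simnb_size
    return TransitionScan(e_PC_grid, e_IN_grid, outcomes, flags, sizes)


# ---------------------------------------------------------------------------
# internal deadline

@dataclass
class DeadlineResult:
    deadline: float | None       # s after the silencing pulse onset
    ipis: np.ndarray
    outcomes: list[str]
    simnb_sizes: np.ndarray
    ux_glut: np.ndarray          # u·x of glutamatergic synapses at probe time
    ux_gaba: np.ndarray


def deadline_scan(p: StpRnnParams, silencing: tuple[float, float] = (0.25, 1.0),
                  probe: tuple[float, float] = (0.25, 0.25),
                  ipi_range: tuple[float, float] = (0.1, 3.0),
                  coarse_step: float = 0.2, tol: float = 0.005,
                  pulse_duration: float = 0.020, settle_time: float = 20.0,
                  dt: float = 2e-4) -> DeadlineResult:
    """Latest inter-pulse interval at which a probe pulse still restores the
    active state after silencing, refined by bisection.

    The network starts at the active fixed point, is silenced by the
    ``silencing`` pulse (verified to converge to the silent state), and the
    ``probe`` pulse is applied at a variable delay measured from the
    silencing pulse onset. The boundary between 'to_active' and 'to_silent'
    probes is bisected to ±``tol`` seconds.
    """
    fps = spontaneous_fixed_points(p)
    if "active" not in fps or "silent" not in fps:
        raise ValueError("model is not bi-stable; deadline undefined")
    # verify that the silencing pulse silences
    check = pulse_experiment(p, "active", *silencing, settle_time=settle_time,
                             dt=dt, fps=fps)
    if check.outcome != "to_silent":
        raise ValueError("silencing pulse does not silence the network")
    # trajectory from the silencing pulse onset, cached for state snapshots
    s = fps["active"].state
    n_pulse = int(round(pulse_duration / dt))
    for _ in range(n_pulse):
        s = _sanitize(_rk4_step(s, p, silencing[0], silencing[1], dt), p)
    n_free = int(round(ipi_range[1] / dt))
    snapshots = [None] * n_pulse + [s]
    for _ in range(n_free - n_pulse):
        s = _sanitize(_rk4_step(s, p, 0.0, 0.0, dt), p)
        snapshots.append(s)

    def probe_at(ipi: float) -> PulseOutcome:
        idx = int(round(ipi / dt))
        if idx < n_pulse:
            raise ValueError("probe would overlap the silencing pulse")
        return pulse_experiment(p, initial_state=snapshots[idx],
                                e_PC=probe[0], e_IN=probe[1],
                                pulse_duration=pulse_duration,
                                settle_time=settle_time, dt=dt, fps=fps)

    ipis = np.arange(ipi_range[0], ipi_range[1] + 1e-12, coarse_step)
    outcomes, sizes, uxg, uxi = [], [], [], []
    for ipi in ipis:
        r = probe_at(ipi)
        outcomes.append(r.outcome)
        sizes.append(r.simnb_size)
        st = snapshots[int(round(ipi / dt))]
        uxg.append(st[6] * st[2])    # u_PP · x_PP
        uxi.append(st[9] * st[5])    # u_II · x_II
    success = [i for i, o in enumerate(outcomes) if o == "to_active"]
    if not success:
        return DeadlineResult(None, ipis, outcomes, np.array(sizes),
                              np.array(uxg), np.array(uxi))
    lo = ipis[success[-1]]
    hi = ipis[success[-1] + 1] if success[-1] + 1 < len(ipis) else ipi_range[1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if probe_at(mid).outcome == "to_active":
            lo = mid
        else:
            hi = mid
    return DeadlineResult(float(0.5 * (lo + hi)), ipis, outcomes,
                          np.array(sizes), np.array(uxg), np.array(uxi))


# ---------------------------------------------------------------------------
# parameter-scaling experiments

def scaling_experiment(p: StpRnnParams, target: str, scales,
                       regime_resolution: int = 101,
                       probe: tuple[float, float] = (0.25, 0.25),
                       settle_time: float = 8.0, dt: float = 2e-4) -> list[dict]:
    """Scale a synaptic efficacy and report regime areas, the maximal
    pyramidal-rate extent of the ISN domain, and the simNB size of a
    standard rest-state probe pulse.
    """
    if target not in ("J_I", "J_P"):
        raise ValueError("target must be 'J_I' or 'J_P'")
    out = []
    for scale in scales:
        q = replace(p, **{target: getattr(p, target) * float(scale)})
        rm = regime_map(q, resolution=regime_resolution)
        fps = spontaneous_fixed_points(q)
        size = float("nan")
        if "silent" in fps:
            r = pulse_experiment(q, "silent", *probe, settle_time=settle_time,
                                 dt=dt, fps=fps)
            size = r.simnb_size
        out.append({"scale": float(scale), "params": q,
                    "areas": rm.areas, "isn_ap_range": rm.isn_ap_range,
                    "simnb_size": size})
    return out
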