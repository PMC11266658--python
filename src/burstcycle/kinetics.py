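"""Exact dwell-time densities and nonequilibrium thermodynamics of promoter-state models.

A promoter is modelled as a continuous-time Markov chain over a handful of
*microstates*.  The observer cannot distinguish all of them: microstates are
lumped into observable *mesostates* (ON / OFF).  The time the chain dwells in
a mesostate before leaving it follows a phase-type distribution whose density
is a sum of exponentials,

    f(t) = sum_k c_k exp(lambda_k t),        lambda_k < 0,

with exactly two terms for a two-microstate mesostate (a biexponential).  A
density with f(0) = 0 is called *maximally peaked*; by Tu's theorem a
reversible (detailed-balanced) stationary process can only produce monotone
dwell densities, so a peaked density is a fingerprint of broken detailed
balance.

The three-state *clock model* (two ON microstates 1, 2 and one OFF
microstate 3; forward cycle 3 -> 1 -> 2 -> 3, an internal reverse edge
2 -> 1, and a single reverse rate ``alpha`` on both anticlockwise edges
1 -> 3 and 3 -> 2) interpolates between maximal irreversibility
(``alpha = 0``) and equilibrium (``alpha = alpha_eq``).  For this single
cycle the Schnakenberg entropy-production rate reduces to

    sigma = J+ * Delta_s,    Delta_s = 2 k_B ln(alpha_eq / alpha),
    J+ = w13 p3 - w31 p1,    alpha_eq = sqrt(w32 w21 w13 / w12),

where ``p`` is the stationary distribution and k_B = 1 internally.

Rate-index convention: ``rate(i, j)`` is the rate FROM state ``j`` TO state
``i``, so the formulas above read literally (w13 is the rate 3 -> 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RateGraph",
    "ClockModel",
    "SpectralDensity",
    "PeakClass",
    "ThermoSummary",
    "stationary_distribution",
    "mesostate_dwell_density",
    "density_eval",
    "classify_density",
    "alpha_eq",
    "entropy_per_cycle",
    "cycle_current",
    "entropy_rate",
    "is_detailed_balanced",
    "thermo_summary",
    "sample_mesostate_dwells",
    "graph_to_json",
    "graph_from_json",
]

#: relative tolerance on f(0) (against the density maximum) below which a
#: density counts as maximally peaked.
TOL_F0 = 1e-6
#: tolerance on negative spectral coefficients below which a density still
#: counts as monotone.
TOL_C = 1e-9
#: default relative tolerance for the detailed-balance cycle condition.
TOL_DB = 1e-9


class ConnectivityError(ValueError):
    """The graph restricted to positive rates is not strongly connected."""


class AbsorbingMesostateError(ValueError):
    """The mesostate has no exit transition with positive rate."""


@dataclass(frozen=True)
class RateGraph:
    """Continuous-time Markov chain with a mesostate partition.

    Parameters
    ----------
    rates :
        ``(n, n)`` array with ``rates[i, j]`` the transition rate from state
        ``j`` to state ``i`` in 1/s.  The diagonal is ignored (the generator
        diagonal is derived as the negative sum of outgoing rates).
    mesostates :
        length-``n`` sequence of labels (e.g. ``"ON"``/``"OFF"``), one per
        state.
    """

    rates: np.ndarray
    mesostates: tuple

    def __init__(self, rates, mesostates):
        rates = np.asarray(rates, dtype=float)
        if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
            raise ValueError("rates must be a square matrix")
        if rates.shape[0] < 1:
            raise ValueError("at least one state required")
        off = rates[~np.eye(rates.shape[0], dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        rates = rates.copy()
        np.fill_diagonal(rates, 0.0)
        mesostates = tuple(mesostates)
        if len(mesostates) != rates.shape[0]:
            raise ValueError("one mesostate label per state required")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "mesostates", mesostates)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    def rate(self, i: int, j: int) -> float:
        """Rate from state ``j`` to state ``i`` (0-based indices)."""
        return float(self.rates[i, j])

    def generator(self) -> np.ndarray:
        """Generator matrix ``G`` with ``dp/dt = G p`` (columns sum to 0)."""
        g = self.rates.copy()
        np.fill_diagonal(g, 0.0)
        np.fill_diagonal(g, -g.sum(axis=0))
        return g

    def states_of(self, label) -> np.ndarray:
        idx = np.array([k for k, m in enumerate(self.mesostates) if m == label])
        if idx.size == 0:
            raise ValueError(f"no state carries mesostate label {label!r}")
        return idx

    def labels(self) -> tuple:
        seen = []
        for m in self.mesostates:
            if m not in seen:
                seen.append(m)
        return tuple(seen)


@dataclass(frozen=True)
class ClockModel:
    """Three-state promoter clock (ON microstates 1, 2; OFF microstate 3).

    Forward cycle 3 -> 1 -> 2 -> 3 with rates ``w13``, ``w21``, ``w32``; an
    internal ON reverse edge 2 -> 1 with rate ``w12``; and the reverse rate
    ``alpha`` assigned to both anticlockwise edges 1 -> 3 and 3 -> 2, so the
    detailed-balance cycle condition reads ``w32 w21 w13 = alpha**2 w12``.
    All rates in 1/s.
    """

    w21: float
    w32: float
    w13: float
    w12: float
    alpha: float = 0.0

    def __post_init__(self):
        for name in ("w21", "w32", "w13", "w12"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def w31(self) -> float:
        """Rate 1 -> 3 (= alpha by the clock convention)."""
        return self.alpha

    @property
    def w23(self) -> float:
        """Rate 3 -> 2 (= alpha by the clock convention)."""
        return self.alpha

    def to_rate_graph(self) -> RateGraph:
        w = np.zeros((3, 3))
        w[1, 0] = self.w21   # 1 -> 2
        w[2, 1] = self.w32   # 2 -> 3
        w[0, 2] = self.w13   # 3 -> 1
        w[0, 1] = self.w12   # 2 -> 1
        w[2, 0] = self.alpha  # 1 -> 3
        w[1, 2] = self.alpha  # 3 -> 2
        return RateGraph(w, ("ON", "ON", "OFF"))


@dataclass
class SpectralDensity:
    """Phase-type dwell density in spectral form, f(t) = sum_k c_k e^{lambda_k t}.

    Exponents are sorted by decreasing magnitude (|lambda_1| >= |lambda_2|).
    For a defective (non-diagonalisable) two-state sub-generator the density
    takes the degenerate form ``(c + d t) e^{lambda t}``; then ``degenerate``
    is True and ``linear_coefficient`` holds ``d``.
    """

    coefficients: np.ndarray
    exponents: np.ndarray
    entry_distribution: np.ndarray
    degenerate: bool = False
    linear_coefficient: float = 0.0

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))
        self.exponents = np.atleast_1d(np.asarray(self.exponents, float))
        self.entry_distribution = np.asarray(self.entry_distribution, float)
        if np.any(self.exponents >= 0):
            raise ValueError("exponents must be strictly negative")
        order = np.argsort(-np.abs(self.exponents), kind="stable")
        self.exponents = self.exponents[order]
        self.coefficients = self.coefficients[order]

    def density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        e = np.exp(np.multiply.outer(t, self.exponents))
        f = e @ self.coefficients
        if self.degenerate:
            f = f + self.linear_coefficient * t * np.exp(self.exponents[0] * t)
        return f

    def survival(self, t) -> np.ndarray:
        """P(T > t), from the same expansion with coefficients c_k/(-lambda_k)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        lam = self.exponents
        coef = self.coefficients / (-lam)
        s = np.exp(np.multiply.outer(t, lam)) @ coef
        if self.degenerate:
            d, l0 = self.linear_coefficient, self.exponents[0]
            # integral of d*u*e^{l0 u} from t to inf
            s = s + d * np.exp(l0 * t) * (t / (-l0) + 1.0 / l0**2)
        return s

    def mean(self) -> float:
        m = float(np.sum(self.coefficients / self.exponents**2))
        if self.degenerate:
            m += self.linear_coefficient * 2.0 / (-self.exponents[0]) ** 3
        return m

    def normalization(self) -> float:
        """Integral of the density over [0, inf); 1 for a proper density."""
        n = float(np.sum(self.coefficients / (-self.exponents)))
        if self.degenerate:
            n += self.linear_coefficient / self.exponents[0] ** 2
        return n

    def time_horizon(self) -> float:
        """A grid horizon covering essentially all mass (several slow lifetimes)."""
        return 10.0 / np.abs(self.exponents).min()


@dataclass(frozen=True)
class PeakClass:
    """Peakedness class of a dwell density: monotone / peaked / maximally_peaked."""

    label: str
    f0: float


@dataclass(frozen=True)
class ThermoSummary:
    """Single-cycle steady-state thermodynamics of a clock model (k_B = 1)."""

    alpha_eq: float
    delta_s_cycle: float
    current_plus: float
    sigma: float
    stationary_p: np.ndarray


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_strongly_connected(w: np.ndarray) -> None:
    adj = (w > 0).astype(int).T  # adj[j, i]: edge j -> i
    n, _ = connected_components(adj, directed=True, connection="strong")
    if n != 1:
        raise ConnectivityError(
            "graph restricted to positive rates is not strongly connected"
        )


def stationary_distribution(g: RateGraph) -> np.ndarray:
    """Steady-state probabilities ``p`` with ``G p = 0`` and ``sum(p) = 1``."""
    _check_strongly_connected(g.rates)
    gen = g.generator()
    n = g.n_states
    a = np.vstack([gen, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _mesostate_parts(g: RateGraph, label):
    inside = g.states_of(label)
    outside = np.array([k for k in range(g.n_states) if k not in set(inside)])
    return inside, outside


def _entry_distribution(g: RateGraph, inside, outside) -> np.ndarray:
    """Stationary-flux weighting of the entry transitions into the mesostate."""
    p = stationary_distribution(g)
    flux = g.rates[np.ix_(inside, outside)] @ p[outside]
    total = flux.sum()
    if total <= 0:
        raise AbsorbingMesostateError("mesostate is never entered at steady state")
    return flux / total


def mesostate_dwell_density(g: RateGraph, label) -> SpectralDensity:
    """Exact phase-type density of a sojourn in the mesostate ``label``.

    The sojourn starts from the stationary-flux entry distribution over the
    mesostate's member states, evolves under the sub-generator restricted to
    the mesostate, and ends at the first exit.  The density is the spectral
    expansion of ``r^T exp(A t) pi`` (entry ``pi``, exit rates ``r``).
    """
    inside, outside = _mesostate_parts(g, label)
    if outside.size == 0:
        raise AbsorbingMesostateError("mesostate covers the whole chain")
    gen = g.generator()
    sub = gen[np.ix_(inside, inside)]
    exit_rates = g.rates[np.ix_(outside, inside)].sum(axis=0)
    if exit_rates.sum() <= 0:
        raise AbsorbingMesostateError(f"mesostate {label!r} has no exit rate")
    pi = _entry_distribution(g, inside, outside)

    lam, vec = np.linalg.eig(sub)
    if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-300):
        raise ValueError("complex dwell spectrum not supported")
    lam = lam.real
    scale = np.max(np.abs(lam))

    if inside.size == 2 and abs(lam[0] - lam[1]) < 1e-9 * scale:
        # defective 2x2 sub-generator: Jordan form gives (c + d t) e^{l t}
        l0 = lam.mean()
        c = float(exit_rates @ pi)
        d = float(exit_rates @ (sub - l0 * np.eye(2)) @ pi)
        return SpectralDensity(
            coefficients=[c],
            exponents=[l0],
            entry_distribution=pi,
            degenerate=abs(d) > 1e-12 * scale**2,
            linear_coefficient=d,
        )

    vec = vec.real
    try:
        left = np.linalg.inv(vec)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defective n>2
        raise ValueError("defective sub-generator with >2 states") from err
    coef = (exit_rates @ vec) * (left @ pi)
    return SpectralDensity(coefficients=coef, exponents=lam, entry_distribution=pi)


def density_eval(d: SpectralDensity, t) -> np.ndarray:
    """Evaluate the dwell density on a time grid (t >= 0, in s)."""
    return d.density(t)


def classify_density(
    d: SpectralDensity, tol_f0: float = TOL_F0, tol_c: float = TOL_C
) -> PeakClass:
    """Classify a dwell density as monotone, peaked, or maximally peaked.

    Maximally peaked means ``|f(0)| <= tol_f0 * max f``; monotone means all
    spectral coefficients are nonnegative (within ``tol_c`` relative to the
    largest coefficient), which implies ``f`` decreases from ``t = 0``.
    """
    f0 = float(d.density(0.0))
    t = np.linspace(0.0, d.time_horizon(), 2048)
    fmax = float(d.density(t).max())
    if fmax <= 0:
        return PeakClass("monotone", f0)
    if abs(f0) <= tol_f0 * fmax:
        return PeakClass("maximally_peaked", f0)
    cscale = np.max(np.abs(d.coefficients))
    if not d.degenerate and np.all(d.coefficients >= -tol_c * cscale):
        return PeakClass("monotone", f0)
    if d.degenerate and d.linear_coefficient <= 0 and np.all(
        d.coefficients >= -tol_c * cscale
    ):
        return PeakClass("monotone", f0)
    return PeakClass("peaked", f0)


def alpha_eq(m: ClockModel) -> float:
    """Equilibrium reverse rate, alpha_eq = sqrt(w32 w21 w13 / w12)."""
    return float(np.sqrt(m.w32 * m.w21 * m.w13 / m.w12))


def entropy_per_cycle(m: ClockModel) -> float:
    """Entropy produced per clockwise cycle, Delta_s = 2 ln(alpha_eq/alpha), in k_B.

    Diverges as alpha -> 0: excluding the reverse transitions entirely would
    require infinite entropy production.
    """
    if m.alpha == 0:
        warnings.warn(
            "alpha = 0: entropy per cycle is infinite (reverse transitions "
            "fully excluded)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return 2.0 * float(np.log(alpha_eq(m) / m.alpha))


def cycle_current(m: ClockModel) -> float:
    """Net clockwise probability current, J+ = w13 p3 - w31 p1, in 1/s."""
    p = stationary_distribution(m.to_rate_graph())
    return float(m.w13 * p[2] - m.w31 * p[0])


def entropy_rate(m: ClockModel) -> float:
    """Schnakenberg entropy-production rate, sigma = J+ * Delta_s, in k_B/s."""
    if m.alpha == 0:
        warnings.warn(
            "alpha = 0: entropy production rate is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return cycle_current(m) * entropy_per_cycle(m)


def is_detailed_balanced(m: ClockModel, tol: float = TOL_DB) -> bool:
    """Cycle condition for detailed balance: w32 w21 w13 = alpha**2 w12."""
    fwd = m.w32 * m.w21 * m.w13
    return abs(fwd - m.alpha**2 * m.w12) <= tol * fwd


def thermo_summary(m: ClockModel) -> ThermoSummary:
    """Bundle (alpha_eq, Delta_s, J+, sigma, p) for one clock model."""
    p = stationary_distribution(m.to_rate_graph())
    jplus = float(m.w13 * p[2] - m.w31 * p[0])
    if m.alpha == 0:
        ds = float("inf")
        sig = float("inf")
    else:
        ds = 2.0 * float(np.log(alpha_eq(m) / m.alpha))
        sig = jplus * ds
    return ThermoSummary(alpha_eq(m), ds, jplus, sig, p)


# ---------------------------------------------------------------------------
# stochastic dwell sampling (oracle counterpart of the spectral form)
# ---------------------------------------------------------------------------

def sample_mesostate_dwells(g: RateGraph, label, n: int, rng) -> np.ndarray:
    """Sample ``n`` mesostate sojourn times by exact jump-chain simulation.

    Entry states are drawn from the stationary-flux entry distribution; the
    jump chain inside the mesostate is then simulated (exponential sojourn in
    each microstate, next transition proportional to outgoing rates) until the
    first exit, exactly as a full Gillespie run would produce them.
    Vectorised across samples.
    """
    rng = np.random.default_rng(rng)
    inside, outside = _mesostate_parts(g, label)
    pi = _entry_distribution(g, inside, outside)
    k = inside.size
    w_in = g.rates[np.ix_(inside, inside)]       # within-mesostate rates
    w_out = g.rates[np.ix_(outside, inside)].sum(axis=0)  # exit rate per state
    total = w_in.sum(axis=0) + w_out             # total leave-state rate
    if np.any(total <= 0):
        raise AbsorbingMesostateError("absorbing microstate inside mesostate")
    p_exit = w_out / total
    # next-state distribution within the mesostate, conditional on staying
    with np.errstate(invalid="ignore", divide="ignore"):
        p_next = np.where(
            (total - w_out) > 0, w_in / np.maximum(total - w_out, 1e-300), 0.0
        )

    state = rng.choice(k, size=n, p=pi)
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    # expected number of internal jumps is O(1); cap generously
    for _ in range(10_000):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        s = state[idx]
        t[idx] += rng.exponential(1.0 / total[s])
        exits = rng.random(idx.size) < p_exit[s]
        active[idx[exits]] = False
        stay = idx[~exits]
        if stay.size:
            u = rng.random(stay.size)
            cdf = np.cumsum(p_next[:, state[stay]], axis=0)
            state[stay] = (u[:, None] > cdf.T).sum(axis=1)
    else:  # pragma: no cover
        raise RuntimeError("dwell sampling did not terminate")
    return t


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def graph_to_json(g: RateGraph) -> str:
    """Serialize to ``{"states": N, "rates": [[i, j, w]...], "mesostates": {...}}``.

    Indices are 1-based in the document (state 1 is index 0 in memory) and
    ``[i, j, w]`` means rate ``w`` from ``j`` to ``i``.
    """
    rates = [
        [i + 1, j + 1, float(g.rates[i, j])]
        for i in range(g.n_states)
        for j in range(g.n_states)
        if i != j and g.rates[i, j] > 0
    ]
    meso = {}
    for k, label in enumerate(g.mesostates):
        meso.setdefault(str(label), []).append(k + 1)
    return json.dumps({"states": g.n_states, "rates": rates, "mesostates": meso})


def graph_from_json(doc: str) -> RateGraph:
    """Inverse of :func:`graph_to_json`; also accepts the ``{"clock": ...}``
    shorthand with keys w21, w32, w13, w12, alpha."""
    obj = json.loads(doc) if isinstance(doc, str) else doc
    if "clock" in obj:
        c = obj["clock"]
        return ClockModel(
            w21=c["w21"], w32=c["w32"], w13=c["w13"], w12=c["w12"],
            alpha=c.get("alpha", 0.0),
        ).to_rate_graph()
    n = int(obj["states"])
    w = np.zeros((n, n))
    for i, j, val in obj["rates"]:
        w[int(i) - 1, int(j) - 1] = float(val)
    labels = [None] * n
    for label, members in obj["mesostates"].items():
        for s in members:
            labels[int(s) - 1] = label
    if any(l is None for l in labels):
        raise ValueError("mesostate partition does not cover all states")
    return RateGraph(w, labels)
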