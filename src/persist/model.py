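"""Steady-state / ODE model of cleavage-regulated transcripts and circuits.

Each engineered transcript is modelled as a two-species scheme:

* ``U`` — the uncut transcript, produced at ``alpha * copies`` and lost to
  baseline decay ``d0``, to degradation-motif decay ``d_fast(n)`` (when an
  ON motif with ``n`` wt1 repeats is present), to ON-motif cleavage
  (``k_on``, which converts U into S) and to 5'-site cleavage (``k_off``,
  which destroys the transcript).
* ``S`` — the cleaved, stabilizer-protected species; exists only when the
  transcript carries an ON motif.  Produced from U at ``k_on``, lost at the
  slow decay ``d_slow`` and to 5'-site cleavage (a 5' cut decapitates the
  stabilized species just as it does the uncut one).

Both species are translated; proteins decay at ``dp`` (``dp_pest`` for
PEST-tagged payloads).  Cleavage of a site by an enzyme at level ``E``
proceeds at ``activity * vmax_rel * vmax * E / (K + E)`` — saturating in
the enzyme, scaled by the cross-reactivity fraction.  Payload proteins that
are themselves endoRNases close the loop by driving downstream cleavage.

For acyclic circuits the steady state has a closed form (solved transcript
by transcript in dependency order); circuits with feedback are integrated
as ODEs.  The two routes agree to the integration tolerance and are tested
against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .registry import Registry, EndoRNase, CrossReactivityMatrix

__all__ = [
    "ModelParams", "OnMotif", "Transcript", "CircuitSpec", "CircuitState",
    "FixedPoint", "FixedPointSet", "cleavage_rate", "transcript_output",
    "steady_state", "simulate", "dose_response", "find_fixed_points",
    "deg_ladder",
]

MAX_REPEATS = 30


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters (rates in 1/h, levels in arbitrary units)."""

    d0: float = 0.1
    d_slow: float = 0.05
    kp: float = 1.0
    dp: float = 0.1
    dp_pest: float = 0.5
    vmax: float = 310.0
    K: float = 1000.0
    k_rnasep: float = 10.805
    d_fast_knots: tuple[tuple[float, float], ...] = (
        (0, 0.0), (4, 0.3), (8, 1.1), (16, 6.0), (30, 35.0))
    alpha_default: float = 1.0
    t_end: float = 48.0

    def __post_init__(self):
        if self.dp_pest <= self.dp:
            raise ValueError("dp_pest must exceed dp")
        knots = sorted(self.d_fast_knots)
        vals = [v for _, v in knots]
        if vals != sorted(vals) or vals[0] != 0.0 or knots[0][0] != 0:
            raise ValueError("d_fast knots must be nondecreasing with d_fast(0)=0")
        for name in ("d0", "d_slow", "kp", "dp", "dp_pest", "vmax", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def d_fast(self, n: int | float) -> float:
        """Decay added by ``n`` degradation-motif repeats (piecewise linear)."""
        if not 0 <= n <= MAX_REPEATS:
            raise ValueError(f"repeat count {n} outside [0, {MAX_REPEATS}]")
        xs, ys = zip(*sorted(self.d_fast_knots))
        return float(np.interp(n, xs, ys))

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ModelParams":
        m = cfg["model"]
        knots = tuple(sorted((float(k), float(v)) for k, v in m["d_fast_knots"].items()))
        return cls(d0=m["d0"], d_slow=m["d_slow"], kp=m["kp"], dp=m["dp"],
                   dp_pest=m["dp_pest"], vmax=m["vmax"],
                   K=m.get("K", 1000.0), k_rnasep=m["k_rnasep"],
                   d_fast_knots=knots, alpha_default=m["alpha_default"],
                   t_end=m["t_end"])


@dataclass(frozen=True)
class OnMotif:
    """3' ON cassette: stabilizer, cleavage sites, degradation repeats."""

    sites: tuple[str, ...] = ()
    deg_repeats: int = 0
    rnasep_site: bool = False

    def __post_init__(self):
        if not 0 <= self.deg_repeats <= MAX_REPEATS:
            raise ValueError(f"deg_repeats {self.deg_repeats} outside [0, {MAX_REPEATS}]")


@dataclass(frozen=True)
class Transcript:
    name: str
    payload: str
    alpha: float = 1.0
    five_prime_sites: tuple[str, ...] = ()
    on_motif: OnMotif | None = None
    pest: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        object.__setattr__(self, "five_prime_sites", tuple(self.five_prime_sites))


@dataclass
class CircuitSpec:
    """A set of transcripts with per-plasmid copy numbers and a registry."""

    transcripts: list[Transcript]
    copies: dict[str, float]
    registry: Registry

    def __post_init__(self):
        names = [t.name for t in self.transcripts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate transcript names")
        for t in self.transcripts:
            for sid in list(t.five_prime_sites) + (list(t.on_motif.sites) if t.on_motif else []):
                self.registry.site(sid)  # raises on unknown id
        for n, c in self.copies.items():
            if c < 0:
                raise ValueError(f"negative copy number for {n}")

    def with_copies(self, **overrides: float) -> "CircuitSpec":
        new = dict(self.copies)
        new.update(overrides)
        return CircuitSpec(self.transcripts, new, self.registry)

    @property
    def payloads(self) -> list[str]:
        seen: list[str] = []
        for t in self.transcripts:
            if t.payload not in seen:
                seen.append(t.payload)
        return seen

    def enzyme_payloads(self) -> list[str]:
        enz = {e.name for e in self.registry.enzymes}
        return [p for p in self.payloads if p in enz]

    def is_acyclic(self) -> bool:
        """True when no enzyme payload feeds back onto its own production chain."""
        prod = {}  # payload -> transcripts producing it
        for t in self.transcripts:
            prod.setdefault(t.payload, []).append(t)
        enz = set(self.enzyme_payloads())
        deps: dict[str, set[str]] = {}
        for t in self.transcripts:
            req = set()
            for sid in self._all_sites(t):
                for e in self.registry.enzymes:
                    if e.name in enz and self.registry.matrix.activity(e.name, sid) > 0:
                        req.add(e.name)
            deps[t.name] = req
        # DFS for cycles over payload->transcript->payload edges
        color: dict[str, int] = {}

        def visit(p: str) -> bool:
            color[p] = 1
            for t in prod.get(p, []):
                for q in deps[t.name]:
                    c = color.get(q, 0)
                    if c == 1 or (c == 0 and visit(q)):
                        return True
            color[p] = 2
            return False

        return not any(visit(p) for p in enz if color.get(p, 0) == 0)

    @staticmethod
    def _all_sites(t: Transcript) -> list[str]:
        return list(t.five_prime_sites) + (list(t.on_motif.sites) if t.on_motif else [])


@dataclass
class CircuitState:
    """Levels at one time point (all in arbitrary units, nonnegative)."""

    uncut: dict[str, float]
    stabilized: dict[str, float]
    proteins: dict[str, float]

    def output(self, payload: str) -> float:
        return self.proteins[payload]


def cleavage_rate(enzyme_level: float, enzyme: EndoRNase, site,
                  matrix: CrossReactivityMatrix, params: ModelParams) -> float:
    """Saturating cleavage rate of one enzyme acting on one site (1/h)."""
    if np.any(np.asarray(enzyme_level) < 0):
        raise ValueError("enzyme level must be nonnegative")
    a = matrix.activity(enzyme.name, site if isinstance(site, str) else site.site_id)
    if a == 0.0:
        return 0.0 * np.asarray(enzyme_level) if np.ndim(enzyme_level) else 0.0
    return a * enzyme.vmax_rel * params.vmax * enzyme_level / (enzyme.K + enzyme_level)


def _site_rate(circuit: CircuitSpec, sid: str, enzyme_levels: Mapping[str, float],
               params: ModelParams):
    """Total cleavage rate at a site from every enzyme present."""
    total = 0.0
    for name, level in enzyme_levels.items():
        e = circuit.registry.enzyme(name)
        total = total + cleavage_rate(level, e, sid, circuit.registry.matrix, params)
    return total


def _transcript_rates(circuit: CircuitSpec, t: Transcript,
                      enzyme_levels: Mapping[str, float], params: ModelParams):
    """(k_on, k_off, d_deg) for one transcript given enzyme levels."""
    k_off = 0.0
    for sid in t.five_prime_sites:
        k_off = k_off + _site_rate(circuit, sid, enzyme_levels, params)
    k_on = 0.0
    d_deg = 0.0
    if t.on_motif is not None:
        for sid in t.on_motif.sites:
            k_on = k_on + _site_rate(circuit, sid, enzyme_levels, params)
        if t.on_motif.rnasep_site:
            k_on = k_on + params.k_rnasep
        d_deg = params.d_fast(t.on_motif.deg_repeats)
    return k_on, k_off, d_deg


def _transcript_steady(circuit: CircuitSpec, t: Transcript,
                       enzyme_levels: Mapping[str, float], params: ModelParams,
                       copies: float):
    k_on, k_off, d_deg = _transcript_rates(circuit, t, enzyme_levels, params)
    U = t.alpha * copies / (params.d0 + d_deg + k_on + k_off)
    S = k_on * U / (params.d_slow + k_off) if t.on_motif is not None else 0.0
    return U, S


def transcript_output(t: Transcript, enzyme_levels: Mapping[str, float],
                      params: ModelParams, copies: float,
                      registry: Registry) -> float:
    """Closed-form steady-state protein production flux kp*(U+S) (a.u./h)."""
    circuit = CircuitSpec([t], {t.name: copies}, registry)
    U, S = _transcript_steady(circuit, t, enzyme_levels, params, copies)
    return params.kp * (U + S)


# ---------------------------------------------------------------------------
# steady state & simulation


def _enzyme_fixed_point_map(circuit: CircuitSpec, params: ModelParams):
    """g(E) mapping enzyme-protein levels to their implied steady levels."""
    enz_names = circuit.enzyme_payloads()

    def g(E: np.ndarray) -> np.ndarray:
        levels = {n: max(float(v), 0.0) for n, v in zip(enz_names, E)}
        flux = dict.fromkeys(enz_names, 0.0)
        for t in circuit.transcripts:
            if t.payload in flux:
                U, S = _transcript_steady(circuit, t, levels, params,
                                          circuit.copies.get(t.name, 0.0))
                flux[t.payload] += params.kp * (U + S)
        out = np.empty(len(enz_names))
        for i, n in enumerate(enz_names):
            dp = params.dp_pest if any(
                t.pest and t.payload == n for t in circuit.transcripts) else params.dp
            out[i] = flux[n] / dp
        return out

    return enz_names, g


def steady_state(circuit: CircuitSpec, params: ModelParams,
                 enzyme_guess: Mapping[str, float] | None = None) -> CircuitState:
    """Steady state of a circuit.

    Acyclic circuits are solved exactly by damped fixed-point iteration on
    enzyme levels (which converges in ``depth`` steps because the dependency
    graph is a DAG); cyclic circuits are refined with a root finder from the
    supplied or default guess.
    """
    enz_names, g = _enzyme_fixed_point_map(circuit, params)
    E = np.array([enzyme_guess.get(n, 0.0) if enzyme_guess else 0.0
                  for n in enz_names])
    if circuit.is_acyclic():
        for _ in range(len(circuit.transcripts) + 2):
            E = g(E)
    else:
        sol = root(lambda x: g(np.maximum(x, 0.0)) - np.maximum(x, 0.0), E,
                   method="hybr", tol=1e-12)
        E = np.maximum(sol.x, 0.0)
    levels = dict(zip(enz_names, E))
    return _state_from_enzymes(circuit, params, levels)


def _state_from_enzymes(circuit: CircuitSpec, params: ModelParams,
                        levels: Mapping[str, float]) -> CircuitState:
    uncut, stab, prot = {}, {}, {}
    flux: dict[str, float] = {}
    pest_payload: dict[str, bool] = {}
    for t in circuit.transcripts:
        U, S = _transcript_steady(circuit, t, levels, params,
                                  circuit.copies.get(t.name, 0.0))
        uncut[t.name], stab[t.name] = U, S
        flux[t.payload] = flux.get(t.payload, 0.0) + params.kp * (U + S)
        pest_payload[t.payload] = pest_payload.get(t.payload, False) or t.pest
    for p, f in flux.items():
        dp = params.dp_pest if pest_payload[p] else params.dp
        prot[p] = f / dp
    return CircuitState(uncut, stab, prot)


def _species_layout(circuit: CircuitSpec):
    """Flat state layout: U per transcript, S per ON transcript, P per payload."""
    u_idx = {t.name: i for i, t in enumerate(circuit.transcripts)}
    s_names = [t.name for t in circuit.transcripts if t.on_motif is not None]
    s_idx = {n: len(u_idx) + i for i, n in enumerate(s_names)}
    payloads = circuit.payloads
    p_idx = {p: len(u_idx) + len(s_idx) + i for i, p in enumerate(payloads)}
    return u_idx, s_idx, p_idx


def _rhs(circuit: CircuitSpec, params: ModelParams):
    u_idx, s_idx, p_idx = _species_layout(circuit)
    enz = set(circuit.enzyme_payloads())
    pest_payload: dict[str, bool] = {}
    for t in circuit.transcripts:
        pest_payload[t.payload] = pest_payload.get(t.payload, False) or t.pest

    def rhs(_t, y):
        y = np.maximum(y, 0.0)
        levels = {p: y[p_idx[p]] for p in p_idx if p in enz}
        dy = np.zeros_like(y)
        for tr in circuit.transcripts:
            k_on, k_off, d_deg = _transcript_rates(circuit, tr, levels, params)
            U = y[u_idx[tr.name]]
            prod = tr.alpha * circuit.copies.get(tr.name, 0.0)
            dy[u_idx[tr.name]] = prod - (params.d0 + d_deg + k_on + k_off) * U
            total = U
            if tr.on_motif is not None:
                S = y[s_idx[tr.name]]
                dy[s_idx[tr.name]] = k_on * U - (params.d_slow + k_off) * S
                total = U + S
            dp = params.dp_pest if pest_payload[tr.payload] else params.dp
            dy[p_idx[tr.payload]] += params.kp * total
        for p, i in p_idx.items():
            dp = params.dp_pest if pest_payload[p] else params.dp
            dy[i] -= dp * y[i]
        return dy

    return rhs, (u_idx, s_idx, p_idx)


class IntegrationError(RuntimeError):
    pass


def simulate(circuit: CircuitSpec, params: ModelParams,
             t_end: float | None = None, x0: CircuitState | None = None,
             n_points: int = 50):
    """Integrate the circuit ODEs from ``x0`` (default: everything zero).

    Returns ``(times, states)`` where ``states`` is a list of
    :class:`CircuitState`, the last at ``t_end``.
    """
    t_end = params.t_end if t_end is None else t_end
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rhs, (u_idx, s_idx, p_idx) = _rhs(circuit, params)
    dim = len(u_idx) + len(s_idx) + len(p_idx)
    y0 = np.zeros(dim)
    if x0 is not None:
        for n, i in u_idx.items():
            y0[i] = x0.uncut.get(n, 0.0)
        for n, i in s_idx.items():
            y0[i] = x0.stabilized.get(n, 0.0)
        for p, i in p_idx.items():
            y0[i] = x0.proteins.get(p, 0.0)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-8,
                    atol=1e-10, t_eval=t_eval)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = "unknown"
        if sol.y.size and not np.all(np.isfinite(sol.y)):
            i = int(np.argwhere(~np.isfinite(sol.y))[0][0])
            names = list(u_idx) + list(s_idx) + list(p_idx)
            bad = names[i] if i < len(names) else "unknown"
        raise IntegrationError(f"integration failed (first non-finite species: {bad})")
    states = []
    for k in range(sol.y.shape[1]):
        y = np.maximum(sol.y[:, k], 0.0)
        states.append(CircuitState(
            {n: float(y[i]) for n, i in u_idx.items()},
            {n: float(y[i]) for n, i in s_idx.items()},
            {p: float(y[i]) for p, i in p_idx.items()}))
    return sol.t, states


def trajectory_frame(times, states):
    """Tidy (time, species, level) table for export."""
    import pandas as pd

    rows = []
    for t, st in zip(times, states):
        for n, v in st.uncut.items():
            rows.append((t, f"U:{n}", v))
        for n, v in st.stabilized.items():
            rows.append((t, f"S:{n}", v))
        for p, v in st.proteins.items():
            rows.append((t, f"P:{p}", v))
    return pd.DataFrame(rows, columns=["time", "species", "level"])


def dose_response(circuit: CircuitSpec, input_transcript: str,
                  copy_grid: Sequence[float], params: ModelParams,
                  output_payload: str | None = None):
    """Noiseless endpoint output versus input copy number.

    Returns a ``pandas.DataFrame`` with the input copies and every payload's
    steady-state level; ``output_payload`` selects the column reported as
    ``output``.
    """
    import pandas as pd

    if len(copy_grid) == 0:
        raise ValueError("copy grid must be nonempty")
    if any(c < 0 for c in copy_grid):
        raise ValueError("copy grid must be nonnegative")
    rows = []
    guess: Mapping[str, float] | None = None
    for c in copy_grid:
        st = steady_state(circuit.with_copies(**{input_transcript: float(c)}),
                          params, enzyme_guess=guess)
        guess = st.proteins
        rows.append({"copies": float(c), **{p: st.proteins[p] for p in circuit.payloads}})
    df = pd.DataFrame(rows)
    if output_payload is not None:
        df["output"] = df[output_payload]
    return df


# ---------------------------------------------------------------------------
# fixed points


@dataclass(frozen=True)
class FixedPoint:
    state: CircuitState
    stable: bool
    marginal: bool = False
    max_eig_real: float = float("nan")


@dataclass
class FixedPointSet:
    points: list[FixedPoint]
    n_starts: int
    tol: float

    @property
    def n_stable(self) -> int:
        return sum(p.stable for p in self.points)

    @property
    def n_unstable(self) -> int:
        return sum((not p.stable) and (not p.marginal) for p in self.points)


def _jacobian(rhs, y, eps=1e-6):
    n = len(y)
    J = np.empty((n, n))
    f0 = rhs(0.0, y)
    for j in range(n):
        h = eps * max(abs(y[j]), 1.0)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (rhs(0.0, yp) - f0) / h
    return J


def find_fixed_points(circuit: CircuitSpec, params: ModelParams,
                      n_starts: int = 32, seed: int = 0,
                      tol: float = 1e-4) -> FixedPointSet:
    """Multi-start root finding on the enzyme-level fixed-point equations.

    Starts combine a lattice over {0, K/10, K, 10K} per feedback enzyme
    with lognormal random starts; duplicates within relative ``tol`` are
    merged and stability is labelled from the full-system Jacobian.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be at least 8")
    enz_names, g = _enzyme_fixed_point_map(circuit, params)
    rng = np.random.default_rng(seed)
    dim = len(enz_names)
    if dim == 0:
        return FixedPointSet([FixedPoint(steady_state(circuit, params), True, False, -params.dp)],
                             n_starts, tol)
    Ks = np.array([circuit.registry.enzyme(n).K for n in enz_names])
    lattice_vals = [0.0, 0.1, 1.0, 10.0]
    starts = []
    for combo in np.stack(np.meshgrid(*[lattice_vals] * dim), -1).reshape(-1, dim):
        starts.append(combo * Ks)
    while len(starts) < max(n_starts, len(starts)):
        starts.append(Ks * rng.lognormal(0.0, 2.0, size=dim))
    starts = starts[: max(n_starts, 4 ** dim)]

    def F(x):
        xe = np.maximum(x, 0.0)
        return g(xe) - xe

    found: list[np.ndarray] = []
    residuals = []
    for s0 in starts:
        sol = root(F, np.asarray(s0, dtype=float), method="hybr", tol=1e-12)
        x = np.maximum(sol.x, 0.0)
        r = np.linalg.norm(F(x))
        residuals.append(r)
        if not sol.success and r > 1e-8 * (1 + np.linalg.norm(x)):
            continue
        if any(np.all(np.abs(x - y) <= tol * (1.0 + np.abs(y))) for y in found):
            continue
        found.append(x)
    if not found:
        raise RuntimeError(
            f"no fixed point converged from {len(starts)} starts; "
            f"residual norms: {np.round(sorted(residuals)[:5], 6)}")

    rhs, (u_idx, s_idx, p_idx) = _rhs(circuit, params)
    points = []
    for x in sorted(found, key=lambda v: tuple(v)):
        st = _state_from_enzymes(circuit, params, dict(zip(enz_names, x)))
        y = np.zeros(len(u_idx) + len(s_idx) + len(p_idx))
        for n, i in u_idx.items():
            y[i] = st.uncut[n]
        for n, i in s_idx.items():
            y[i] = st.stabilized[n]
        for p, i in p_idx.items():
            y[i] = st.proteins[p]
        lam = np.max(np.linalg.eigvals(_jacobian(rhs, y)).real)
        margin = 1e-9
        points.append(FixedPoint(st, stable=lam < -margin,
                                 marginal=abs(lam) <= margin, max_eig_real=float(lam)))
    return FixedPointSet(points, n_starts=len(starts), tol=tol)


# ---------------------------------------------------------------------------
# vectorized per-cell endpoints (poly-transfection rendering)


def _rates_many(circuit: CircuitSpec, t: Transcript, levels: dict, params: ModelParams):
    k_off = 0.0
    for sid in t.five_prime_sites:
        for name, E in levels.items():
            e = circuit.registry.enzyme(name)
            a = circuit.registry.matrix.activity(name, sid)
            if a > 0:
                k_off = k_off + a * e.vmax_rel * params.vmax * E / (e.K + E)
    k_on = 0.0
    d_deg = 0.0
    if t.on_motif is not None:
        for sid in t.on_motif.sites:
            for name, E in levels.items():
                e = circuit.registry.enzyme(name)
                a = circuit.registry.matrix.activity(name, sid)
                if a > 0:
                    k_on = k_on + a * e.vmax_rel * params.vmax * E / (e.K + E)
        if t.on_motif.rnasep_site:
            k_on = k_on + params.k_rnasep
        d_deg = params.d_fast(t.on_motif.deg_repeats)
    return k_on, k_off, d_deg


def _flux_many(circuit: CircuitSpec, copies: Mapping[str, np.ndarray],
               levels: dict, params: ModelParams) -> dict:
    """Per-payload protein production flux arrays given enzyme-level arrays."""
    flux: dict[str, np.ndarray | float] = {}
    for t in circuit.transcripts:
        k_on, k_off, d_deg = _rates_many(circuit, t, levels, params)
        c = copies.get(t.name, 0.0)
        U = t.alpha * c / (params.d0 + d_deg + k_on + k_off)
        total = U
        if t.on_motif is not None:
            total = U + k_on * U / (params.d_slow + k_off)
        flux[t.payload] = flux.get(t.payload, 0.0) + params.kp * total
    return flux


def _payload_dp(circuit: CircuitSpec, params: ModelParams) -> dict[str, float]:
    dp = {}
    for t in circuit.transcripts:
        pest = dp.get(t.payload) == params.dp_pest or t.pest
        dp[t.payload] = params.dp_pest if pest else params.dp
    return dp


def endpoint_many(circuit: CircuitSpec, copies: Mapping[str, np.ndarray],
                  params: ModelParams, t_end: float | None = None,
                  dt: float = 0.05) -> dict[str, np.ndarray]:
    """Per-cell payload levels at the endpoint for a copy-number table.

    Acyclic circuits are evaluated at their exact closed-form steady state
    (the 48-h endpoint is several protein half-lives out, and all reported
    statistics are ratios that the residual protein transient cancels from).
    Circuits with feedback are integrated per cell with mRNA species at
    quasi-steady state — mRNA relaxes on the 1/(d0+d_fast+cleavage) time
    scale, minutes against the hours-long protein scale — so only protein
    levels remain dynamic; integration is vectorized across cells (RK4,
    fixed step ``dt`` hours) from an all-zero initial condition, which is
    the post-transfection state.
    """
    t_end = params.t_end if t_end is None else t_end
    n = max(np.size(v) for v in copies.values()) if copies else 1
    enz_names = circuit.enzyme_payloads()
    dp = _payload_dp(circuit, params)
    if circuit.is_acyclic():
        levels = {e: np.zeros(n) for e in enz_names}
        for _ in range(len(circuit.transcripts) + 2):
            flux = _flux_many(circuit, copies, levels, params)
            levels = {e: flux[e] / dp[e] for e in enz_names}
        flux = _flux_many(circuit, copies, levels, params)
        return {p: np.broadcast_to(np.asarray(f / dp[p], dtype=float), (n,)).copy()
                for p, f in flux.items()}

    payloads = circuit.payloads
    P = {p: np.zeros(n) for p in payloads}

    def deriv(state):
        levels = {e: np.maximum(state[e], 0.0) for e in enz_names}
        flux = _flux_many(circuit, copies, levels, params)
        return {p: flux[p] - dp[p] * state[p] for p in payloads}

    steps = int(np.ceil(t_end / dt))
    h = t_end / steps
    for _ in range(steps):
        k1 = deriv(P)
        k2 = deriv({p: P[p] + 0.5 * h * k1[p] for p in payloads})
        k3 = deriv({p: P[p] + 0.5 * h * k2[p] for p in payloads})
        k4 = deriv({p: P[p] + h * k3[p] for p in payloads})
        P = {p: P[p] + h / 6.0 * (k1[p] + 2 * k2[p] + 2 * k3[p] + k4[p])
             for p in payloads}
    for p in payloads:
        if not np.all(np.isfinite(P[p])):
            bad = int(np.argwhere(~np.isfinite(P[p]))[0][0])
            raise IntegrationError(f"per-cell integration failed for payload {p}, cell {bad}")
    return {p: np.maximum(v, 0.0) for p, v in P.items()}


def deg_ladder(n_values: Iterable[int], params: ModelParams) -> dict[int, float]:
    """Fold-reduction in output per degradation-repeat count.

    ``fold(n) = (d0 + d_fast(n)) / d0`` — the steady-state output ratio of a
    plain reporter to one carrying ``n`` repeats (no stabilizer rescue, no
    enzyme).
    """
    return {int(n): (params.d0 + params.d_fast(n)) / params.d0 for n in n_values}
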