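"""Synthetic poly-transfection flow-cytometry data.

Transient poly-transfection delivers several independent DNA complexes;
each cell takes up a random dose of every complex, so one experiment
samples a wide grid of copy-number ratios.  The generator reproduces the
statistical structure that the downstream analysis relies on:

* per-complex zero-inflated lognormal uptake, with near-perfect
  correlation between plasmids co-delivered in one complex (that is what
  makes a constitutive marker track its complex's payload);
* steady-state protein output of the regulatory circuit at the 48-h
  endpoint, per cell;
* linear spectral bleed-through between fluorophores, lognormal
  autofluorescence and multiplicative measurement noise.

Doublets, scatter gating, detector saturation and acquisition drift are
deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CircuitSpec, ModelParams, endpoint_many

CHANNELS = ("tagBFP", "EYFP", "mKO2", "iRFP720")


@dataclass
class EventTable:
    """Per-cell fluorescence in arbitrary units; rows = cells."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("event table contains non-finite values")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class Complex:
    plasmids: tuple[tuple[str, float], ...]   # (transcript name, mass fraction)
    marker: str                               # fluorophore tracking this complex

    def __post_init__(self):
        total = sum(f for _, f in self.plasmids)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class TransfectionDesign:
    complexes: tuple[Complex, ...]
    n_events: int = 10_000
    endpoint: float = 48.0

    def __post_init__(self):
        markers = [c.marker for c in self.complexes]
        if len(set(markers)) != len(markers):
            raise ValueError("complex markers must be distinct")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class UptakeModel:
    p_transfected: float = 0.6
    log_mu: float = 4.0
    log_sigma: float = 1.2
    rho_within: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.p_transfected <= 1.0:
            raise ValueError("p_transfected must be in [0, 1]")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if not 0.9 <= self.rho_within <= 1.0:
            raise ValueError("rho_within must be in [0.9, 1]")

    @property
    def jitter_sigma(self) -> float:
        """Within-complex log jitter achieving the requested correlation."""
        return self.log_sigma * np.sqrt(1.0 / self.rho_within - 1.0)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "UptakeModel":
        u = cfg["uptake"]
        return cls(u["p_transfected"], u["log_mu"], u["log_sigma"], u["rho_within"])


@dataclass(frozen=True)
class SpectralModel:
    channels: tuple[str, ...] = CHANNELS
    bleed: tuple[tuple[str, str, float], ...] = ()   # (source, channel, fraction)
    autofluor_mu: tuple[float, ...] = (3.9, 3.7, 3.5, 3.2)   # ln a.u. per channel
    autofluor_sigma: float = 0.35
    cv_meas: float = 0.25

    def __post_init__(self):
        if self.cv_meas < 0:
            raise ValueError("cv_meas must be nonnegative")
        for src, ch, v in self.bleed:
            if v < 0:
                raise ValueError(f"negative bleed {src}->{ch}")
            if src == ch:
                raise ValueError("diagonal bleed entries are fixed at 1")

    def mixing_matrix(self) -> np.ndarray:
        """Fluorophore (row) -> channel (column) mixing, diagonal 1."""
        n = len(self.channels)
        m = np.eye(n)
        idx = {c: i for i, c in enumerate(self.channels)}
        for src, ch, v in self.bleed:
            m[idx[src], idx[ch]] = v
        return m

    @classmethod
    def from_config(cls, cfg: Mapping) -> "SpectralModel":
        s = cfg["spectral"]
        chans = tuple(s["channels"])
        bleed = tuple((b["source"], b["channel"], float(b["value"]))
                      for b in s.get("bleed", []))
        mu = tuple(float(s["autofluor_mu"][c]) for c in chans)
        return cls(chans, bleed, mu, float(s["autofluor_sigma"]), float(s["cv_meas"]))


def _streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Deterministic named child streams from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def sample_copies(design: TransfectionDesign, uptake: UptakeModel,
                  seed: int) -> pd.DataFrame:
    """Per-cell plasmid copy numbers (columns: every plasmid in the design).

    Each complex is taken up independently: a Bernoulli gate for
    transfection, a lognormal total dose, and a small lognormal jitter per
    plasmid that sets the within-complex correlation.
    """
    rng = _streams(seed, "uptake")["uptake"]
    n = design.n_events
    cols: dict[str, np.ndarray] = {}
    sj = uptake.jitter_sigma
    for cx in design.complexes:
        gate = rng.random(n) < uptake.p_transfected
        total = np.exp(rng.normal(uptake.log_mu, uptake.log_sigma, n)) * gate
        for name, frac in cx.plasmids:
            jitter = np.exp(rng.normal(0.0, sj, n)) if sj > 0 else 1.0
            cols[name] = cols.get(name, 0.0) + total * frac * jitter
    return pd.DataFrame(cols)


def render_events(copies: pd.DataFrame, circuit: CircuitSpec,
                  params: ModelParams, spectral: SpectralModel,
                  seed: int, metadata: Mapping | None = None) -> EventTable:
    """Simulate every cell to the endpoint and measure it through the optics."""
    missing = [c for c in copies.columns
               if c not in {t.name for t in circuit.transcripts}]
    if missing:
        raise ValueError(f"copy columns do not resolve to circuit transcripts: {missing}")
    rng = _streams(seed, "spectral")["spectral"]
    copy_arrays = {c: copies[c].to_numpy(dtype=float) for c in copies.columns}
    levels = endpoint_many(circuit, copy_arrays, params, t_end=params.t_end)
    n = len(copies)
    fluor = np.zeros((n, len(spectral.channels)))
    for i, ch in enumerate(spectral.channels):
        if ch in levels:
            fluor[:, i] = levels[ch]
    mixed = fluor @ spectral.mixing_matrix()
    if spectral.cv_meas > 0:
        sigma = np.sqrt(np.log1p(spectral.cv_meas ** 2))
        mixed = mixed * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=mixed.shape))
    auto = np.exp(rng.normal(np.asarray(spectral.autofluor_mu),
                             spectral.autofluor_sigma, size=mixed.shape))
    out = pd.DataFrame(mixed + auto, columns=list(spectral.channels))
    meta = {"seed": seed, "n_events": n, **(metadata or {})}
    return EventTable(out, meta)


def generate_controls(spectral: SpectralModel, params: ModelParams, seed: int,
                      registry=None, n_events: int = 10_000,
                      log_mu: float = 4.0, log_sigma: float = 1.7
                      ) -> dict[str, EventTable]:
    """Untransfected + one bright single-color table per fluorophore.

    Single-color controls express one fluorophore across >= 3 decades of
    copy number, which is what the compensation fit needs.
    """
    from .registry import default_registry
    from .model import Transcript

    registry = registry or default_registry()
    streams = _streams(seed, "untransfected", *spectral.channels)
    out: dict[str, EventTable] = {}

    blank = pd.DataFrame(np.zeros((n_events, 1)), columns=["blank"])
    blank_circuit = CircuitSpec([Transcript(name="blank", payload="none")],
                                {"blank": 0.0}, registry)
    out["untransfected"] = render_events(
        blank, blank_circuit, params, spectral,
        int(streams["untransfected"].integers(2 ** 31)),
        metadata={"role": "untransfected"})

    for ch in spectral.channels:
        rng = streams[ch]
        copies = pd.DataFrame({
            "ctrl": np.exp(rng.normal(log_mu, log_sigma, n_events))})
        circuit = CircuitSpec([Transcript(name="ctrl", payload=ch)],
                              {"ctrl": 1.0}, registry)
        out[ch] = render_events(copies, circuit, params, spectral,
                                int(rng.integers(2 ** 31)),
                                metadata={"role": f"single-color:{ch}"})
    return out
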