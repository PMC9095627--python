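"""Flow-cytometry analysis: compensation, gating, binning and the derived
statistics (slope-normalized fold change, saturation fits, logic calls,
bistable state fractions, induction ratios).

The procedures mirror a standard transient-transfection workflow: estimate
a spillover matrix from single-color controls, unmix, threshold positive
cells against an untransfected sample, then summarize output-versus-marker
relationships either by binned medians or by linear fits whose slopes are
ratioed against no-site controls to remove nonspecific enzyme effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import EventTable

__all__ = [
    "CompensationMatrix", "BinSummary", "SlopeFit", "FoldChangeResult",
    "MMFit", "BistableFractions", "TSARatio", "estimate_compensation",
    "apply_compensation", "gate_positive", "bin_summarize", "fit_slope",
    "fold_change", "fit_mm", "cffl_dynamic_range", "logic_call",
    "bistable_fractions", "bistability_thresholds", "tsa_ratio",
]


class InsufficientControlError(ValueError):
    pass


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# compensation


@dataclass
class CompensationMatrix:
    """Estimated fluorophore->channel mixing with its cached inverse."""

    channels: tuple[str, ...]
    mixing: np.ndarray

    def __post_init__(self):
        if not np.allclose(np.diag(self.mixing), 1.0):
            raise ValueError("mixing diagonal must be 1")
        self.inverse = np.linalg.inv(self.mixing)
        self.condition_number = float(np.linalg.cond(self.mixing))

    @classmethod
    def identity(cls, channels: Sequence[str]) -> "CompensationMatrix":
        return cls(tuple(channels), np.eye(len(channels)))


def estimate_compensation(controls: Mapping[str, EventTable],
                          untransfected: EventTable,
                          min_bright: int = 100) -> CompensationMatrix:
    """Spillover estimation from single-color controls.

    For each control the untransfected channel medians are subtracted, the
    brightest decade of the primary channel is selected, and each spillover
    entry is the median of the per-cell secondary/primary ratio — robust to
    the multiplicative measurement noise that attenuates a least-squares
    slope.
    """
    channels = tuple(untransfected.channels)
    bg = untransfected.data.median(axis=0)
    mixing = np.eye(len(channels))
    idx = {c: i for i, c in enumerate(channels)}
    for fluor, table in controls.items():
        if fluor not in idx:
            raise KeyError(f"control fluorophore {fluor!r} is not a channel")
        if len(table) < 1000:
            raise InsufficientControlError(
                f"{fluor} control has {len(table)} events; need >= 1000")
        sub = table.data[list(channels)] - bg[list(channels)]
        primary = sub[fluor].to_numpy()
        # two decades below a robust brightness anchor; a narrower window
        # puts too many cells on the selection boundary, where conditioning
        # on measured brightness biases the noise ratio
        bright = primary >= np.percentile(primary, 99.5) / 100.0
        if bright.sum() < min_bright:
            raise InsufficientControlError(
                f"{fluor} control has {int(bright.sum())} bright cells; need >= {min_bright}")
        x = primary[bright]
        for ch in channels:
            if ch == fluor:
                continue
            y = sub[ch].to_numpy()[bright]
            mixing[idx[fluor], idx[ch]] = max(float(np.median(y / x)), 0.0)
    m = CompensationMatrix(channels, mixing)
    if not np.isfinite(m.condition_number) or m.condition_number > 1e6:
        raise FitError(f"compensation matrix ill-conditioned ({m.condition_number:.3g})")
    return m


def apply_compensation(events: EventTable, m: CompensationMatrix) -> EventTable:
    """Unmix measured channels; negative unmixed values are kept as-is."""
    if tuple(events.channels) != m.channels:
        raise ValueError(f"channel mismatch: {events.channels} vs {list(m.channels)}")
    unmixed = events.data.to_numpy() @ m.inverse
    return EventTable(pd.DataFrame(unmixed, columns=list(m.channels)),
                      {**events.metadata, "compensated": True})


# ---------------------------------------------------------------------------
# gating & binning


def gate_positive(events: EventTable, channel: str,
                  untransfected: EventTable,
                  percentile: float = 99.9) -> np.ndarray:
    """Mask of cells above the untransfected background on one channel."""
    thr = float(np.percentile(untransfected.data[channel], percentile))
    return events.data[channel].to_numpy() > thr


@dataclass
class BinSummary:
    edges: np.ndarray              # len n_bins+1, log-spaced over the marker
    midpoints: np.ndarray          # per kept bin
    n: np.ndarray
    median: np.ndarray
    iqr: np.ndarray
    max_iqr: float                 # the figure shading statistic

    def __len__(self):
        return len(self.midpoints)


def bin_summarize(events: EventTable, marker_channel: str, output_channel: str,
                  n_bins: int = 20, n_min: int = 20) -> BinSummary:
    """Log-spaced binning of output against the marker (gated events only)."""
    marker = events.data[marker_channel].to_numpy()
    output = events.data[output_channel].to_numpy()
    pos = marker > 0
    marker, output = marker[pos], output[pos]
    if marker.size == 0:
        raise ValueError("no positive-marker events to bin")
    edges = np.geomspace(marker.min(), marker.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(marker, edges) - 1, 0, n_bins - 1)
    mids, ns, meds, iqrs = [], [], [], []
    for b in range(n_bins):
        sel = which == b
        cnt = int(sel.sum())
        if cnt < n_min:
            continue
        q1, q2, q3 = np.percentile(output[sel], [25, 50, 75])
        mids.append(np.sqrt(edges[b] * edges[b + 1]))
        ns.append(cnt)
        meds.append(q2)
        iqrs.append(q3 - q1)
    if len(mids) < 2:
        raise ValueError(f"only {len(mids)} bins with >= {n_min} events; cannot summarize")
    return BinSummary(edges, np.array(mids), np.array(ns), np.array(meds),
                      np.array(iqrs), float(max(iqrs)))


# ---------------------------------------------------------------------------
# linear fits and fold change


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    stderr: float
    n: int


def fit_slope(events: EventTable, marker_channel: str,
              output_channel: str) -> SlopeFit:
    """Least-squares line of output on marker over gated cells (linear scale)."""
    x = events.data[marker_channel].to_numpy(dtype=float)
    y = events.data[output_channel].to_numpy(dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 events for a slope fit, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("degenerate marker variance")
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SlopeFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                    stderr=float(res.bse[1]), n=int(x.size))


@dataclass
class FoldChangeResult:
    raw_ratio: float
    nonspecific_ratio: float
    normalized_fold: float
    direction: str                 # "repression" | "activation"


def fold_change(site_pair: tuple[SlopeFit, SlopeFit],
                nosite_pair: tuple[SlopeFit, SlopeFit]) -> FoldChangeResult:
    """Slope-ratio fold change, normalized by the no-site control.

    ``site_pair`` and ``nosite_pair`` are (without enzyme, with enzyme)
    fits.  The no-site ratio removes nonspecific effects of enzyme
    expression; a normalized ratio above 1 is repression, below 1 is
    reported as activation with the reciprocal convention.
    """
    for label, fit in zip(("site/-E", "site/+E", "nosite/-E", "nosite/+E"),
                          (*site_pair, *nosite_pair)):
        if not np.isfinite(fit.slope) or fit.slope <= 0:
            raise FitError(f"fold change undefined: nonpositive slope in {label}")
    raw = site_pair[0].slope / site_pair[1].slope
    nonspec = nosite_pair[0].slope / nosite_pair[1].slope
    norm = raw / nonspec
    if norm >= 1.0:
        return FoldChangeResult(raw, nonspec, norm, "repression")
    return FoldChangeResult(raw, nonspec, 1.0 / norm, "activation")


# ---------------------------------------------------------------------------
# saturation fit


@dataclass
class MMFit:
    vmax_hat: float
    K_hat: float
    baseline: float
    residual_norm: float
    large_K_uncertainty: bool      # flagged when data never approach saturation


def fit_mm(summary: BinSummary) -> MMFit:
    """Fit median ~ baseline + vmax*x/(K+x) over bin midpoints.

    Multi-start nonlinear least squares with K initialized at the quartiles
    of the binned marker range; best start by residual norm wins.
    """
    from scipy.optimize import curve_fit

    if len(summary) < 4:
        raise ValueError("need >= 4 bins for a saturation fit")
    x, y = summary.midpoints, summary.median

    def f(x, vmax, K, baseline):
        return baseline + vmax * x / (K + x)

    best = None
    for K0 in np.percentile(x, [25, 50, 75]):
        try:
            p0 = [max(y.max() - y.min(), 1e-9), K0, max(y.min(), 0.0)]
            popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20_000,
                                bounds=([0, 1e-12, -np.inf], [np.inf] * 3))
        except RuntimeError:
            continue
        r = float(np.linalg.norm(y - f(x, *popt)))
        if best is None or r < best[0]:
            best = (r, popt)
    if best is None:
        raise FitError(f"saturation fit failed from all starts; data range {y.min()}..{y.max()}")
    r, (vmax, K, baseline) = best
    return MMFit(float(vmax), float(K), float(baseline), r,
                 large_K_uncertainty=bool(K > x.max()))


# ---------------------------------------------------------------------------
# composite statistics


def cffl_dynamic_range(summary, eval_marker: float = 10_000.0) -> float:
    """Dynamic range rule: output at the bin containing ``eval_marker``
    divided by output at the lowest marker bin.

    Accepts a :class:`BinSummary` or a pair of arrays ``(marker, output)``
    describing a noiseless dose-response curve (geometric interpolation).
    """
    if isinstance(summary, BinSummary):
        marker, output = summary.midpoints, summary.median
        if not summary.edges[0] <= eval_marker <= summary.edges[-1]:
            raise ValueError(f"eval_marker {eval_marker} outside binned range "
                             f"[{summary.edges[0]:.3g}, {summary.edges[-1]:.3g}]")
        b = int(np.clip(np.searchsorted(summary.edges, eval_marker) - 1, 0,
                        len(summary.edges) - 2))
        mid = np.sqrt(summary.edges[b] * summary.edges[b + 1])
        at_eval = output[int(np.argmin(np.abs(np.log(marker / mid))))]
    else:
        marker, output = (np.asarray(a, dtype=float) for a in summary)
        order = np.argsort(marker)
        marker, output = marker[order], output[order]
        if not marker[0] <= eval_marker <= marker[-1]:
            raise ValueError(f"eval_marker {eval_marker} outside curve range "
                             f"[{marker[0]:.3g}, {marker[-1]:.3g}]")
        at_eval = float(np.exp(np.interp(np.log(eval_marker), np.log(marker),
                                         np.log(np.maximum(output, 1e-300)))))
    return float(at_eval / output[0])


def logic_call(outputs: Sequence[float], band: tuple[float, float],
               truth_table: Sequence[bool] | None = None,
               reference: float | None = None):
    """Call four-condition outputs against the shared threshold band.

    Returns ``(calls, passed)``; ``passed`` is None when no truth table is
    supplied.  An ambiguous condition (inside the band) always fails.
    """
    from .gates import call_outputs

    if len(outputs) != 4:
        raise ValueError("expected outputs for exactly 4 input conditions")
    _, calls, _ = call_outputs(list(outputs), band, reference)
    if truth_table is None:
        return calls, None
    passed = all(c == ("on" if e else "off") for c, e in zip(calls, truth_table))
    return calls, passed


@dataclass
class BistableFractions:
    thresholds: dict[str, float]
    high_x_low_y: float
    high_y_low_x: float
    both_high: float
    both_low: float

    @property
    def exclusivity(self) -> float:
        return self.high_x_low_y + self.high_y_low_x


def bistability_thresholds(background: EventTable,
                           single_node_controls: Mapping[str, EventTable],
                           channels: Sequence[str]) -> dict[str, float]:
    """Geometric midpoint between background median and the bright 95th
    percentile of each output channel on its single-node control."""
    thr = {}
    for ch in channels:
        bgm = float(background.data[ch].median())
        hi = float(np.percentile(single_node_controls[ch].data[ch], 95))
        thr[ch] = float(np.sqrt(max(bgm, 1e-12) * max(hi, 1e-12)))
    return thr


def bistable_fractions(events: EventTable, gate_mask: np.ndarray,
                       thresholds: Mapping[str, float],
                       x_channel: str = "mKO2",
                       y_channel: str = "EYFP") -> BistableFractions:
    """Quadrant state fractions among gated (double-positive) cells."""
    sel = events.data[np.asarray(gate_mask, dtype=bool)]
    if len(sel) == 0:
        raise ValueError("empty gated set")
    x_hi = sel[x_channel].to_numpy() > thresholds[x_channel]
    y_hi = sel[y_channel].to_numpy() > thresholds[y_channel]
    n = len(sel)
    return BistableFractions(
        thresholds=dict(thresholds),
        high_x_low_y=float((x_hi & ~y_hi).sum() / n),
        high_y_low_x=float((~x_hi & y_hi).sum() / n),
        both_high=float((x_hi & y_hi).sum() / n),
        both_low=float((~x_hi & ~y_hi).sum() / n))


# ---------------------------------------------------------------------------
# induction ratio


@dataclass
class TSARatio:
    ratios: np.ndarray             # per clone; NaN where the denominator is 0
    mean: float
    sd: float
    undefined: int


def tsa_ratio(induced_plus: Sequence[float],
              induced_minus: Sequence[float]) -> TSARatio:
    """Per-clone ratio of induced output with vs without the HDAC inhibitor.

    A mean ratio near 1 indicates the induction response is not being
    rescued by deacetylation blockade, i.e. no silencing."""
    plus = np.asarray(induced_plus, dtype=float)
    minus = np.asarray(induced_minus, dtype=float)
    if plus.shape != minus.shape:
        raise ValueError("clone lists must be paired")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(minus > 0, plus / minus, np.nan)
    ok = np.isfinite(r)
    return TSARatio(r, float(np.mean(r[ok])), float(np.std(r[ok], ddof=1))
                    if ok.sum() > 1 else 0.0, int((~ok).sum()))
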