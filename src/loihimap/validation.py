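"""Agreement metrics between reference and emulator traces.

Comparison happens on the physical scale: emulator levels are inverse-mapped
to mV (``V = v * V_s + V_r``) and the hardware current to pA
(``I = u * C * V_s / dt``), then RMSE and the Pearson product-moment
correlation are computed over the paired samples.

Pairing convention.  The emulator's voltage ``v[k]`` approximates the
potential at the end of step ``k`` and is paired with the reference
``V(t_k)``.  The emulator's current ``u[k]``, however, is the left-endpoint
quantity that *drives* step ``k`` in the Euler update, so it is paired with
the reference ``I_syn(t_{k-1})``.  With this pairing both state variables
are compared without an artificial one-step phase error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import from_levels
from .params import MappingConfig, PhysicalLIFParams
from .emulator import EmulatorTrace
from .reference import Trace

__all__ = [
    "PairedSeries",
    "StateReport",
    "ComparisonReport",
    "align",
    "rmse",
    "pearson",
    "diagnostics",
    "compare",
]


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length paired samples: inverse-mapped emulator values ``y_L``
    against reference values ``y_B``, on a shared time base."""

    y_L: np.ndarray
    y_B: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y_L", np.asarray(self.y_L, dtype=float))
        object.__setattr__(self, "y_B", np.asarray(self.y_B, dtype=float))
        if self.y_L.shape != self.y_B.shape:
            raise ValueError("paired series must have equal length")

    @property
    def n(self) -> int:
        return self.y_L.size


@dataclass(frozen=True)
class StateReport:
    rmse: float
    pearson_r: float | None
    n: int


@dataclass(frozen=True)
class ComparisonReport:
    """Scalar agreement metrics for one reference/emulator trace pair."""

    V: StateReport
    I: StateReport
    spike_count_ref: int
    spike_count_emu: int

    @property
    def rmse(self) -> float:
        return self.V.rmse

    @property
    def pearson_r(self) -> float | None:
        return self.V.pearson_r

    def to_dict(self) -> dict:
        return {
            "V": {"rmse_mV": self.V.rmse, "pearson_r": self.V.pearson_r, "n": self.V.n},
            "I": {"rmse_pA": self.I.rmse, "pearson_r": self.I.pearson_r, "n": self.I.n},
            "spike_count_ref": self.spike_count_ref,
            "spike_count_emu": self.spike_count_emu,
        }


def align(
    ref: Trace,
    emu: EmulatorTrace,
    cfg: MappingConfig,
    params: PhysicalLIFParams,
    state: str = "V",
) -> PairedSeries:
    """Pair an emulator trace with a reference trace on the emulator grid.

    The reference grid step ``h`` must divide the emulator step ``dt``; the
    reference is subsampled at every ``dt/h``-th point.  The pairing covers
    steps 1..n (the shared initial condition at step 0 is excluded), so a
    500 ms run at dt = 1 pairs 500 samples.
    """
    if state not in ("V", "I"):
        raise ValueError("state must be 'V' or 'I'")
    h = ref.h
    stride = cfg.dt / h
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"reference step h = {h} must divide dt = {cfg.dt}")
    stride = int(round(stride))
    n_emu = emu.n_steps
    if abs(ref.duration - n_emu * cfg.dt) > 1e-6 * cfg.dt:
        raise ValueError(
            f"durations differ: reference {ref.duration} ms vs "
            f"emulator {n_emu * cfg.dt} ms"
        )
    k = np.arange(1, n_emu + 1)
    if state == "V":
        y_L = from_levels(emu.v[1:], params.V_r, cfg.V_s)
        y_B = ref.V[k * stride]
    else:
        y_L = emu.u[1:] * (params.C * cfg.V_s / cfg.dt)
        y_B = ref.I_syn[(k - 1) * stride]
    return PairedSeries(y_L=y_L, y_B=y_B)


def rmse(p: PairedSeries) -> float:
    """Root mean square error between the paired series."""
    if p.n < 1:
        raise ValueError("rmse requires at least one paired sample")
    return float(np.sqrt(np.mean((p.y_L - p.y_B) ** 2)))


def pearson(p: PairedSeries) -> float:
    """Pearson product-moment correlation between the paired series."""
    if p.n < 2:
        raise ValueError("pearson requires at least two paired samples")
    dL = p.y_L - p.y_L.mean()
    dB = p.y_B - p.y_B.mean()
    den = np.sqrt((dL**2).sum() * (dB**2).sum())
    if den == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    return float((dL * dB).sum() / den)


def diagnostics(p: PairedSeries, density_points: int = 256) -> dict:
    """Plot-ready diagnostic summaries for a paired series.

    Returns a dict with
      - ``density``: common value grid and Gaussian-kernel density estimates
        (Silverman bandwidth) of each series — the distribution comparison;
      - ``raster``: per-step value arrays for both series — localized
        discrepancies that averages hide;
      - ``scatter``: the sample pairs with least-squares trend-line slope and
        intercept — an almost perfectly linear cloud of slope 1 is the
        signature of a faithful mapping.
    """
    from scipy import stats

    lo = min(p.y_L.min(), p.y_B.min())
    hi = max(p.y_L.max(), p.y_B.max())
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, density_points)
    out: dict = {}
    densities = {}
    for name, y in (("y_L", p.y_L), ("y_B", p.y_B)):
        if np.ptp(y) > 0:
            kde = stats.gaussian_kde(y, bw_method="silverman")
            densities[name] = kde(grid)
        else:  # degenerate constant series: unit point mass as a histogram spike
            pdf = np.zeros_like(grid)
            idx = int(np.argmin(np.abs(grid - y[0])))
            pdf[idx] = 1.0 / (grid[1] - grid[0])
            densities[name] = pdf
    out["density"] = {"grid": grid, **densities}
    out["raster"] = {"step": np.arange(1, p.n + 1), "y_L": p.y_L, "y_B": p.y_B}
    dB = p.y_B - p.y_B.mean()
    varB = float((dB**2).mean())
    if varB > 0:
        slope = float(((p.y_L - p.y_L.mean()) * dB).mean() / varB)
    else:
        slope = 0.0
    intercept = float(p.y_L.mean() - slope * p.y_B.mean())
    out["scatter"] = {"y_B": p.y_B, "y_L": p.y_L, "slope": slope, "intercept": intercept}
    return out


def compare(
    ref: Trace,
    emu: EmulatorTrace,
    cfg: MappingConfig,
    params: PhysicalLIFParams,
    spike_mask_steps: int = 0,
) -> ComparisonReport:
    """Full scalar comparison of one trace pair: RMSE and correlation for
    both state variables plus spike counts.  Pure: identical inputs give an
    identical report.

    ``spike_mask_steps > 0`` excludes samples within that many emulator steps
    of any spike (on either backend) from the metrics, so reset transients do
    not dominate the error in the spiking regime.  The default compares all
    time points.
    """
    keep = None
    if spike_mask_steps > 0:
        n = emu.n_steps
        keep = np.ones(n, dtype=bool)
        spike_steps = np.concatenate(
            [
                np.asarray(emu.spike_steps, dtype=float),
                np.asarray(ref.spike_times, dtype=float) / cfg.dt,
            ]
        )
        for s in spike_steps:
            lo = max(int(round(s)) - spike_mask_steps, 1)
            hi = min(int(round(s)) + spike_mask_steps, n)
            keep[lo - 1 : hi] = False
    reports = {}
    for state in ("V", "I"):
        p = align(ref, emu, cfg, params, state=state)
        if keep is not None:
            p = PairedSeries(y_L=p.y_L[keep], y_B=p.y_B[keep])
        try:
            r = pearson(p)
        except ValueError:
            r = None  # constant series (e.g. u == 0 under pure bias drive)
        reports[state] = StateReport(rmse=rmse(p), pearson_r=r, n=p.n)
    return ComparisonReport(
        V=reports["V"],
        I=reports["I"],
        spike_count_ref=int(len(ref.spike_times)),
        spike_count_emu=int(len(emu.spike_steps)),
    )
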