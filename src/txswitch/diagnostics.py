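"""Envelope comparison across process representations and chain
diagnostics.

The envelope comparison quantifies how well each approximate transition
law (birth-death decomposition, its truncated-normal approximation, and
the LNA) reproduces the pointwise 95% band of the exact jump process: all
four representations are simulated on the same grid, envelopes are
computed by identical code, and each approximation is scored by the
integrated absolute deviation (IAD) of its envelope from the exact one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bda import simulate_bda_paths, simulate_bdd_paths
from .lna import simulate_lna_path
from .ssa import pointwise_envelope, simulate_ensemble
from .synthetic import PRESETS, ScenarioPreset

__all__ = ["EnvelopeReport", "compare_envelopes", "chain_diagnostics",
           "integrated_autocorr_time", "effective_sample_size"]

REPRESENTATIONS = ("exact", "bdd", "bda", "lna")
SPECIES = ("mrna", "protein")


@dataclass
class EnvelopeReport:
    grid: np.ndarray
    envelopes: dict     # (representation, species) -> (lower, upper)
    iad: dict           # (representation, species) -> float, vs exact
    iad_norm: dict      # IAD divided by the time-average exact mean level
    level: float
    n_paths: int


def _iad(grid, lo_a, hi_a, lo_e, hi_e) -> float:
    return float(np.trapezoid(np.abs(lo_a - lo_e), grid)
                 + np.trapezoid(np.abs(hi_a - hi_e), grid))


def compare_envelopes(preset: ScenarioPreset | str, n_paths: int = 10_000,
                      seed: int = 0, level: float = 0.95) -> EnvelopeReport:
    """Simulate all four representations and score approximate envelopes.

    The same quantile code runs on every ensemble; only the path sampler
    differs, so IADs are directly comparable.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n_paths < 100:
        raise ValueError("need at least 100 paths")
    pars = preset.params
    grid = np.arange(0.0, preset.horizon + preset.dt / 2, preset.dt)
    ensembles = {
        "exact": simulate_ensemble(pars, grid, n_paths, seed=seed),
        "bdd": simulate_bdd_paths(pars, grid, n_paths, seed=seed + 1),
        "bda": simulate_bda_paths(pars, grid, n_paths, seed=seed + 2),
        "lna": simulate_lna_path(pars, grid, seed=seed + 3,
                                 n_paths=n_paths),
    }
    envelopes = {}
    for rep, ens in ensembles.items():
        lo, hi = pointwise_envelope(ens.astype(float), level=level)
        for si, sp in enumerate(SPECIES):
            envelopes[(rep, sp)] = (lo[:, si], hi[:, si])
    iad = {}
    iad_norm = {}
    exact_mean = ensembles["exact"].mean(axis=0)
    for rep in ("bdd", "bda", "lna"):
        for si, sp in enumerate(SPECIES):
            lo_e, hi_e = envelopes[("exact", sp)]
            lo_a, hi_a = envelopes[(rep, sp)]
            v = _iad(grid, lo_a, hi_a, lo_e, hi_e)
            iad[(rep, sp)] = v
            scale = float(exact_mean[:, si].mean())
            iad_norm[(rep, sp)] = v / (scale * (grid[-1] - grid[0]))
    return EnvelopeReport(grid=grid, envelopes=envelopes, iad=iad,
                          iad_norm=iad_norm, level=level, n_paths=n_paths)


def integrated_autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """IACT by FFT autocorrelation with the standard self-consistent
    window (stop at the first m with m >= c * iact(m))."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return np.nan
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    tau = 1.0
    for m in range(1, n):
        tau += 2.0 * acf[m]
        if m >= c * tau:
            break
    return max(tau, 1.0)


def effective_sample_size(x: np.ndarray) -> float:
    tau = integrated_autocorr_time(x)
    if not np.isfinite(tau):
        return np.nan
    return x.size / tau


def plot_envelopes(report: EnvelopeReport, path=None):
    """2x2 figure of the 95% envelopes (rows: mRNA, protein; one column
    per scenario call — pass a list of reports for side-by-side).
    Requires matplotlib; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    reports = report if isinstance(report, (list, tuple)) else [report]
    fig, axes = plt.subplots(2, len(reports), figsize=(6 * len(reports), 7),
                             squeeze=False)
    colors = {"exact": "k", "bdd": "tab:blue", "bda": "tab:red",
              "lna": "tab:green"}
    for ci, rep in enumerate(reports):
        for si, sp in enumerate(SPECIES):
            ax = axes[si][ci]
            for r in REPRESENTATIONS:
                lo, hi = rep.envelopes[(r, sp)]
                ax.plot(rep.grid, lo, color=colors[r], lw=1, label=r)
                ax.plot(rep.grid, hi, color=colors[r], lw=1)
            ax.set_ylabel(sp)
            ax.set_xlabel("time (h)")
            if si == 0 and ci == 0:
                handles, labels = ax.get_legend_handles_labels()
                ax.legend(handles[:4], labels[:4], fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def chain_diagnostics(samples: dict) -> dict:
    """Per-parameter effective sample size and autocorrelation time.

    `samples` maps parameter names to 1-D chains.  Constant chains are
    reported as degenerate with a warning.
    """
    if not samples:
        raise ValueError("empty sample store")
    out = {}
    for name, x in samples.items():
        x = np.asarray(x, dtype=float)
        tau = integrated_autocorr_time(x)
        if not np.isfinite(tau):
            warnings.warn(f"chain '{name}' is degenerate (constant)")
            out[name] = {"ess": np.nan, "iact": np.nan, "degenerate": True}
        else:
            out[name] = {"ess": x.size / tau, "iact": tau,
                         "degenerate": False}
    return out
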