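"""Convergence and mixing diagnostics for retained posterior draws.

Single-chain tools matching the analysis workflow: Geweke early/late z-scores
with autocorrelation-robust variance, effective sample size by Geyer's
initial-monotone-sequence rule, sequential five-number summaries (the
"ten boxplots of 1000 draws" visual check), and the Metropolis acceptance
rate echoed from the sampler metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DiagnosticError
from .sampler import PosteriorDraws


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalized autocovariances up to max_lag via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:max_lag + 1].real / n
    return acov


def _ims_tau(x: np.ndarray) -> float:
    """Integrated autocorrelation time 1 + 2 sum rho_k via the initial
    monotone sequence estimator (sums adjacent-pair autocovariances while
    positive and nonincreasing)."""
    n = x.size
    acov = _autocovariances(x, n - 1)
    if acov[0] <= 0:
        raise DiagnosticError("zero-variance chain")
    # paired sums Gamma_m = acov[2m] + acov[2m+1]
    n_pairs = (n - 1) // 2
    tau = acov[0]
    prev = np.inf
    for m in range(n_pairs):
        g = acov[2 * m + 1] + acov[2 * m + 2]
        if g <= 0:
            break
        g = min(g, prev)  # enforce monotonicity
        prev = g
        tau += 2.0 * g
    return float(tau / acov[0])


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS = n / (1 + 2 sum_k rho_k), initial-monotone-sequence rule, capped
    at the chain length (antithetic chains report n, not more)."""
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 100:
        raise DiagnosticError("chain too short for ESS (need >= 100 draws)")
    if np.ptp(x) == 0:
        raise DiagnosticError("zero-variance chain: ESS undefined")
    tau = _ims_tau(x)
    return float(min(x.size / max(tau, 1e-12), float(x.size)))


def _segment_variance(x: np.ndarray) -> float:
    """Autocorrelation-adjusted long-run variance estimate (spectral density
    at zero) of a chain segment: var * tau."""
    return float(np.var(x, ddof=1) * _ims_tau(x))


def geweke_diagnostic(chain: np.ndarray, frac_a: float = 0.1,
                      frac_b: float = 0.5) -> float:
    """Geweke z-score comparing the first frac_a to the last frac_b of a
    chain, with long-run (spectral-at-zero) variance estimates per window.

    |z| below ~2-4 is consistent with stationarity of the retained draws.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 100:
        raise DiagnosticError("chain too short for the Geweke diagnostic")
    if np.var(x) == 0:
        raise DiagnosticError("zero-variance chain: Geweke diagnostic undefined")
    na = int(np.floor(frac_a * x.size))
    nb = int(np.floor(frac_b * x.size))
    a, b = x[:na], x[-nb:]
    if np.var(a) == 0 or np.var(b) == 0:
        raise DiagnosticError("constant chain segment: Geweke diagnostic undefined")
    sa = _segment_variance(a)
    sb = _segment_variance(b)
    return float((a.mean() - b.mean()) / np.sqrt(sa / na + sb / nb))


def sequential_boxplot_summary(chain: np.ndarray, n_segments: int = 10) -> list[tuple]:
    """Five-number summaries (min, Q1, median, Q3, max) of equal contiguous
    segments; trailing remainder draws are dropped."""
    x = np.asarray(chain, dtype=float).ravel()
    if n_segments < 1 or n_segments > x.size:
        raise DiagnosticError("n_segments must be in [1, chain length]")
    seg_len = x.size // n_segments
    out = []
    for s in range(n_segments):
        seg = x[s * seg_len:(s + 1) * seg_len]
        q1, med, q3 = np.percentile(seg, [25, 50, 75])
        out.append((float(seg.min()), float(q1), float(med), float(q3), float(seg.max())))
    return out


@dataclass(frozen=True)
class DiagnosticReport:
    table: pd.DataFrame          # per-parameter geweke_z / ess
    segment_summaries: dict      # parameter -> list of five-number tuples
    acceptance_rate: float

    def worst_geweke(self) -> float:
        return float(self.table["geweke_z"].abs().max())

    def min_ess(self) -> float:
        return float(self.table["ess"].min())


def diagnostic_report(draws: PosteriorDraws, n_segments: int = 10) -> DiagnosticReport:
    """Geweke z, ESS and segment summaries for every retained parameter chain."""
    frame = draws.to_frame()
    rows, segments = [], {}
    for col in frame.columns:
        x = frame[col].to_numpy()
        try:
            z = geweke_diagnostic(x)
            ess = effective_sample_size(x)
        except DiagnosticError:
            z, ess = np.nan, np.nan
        rows.append({"parameter": col, "geweke_z": z, "ess": ess})
        segments[col] = sequential_boxplot_summary(x, min(n_segments, x.size))
    table = pd.DataFrame(rows).set_index("parameter")
    return DiagnosticReport(table=table, segment_summaries=segments,
                            acceptance_rate=float(draws.meta.get("acceptance_rate", np.nan)))


def plot_sequential_boxplots(draws: PosteriorDraws, parameters: list[str] | None = None,
                             n_segments: int = 10, path=None):
    """Sequential boxplots of chain segments, one panel per parameter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = draws.to_frame()
    if parameters is None:
        parameters = list(frame.columns)
    fig, axes = plt.subplots(len(parameters), 1,
                             figsize=(7, 2.2 * len(parameters)), squeeze=False)
    for ax, par in zip(axes[:, 0], parameters):
        x = frame[par].to_numpy()
        seg_len = x.size // n_segments
        segs = [x[s * seg_len:(s + 1) * seg_len] for s in range(n_segments)]
        ax.boxplot(segs, showfliers=False)
        ax.set_ylabel(par, fontsize=7)
    axes[-1, 0].set_xlabel("chain segment")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
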