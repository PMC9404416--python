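"""MCMC convergence diagnostics for variance-component chains.

Effective sample size uses Geyer's initial-positive-sequence estimator on
the autocorrelation function; the Geweke diagnostic compares the mean of the
first 10% of the chain against the last 50%, with segment variances
adjusted for autocorrelation through the segment ESS.  Components with
|z| > 2 or ESS < 100 are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["effective_sample_size", "geweke_z", "diagnostics_frame", "trace_frame"]


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]

def effective_sample_size(x) -> float:
    """ESS by summing paired autocorrelations while the pair sums stay positive."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    rho = _autocorr(x)
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, max(n / tau, 1.0)))


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence score between early and late chain segments."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    va = a.var(ddof=1) / effective_sample_size(a)
    vb = b.var(ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def diagnostics_frame(results) -> pd.DataFrame:
    """Per-component report: mean, sd, ESS, Geweke z and a flag column."""
    frame = results.samples_frame()
    rows = []
    for (comp, a, b), grp in frame.groupby(["component", "trait_i", "trait_j"], sort=False):
        x = grp["value"].to_numpy()
        ess = effective_sample_size(x)
        z = geweke_z(x)
        rows.append(
            {
                "component": comp,
                "trait_i": a,
                "trait_j": b,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                "ess": ess,
                "geweke_z": z,
                "flagged": bool(abs(z) > 2.0 or ess < 100),
            }
        )
    return pd.DataFrame(rows)


def trace_frame(results) -> pd.DataFrame:
    """Iteration-by-value trace data (for plotting covariance components)."""
    return results.samples_frame()
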