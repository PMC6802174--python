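"""Binding constants from ¹H NMR titration slopes.

DNA-bound polyamine protons relax too fast to be observed (T₂
broadening), so the integrated ¹H signal tracks the *free* polyamine
fraction.  With DNA in excess and fast exchange, the free fraction is
1 / (1 + K·[DNA]), hence the inverse relative intensity is linear in
DNA concentration with slope K:

    1 / I_rel = 1 + K · [DNA]       (I_rel = I / I₀)

Titration data show two slope regimes split at 0.5 mM DNA; the
low-concentration slope is labeled K₂ and the high-concentration slope
K₁ (the regime a dilute-polyamine simulation corresponds to).  The fit
is a continuous piecewise-linear least squares with a fixed (or
profiled) breakpoint; because the intercept is one after normalization,
the slopes are the binding constants directly, in mM⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitrationDataset",
    "TitrationFit",
    "invert_normalize",
    "fit_two_regime",
    "profile_breakpoint",
    "bootstrap_ci",
    "read_titration_csv",
    "write_titration_csv",
]


@dataclass
class TitrationDataset:
    """A titration series: DNA concentrations (mM) and signal intensities."""

    dna_conc: np.ndarray  # mM, strictly increasing, >= 0
    intensity: np.ndarray  # summed integrated signal, arbitrary units
    polyamine_conc: float = 0.1  # mM, fixed

    def __post_init__(self):
        self.dna_conc = np.asarray(self.dna_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.dna_conc.shape != self.intensity.shape:
            raise ValueError("concentration and intensity lengths differ")
        if np.any(self.dna_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.dna_conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")


@dataclass
class TitrationFit:
    """Two-regime slope fit of inverse relative intensity vs [DNA]."""

    K2_low: float  # mM⁻¹, slope below the breakpoint
    K1_high: float  # mM⁻¹, slope above the breakpoint
    breakpoint: float  # mM
    I0: float  # zero-DNA intensity used for normalization
    intercept: float  # fitted value of 1/I_rel at zero DNA (≈ 1)
    rss: float  # residual sum of squares
    n_low: int
    n_high: int


def invert_normalize(data: TitrationDataset, I0: float | None = None):
    """Return (conc, 1/I_rel) with I_rel = I / I₀.

    I₀ defaults to the measured zero-DNA intensity, which must then be
    present in the series.  By construction 1/I_rel = 1 at zero DNA.
    """
    if I0 is None:
        if data.dna_conc[0] != 0:
            raise ValueError("no zero-DNA point in the series; supply I0")
        I0 = float(data.intensity[0])
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    return data.dna_conc.copy(), I0 / data.intensity


def _design(conc: np.ndarray, breakpoint: float) -> np.ndarray:
    """Design matrix of the continuous piecewise-linear model."""
    return np.column_stack(
        [
            np.ones_like(conc),
            np.minimum(conc, breakpoint),
            np.maximum(conc - breakpoint, 0.0),
        ]
    )


def fit_two_regime(
    conc: np.ndarray,
    inv_rel: np.ndarray,
    breakpoint: float = 0.5,
    I0: float = 1.0,
) -> TitrationFit:
    """Continuous two-slope least-squares fit with a fixed breakpoint.

    ``conc`` and ``inv_rel`` are the output of :func:`invert_normalize`.
    Requires at least two points in each regime (a point at the
    breakpoint counts toward the low regime).
    """
    conc = np.asarray(conc, dtype=float)
    inv_rel = np.asarray(inv_rel, dtype=float)
    n_low = int(np.sum(conc <= breakpoint))
    n_high = int(np.sum(conc > breakpoint))
    if n_low < 2 or n_high < 2:
        raise ValueError(
            f"need >= 2 points in each regime, got {n_low} at or below and "
            f"{n_high} above the {breakpoint} mM breakpoint"
        )
    X = _design(conc, breakpoint)
    beta, *_ = np.linalg.lstsq(X, inv_rel, rcond=None)
    resid = inv_rel - X @ beta
    return TitrationFit(
        K2_low=float(beta[1]),
        K1_high=float(beta[2]),
        breakpoint=float(breakpoint),
        I0=float(I0),
        intercept=float(beta[0]),
        rss=float(resid @ resid),
        n_low=n_low,
        n_high=n_high,
    )


def profile_breakpoint(conc, inv_rel, candidates) -> TitrationFit:
    """Grid-search the breakpoint minimizing the residual sum of squares."""
    best = None
    for b in candidates:
        try:
            fit = fit_two_regime(conc, inv_rel, breakpoint=float(b))
        except ValueError:
            continue
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        raise ValueError("no candidate breakpoint leaves 2 points per regime")
    return best


def bootstrap_ci(
    conc,
    inv_rel,
    breakpoint: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
):
    """Percentile bootstrap intervals for (K2_low, K1_high).

    Points are resampled with replacement within each regime
    (stratified), keeping both regimes populated; replicates whose
    resample leads to a singular fit are skipped and counted.  Returns
    ``{"K2_low": (lo, hi), "K1_high": (lo, hi), "n_skipped": int}``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    conc = np.asarray(conc, dtype=float)
    inv_rel = np.asarray(inv_rel, dtype=float)
    rng = np.random.default_rng(seed)
    low = np.where(conc <= breakpoint)[0]
    high = np.where(conc > breakpoint)[0]
    k2s, k1s, skipped = [], [], 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(low, size=len(low)), rng.choice(high, size=len(high))]
        )
        c, y = conc[idx], inv_rel[idx]
        X = _design(c, breakpoint)
        if np.linalg.matrix_rank(X) < 3:
            skipped += 1
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        k2s.append(beta[1])
        k1s.append(beta[2])
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    return {
        "K2_low": tuple(np.percentile(k2s, q)),
        "K1_high": tuple(np.percentile(k1s, q)),
        "n_skipped": skipped,
    }


def read_titration_csv(path) -> TitrationDataset:
    """Read a (conc_mM, intensity) CSV table."""
    import pandas as pd

    df = pd.read_csv(path)
    return TitrationDataset(
        dna_conc=df["conc_mM"].to_numpy(), intensity=df["intensity"].to_numpy()
    )


def write_titration_csv(data: TitrationDataset, path) -> None:
    import pandas as pd

    pd.DataFrame({"conc_mM": data.dna_conc, "intensity": data.intensity}).to_csv(
        path, index=False
    )
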