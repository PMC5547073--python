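"""ROI time-series conditioning: nuisance regression, MODWT band-pass,
significance-gated Pearson correlation.

The band-pass step is the maximum-overlap discrete wavelet transform
(MODWT): a non-decimated, shift-invariant wavelet decomposition whose
detail scale ``j`` occupies the dyadic frequency band
``[1/2**(j+1), 1/2**j]`` of the sampling rate.  At TR = 1.7 s, scale 3
spans approximately 0.037–0.074 Hz, the low-frequency band where
resting-state fluctuations live.  Correlations between the scale-3
coefficient series of every region pair, gated at p < alpha, give the
functional connectivity matrix networks are thresholded from.

The MODWT is computed by circular convolution with the rescaled
(``1/sqrt(2)`` per level) Daubechies filters; filter coefficients come from
PyWavelets.  Circular boundary handling keeps the coefficient count equal
to the series length, makes the transform exactly shift-equivariant, and
preserves total energy across scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pywt
from scipy import stats

__all__ = [
    "RoiTimeSeries",
    "CorrelationMatrix",
    "nuisance_regress",
    "modwt",
    "modwt_detail",
    "modwt_bandpass",
    "modwt_passband_hz",
    "gated_correlation_matrix",
    "read_roi_tsv",
    "write_roi_tsv",
    "write_correlation_tsv",
    "read_correlation_tsv",
]

MIN_VOLUMES = 16  # needed for a scale-3 decomposition


@dataclass(frozen=True)
class RoiTimeSeries:
    """Region-by-volume signal matrix with its sampling interval.

    ``values`` has shape ``(n_regions, n_volumes)``; ``tr_seconds`` is the
    repetition time (sampling interval) in seconds.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if v.ndim != 2:
            raise ValueError("values must be a 2-D regions x volumes matrix")
        if not np.isfinite(v).all():
            raise ValueError("time series contain missing or non-finite values")
        if v.shape[1] < MIN_VOLUMES:
            raise ValueError(
                f"need at least {MIN_VOLUMES} volumes for a scale-3 decomposition, "
                f"got {v.shape[1]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match the number of rows")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix with a significance gate.

    Entries failing the gate (p >= alpha, or a zero-variance region) are
    stored as 0 with ``gate`` False.  The diagonal is ``r = 1`` and gated
    in, but is never used downstream.
    """

    r: np.ndarray
    gate: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.gate, dtype=bool)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "gate", g)
        if r.shape != g.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r and gate must be matching square matrices")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    def gated_upper_triangle(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, |r|) arrays of the retained strictly-upper-triangle entries."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        keep = self.gate[iu, ju]
        return iu[keep], ju[keep], np.abs(self.r[iu[keep], ju[keep]])


# -- nuisance regression -----------------------------------------------------


def nuisance_regress(ts: RoiTimeSeries, regressors: np.ndarray) -> RoiTimeSeries:
    """Project confound regressors (plus an intercept) out of every region.

    Each region's series is replaced by its least-squares residual after
    regression on the given columns and a constant.  The design must have
    full column rank; otherwise the offending (linearly dependent) columns
    are named in the error.
    """
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != ts.n_volumes:
        raise ValueError(
            f"regressors have {x.shape[0]} rows but the series has {ts.n_volumes} volumes"
        )
    design = np.column_stack([np.ones(ts.n_volumes), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase the rank of the prefix design
        bad = []
        running = design[:, :1]
        for col in range(1, design.shape[1]):
            cand = np.column_stack([running, design[:, col]])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(running):
                bad.append(col - 1)  # 0-based index into the user's regressors
            else:
                running = cand
        raise ValueError(
            f"rank-deficient nuisance design: regressor columns {bad} are "
            "linearly dependent on the intercept and earlier columns"
        )
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    residuals = ts.values.T - design @ beta
    return RoiTimeSeries(residuals.T, ts.tr_seconds, ts.region_labels)


# -- MODWT -------------------------------------------------------------------


def _modwt_filters(wavelet: str) -> Tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)  # scaling (smooth)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)  # wavelet (detail)
    return g, h


def _circular_filter(v: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Row-wise circular convolution y[t] = sum_l filt[l] v[t - l mod n]."""
    n = v.shape[-1]
    padded = np.zeros(n)
    for l, c in enumerate(filt):  # wrap filters longer than the signal
        padded[l % n] += c
    return np.fft.irfft(np.fft.rfft(v, axis=-1) * np.fft.rfft(padded), n=n, axis=-1)


def _upsampled(filt: np.ndarray, spacing: int) -> np.ndarray:
    out = np.zeros((len(filt) - 1) * spacing + 1)
    out[::spacing] = filt
    return out


def modwt(
    x: np.ndarray, wavelet: str = "db4", level: int = 4
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Full MODWT pyramid: detail coefficients for scales 1..level plus the smooth.

    Works row-wise on a 1-D series or a 2-D (series x time) matrix.  With
    circular boundaries the transform is energy-preserving:
    ``sum_j ||W_j||**2 + ||V_J||**2 == ||x||**2``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    min_len = 2 ** (level + 1)
    if n < min_len:
        raise ValueError(
            f"series of length {n} too short for a scale-{level} MODWT; "
            f"minimum length is {min_len}"
        )
    g, h = _modwt_filters(wavelet)
    details: List[np.ndarray] = []
    v = x
    for j in range(1, level + 1):
        spacing = 2 ** (j - 1)
        details.append(_circular_filter(v, _upsampled(h, spacing)))
        v = _circular_filter(v, _upsampled(g, spacing))
    return details, v


def modwt_detail(
    x: np.ndarray, scale: int = 3, wavelet: str = "db4"
) -> np.ndarray:
    """Detail coefficients at one scale (same length as the input)."""
    details, _ = modwt(x, wavelet=wavelet, level=scale)
    return details[scale - 1]


def modwt_bandpass(
    ts: RoiTimeSeries, scale: int = 3, wavelet: str = "db4"
) -> np.ndarray:
    """Band-pass each region by keeping its MODWT detail coefficients at ``scale``.

    Returns an ``(n_regions, n_volumes)`` coefficient matrix.  The default
    scale 3 isolates the ~0.03–0.07 Hz resting-state band at TR = 1.7 s.
    """
    return modwt_detail(ts.values, scale=scale, wavelet=wavelet)


def modwt_passband_hz(scale: int, tr_seconds: float) -> Tuple[float, float]:
    """Nominal (low, high) frequency edges of a MODWT detail scale, in Hz."""
    return 1.0 / (2 ** (scale + 1) * tr_seconds), 1.0 / (2**scale * tr_seconds)


# -- gated correlation -------------------------------------------------------


def gated_correlation_matrix(coeffs: np.ndarray, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Pearson correlation with a two-sided significance gate.

    p-values come from the t statistic ``r * sqrt((n-2)/(1-r**2))`` with
    ``n - 2`` degrees of freedom on the coefficient series (nominal df; no
    autocorrelation correction is applied).  Entries with ``p >= alpha`` are
    zeroed and gated out.  A zero-variance region has its whole row/column
    gated out with a warning.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two regions")
    n_regions, n_obs = c.shape
    if n_obs < 3:
        raise ValueError("need at least 3 observations per region")
    sd = c.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"regions {np.nonzero(degenerate)[0].tolist()} have zero variance; "
            "their correlations are gated out",
            stacklevel=2,
        )
    safe = c.copy()
    safe[degenerate] = np.random.default_rng(0).standard_normal((degenerate.sum(), n_obs))
    r = np.corrcoef(safe)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = rr * np.sqrt((n_obs - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(t, df=n_obs - 2)
    gate = p < alpha
    np.fill_diagonal(gate, True)
    gate[degenerate, :] = False
    gate[:, degenerate] = False
    np.fill_diagonal(gate, True)

    r_out = np.where(gate, r, 0.0)
    np.fill_diagonal(r_out, 1.0)
    return CorrelationMatrix(r=r_out, gate=gate, n_obs=n_obs)


# -- I/O ---------------------------------------------------------------------


def write_roi_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    """TSV with one region per row (first column = label) + a JSON sidecar
    carrying ``tr_seconds`` (same stem, ``.json`` suffix)."""
    path = Path(path)
    with open(path, "w") as fh:
        cols = "\t".join(f"v{t}" for t in range(ts.n_volumes))
        fh.write(f"region\t{cols}\n")
        for label, row in zip(ts.region_labels, ts.values):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"tr_seconds": ts.tr_seconds}) + "\n")


def read_roi_tsv(path: str | Path, tr_seconds: Optional[float] = None) -> RoiTimeSeries:
    path = Path(path)
    if tr_seconds is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no tr_seconds given and sidecar {sidecar} not found"
            )
        tr_seconds = float(json.loads(sidecar.read_text())["tr_seconds"])
    labels: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("region\t"):
            raise ValueError(f"{path}: expected a 'region<TAB>v0...' header line")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return RoiTimeSeries(np.array(rows), tr_seconds, labels)


def write_correlation_tsv(cm: CorrelationMatrix, r_path: str | Path, gate_path: str | Path) -> None:
    np.savetxt(r_path, cm.r, delimiter="\t", fmt="%.10g")
    np.savetxt(gate_path, cm.gate.astype(int), delimiter="\t", fmt="%d")


def read_correlation_tsv(r_path: str | Path, gate_path: str | Path, n_obs: int) -> CorrelationMatrix:
    r = np.loadtxt(r_path, delimiter="\t")
    gate = np.loadtxt(gate_path, delimiter="\t").astype(bool)
    return CorrelationMatrix(r=r, gate=gate, n_obs=n_obs)
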