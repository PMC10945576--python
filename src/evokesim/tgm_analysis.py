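"""Quantitative features of temporal generalisation matrices and the
rise/fall-shape fitting sweep.

Feature extraction operationalises the qualitative signatures seen in evoked
decoding: the diagonal accuracy profile, a slice at the training time of
maximum accuracy, the late-trial broadening (contiguous above-chance
run-length along the diagonal in the last part of the trial), and the
row-periodicity (dominant normalised spectral peak over detrended rows, the
"chequer" signature of a single shared response frequency).

The sweep generates datasets over a grid of response-gate rise (delta2) and
fall (delta3) durations, decodes each, averages the TGMs per cell and
correlates them against a reference TGM; the argmax cell is the fitted shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import detrend
from scipy.stats import pearsonr

from .decoding import TGM, average_tgms, compute_tgm
from .simulator import SimulationConfig, sample_dataset

__all__ = [
    "TGMFeatures",
    "SweepResult",
    "extract_features",
    "correlate_tgms",
    "sweep_response_shape",
    "load_reference_tgm",
]


@dataclass
class TGMFeatures:
    """Scalar and profile features of one TGM."""

    diagonal: np.ndarray
    vertical_slice: np.ndarray
    t_star: int
    late_width: int
    row_periodicity: float
    row_period_freq: float  # cycles per sample of the dominant row peak


@dataclass
class SweepResult:
    """Grid of correlations between swept simulated TGMs and a reference."""

    delta2_grid: np.ndarray
    delta3_grid: np.ndarray
    correlation: np.ndarray  # (len(delta2_grid), len(delta3_grid))
    argmax: tuple[float, float]
    errors: dict[tuple[float, float], str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"delta2": d2, "delta3": d3, "correlation": self.correlation[i, j]}
            for i, d2 in enumerate(self.delta2_grid)
            for j, d3 in enumerate(self.delta3_grid)
        ]
        return pd.DataFrame(rows)


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def extract_features(
    tgm: TGM,
    chance: float = 0.5,
    threshold_offset: float = 0.05,
    late_fraction: float = 0.4,
) -> TGMFeatures:
    """Extract the characteristic TGM features.

    `late_width` is the longest contiguous stretch of diagonal accuracy above
    ``chance + threshold_offset`` within the last `late_fraction` of the
    trial. `row_periodicity` is the largest normalised (non-DC) spectral peak
    of the linearly detrended TGM rows, averaged across rows.
    """
    acc = tgm.accuracy
    T = acc.shape[0]
    diag = np.diag(acc).copy()
    t_star = int(np.argmax(diag))  # earliest argmax on ties
    vslice = acc[t_star, :].copy()

    late_start = int(np.ceil((1.0 - late_fraction) * T))
    late_mask = diag[late_start:] > chance + threshold_offset
    late_width = _longest_run(late_mask)

    rows = detrend(acc, axis=1)
    power = np.abs(np.fft.rfft(rows, axis=1)) ** 2
    mean_power = power.mean(axis=0)[1:]  # drop DC
    total = mean_power.sum()
    if total <= 1e-16:  # numerically flat TGM: no detectable periodicity
        periodicity, freq = 0.0, 0.0
    else:
        k = int(np.argmax(mean_power)) + 1
        periodicity = float(mean_power[k - 1] / total)
        freq = k / T
    return TGMFeatures(
        diagonal=diag,
        vertical_slice=vslice,
        t_star=t_star,
        late_width=int(late_width),
        row_periodicity=periodicity,
        row_period_freq=freq,
    )


def correlate_tgms(simulated: TGM | np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation between two TGMs over their vectorised entries."""
    a = simulated.accuracy if isinstance(simulated, TGM) else np.asarray(simulated)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"TGM shapes differ: {a.shape} vs {b.shape}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance TGM")
    return float(pearsonr(a.ravel(), b.ravel())[0])


def load_reference_tgm(path: str) -> np.ndarray:
    """Load a square reference TGM from a headerless CSV matrix."""
    ref = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if ref.ndim != 2 or ref.shape[0] != ref.shape[1]:
        raise ValueError(f"reference TGM in {path!r} is not square: {ref.shape}")
    return ref


def _with_shape(config: SimulationConfig, delta2: float, delta3: float) -> SimulationConfig:
    shape = replace(config.response, delta2=float(delta2), delta3=float(delta3))
    return replace(config, response=shape)


def sweep_response_shape(
    base_config: SimulationConfig,
    delta2_grid: np.ndarray,
    delta3_grid: np.ndarray,
    runs: int,
    reference: np.ndarray,
    seed: int,
    n_folds: int = 10,
) -> SweepResult:
    """Fit the response-gate rise/fall durations against a reference TGM.

    Per grid cell, `runs` datasets are generated (fresh seeds split per cell
    and run), decoded into TGMs, averaged, and the average is correlated with
    the reference. Cell failures are recorded and the sweep continues.
    """
    d2s = np.asarray(delta2_grid, dtype=float)
    d3s = np.asarray(delta3_grid, dtype=float)
    if d2s.size == 0 or d3s.size == 0 or runs < 1:
        raise ValueError("grids must be non-empty and runs >= 1")
    corr = np.full((d2s.size, d3s.size), np.nan)
    errors: dict[tuple[float, float], str] = {}
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(d2s.size * d3s.size)
    for i, d2 in enumerate(d2s):
        for j, d3 in enumerate(d3s):
            cell_ss = cell_seeds[i * d3s.size + j]
            try:
                cfg = _with_shape(base_config, d2, d3)
                tgms = []
                for run_ss in cell_ss.spawn(runs):
                    run_seed = int(run_ss.generate_state(1)[0] % (2**31))
                    ds = sample_dataset(cfg, run_seed)
                    tgms.append(compute_tgm(ds, n_folds=n_folds, seed=run_seed))
                corr[i, j] = correlate_tgms(average_tgms(tgms), reference)
            except Exception as exc:  # record and continue
                errors[(float(d2), float(d3))] = f"{type(exc).__name__}: {exc}"
    if np.all(np.isnan(corr)):
        raise RuntimeError(f"every sweep cell failed: {errors}")
    flat = np.nanargmax(corr)
    i, j = np.unravel_index(flat, corr.shape)
    return SweepResult(
        delta2_grid=d2s,
        delta3_grid=d3s,
        correlation=corr,
        argmax=(float(d2s[i]), float(d3s[j])),
        errors=errors,
    )
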