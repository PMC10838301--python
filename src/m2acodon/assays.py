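"""Reducers for orthogonal reporter and biophysical assays.

Three small computations that accompany the sequencing analysis:

* dual-luciferase normalization — firefly over Renilla activity, further
  normalized within genotype to an empty control construct, so reporter
  readouts are comparable across genotypes and transfections;
* apparent translation efficiency — relative protein amount divided by
  relative mRNA level for a gene;
* melting-transition detection — low-pass (FFT) smoothing of a fluorescence
  melting curve, negative first derivative on the temperature grid, and peak
  picking to report up to two transition temperatures (Tm1 <= Tm2,
  tertiary- and secondary-structure dissolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "normalize_reporter",
    "apparent_te",
    "MeltingCurve",
    "melting_transitions",
]


def normalize_reporter(
    readings: pd.DataFrame, control_construct: str = "empty"
) -> pd.DataFrame:
    """Normalize firefly/Renilla readings to the control construct per genotype.

    ``readings`` needs columns genotype, construct, firefly, renilla; rows
    are individual transfections (replicates). Per replicate the activity is
    (F/R); per genotype it is divided by the mean (F/R) of the control
    construct, which absorbs genotype-level transcription differences.
    Returns per (genotype, construct): n, mean and sd of normalized activity.
    """
    required = {"genotype", "construct", "firefly", "renilla"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings missing columns: {sorted(missing)}")
    if (readings["firefly"] <= 0).any() or (readings["renilla"] <= 0).any():
        raise ValueError("luciferase activities must be positive")
    df = readings.copy()
    df["fr"] = df["firefly"] / df["renilla"]
    out_rows = []
    for genotype, sub in df.groupby("genotype", sort=False):
        ctrl = sub.loc[sub["construct"] == control_construct, "fr"]
        if ctrl.empty:
            raise ValueError(
                f"control construct {control_construct!r} absent for genotype "
                f"{genotype!r}"
            )
        ctrl_mean = ctrl.mean()
        for construct, cs in sub.groupby("construct", sort=False):
            norm = cs["fr"] / ctrl_mean
            out_rows.append(
                {
                    "genotype": genotype,
                    "construct": construct,
                    "n": len(norm),
                    "normalized_activity": norm.mean(),
                    "sd": norm.std(ddof=1) if len(norm) > 1 else 0.0,
                }
            )
    return pd.DataFrame(out_rows)


def apparent_te(protein_rel: float, mrna_rel: float) -> float:
    """Apparent translation efficiency: relative protein over relative mRNA."""
    if protein_rel <= 0 or mrna_rel <= 0:
        raise ValueError("protein and mRNA relative levels must be positive")
    return protein_rel / mrna_rel


@dataclass(frozen=True)
class MeltingCurve:
    """A fluorescence melting curve on a strictly increasing temperature grid."""

    temperature: np.ndarray  # degrees C
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence must be matching 1-D arrays")
        if len(t) < 10:
            raise ValueError("melting curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "fluorescence", f)


def _fft_lowpass(values: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Zero all but the lowest ``keep_fraction`` of rFFT components.

    The endpoint-connecting linear trend is removed first and restored after,
    so the implicit periodic extension has no jump and the filter does not
    ring at the grid edges.
    """
    n = len(values)
    trend = values[0] + (values[-1] - values[0]) * np.arange(n) / (n - 1)
    spectrum = np.fft.rfft(values - trend)
    keep = max(2, int(np.ceil(keep_fraction * len(spectrum))))
    spectrum[keep:] = 0.0
    return np.fft.irfft(spectrum, n=n) + trend


def melting_transitions(
    curve: MeltingCurve,
    max_peaks: int = 2,
    keep_fraction: float = 0.10,
    min_prominence_fraction: float = 0.05,
) -> list[tuple[float, float]]:
    """Detect up to ``max_peaks`` melting transitions (Tm, prominence).

    Pipeline: FFT low-pass smoothing keeping the lowest ``keep_fraction`` of
    frequency components; negative first derivative -dF/dT by central
    differences on the (possibly non-uniform) grid (SYBR fluorescence drops
    as structure melts, so transitions are maxima of -dF/dT); peaks ranked
    by prominence, with a floor of ``min_prominence_fraction`` of the
    derivative range to ignore ripple. Returned ascending in temperature.
    A flat or featureless curve yields an empty list.
    """
    t = curve.temperature
    smooth = _fft_lowpass(curve.fluorescence, keep_fraction)
    deriv = -np.gradient(smooth, t)
    span = deriv.max() - deriv.min()
    scale = max(1.0, float(np.max(np.abs(curve.fluorescence))))
    if not np.isfinite(span) or span <= 1e-9 * scale:
        return []
    peaks, props = find_peaks(deriv, prominence=min_prominence_fraction * span)
    if len(peaks) == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:max_peaks]
    chosen = sorted(peaks[order])
    return [(float(t[i]), float(deriv[i] - deriv.min())) for i in chosen]


def melting_transitions_table(
    temperature: Sequence[float],
    replicate_fluorescence: pd.DataFrame,
    max_peaks: int = 2,
    **kwargs,
) -> pd.DataFrame:
    """Per-replicate transition detection summarized as mean +/- sd per peak.

    ``replicate_fluorescence`` holds one column per replicate on the shared
    temperature grid. Replicates are processed independently (no pooling
    before peak detection).
    """
    temperature = np.asarray(temperature, dtype=float)
    rows = []
    for col in replicate_fluorescence.columns:
        curve = MeltingCurve(temperature, replicate_fluorescence[col].to_numpy())
        for k, (tm, prom) in enumerate(
            melting_transitions(curve, max_peaks=max_peaks, **kwargs), start=1
        ):
            rows.append({"replicate": col, "transition": f"Tm{k}", "tm": tm,
                         "prominence": prom})
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        return pd.DataFrame(columns=["transition", "n", "tm_mean", "tm_sd"])
    agg = per_rep.groupby("transition")["tm"].agg(["count", "mean", "std"])
    agg.columns = ["n", "tm_mean", "tm_sd"]
    return agg.reset_index()
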