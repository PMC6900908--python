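"""Band power, regional aggregation, entrainment peak, and alpha laterality.

Powers are Welch estimates (4 s Hann windows, 50 % overlap, 0.25 Hz bins at
250 Hz) integrated over half-open bands [low, high), so the five canonical
bands partition 0.5-50 Hz without double counting the shared edges.  Powers
are linear (uV^2); regional values are arithmetic means of member channels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .montage import LI_LEFT, LI_RIGHT, Montage, default_montage
from .simulate import EegRecording

__all__ = [
    "BANDS", "welch_psd", "band_power", "band_power_table", "region_power",
    "region_power_table", "power_change", "peak_at_6hz", "laterality_index",
    "alpha_laterality",
]

#: Canonical EEG bands (Hz), half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

WINDOW_S = 4.0  # Welch segment length; 0.25 Hz resolution


def welch_psd(x: np.ndarray, fs: float, window_s: float = WINDOW_S):
    """Welch PSD (Hann, 50 % overlap) along the last axis; density units x^2/Hz."""
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < 2 * nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is shorter than two {window_s} s windows"
        )
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend="constant", axis=-1)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float],
               window_s: float = WINDOW_S) -> float | np.ndarray:
    """Welch PSD integrated over [low, high); non-negative, units x^2."""
    low, high = band
    f, pxx = welch_psd(np.asarray(x, float), fs, window_s)
    df = f[1] - f[0]
    mask = (f >= low) & (f < high)
    return np.sum(pxx[..., mask], axis=-1) * df


def band_power_table(rec: EegRecording, epoch: str,
                     bands: dict[str, tuple[float, float]] = BANDS,
                     window_s: float = WINDOW_S) -> pd.DataFrame:
    """Per-channel band powers for one labeled epoch (channels x bands)."""
    x = rec.epoch_data(epoch)
    f, pxx = welch_psd(x, rec.sample_rate, window_s)
    df = f[1] - f[0]
    out = {}
    for name, (low, high) in bands.items():
        mask = (f >= low) & (f < high)
        out[name] = np.sum(pxx[:, mask], axis=1) * df
    table = pd.DataFrame(out, index=list(rec.channels))
    table.index.name = "channel"
    table.attrs["epoch"] = epoch
    return table


def region_power(table: pd.DataFrame, region: str,
                 montage: Montage | None = None) -> pd.Series:
    """Arithmetic mean of the region's member-channel rows."""
    montage = montage or default_montage()
    members = list(montage.regions[region])
    return table.loc[members].mean(axis=0)


def region_power_table(table: pd.DataFrame,
                       montage: Montage | None = None) -> pd.DataFrame:
    """Region x band aggregates of a channel x band table."""
    montage = montage or default_montage()
    rows = {r: region_power(table, r, montage) for r in montage.regions}
    out = pd.DataFrame(rows).T
    out.index.name = "region"
    return out


def power_change(stim: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Elementwise stimulation - baseline power; indices must match."""
    if not stim.index.equals(baseline.index) or not stim.columns.equals(baseline.columns):
        raise ValueError("stimulation and baseline tables have mismatched layout")
    return stim - baseline


def peak_at_6hz(
    rec: EegRecording,
    stim_epoch: str = "stimulation",
    baseline_epoch: str = "baseline",
    target_hz: float = 6.0,
    montage: Montage | None = None,
    region: str = "Midline",
    window_s: float = WINDOW_S,
) -> float:
    """Entrainment peak: midline PSD at the bin nearest the target frequency,
    as a stimulation / baseline ratio (1.0 means no entrainment).
    """
    montage = montage or default_montage()
    idx = [rec.channels.index(c) for c in montage.regions[region]]

    def _midline_psd(epoch: str) -> tuple[np.ndarray, np.ndarray]:
        f, pxx = welch_psd(rec.epoch_data(epoch)[idx, :], rec.sample_rate, window_s)
        return f, pxx.mean(axis=0)

    f, stim_psd = _midline_psd(stim_epoch)
    _, base_psd = _midline_psd(baseline_epoch)
    df = f[1] - f[0]
    if df > 1.0:
        warnings.warn(f"frequency grid of {df:.2f} Hz is coarser than 1 Hz", stacklevel=2)
    bin_i = int(np.argmin(np.abs(f - target_hz)))
    if base_psd[bin_i] <= 0:
        raise ValueError("baseline PSD at the target bin is zero; ratio undefined")
    return float(stim_psd[bin_i] / base_psd[bin_i])


def laterality_index(left_power: float, right_power: float) -> float:
    """Alpha asymmetry LI = (L - R)/(L + R); positive = left-hemisphere dominance."""
    if left_power < 0 or right_power < 0:
        raise ValueError("powers must be non-negative")
    total = left_power + right_power
    if total == 0:
        raise ValueError("L + R = 0: laterality undefined")
    return float((left_power - right_power) / total)


def alpha_laterality(table: pd.DataFrame) -> float:
    """LI of alpha power over the lateral prefrontal+frontal channels."""
    left = float(table.loc[list(LI_LEFT), "alpha"].mean())
    right = float(table.loc[list(LI_RIGHT), "alpha"].mean())
    return laterality_index(left, right)
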