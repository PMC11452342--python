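"""Front-end feature extraction and data containers.

Three neural feature paths share one 50-ms time base: Gaussian-smoothed spike
counts, band-limited raw LFP (the local motor potential), and Welch band
log-powers in eight standard frequency bands.  Feature windows are aligned
causally: the feature at step k uses data ending at k * 50 ms, so downstream
one-step-ahead prediction never peeks forward.  All extraction is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .training import TimeSeriesPair

__all__ = [
    "RecordingBundle",
    "bin_and_smooth_spikes",
    "raw_lfp_feature",
    "lfp_band_log_powers",
    "LFP_BANDS",
    "load_timeseries",
    "save_timeseries",
]

#: standard LFP bands (Hz): delta through high gamma
LFP_BANDS = (
    ("delta", 0.1, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("low_beta", 12.0, 24.0),
    ("mid_beta", 24.0, 34.0),
    ("high_beta", 34.0, 55.0),
    ("low_gamma", 65.0, 95.0),
    ("high_gamma", 130.0, 170.0),
)


@dataclass
class RecordingBundle:
    """Raw recording: spike counts and/or LFP plus optional event markers."""

    spike_counts: np.ndarray | None = None  # (T_raw x channels) at spike_bin s
    spike_bin: float = 0.01
    lfp: np.ndarray | None = None  # (T_raw' x channels) at lfp_fs Hz
    lfp_fs: float = 1000.0
    event_times: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spike_bin <= 0 or self.lfp_fs <= 0:
            raise ValueError("sampling parameters must be positive")
        if self.spike_counts is not None:
            sc = np.asarray(self.spike_counts)
            if np.any(sc < 0) or not np.allclose(sc, np.round(sc)):
                raise ValueError("spike counts must be nonnegative integers")


def gaussian_kernel(sigma_bins: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian kernel truncated at +/- truncate * sigma, unit sum."""
    half = int(np.ceil(truncate * sigma_bins))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma_bins) ** 2)
    return k / k.sum()


def bin_and_smooth_spikes(
    counts: np.ndarray,
    bin_s: float = 0.010,
    sigma_s: float = 0.050,
    out_step_s: float = 0.050,
) -> np.ndarray:
    """Gaussian-smooth binned spike counts and downsample to the output step.

    ``counts`` is (T x channels) at ``bin_s`` resolution (10-ms bins by
    default); smoothing uses a Gaussian kernel of standard deviation
    ``sigma_s`` (50 ms) and every (out_step_s / bin_s)-th sample is retained,
    aligned to the end of each output step.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] == 1 and counts.size > counts.shape[1]:
        counts = counts.T
    if np.any(counts < 0):
        raise ValueError("negative spike counts")
    step = out_step_s / bin_s
    if abs(step - round(step)) > 1e-9:
        raise ValueError("bin width must divide the output step")
    step = int(round(step))
    kernel = gaussian_kernel(sigma_s / bin_s)
    sm = np.empty_like(counts)
    for j in range(counts.shape[1]):
        sm[:, j] = np.convolve(counts[:, j], kernel, mode="same")
    return sm[step - 1 :: step]


def raw_lfp_feature(lfp: np.ndarray, fs: float, out_fs: float = 20.0) -> np.ndarray:
    """Band-limited raw LFP resampled to the behavior rate (20 Hz).

    High-pass above 0.5 Hz (baseline removal) and low-pass below 10 Hz
    (antialiasing), both zero-phase, then downsampled.
    """
    if fs <= out_fs:
        raise ValueError("LFP sampling rate must exceed the output rate")
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[0] == 1 and lfp.size > lfp.shape[1]:
        lfp = lfp.T
    sos_hp = scipy.signal.butter(2, 0.5, "highpass", fs=fs, output="sos")
    sos_lp = scipy.signal.butter(4, 10.0, "lowpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos_hp, lfp, axis=0)
    x = scipy.signal.sosfiltfilt(sos_lp, x, axis=0)
    factor = fs / out_fs
    if abs(factor - round(factor)) < 1e-9:
        return x[int(round(factor)) - 1 :: int(round(factor))]
    up, down = (np.array([out_fs, fs]) / np.gcd(int(out_fs), int(fs))).astype(int)
    return scipy.signal.resample_poly(x, up, down, axis=0)


def lfp_band_log_powers(
    lfp: np.ndarray,
    fs: float,
    window_s: float = 0.300,
    step_s: float = 0.050,
    n_subwindows: int = 8,
) -> np.ndarray:
    """Welch band log-powers in sliding causal windows.

    Per 300-ms window (ending at each 50-ms step), a Welch spectrum with
    ``n_subwindows`` half-overlapping segments; the feature is the log of the
    mean power within each of the eight standard bands.  Output is
    (T x 8 * channels), ordered channel-major (all bands of channel 0 first).
    """
    if fs < 2 * LFP_BANDS[-1][2]:
        raise ValueError("sampling rate too low for the highest band")
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[0] == 1 and lfp.size > lfp.shape[1]:
        lfp = lfp.T
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win > lfp.shape[0]:
        raise ValueError("window exceeds data length")
    # n_subwindows half-overlapping segments tile the window:
    # win = nperseg + (n_subwindows - 1) * nperseg / 2
    nperseg = int(np.floor(2 * win / (n_subwindows + 1)))
    nfft = max(nperseg, int(2 ** np.ceil(np.log2(fs))))  # ~1 Hz grid
    n_ch = lfp.shape[1]
    starts = np.arange(win, lfp.shape[0] + 1, step) - win
    out = np.empty((len(starts), 8 * n_ch))
    for i, s in enumerate(starts):
        seg = lfp[s : s + win]
        freqs, pxx = scipy.signal.welch(
            seg, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft, axis=0
        )
        for c in range(n_ch):
            for b, (_, lo, hi) in enumerate(LFP_BANDS):
                sel = (freqs >= lo) & (freqs <= hi)
                if not sel.any():
                    sel = np.argmin(np.abs(freqs - 0.5 * (lo + hi)))
                out[i, c * 8 + b] = np.log(pxx[sel, c].mean() + 1e-300)
    return out


# ---------------------------------------------------------------------------
# containers on disk
# ---------------------------------------------------------------------------

def save_timeseries(path, data: TimeSeriesPair) -> None:
    """Write a neural/behavior pair to HDF5 (``.h5``) or CSV."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("Y", data=data.Y)
            f.create_dataset("Z", data=np.asarray(data.Z, dtype=float))
            f.create_dataset("mask", data=data.mask)
            f.attrs["dt"] = data.dt
        return
    cols = {f"y{j}": data.Y[:, j] for j in range(data.Y.shape[1])}
    cols.update({f"z{j}": np.asarray(data.Z)[:, j] for j in range(data.Z.shape[1])})
    cols["mask"] = data.mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def load_timeseries(path) -> TimeSeriesPair:
    """Read a neural/behavior pair from HDF5 or CSV (columns y*, z*, mask)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            return TimeSeriesPair(
                Y=f["Y"][...],
                Z=f["Z"][...],
                mask=f["mask"][...].astype(bool) if "mask" in f else None,
                dt=float(f.attrs.get("dt", 0.05)),
            )
    df = pd.read_csv(path)
    ycols = sorted([c for c in df.columns if c.startswith("y")], key=lambda c: int(c[1:]))
    zcols = sorted([c for c in df.columns if c.startswith("z")], key=lambda c: int(c[1:]))
    mask = df["mask"].to_numpy().astype(bool) if "mask" in df.columns else None
    return TimeSeriesPair(Y=df[ycols].to_numpy(), Z=df[zcols].to_numpy(), mask=mask)
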