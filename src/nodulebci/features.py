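"""Time-frequency and cross-channel features of multichannel EEG epochs.

Single-channel features come from the Hilbert-Huang view of the MEMD
decomposition: each IMF's analytic signal yields an instantaneous amplitude
a_k(t), unwrapped phase theta_k(t), and instantaneous frequency
w_k(t) = d(theta)/dt.  Squared amplitudes are accumulated on a frequency
grid to form the Hilbert spectrum H(w, t); integrating H over a frequency
band gives the band energy over time (IES), integrating over time gives the
marginal spectrum MS(w).  Hjorth mobility, sqrt(Var(y')/Var(y)), summarises
spectral width in the time domain.

Cross-channel features between channel pairs: cross-sample entropy (negative
log conditional template-match probability, Chebyshev distance), the
phase-locking value Q = |mean exp(j(theta1 - theta2))|, and the analogous
frequency-locking value S.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert as _hilbert

from .containers import Epoch
from .errors import DataError, ValidationError
from .memd import IMFSet, memd

__all__ = [
    "AnalyticIMF",
    "SpectralSummary",
    "FeatureConfig",
    "hilbert_analytic",
    "hilbert_spectrum",
    "band_energy_ies",
    "marginal_spectrum",
    "hjorth_mobility",
    "cross_sample_entropy",
    "phase_locking_value",
    "frequency_locking_value",
    "time_freq_stats",
    "assemble_features",
    "extract_epoch_features",
    "feature_matrix",
    "EEG_BANDS",
]

#: Canonical EEG bands in Hz (half-open [lo, hi) on the grid).
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}


@dataclass
class AnalyticIMF:
    """Analytic-signal view of one IMF channel series.

    ``valid`` is False for an all-zero input, whose phase is undefined.
    inst_freq is in rad/s (divide by 2*pi for Hz).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray
    fs: float
    valid: bool = True


def hilbert_analytic(x: np.ndarray, fs: float) -> AnalyticIMF:
    """Analytic signal Z = u + jH[u] of a single series.

    The Hilbert transform is the Cauchy-principal-value convolution with
    1/(pi t), computed here through the one-sided-spectrum construction.
    The amplitude is |Z|, the phase is arg Z unwrapped, and the
    instantaneous frequency is the central-difference derivative of the
    phase times fs.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValidationError("need a 1-D series of length >= 16")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples")
    if np.allclose(x, 0.0):
        z = np.zeros(len(x))
        return AnalyticIMF(amplitude=z, phase=z.copy(), inst_freq=z.copy(),
                           fs=fs, valid=False)
    z = _hilbert(x)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    inst_freq = np.gradient(phase) * fs
    return AnalyticIMF(amplitude=amplitude, phase=phase, inst_freq=inst_freq,
                       fs=fs, valid=True)


@dataclass
class SpectralSummary:
    """Hilbert spectrum on a fixed grid plus its integrals.

    H has shape (n_bins, n_samples) and holds squared amplitude; freq_edges
    are the bin edges in Hz; dt = 1/fs.  n_out_of_grid counts samples whose
    instantaneous frequency fell outside the grid and was accumulated into
    the boundary bin.
    """

    H: np.ndarray
    freq_edges: np.ndarray
    dt: float
    n_out_of_grid: int = 0

    @property
    def bin_width(self) -> float:
        return float(self.freq_edges[1] - self.freq_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    def total_mass(self) -> float:
        return float(self.H.sum() * self.bin_width * self.dt)


def default_freq_grid(lo: float = 0.5, hi: float = 48.0,
                      width: float = 0.5) -> np.ndarray:
    """Bin edges of the 0.5 Hz analysis grid covering [lo, hi].

    Bins are centred on the half-Hz multiples (edges offset by width/2), so
    a tone at a round frequency falls inside one bin instead of on an edge,
    and every bin centre falls in exactly one of the half-open EEG bands.
    """
    return np.arange(lo - width / 2, hi, width)


def hilbert_spectrum(
    analytic_imfs: list[AnalyticIMF],
    fs: float,
    freq_edges: np.ndarray | None = None,
) -> SpectralSummary:
    """Accumulate a_k(t)^2 into the grid cell containing w_k(t)/2pi.

    The squared-amplitude convention makes the band integral (IES) an energy
    and keeps the marginal spectrum consistent with it.  Out-of-grid
    instantaneous frequencies land in the nearest boundary cell and are
    counted.
    """
    if freq_edges is None:
        freq_edges = default_freq_grid()
    freq_edges = np.asarray(freq_edges, dtype=float)
    n_bins = len(freq_edges) - 1
    if not analytic_imfs:
        raise ValidationError("no analytic IMFs given")
    n_t = len(analytic_imfs[0].amplitude)
    H = np.zeros((n_bins, n_t))
    n_out = 0
    t_idx = np.arange(n_t)
    for a in analytic_imfs:
        if not a.valid:
            continue
        f_hz = a.inst_freq / (2.0 * np.pi)
        raw_bin = np.searchsorted(freq_edges, f_hz, side="right") - 1
        n_out += int(np.sum((raw_bin < 0) | (raw_bin >= n_bins)))
        bins = np.clip(raw_bin, 0, n_bins - 1)
        np.add.at(H, (bins, t_idx), a.amplitude**2)
    return SpectralSummary(H=H, freq_edges=freq_edges, dt=1.0 / fs,
                           n_out_of_grid=n_out)


def band_energy_ies(spec: SpectralSummary,
                    band: tuple[float, float]) -> np.ndarray:
    """Per-sample energy IES(t): integral of H over the band [w1, w2).

    Band membership is decided by bin center, so bands whose edges align
    with grid edges tile the grid without overlap and their IES values sum
    exactly to the full-grid integral.
    """
    w1, w2 = band
    if w2 <= w1:
        raise ValidationError("band must be increasing")
    centers = spec.bin_centers
    sel = (centers >= w1) & (centers < w2)
    return spec.H[sel].sum(axis=0) * spec.bin_width


def marginal_spectrum(spec: SpectralSummary) -> np.ndarray:
    """MS(w): row-wise time integral of the Hilbert spectrum."""
    return spec.H.sum(axis=1) * spec.dt


def hjorth_mobility(y: np.ndarray, fs: float) -> float:
    """sqrt(Var(y')/Var(y)) with y' the first differences scaled by fs.

    For a sinusoid of frequency f << fs this tends to 2*pi*f rad/s.  A
    constant series has no defined mobility and returns NaN (flagged, never
    silently zero).
    """
    y = np.asarray(y, dtype=float)
    v = np.var(y)
    if v == 0:
        return float("nan")
    dy = np.diff(y) * fs
    return float(np.sqrt(np.var(dy) / v))


def cross_sample_entropy(
    u: np.ndarray,
    v: np.ndarray,
    m: int = 2,
    r_frac: float = 0.2,
    r: float | None = None,
) -> float:
    """Cross-sample entropy C(m, R) = -ln(B^{m+1}(R) / B^m(R)).

    Templates of length m (and m+1) are slid over both series; B^m is the
    mean fraction of template pairs within Chebyshev distance R (the max
    over template offsets of the absolute sample difference).  R defaults to
    ``r_frac`` times the pooled standard deviation of the two series, so the
    statistic is symmetric in its arguments.  Both template lengths use the
    same N - m template count.  Returns NaN (flagged) when no templates
    match at either length.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim != 1 or v.ndim != 1 or len(u) != len(v):
        raise ValidationError("u and v must be 1-D with equal length")
    n = len(u)
    if n < m + 2:
        raise ValidationError(f"series too short for m={m}")
    if r is None:
        r = r_frac * math.sqrt((np.var(u) + np.var(v)) / 2.0)
    U = sliding_window_view(u, m + 1)   # (n - m, m + 1)
    V = sliding_window_view(v, m + 1)
    diff = np.abs(U[:, None, :] - V[None, :, :])
    d_m = diff[:, :, :m].max(axis=-1)
    d_m1 = diff.max(axis=-1)
    b_m = float((d_m <= r).mean())
    b_m1 = float((d_m1 <= r).mean())
    if b_m == 0.0 or b_m1 == 0.0:
        return float("nan")
    return -math.log(b_m1 / b_m)


def phase_locking_value(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Q = |mean exp(j(theta1 - theta2))| in [0, 1].

    1 means a constant phase offset between the channels; independent
    uniform phases give a Rayleigh-small value of order 1/sqrt(N).
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape or theta1.ndim != 1:
        raise ValidationError("phase series must be 1-D with equal length")
    return float(np.abs(np.mean(np.exp(1j * (theta1 - theta2)))))


def frequency_locking_value(
    w1: np.ndarray, w2: np.ndarray, dt: float
) -> float:
    """S = |mean exp(j(w1 - w2) dt)| for instantaneous-frequency series."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape or w1.ndim != 1:
        raise ValidationError("frequency series must be 1-D with equal length")
    return float(np.abs(np.mean(np.exp(1j * (w1 - w2) * dt))))


# ---------------------------------------------------------------------------
# Per-epoch feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Layout-defining knobs for the per-epoch feature vector.

    pair_channels selects the channels whose pairs get PLV/FLV/cross-SampEn;
    the default 'frontal' takes the first ``n_frontal`` channels of the
    montage (the target response is prefrontal-dominant), 'all' takes every
    pair.  phase_band is the band of interest whose IMFs (by mean
    instantaneous frequency) are summed to form the signal used for pair
    features; the P300 is a delta/theta transient, hence 0.5-8 Hz.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EEG_BANDS))
    mob_window_s: float = 0.25
    response_window_ms: tuple[float, float] = (280.0, 320.0)
    pair_channels: str | list[int] = "frontal"
    n_frontal: int = 3
    phase_band: tuple[float, float] = (0.5, 8.0)
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    memd_K: int = 16
    memd_max_imfs: int = 6
    memd_seed: int = 0
    impute_value: float = 0.0

    def pair_indices(self, n_channels: int) -> list[tuple[int, int]]:
        if self.pair_channels == "all":
            chans = list(range(n_channels))
        elif self.pair_channels == "frontal":
            chans = list(range(min(self.n_frontal, n_channels)))
        else:
            chans = list(self.pair_channels)
        return [(a, b) for i, a in enumerate(chans) for b in chans[i + 1:]]


def time_freq_stats(
    epoch: Epoch,
    spectra: list[SpectralSummary],
    config: FeatureConfig,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-channel (mean, sd) summaries of time- and frequency-domain
    descriptors.

    Time domain (F_t): the raw signal over the epoch, Hjorth mobility in
    non-overlapping windows, and the mean amplitude inside the
    stimulus-locked response window (280-320 ms by default — the latency
    range where the target response peaks and the amplitude difference
    separates the two classes).  Frequency domain (F_s): each band's IES
    time series, and the marginal spectrum over the grid.  Every descriptor
    is reduced to its mean and standard deviation.
    """
    if not config.bands:
        raise ValidationError("empty band set")
    f_t: dict[str, float] = {}
    f_s: dict[str, float] = {}
    n_win = max(4, int(round(config.mob_window_s * epoch.fs)))
    r0_ms, r1_ms = config.response_window_ms
    i0 = int(round((r0_ms - epoch.t0_offset_ms) / 1000.0 * epoch.fs))
    i1 = int(round((r1_ms - epoch.t0_offset_ms) / 1000.0 * epoch.fs)) + 1
    resp_ok = 0 <= i0 < i1 <= epoch.n_samples
    for ch in range(epoch.n_channels):
        y = epoch.data[ch]
        name = f"ch{ch}"
        f_t[f"{name}_sig_mean"] = float(y.mean())
        f_t[f"{name}_sig_sd"] = float(y.std())
        f_t[f"{name}_resp_amp"] = (
            float(y[i0:i1].mean()) if resp_ok else float("nan")
        )
        mobs = [
            hjorth_mobility(y[i: i + n_win], epoch.fs)
            for i in range(0, len(y) - n_win + 1, n_win)
        ]
        mobs_arr = np.asarray(mobs)
        if len(mobs_arr) == 0 or np.any(np.isnan(mobs_arr)):
            f_t[f"{name}_mob_mean"] = float("nan")
            f_t[f"{name}_mob_sd"] = float("nan")
        else:
            f_t[f"{name}_mob_mean"] = float(mobs_arr.mean())
            f_t[f"{name}_mob_sd"] = float(mobs_arr.std())
        spec = spectra[ch]
        for band_name, band in config.bands.items():
            ies = band_energy_ies(spec, band)
            f_s[f"{name}_ies_{band_name}_mean"] = float(ies.mean())
            f_s[f"{name}_ies_{band_name}_sd"] = float(ies.std())
        ms = marginal_spectrum(spec)
        f_s[f"{name}_ms_mean"] = float(ms.mean())
        f_s[f"{name}_ms_sd"] = float(ms.std())
    return f_t, f_s


def assemble_features(
    blocks: list[tuple[str, dict[str, float]]],
    impute_value: float = 0.0,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate named feature blocks into one vector with a fixed layout.

    Order is [F_t | F_s | Q | S | cross-SampEn] (block order as given).
    Flagged (NaN) entries are imputed with ``impute_value`` and a parallel
    0/1 indicator column per flaggable block entry is appended, so the
    classifier can distinguish "undefined" from a genuine value.
    """
    names: list[str] = []
    values: list[float] = []
    flags: list[tuple[str, float]] = []
    for block_name, block in blocks:
        for key, val in block.items():
            names.append(f"{block_name}_{key}")
            if isinstance(val, float) and math.isnan(val):
                values.append(impute_value)
                flags.append((f"flag_{block_name}_{key}", 1.0))
            else:
                values.append(float(val))
                flags.append((f"flag_{block_name}_{key}", 0.0))
    # indicators only for entries that can be undefined
    for fname, fval in flags:
        flaggable = (
            fname.startswith(("flag_q_", "flag_s_", "flag_xse_"))
            or (fname.startswith("flag_ft_")
                and ("_mob_" in fname or "_resp_" in fname))
        )
        if flaggable:
            names.append(fname)
            values.append(fval)
    return np.asarray(values), names


def extract_epoch_features(
    epoch: Epoch,
    config: FeatureConfig | None = None,
    imfset: IMFSet | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Full per-epoch feature vector from the MEMD + Hilbert-Huang chain.

    Runs MEMD on the epoch (unless an IMFSet is supplied), builds per-channel
    analytic IMFs and Hilbert spectra, computes the (mean, sd) time/frequency
    summaries, and adds PLV/FLV/cross-SampEn for the configured channel
    pairs on the band-of-interest IMF sum.
    """
    config = config or FeatureConfig()
    if imfset is None:
        imfset = memd(epoch.data, K=config.memd_K,
                      max_imfs=config.memd_max_imfs, seed=config.memd_seed)
    n_ch = epoch.n_channels
    analytic: list[list[AnalyticIMF]] = [[] for _ in range(n_ch)]
    for k in range(imfset.n_imfs):
        for ch in range(n_ch):
            analytic[ch].append(hilbert_analytic(imfset.imfs[k, ch], epoch.fs))
    spectra = []
    for ch in range(n_ch):
        if analytic[ch]:
            spectra.append(hilbert_spectrum(analytic[ch], epoch.fs))
        else:
            edges = default_freq_grid()
            spectra.append(SpectralSummary(
                H=np.zeros((len(edges) - 1, epoch.n_samples)),
                freq_edges=edges, dt=1.0 / epoch.fs))

    f_t, f_s = time_freq_stats(epoch, spectra, config)

    # band-of-interest signal per channel: sum of IMFs whose mean
    # instantaneous frequency falls in phase_band (fallback: slowest IMF)
    lo, hi = config.phase_band
    band_analytic: list[AnalyticIMF | None] = []
    for ch in range(n_ch):
        parts = []
        for k, a in enumerate(analytic[ch]):
            if not a.valid:
                continue
            interior = slice(len(a.inst_freq) // 10, -len(a.inst_freq) // 10 or None)
            f_mean = float(np.mean(a.inst_freq[interior])) / (2 * np.pi)
            if lo <= f_mean < hi:
                parts.append(imfset.imfs[k, ch])
        if not parts and imfset.n_imfs > 0:
            parts = [imfset.imfs[-1, ch]]
        if parts:
            summed = np.sum(parts, axis=0)
            a = hilbert_analytic(summed, epoch.fs)
            band_analytic.append(a if a.valid else None)
        else:
            band_analytic.append(None)

    q_block: dict[str, float] = {}
    s_block: dict[str, float] = {}
    x_block: dict[str, float] = {}
    for a_idx, b_idx in config.pair_indices(n_ch):
        key = f"ch{a_idx}-ch{b_idx}"
        aa, bb = band_analytic[a_idx], band_analytic[b_idx]
        if aa is None or bb is None:
            q_block[key] = float("nan")
            s_block[key] = float("nan")
            x_block[key] = float("nan")
            continue
        q_block[key] = phase_locking_value(aa.phase, bb.phase)
        s_block[key] = frequency_locking_value(aa.inst_freq, bb.inst_freq,
                                               1.0 / epoch.fs)
        x_block[key] = cross_sample_entropy(
            epoch.data[a_idx], epoch.data[b_idx],
            m=config.sampen_m, r_frac=config.sampen_r_frac)

    return assemble_features(
        [("ft", f_t), ("fs", f_s), ("q", q_block), ("s", s_block),
         ("xse", x_block)],
        impute_value=config.impute_value,
    )


def feature_matrix(
    epochs: list[Epoch],
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-epoch features into (X, y, layout names).

    All epochs must produce the same layout; a mismatch means the epochs do
    not share channel count or configuration and is refused.
    """
    if not epochs:
        raise ValidationError("no epochs given")
    config = config or FeatureConfig()
    rows = []
    names_ref: list[str] | None = None
    y = np.array([ep.is_target for ep in epochs], dtype=int)
    for ep in epochs:
        vec, names = extract_epoch_features(ep, config)
        if names_ref is None:
            names_ref = names
        elif names != names_ref:
            raise DataError("feature layout mismatch across epochs")
        rows.append(vec)
    return np.vstack(rows), y, names_ref or []
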