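"""Per-channel EEG feature extraction on the 5-second instance clock.

For each instance tick ``t`` (starting at t = 5 s), 34 features are
computed per channel from windows *ending at* ``t``:

====================  =====================================================
signal energy (SE)    mean squared amplitude over w = 1280 samples (5 s)
STE / LTE energy      same over w = 2304 (9 s) and w = 46080 (180 s)
accumulated energy    running sum of SE values plus a per-file random offset
8 DWT band energies   db4 level-4 sub-band energies for 4 nominal bands
                      x {STE, LTE} windows
max Lyapunov          Rosenstein nearest-neighbour divergence slope (5-s win)
correlation dim       Grassberger-Procaccia correlation-integral slope
6 moments             mean / skewness / kurtosis x {STE, LTE}
10 SBP                band power in 0.5-4, 4-8, 8-13, 13-30, 30-48 Hz
                      x {STE, LTE}
4 SEF                 spectral edge frequency 50% / 90% x {STE, LTE}
====================  =====================================================

giving 204 columns for the 6-channel layout.  Ticks earlier than a full
window use a growing window over all samples available up to ``t``, so the
matrix is dense from the first instance.

Nominal DWT bands: a level-4 dyadic decomposition at 256 Hz yields
sub-bands 0-8 (A4), 8-16 (D4), 16-32 (D3), 32-64 (D2) and 64-128 Hz (D1);
the two lowest are merged into the lowest nominal band, so the four
reported bands are A4+D4, D3, D2 and D1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import periodogram

from . import labeling
from .eeg_io import EEGRecord, FeatureMatrix, feature_column_names
from .exceptions import ConfigurationError, ValidationError, WindowError

SBP_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 48.0))
SEF_PERCENTS = (50, 90)


@dataclass
class FeatureConfig:
    """Window lengths and estimator parameters for feature extraction."""

    w_se: int = 1280
    w_ste: int = 2304
    w_lte: int = 46080
    wavelet: str = "db4"
    dwt_level: int = 4
    embed_dim: int = 10
    delay: int = 4
    theiler: int = 20
    lyap_fit_steps: int = 10
    cdim_n_radii: int = 10
    step_s: float = 5.0
    required_channels: int = 6
    ae_offset_scale: float = 10.0
    sbp_bands: tuple = SBP_BANDS
    sef_percents: tuple = SEF_PERCENTS


# ---------------------------------------------------------------------------
# Elementary features


def signal_energy(x, w: int) -> float:
    """Mean squared amplitude over a window of exactly ``w`` samples."""
    x = np.asarray(x, dtype=float)
    if w <= 0:
        raise ValidationError("window length must be positive")
    if len(x) != w:
        raise WindowError(f"expected a window of {w} samples, got {len(x)}")
    return float(np.mean(x ** 2))


def accumulated_energy(energy_series, offset: float = 0.0) -> np.ndarray:
    """Running sum of successive signal-energy values plus a constant offset."""
    e = np.asarray(energy_series, dtype=float)
    if (e < 0).any():
        raise ValidationError("signal energies must be non-negative")
    return offset + np.cumsum(e)


def dwt_subband_signals(x, wavelet: str = "db4", level: int = 4):
    """Reconstructed per-sub-band signals [A_L, D_L, ..., D_1], same length as x."""
    x = np.asarray(x, dtype=float)
    filt_len = pywt.Wavelet(wavelet).dec_len
    if pywt.dwt_max_level(len(x), filt_len) < level:
        raise WindowError(
            f"window of {len(x)} samples too short for a level-{level} "
            f"{wavelet} decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    out = []
    for i in range(len(coeffs)):
        sel = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        out.append(pywt.waverec(sel, wavelet)[: len(x)])
    return out


def dwt_band_energies(x, fs: float = 256.0, window_role: str = "lte",
                      wavelet: str = "db4", level: int = 4,
                      w_ste: int = 2304, w_lte: int = 46080) -> np.ndarray:
    """Energies of the 4 nominal frequency bands over the STE or LTE window.

    The window used for the energy average is the trailing ``w`` samples
    of ``x`` (all of ``x`` if shorter), with ``w`` set by ``window_role``.
    """
    if window_role not in ("ste", "lte"):
        raise ValidationError(f"window_role must be 'ste' or 'lte', got "
                              f"{window_role!r}")
    subbands = dwt_subband_signals(x, wavelet, level)
    # merge A4 + D4 into the lowest nominal band
    bands = [subbands[0] + subbands[1]] + subbands[2:]
    w = {"ste": w_ste, "lte": w_lte}[window_role]
    w = min(w, len(np.asarray(x)))
    return np.array([float(np.mean(b[-w:] ** 2)) for b in bands])


def _psd(x, fs: float):
    """One-sided Hann-tapered periodogram; accepts 1-D or (rows, n) input."""
    return periodogram(np.asarray(x, dtype=float), fs=fs, window="hann",
                       axis=-1)


def spectral_band_power(x, fs: float, band) -> float:
    """Integrated power spectral density over ``[f_lo, f_hi)``."""
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValidationError(f"band {band} outside [0, Nyquist={fs / 2}]")
    freqs, psd = _psd(x, fs)
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return float(np.sum(psd[mask]) * df)


def spectral_edge_frequency(x, fs: float, percent: float,
                            return_flag: bool = False):
    """Lowest frequency F with ``percent``% of the 0.5 Hz-Nyquist power below F."""
    freqs, psd = _psd(x, fs)
    mask = freqs >= 0.5
    cum = np.cumsum(psd[mask])
    total = cum[-1] if len(cum) else 0.0
    if total <= 0:
        return (0.5, True) if return_flag else 0.5
    idx = int(np.searchsorted(cum, percent / 100.0 * total))
    idx = min(idx, len(cum) - 1)
    value = float(freqs[mask][idx])
    return (value, False) if return_flag else value


def moments(x, return_flag: bool = False):
    """First, standardized third and standardized fourth moments.

    Kurtosis is the plain standardized fourth moment (3 for a Gaussian).
    Zero-variance windows yield skewness = kurtosis = 0 with the
    degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise WindowError("empty window")
    mean = float(np.mean(x))
    c = x - mean
    m2 = float(np.mean(c ** 2))
    if m2 <= 0:
        return (mean, 0.0, 0.0, True) if return_flag else (mean, 0.0, 0.0)
    skew = float(np.mean(c ** 3) / m2 ** 1.5)
    kurt = float(np.mean(c ** 4) / m2 ** 2)
    return (mean, skew, kurt, False) if return_flag else (mean, skew, kurt)


# ---------------------------------------------------------------------------
# Non-linear dynamics


def _embed(x, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 1:
        raise WindowError("window too short for the requested embedding")
    idx = np.arange(n)[:, None] + delay * np.arange(dim)[None, :]
    return x[idx]


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    g = points @ points.T
    sq = np.diag(g).copy()
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2, out=d2)


def _sq_dist_matrix_banded(points: np.ndarray, theiler: int) -> np.ndarray:
    """Squared pair distances with the Theiler band (|i-j| <= theiler) set to inf.

    Computed in float32: the matrix only feeds nearest-neighbour selection
    and radius counts, where sub-ppm distance error is immaterial.
    """
    p = points.astype(np.float32)
    g = p @ p.T
    sq = np.einsum("ij,ij->i", p, p)
    d2 = sq[:, None] + sq[None, :]
    d2 -= 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    n = len(p)
    for off in range(-theiler, theiler + 1):
        np.fill_diagonal(d2[max(0, -off):, max(0, off):], np.inf)
    return d2


def max_lyapunov(x, embed_dim: int = 10, delay: int = 4, theiler: int = 20,
                 fit_steps: int = 10) -> float:
    """Largest-Lyapunov estimate via nearest-neighbour divergence (Rosenstein).

    Embeds the window, pairs each point with its nearest neighbour outside
    a Theiler exclusion window, tracks the mean log separation over
    ``fit_steps`` forward steps and returns the least-squares slope
    (nats per sample step).
    """
    x = np.asarray(x, dtype=float)
    min_len = (embed_dim - 1) * delay + theiler + 10
    if len(x) < min_len:
        raise WindowError(f"need at least {min_len} samples, got {len(x)}")
    if np.ptp(x) == 0:
        return 0.0
    pts = _embed(x, embed_dim, delay)
    d2 = _sq_dist_matrix_banded(pts, theiler)
    return _lyap_from_distances(pts, d2, fit_steps)


def _lyap_from_distances(pts: np.ndarray, d2: np.ndarray,
                         fit_steps: int) -> float:
    # neighbour selection uses the float32 matrix; the tracked divergence
    # distances are recomputed in float64, where cancellation matters
    n = len(d2)
    nn = np.argmin(d2, axis=1)
    scale = float(np.std(pts))
    floor = max(1e-300, 1e-12 * scale)
    i_idx = np.arange(n)
    steps = np.arange(fit_steps + 1)
    mean_log = np.empty(len(steps))
    for k in steps:
        valid = (i_idx + k < n) & (nn + k < n)
        diff = pts[i_idx[valid] + k] - pts[nn[valid] + k]
        dk = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        mean_log[k] = np.mean(np.log(np.maximum(dk, floor)))
    return float(np.polyfit(steps, mean_log, 1)[0])


def correlation_dimension(x, embed_dim: int = 10, delay: int = 4,
                          radii=None, theiler: int = 20,
                          n_radii: int = 10, min_pairs: int = 10,
                          return_flag: bool = False):
    """Correlation-dimension estimate (Grassberger-Procaccia).

    The correlation integral C(r) is the fraction of Theiler-separated
    point pairs closer than r; the estimate is the least-squares slope of
    log C(r) against log r over radii with enough pairs.  Degenerate
    windows (or radii ranges with no usable scaling region) return 0 with
    the flag set.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return (0.0, True) if return_flag else 0.0
    pts = _embed(x, embed_dim, delay)
    n = len(pts)
    if n < 100:
        raise WindowError(f"need >= 100 embedded points, got {n}")
    if radii is None:
        sigma = float(np.std(x))
        radii = sigma * np.logspace(-2, 0, n_radii)
    d2 = _sq_dist_matrix_banded(pts, theiler)
    slope, flag = _cdim_from_distances(d2, np.asarray(radii, dtype=float),
                                       theiler, min_pairs)
    return (slope, flag) if return_flag else slope


def _cdim_from_distances(d2: np.ndarray, radii: np.ndarray, theiler: int,
                         min_pairs: int):
    n = len(d2)
    # banded entries are inf and never counted; each unordered pair twice
    banded = (2 * theiler + 1) * n - theiler * (theiler + 1)
    total = (n * n - banded) // 2
    if total < min_pairs:
        return 0.0, True
    counts = np.array([np.count_nonzero(d2 < np.float32(r * r)) // 2
                       for r in radii])
    c = counts / total
    valid = (counts >= min_pairs) & (c < 1.0)
    if valid.sum() < 2:
        return 0.0, True
    slope = float(np.polyfit(np.log(radii[valid]), np.log(c[valid]), 1)[0])
    return slope, False


# ---------------------------------------------------------------------------
# Full matrix extraction


def _window_bounds(ends: np.ndarray, w: int) -> np.ndarray:
    return np.maximum(ends - w, 0)


def _windowed_mean(csum: np.ndarray, starts, ends) -> np.ndarray:
    return (csum[ends] - csum[starts]) / (ends - starts)


def _grouped_psd_features(x, starts, ends, fs, sbp_bands, sef_percents,
                          chunk: int = 64):
    """SBP and SEF values for many trailing windows, batched by window length.

    Returns (sbp, sef): sbp has shape (n_ticks, n_bands), sef shape
    (n_ticks, n_percents).
    """
    n_ticks = len(ends)
    sbp = np.empty((n_ticks, len(sbp_bands)))
    sef = np.empty((n_ticks, len(sef_percents)))
    lengths = ends - starts
    for length in np.unique(lengths):
        rows = np.flatnonzero(lengths == length)
        for lo in range(0, len(rows), chunk):
            sel = rows[lo:lo + chunk]
            windows = np.stack([x[starts[r]:ends[r]] for r in sel])
            freqs, psd = _psd(windows, fs)
            df = freqs[1] - freqs[0]
            for bi, (f_lo, f_hi) in enumerate(sbp_bands):
                m = (freqs >= f_lo) & (freqs < f_hi)
                sbp[sel, bi] = psd[:, m].sum(axis=1) * df
            m05 = freqs >= 0.5
            cum = np.cumsum(psd[:, m05], axis=1)
            total = cum[:, -1]
            f05 = freqs[m05]
            for pi, pct in enumerate(sef_percents):
                idx = np.array([int(np.searchsorted(cum[r], pct / 100.0 * total[r]))
                                for r in range(len(sel))])
                idx = np.minimum(idx, len(f05) - 1)
                vals = f05[idx]
                vals[total <= 0] = 0.5
                sef[sel, pi] = vals
    return sbp, sef


def _central_moments(x, starts, ends):
    """mean, skewness, kurtosis per trailing window via cumulative power sums."""
    csums = [np.concatenate([[0.0], np.cumsum(x ** p)]) for p in (1, 2, 3, 4)]
    n = (ends - starts).astype(float)
    s1, s2, s3, s4 = (c[ends] - c[starts] for c in csums)
    m = s1 / n
    m2 = s2 / n - m ** 2
    m3 = s3 / n - 3 * m * s2 / n + 2 * m ** 3
    m4 = s4 / n - 4 * m * s3 / n + 6 * m ** 2 * s2 / n - 3 * m ** 4
    m2 = np.maximum(m2, 0.0)
    pos = m2 > 0
    skew = np.zeros_like(m)
    kurt = np.zeros_like(m)
    skew[pos] = m3[pos] / m2[pos] ** 1.5
    kurt[pos] = m4[pos] / m2[pos] ** 2
    return m, skew, kurt


def extract_feature_matrix(record: EEGRecord, annotations=None,
                           config: FeatureConfig = None, seed: int = 0,
                           allow_channel_mismatch: bool = False
                           ) -> FeatureMatrix:
    """Extract the full instance x feature matrix from a (preprocessed) record.

    One instance per ``step_s`` (default 5 s) tick starting at the first
    tick; all windows end at the tick.  The accumulated-energy offset is
    drawn once per file as U(0, ``ae_offset_scale`` x median SE) from
    ``seed``.  Labels come from the annotation seizure intervals (all
    inter-ictal if ``annotations`` is None).
    """
    cfg = config or FeatureConfig()
    if record.n_channels != cfg.required_channels and not allow_channel_mismatch:
        raise ConfigurationError(
            f"expected {cfg.required_channels} channels, got "
            f"{record.n_channels}; pass allow_channel_mismatch=True to override")

    fs = record.fs
    times = labeling.instance_times(record.duration_s, cfg.step_s)
    if len(times) == 0:
        raise WindowError("record shorter than one instance step")
    ends = np.round(times * fs).astype(int)
    n_ticks = len(times)

    rng = np.random.default_rng(seed)
    # per-file AE offset, shared across channels
    se_all = []
    csum2_per_ch = []
    for x in record.samples:
        c2 = np.concatenate([[0.0], np.cumsum(x ** 2)])
        csum2_per_ch.append(c2)
        s = _window_bounds(ends, cfg.w_se)
        se_all.append(_windowed_mean(c2, s, ends))
    ae_offset = float(rng.uniform(0.0, cfg.ae_offset_scale *
                                  np.median(np.concatenate(se_all))))

    blocks = []
    for ch, x in enumerate(record.samples):
        c2 = csum2_per_ch[ch]
        s_se = _window_bounds(ends, cfg.w_se)
        s_ste = _window_bounds(ends, cfg.w_ste)
        s_lte = _window_bounds(ends, cfg.w_lte)

        se = se_all[ch]
        ste = _windowed_mean(c2, s_ste, ends)
        lte = _windowed_mean(c2, s_lte, ends)
        ae = accumulated_energy(se, ae_offset)

        dwt_vals = np.empty((n_ticks, 8))
        lyap = np.empty(n_ticks)
        cdim = np.empty(n_ticks)
        for i in range(n_ticks):
            win_lte = x[s_lte[i]:ends[i]]
            win_ste = x[s_ste[i]:ends[i]]
            try:
                e_ste = dwt_band_energies(win_ste, fs, "ste", cfg.wavelet,
                                          cfg.dwt_level, cfg.w_ste, cfg.w_lte)
                e_lte = dwt_band_energies(win_lte, fs, "lte", cfg.wavelet,
                                          cfg.dwt_level, cfg.w_ste, cfg.w_lte)
            except WindowError:
                e_ste = e_lte = np.zeros(4)
            dwt_vals[i, 0::2] = e_ste
            dwt_vals[i, 1::2] = e_lte

            win_se = x[s_se[i]:ends[i]]
            min_len = (cfg.embed_dim - 1) * cfg.delay + cfg.theiler + 10
            if len(win_se) < min_len or np.ptp(win_se) == 0:
                lyap[i] = 0.0
                cdim[i] = 0.0
            else:
                # one embedded distance matrix feeds both nonlinear features
                pts = _embed(win_se, cfg.embed_dim, cfg.delay)
                d2 = _sq_dist_matrix_banded(pts, cfg.theiler)
                lyap[i] = _lyap_from_distances(pts, d2, cfg.lyap_fit_steps)
                sigma = float(np.std(win_se))
                radii = sigma * np.logspace(-2, 0, cfg.cdim_n_radii)
                cdim[i], _ = _cdim_from_distances(d2, radii, cfg.theiler, 10)

        mom = {}
        for role, starts in (("ste", s_ste), ("lte", s_lte)):
            mom[role] = _central_moments(x, starts, ends)
        sbp_ste, sef_ste = _grouped_psd_features(x, s_ste, ends, fs,
                                                 cfg.sbp_bands, cfg.sef_percents)
        sbp_lte, sef_lte = _grouped_psd_features(x, s_lte, ends, fs,
                                                 cfg.sbp_bands, cfg.sef_percents)

        cols = [se, ste, lte, ae]
        for b in range(4):
            cols += [dwt_vals[:, 2 * b], dwt_vals[:, 2 * b + 1]]
        cols += [lyap, cdim]
        for mi in range(3):  # mean, skew, kurt
            cols += [mom["ste"][mi], mom["lte"][mi]]
        for b in range(len(cfg.sbp_bands)):
            cols += [sbp_ste[:, b], sbp_lte[:, b]]
        for pi in range(len(cfg.sef_percents)):
            cols += [sef_ste[:, pi], sef_lte[:, pi]]
        blocks.append(np.column_stack(cols))

    values = np.hstack(blocks)
    seizures = annotations.seizures if annotations is not None else []
    labels = labeling.label_instances(times, seizures)
    return FeatureMatrix(values=values, timestamps=times, labels=labels,
                         column_names=feature_column_names(record.channel_names))
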