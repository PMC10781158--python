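"""Time- and frequency-domain blood pressure variability and the alpha index.

The analysis chain mirrors standard practice for rodent beat-to-beat series:

1. three 5-min windows are cut from the recording;
2. per window, the systogram (SBP) and tachogram (PI) are cubic-spline
   interpolated onto a dense uniform grid (250 Hz) and spline-decimated to
   an analysis rate (10 Hz), then linearly detrended;
3. auto- and cross-spectra are estimated by Welch averaging (Hann window,
   50 % overlap, >= 8 segments), which is what makes the squared-coherence
   estimate informative — a single periodogram yields coherence identically 1;
4. the low-frequency (LF) band power, 0.20–0.75 Hz in rats (Mayer waves),
   is obtained by trapezoidal integration of the power spectral density;
5. spontaneous baroreflex sensitivity is estimated as the alpha index,
   ``alpha = sqrt(LF power of PI / LF power of SBP)`` in ms/mmHg, accepted
   only when the mean squared coherence across the LF band exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import csd, detrend, welch

from .beats import BeatSeries, SegmentSet, split_segments

__all__ = [
    "LF_BAND",
    "SpectralOptions",
    "TimeDomainBPV",
    "ResampledSeries",
    "SpectralResult",
    "AlphaIndexResult",
    "time_domain_bpv",
    "resample_beat_series",
    "psd_and_coherence",
    "alpha_index",
    "bpv_endpoints",
]

#: Low-frequency (Mayer wave) band for rats, Hz.
LF_BAND: tuple[float, float] = (0.20, 0.75)


@dataclass(frozen=True)
class SpectralOptions:
    """Tunable parameters of the variability pipeline.

    ``band``            LF band edges in Hz (closed interval).
    ``fs_out``          analysis sampling rate after decimation, Hz.
    ``interp_fs``       dense cubic-spline interpolation rate, Hz; must be
                        an integer multiple of ``fs_out``.
    ``window``          taper for Welch averaging.
    ``n_segments``      number of Welch segments (at 50 % overlap).
    ``overlap``         Welch segment overlap fraction.
    ``gate``            coherence-gate statistic over LF bins: "mean" or "max".
    ``gate_threshold``  squared-coherence threshold for a valid alpha.
    ``window_s``        analysis window length, s.
    ``n_windows``       number of analysis windows per recording.
    """

    band: tuple[float, float] = LF_BAND
    fs_out: float = 10.0
    interp_fs: float = 250.0
    window: str = "hann"
    n_segments: int = 8
    overlap: float = 0.5
    gate: str = "mean"
    gate_threshold: float = 0.5
    window_s: float = 300.0
    n_windows: int = 3


@dataclass(frozen=True)
class TimeDomainBPV:
    """Time-domain variability: per-segment SD/variance averaged over segments.

    Because each value is the arithmetic mean of per-segment statistics,
    ``var_sbp`` need not equal ``sd_sbp**2``.
    """

    sd_sbp: float
    var_sbp: float
    sd_pi: float
    var_pi: float


@dataclass(frozen=True)
class ResampledSeries:
    """Uniformly resampled, linearly detrended beat series."""

    values: np.ndarray
    fs_out: float
    detrended: bool = True
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class SpectralResult:
    """One-sided auto/cross spectra of the PI and SBP series plus LF summaries."""

    freqs: np.ndarray
    psd_sbp: np.ndarray
    psd_pi: np.ndarray
    cross_spectrum: np.ndarray
    coh2: np.ndarray
    lf_band: tuple[float, float]
    lf_power_sbp: float
    lf_power_pi: float


@dataclass(frozen=True)
class AlphaIndexResult:
    """Coherence-gated baroreflex sensitivity estimate.

    ``alpha`` is defined (ms/mmHg) iff ``valid`` is true, i.e. the LF-band
    squared coherence exceeded the gate threshold.
    """

    alpha: float | None
    lf_coh2: float
    valid: bool
    reason: str | None = None


def time_domain_bpv(s: SegmentSet) -> TimeDomainBPV:
    """Sample SD and variance (denominator n-1) per segment, averaged."""
    if len(s) == 0:
        raise ValueError("empty segment set")
    sd_sbp, var_sbp, sd_pi, var_pi = [], [], [], []
    for seg in s:
        if seg.n_beats < 2:
            raise ValueError("each segment needs at least 2 beats")
        sd_sbp.append(np.std(seg.sbp, ddof=1))
        var_sbp.append(np.var(seg.sbp, ddof=1))
        sd_pi.append(np.std(seg.pi, ddof=1))
        var_pi.append(np.var(seg.pi, ddof=1))
    return TimeDomainBPV(
        sd_sbp=float(np.mean(sd_sbp)),
        var_sbp=float(np.mean(var_sbp)),
        sd_pi=float(np.mean(sd_pi)),
        var_pi=float(np.mean(var_pi)),
    )


def _resample(
    t: np.ndarray,
    values: np.ndarray,
    fs_out: float,
    interp_fs: float,
    do_detrend: bool,
) -> ResampledSeries:
    ratio = interp_fs / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("interp_fs must be an integer multiple of fs_out")
    stride = int(round(ratio))
    n_dense = int(np.floor((t[-1] - t[0]) * interp_fs)) + 1
    grid = t[0] + np.arange(n_dense) / interp_fs
    dense = CubicSpline(t, values)(grid)
    coarse = dense[::stride]
    if do_detrend:
        coarse = detrend(coarse, type="linear")
    return ResampledSeries(values=coarse, fs_out=fs_out, detrended=do_detrend, t0=float(t[0]))


def resample_beat_series(
    b: BeatSeries,
    fs_out: float = 10.0,
    interp_fs: float = 250.0,
    signal: str = "sbp",
    do_detrend: bool = True,
    lf_upper_hz: float = LF_BAND[1],
) -> ResampledSeries:
    """Cubic-spline resample one channel of a beat series to a uniform grid.

    The beat points are spline-interpolated at ``interp_fs`` (dense grid)
    and spline-decimated — the dense spline is subsampled — to ``fs_out``,
    then a least-squares linear trend is removed.  ``fs_out`` defaults to
    10 Hz: its 5 Hz Nyquist is far above the 0.75 Hz LF upper edge.
    """
    if b.n_beats < 4:
        raise ValueError("cubic spline resampling needs at least 4 beats")
    if fs_out <= 2 * lf_upper_hz:
        raise ValueError(
            f"Nyquist below LF band: fs_out={fs_out} Hz cannot resolve "
            f"{lf_upper_hz} Hz"
        )
    if signal == "sbp":
        values = b.sbp
    elif signal == "pi":
        values = b.pi
    else:
        raise ValueError(f"unknown signal {signal!r} (expected 'sbp' or 'pi')")
    return _resample(b.t, values, fs_out, interp_fs, do_detrend)


def _welch_nperseg(n: int, n_segments: int, overlap: float) -> int:
    if n_segments <= 1:
        return n
    # with fractional overlap o, K segments cover nperseg*(1 + (K-1)*(1-o))
    denom = 1.0 + (n_segments - 1) * (1.0 - overlap)
    return int(np.floor(n / denom))


def psd_and_coherence(
    pi: ResampledSeries,
    sbp: ResampledSeries,
    opts: SpectralOptions = SpectralOptions(),
) -> SpectralResult:
    """Welch auto- and cross-spectra, squared coherence, and LF band powers.

    Squared coherence is ``|S_xy|^2 / (S_xx * S_yy)`` per frequency bin from
    the segment-averaged spectra.  Band powers integrate the PSD over the
    closed LF interval by the trapezoidal rule.
    """
    if pi.values.size != sbp.values.size:
        raise ValueError("PI and SBP series must have equal length")
    if pi.fs_out != sbp.fs_out:
        raise ValueError("PI and SBP series must share the sampling rate")
    n = pi.values.size
    fs = pi.fs_out
    nperseg = _welch_nperseg(n, opts.n_segments, opts.overlap)
    if nperseg < 64:
        denom = 1.0 + (opts.n_segments - 1) * (1.0 - opts.overlap)
        min_s = 64 * denom / fs
        raise ValueError(
            f"series of {n / fs:.1f} s too short for {opts.n_segments} Welch "
            f"segments; need at least {min_s:.1f} s at {fs:g} Hz"
        )
    noverlap = int(nperseg * opts.overlap) if opts.n_segments > 1 else 0
    kw = dict(fs=fs, window=opts.window, nperseg=nperseg, noverlap=noverlap)
    freqs, pxx = welch(sbp.values, **kw)
    _, pyy = welch(pi.values, **kw)
    _, sxy = csd(pi.values, sbp.values, **kw)
    denom_psd = pxx * pyy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh2 = np.where(denom_psd > 0, np.abs(sxy) ** 2 / denom_psd, 0.0)
    coh2 = np.clip(coh2, 0.0, 1.0)
    return SpectralResult(
        freqs=freqs,
        psd_sbp=pxx,
        psd_pi=pyy,
        cross_spectrum=sxy,
        coh2=coh2,
        lf_band=opts.band,
        lf_power_sbp=band_power(freqs, pxx, opts.band),
        lf_power_pi=band_power(freqs, pyy, opts.band),
    )


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal PSD integral over the closed interval ``band``."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 frequency bins inside the band")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def alpha_index(
    sp: SpectralResult,
    gate: str = "mean",
    threshold: float = 0.5,
) -> AlphaIndexResult:
    """Coherence-gated alpha index, ``sqrt(LF_PI / LF_SBP)`` in ms/mmHg.

    The gate statistic summarises squared coherence over the LF bins
    ("mean" by default, "max" optional); alpha is reported only when it
    exceeds ``threshold``.
    """
    lo, hi = sp.lf_band
    mask = (sp.freqs >= lo) & (sp.freqs <= hi)
    if gate == "mean":
        lf_coh2 = float(np.mean(sp.coh2[mask]))
    elif gate == "max":
        lf_coh2 = float(np.max(sp.coh2[mask]))
    else:
        raise ValueError(f"unknown gate statistic {gate!r}")
    if sp.lf_power_sbp <= 0:
        return AlphaIndexResult(None, lf_coh2, False, reason="no pressure power in band")
    if lf_coh2 <= threshold:
        return AlphaIndexResult(
            None, lf_coh2, False, reason=f"LF squared coherence {lf_coh2:.3f} <= {threshold}"
        )
    return AlphaIndexResult(
        alpha=float(np.sqrt(sp.lf_power_pi / sp.lf_power_sbp)),
        lf_coh2=lf_coh2,
        valid=True,
    )


def bpv_endpoints(b: BeatSeries, opts: SpectralOptions = SpectralOptions()) -> dict:
    """Run the full per-animal variability pipeline on one beat series.

    Splits the recording into ``n_windows`` windows of ``window_s`` s,
    computes time-domain variability, per-window spectra, averages the LF
    band powers and the gate statistic across windows, and applies the
    coherence gate to the averaged powers.

    Returns a dict with keys ``sd_sbp``, ``var_sbp``, ``sd_pi``, ``var_pi``,
    ``lf_sbp``, ``lf_pi``, ``lf_coh2``, ``alpha`` (NaN when gated out) and
    ``alpha_valid``.
    """
    segs = split_segments(b, window_s=opts.window_s, count=opts.n_windows)
    td = time_domain_bpv(segs)
    lf_sbp, lf_pi, gate_vals = [], [], []
    for seg in segs:
        r_sbp = resample_beat_series(seg, opts.fs_out, opts.interp_fs, "sbp",
                                     lf_upper_hz=opts.band[1])
        r_pi = resample_beat_series(seg, opts.fs_out, opts.interp_fs, "pi",
                                    lf_upper_hz=opts.band[1])
        sp = psd_and_coherence(r_pi, r_sbp, opts)
        res = alpha_index(sp, gate=opts.gate, threshold=-1.0)  # ungated, for the statistic
        lf_sbp.append(sp.lf_power_sbp)
        lf_pi.append(sp.lf_power_pi)
        gate_vals.append(res.lf_coh2)
    mean_lf_sbp = float(np.mean(lf_sbp))
    mean_lf_pi = float(np.mean(lf_pi))
    mean_coh2 = float(np.mean(gate_vals))
    valid = mean_coh2 > opts.gate_threshold and mean_lf_sbp > 0
    alpha = float(np.sqrt(mean_lf_pi / mean_lf_sbp)) if valid else float("nan")
    return {
        "sd_sbp": td.sd_sbp,
        "var_sbp": td.var_sbp,
        "sd_pi": td.sd_pi,
        "var_pi": td.var_pi,
        "lf_sbp": mean_lf_sbp,
        "lf_pi": mean_lf_pi,
        "lf_coh2": mean_coh2,
        "alpha": alpha,
        "alpha_valid": valid,
    }
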