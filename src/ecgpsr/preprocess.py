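"""ECG conditioning and single-beat segmentation.

The chain is: zero-phase band-limiting (1 Hz high-pass to remove baseline
wander, 40 Hz low-pass to suppress noise), Pan-Tompkins style QRS
detection with adaptive thresholds and search-back, beat verification
against RR regularity and a median QRS template, screening of whole
recordings, and cutting of fixed-length single-cycle segments with the
QRS fiducial placed at 35% of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import EcgRecord

HIGHPASS_HZ = 1.0
LOWPASS_HZ = 40.0
FILTER_ORDER = 2  # per pass; forward-backward doubles the effective order

REFRACTORY_S = 0.200
PEAK_SNAP_S = 0.050
MWI_WINDOW_S = 0.150

RR_TOLERANCE = 0.20       # verify: adjacent RR within +-20% of median RR
QRS_CORR_MIN = 0.8        # verify: correlation with median QRS template
QRS_WINDOW_S = 0.100      # verify: template half-window around fiducial

FIDUCIAL_FRACTION = 0.35  # cycle split: 35% before / 65% after the fiducial

MIN_DURATION_S = 100.0    # screening
MIN_BEATS = 125


@dataclass(frozen=True)
class BeatSegment:
    """One cardiac cycle of samples with its fiducial position."""

    samples: np.ndarray
    fiducial_offset: int
    cycle_len: int
    subject_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size != self.cycle_len:
            raise ValueError("segment length must equal cycle_len")
        if self.fiducial_offset != int(round(FIDUCIAL_FRACTION * self.cycle_len)):
            raise ValueError("fiducial_offset must sit at 35% of the cycle")


def bandlimit(record: EcgRecord) -> EcgRecord:
    """Zero-phase Butterworth band-limiting to [1, 40] Hz.

    Both filters are applied forward and backward (anti-causal), so peaks
    are not shifted and fiducial timing is preserved.
    """
    if record.fs <= 80:
        raise ValueError("fs must exceed 80 Sa/s (Nyquist above 40 Hz)")
    sos_hp = sps.butter(FILTER_ORDER, HIGHPASS_HZ, "highpass",
                        fs=record.fs, output="sos")
    sos_lp = sps.butter(FILTER_ORDER, LOWPASS_HZ, "lowpass",
                        fs=record.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, record.samples)
    x = sps.sosfiltfilt(sos_lp, x)
    return EcgRecord(samples=x, fs=record.fs, subject_id=record.subject_id,
                     true_r_locations=record.true_r_locations)


def _pan_tompkins_stages(x: np.ndarray, fs: float) -> np.ndarray:
    """Bandpass -> derivative -> squaring -> moving-window integration."""
    sos = sps.butter(2, [5.0, 15.0], "bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(MWI_WINDOW_S * fs)))
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_qrs(record: EcgRecord) -> np.ndarray:
    """Pan-Tompkins style QRS detection.

    Adaptive signal/noise thresholds with a 200 ms refractory period and
    a search-back pass at half threshold when an expected beat is missed.
    Detections are snapped to the local absolute maximum of the
    band-limited ECG within +-50 ms, making the fiducial the R peak.
    """
    fs = record.fs
    if record.duration_s < 2.0:
        raise ValueError("record must be at least 2 s long")
    x = record.samples
    mwi = _pan_tompkins_stages(x, fs)
    if np.max(mwi) <= 0:
        return np.array([], dtype=int)

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))

    detections: list[int] = []
    rr_history: list[int] = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            detections.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(detections) >= 2:
                rr_history.append(detections[-1] - detections[-2])
                rr_history = rr_history[-8:]
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: if the gap since the last beat exceeds 1.66x the
            # recent average RR, accept the strongest missed candidate at
            # half threshold
            if detections and rr_history:
                avg_rr = float(np.mean(rr_history))
                if p - detections[-1] > 1.66 * avg_rr and mwi[p] > 0.5 * thr:
                    detections.append(int(p))
                    spki = 0.25 * mwi[p] + 0.75 * spki
                    rr_history.append(detections[-1] - detections[-2])
                    rr_history = rr_history[-8:]

    # snap to R peak: local absolute maximum of the ECG within +-50 ms
    snap = int(round(PEAK_SNAP_S * fs))
    snapped = []
    for d in detections:
        lo, hi = max(0, d - snap), min(x.size, d + snap + 1)
        snapped.append(lo + int(np.argmax(np.abs(x[lo:hi]))))

    # enforce strictly increasing order and the refractory period
    out: list[int] = []
    for s in sorted(set(snapped)):
        if not out or s - out[-1] >= refractory:
            out.append(s)
    return np.array(out, dtype=int)


def verify_beats(record: EcgRecord, fiducials: np.ndarray) -> np.ndarray:
    """Drop wrong detections and ectopic beats.

    A fiducial is kept iff both adjacent RR intervals are within +-20% of
    the record's median RR and its +-100 ms QRS window correlates >= 0.8
    with the median QRS template.  Endpoints lack one adjacent RR and are
    dropped.
    """
    fiducials = np.asarray(fiducials, dtype=int)
    if fiducials.size < 3:
        raise ValueError("beat verification needs at least 3 fiducials")
    x = record.samples
    fs = record.fs
    rr = np.diff(fiducials)
    median_rr = float(np.median(rr))
    half = int(round(QRS_WINDOW_S * fs))

    windows = []
    valid_window = np.zeros(fiducials.size, dtype=bool)
    for i, f in enumerate(fiducials):
        if f - half >= 0 and f + half + 1 <= x.size:
            windows.append(x[f - half:f + half + 1])
            valid_window[i] = True
    if not windows:
        return np.array([], dtype=int)
    template = np.median(np.stack(windows), axis=0)

    window_of = {}
    j = 0
    for i in range(fiducials.size):
        if valid_window[i]:
            window_of[i] = windows[j]
            j += 1

    kept = []
    for i in range(1, fiducials.size - 1):
        rr_ok = (abs(rr[i - 1] - median_rr) <= RR_TOLERANCE * median_rr
                 and abs(rr[i] - median_rr) <= RR_TOLERANCE * median_rr)
        if not rr_ok or i not in window_of:
            continue
        w = window_of[i]
        denom = np.std(w) * np.std(template)
        corr = 0.0 if denom == 0 else float(
            np.mean((w - w.mean()) * (template - template.mean())) / denom)
        if corr >= QRS_CORR_MIN:
            kept.append(int(fiducials[i]))
    return np.array(kept, dtype=int)


def segment_beats(record: EcgRecord, fiducials: np.ndarray) -> list[BeatSegment]:
    """Cut one fixed-length cardiac cycle per fiducial.

    The cycle length is the record's median RR; each window spans the
    35% of the cycle before the fiducial and the 65% after it.  Beats
    whose window overruns the record bounds are dropped.
    """
    fiducials = np.asarray(fiducials, dtype=int)
    if fiducials.size == 0:
        return []
    if fiducials.size >= 2:
        cycle_len = int(round(float(np.median(np.diff(fiducials)))))
    else:
        cycle_len = int(round(0.8 * record.fs))
    offset = int(round(FIDUCIAL_FRACTION * cycle_len))
    out = []
    for f in fiducials:
        start = f - offset
        end = start + cycle_len
        if start < 0 or end > record.samples.size:
            continue
        out.append(BeatSegment(samples=record.samples[start:end],
                               fiducial_offset=offset, cycle_len=cycle_len,
                               subject_id=record.subject_id))
    return out


def screen_recording(record: EcgRecord, kept_fiducials: np.ndarray) -> bool:
    """Recording passes iff it lasts >= 100 s and has >= 125 verified beats."""
    return (record.duration_s >= MIN_DURATION_S
            and np.asarray(kept_fiducials).size >= MIN_BEATS)
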