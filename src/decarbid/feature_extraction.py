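"""Per-run untargeted feature detection.

The stack mirrors the classic open-source metabolomics sequence: a centroid
noise floor, intensity-seeded extracted-ion-chromatogram (EIC) building
across scans, Savitzky-Golay smoothing, and splitting each EIC into
chromatographic peaks at local intensity minima.

Default parameters (noise level 100, m/z tolerance 0.002 Da or 20 ppm,
group intensity threshold 200, min group size 5 scans, chromatographic
threshold 0.85, top/edge ratio 1.7, min 5 data points) are the processing
settings of the amide-HILIC workflow this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .runs import CentroidSpectrum, Run

__all__ = [
    "EIC",
    "Feature",
    "mz_tolerance",
    "detect_masses",
    "build_eics",
    "smooth_eic",
    "resolve_features",
    "extract_features",
]


def mz_tolerance(mz: float, tol_da: float = 0.002, tol_ppm: float = 20.0) -> float:
    """Combined absolute/relative m/z tolerance: whichever is larger."""
    return max(tol_da, tol_ppm * 1e-6 * mz)


@dataclass
class EIC:
    """An extracted ion trace: per-scan points near a running m/z center."""

    mz_center: float
    scan_idx: np.ndarray
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        for name in ("scan_idx", "rt", "mz", "intensity"):
            setattr(self, name, np.asarray(getattr(self, name)))
        order = np.argsort(self.rt, kind="stable")
        self.scan_idx = self.scan_idx[order]
        self.rt = self.rt[order]
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class Feature:
    """A resolved chromatographic peak in one run."""

    mz: float
    rt_apex: float
    height: float
    area: float  # counts x min
    scan_first: int
    scan_last: int
    run_id: str = ""
    extras: dict = field(default_factory=dict)


def detect_masses(spectrum: CentroidSpectrum, noise_level: float = 100.0) -> CentroidSpectrum:
    """Drop centroid peaks below the intensity noise floor."""
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    keep = spectrum.intensity >= noise_level
    return CentroidSpectrum(
        spectrum.retention_time,
        spectrum.polarity,
        spectrum.mz[keep],
        spectrum.intensity[keep],
    )


def build_eics(
    run: Run | list[CentroidSpectrum],
    mz_tol_da: float = 0.002,
    mz_tol_ppm: float = 20.0,
    min_group_size: int = 5,
    group_intensity_threshold: float = 200.0,
) -> list[EIC]:
    """Greedy intensity-seeded EIC construction across a run's scans.

    All data points are pooled and visited in descending-intensity order.
    Each still-unassigned point seeds a chromatogram; scans are then walked
    outward from the seed scan, and in every scan the nearest unassigned
    point within the tolerance of the running intensity-weighted m/z center
    is appended. Every visited point is consumed exactly once, whether or
    not its chromatogram survives the quality gates: at least
    ``min_group_size`` points and at least one point at or above
    ``group_intensity_threshold``.
    """
    scans = run.scans if isinstance(run, Run) else run
    run_id = run.run_id if isinstance(run, Run) else ""
    if not scans:
        raise ValueError("run contains no scans")
    n_scans = len(scans)
    rts = np.array([s.retention_time for s in scans])
    if np.any(np.diff(rts) < 0):
        raise ValueError("scans are not RT-ordered")

    # Flatten into per-scan m/z-sorted views plus a global intensity order.
    scan_of, flat_mz, flat_int, offsets = [], [], [], [0]
    for i, s in enumerate(scans):
        scan_of.append(np.full(len(s), i))
        flat_mz.append(s.mz)
        flat_int.append(s.intensity)
        offsets.append(offsets[-1] + len(s))
    if offsets[-1] == 0:
        return []
    scan_of = np.concatenate(scan_of)
    flat_mz = np.concatenate(flat_mz)
    flat_int = np.concatenate(flat_int)
    offsets = np.array(offsets)
    assigned = np.zeros(len(flat_mz), dtype=bool)
    # Stable sort so equal intensities resolve in scan/m-z order.
    seed_order = np.argsort(-flat_int, kind="stable")

    def nearest_unassigned(scan: int, center: float, tol: float) -> int:
        """Index (global) of the nearest unassigned in-tolerance point."""
        lo, hi = offsets[scan], offsets[scan + 1]
        if lo == hi:
            return -1
        j = int(np.searchsorted(flat_mz[lo:hi], center)) + lo
        best, best_d = -1, tol
        for k in range(j - 1, lo - 1, -1):
            d = center - flat_mz[k]
            if d > best_d:
                break
            if not assigned[k]:
                best, best_d = k, d
                break
        for k in range(j, hi):
            d = flat_mz[k] - center
            if d > best_d:
                break
            if not assigned[k]:
                if best == -1 or d < best_d:
                    best = k
                break
        return best

    eics: list[EIC] = []
    for seed in seed_order:
        if assigned[seed]:
            continue
        assigned[seed] = True
        members = [int(seed)]
        center = flat_mz[seed]
        w_sum = flat_int[seed]
        wm_sum = flat_int[seed] * flat_mz[seed]
        seed_scan = int(scan_of[seed])
        # Walk left of the seed scan, then right.
        for scan in range(seed_scan - 1, -1, -1):
            tol = mz_tolerance(center, mz_tol_da, mz_tol_ppm)
            k = nearest_unassigned(scan, center, tol)
            if k < 0:
                continue
            assigned[k] = True
            members.append(k)
            w_sum += flat_int[k]
            wm_sum += flat_int[k] * flat_mz[k]
            center = wm_sum / w_sum
        for scan in range(seed_scan + 1, n_scans):
            tol = mz_tolerance(center, mz_tol_da, mz_tol_ppm)
            k = nearest_unassigned(scan, center, tol)
            if k < 0:
                continue
            assigned[k] = True
            members.append(k)
            w_sum += flat_int[k]
            wm_sum += flat_int[k] * flat_mz[k]
            center = wm_sum / w_sum
        if len(members) < min_group_size:
            continue
        m = np.array(members)
        if flat_int[m].max() < group_intensity_threshold:
            continue
        eics.append(
            EIC(
                float(center),
                scan_of[m],
                rts[scan_of[m]],
                flat_mz[m],
                flat_int[m],
                run_id=run_id,
            )
        )
    return eics


def smooth_eic(eic: EIC, window: int = 7, poly_order: int = 2) -> EIC:
    """Savitzky-Golay smoothing of an EIC's intensity profile.

    m/z values are untouched; negative smoothed intensities are clamped to
    zero. EICs shorter than the window are returned unchanged.
    """
    if window % 2 == 0 or window <= poly_order:
        raise ValueError("window must be odd and greater than poly_order")
    if len(eic) < window:
        return eic
    smoothed = savgol_filter(eic.intensity, window, poly_order, mode="interp")
    return EIC(
        eic.mz_center,
        eic.scan_idx,
        eic.rt,
        eic.mz,
        np.clip(smoothed, 0.0, None),
        run_id=eic.run_id,
    )


def _local_minima(y: np.ndarray) -> list[int]:
    """Interior local minima; plateau minima resolve to their first index."""
    minima = []
    n = len(y)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[j]:
            j += 1
        # plateau [i, j]; a minimum iff both neighbours are higher
        if j < n - 1 and y[i - 1] > y[i] and y[j + 1] > y[j]:
            minima.append(i)
        i = j + 1
    return minima


def resolve_features(
    eic: EIC,
    chrom_threshold: float = 0.85,
    min_top_edge_ratio: float = 1.7,
    min_points: int = 5,
) -> list[Feature]:
    """Split an EIC at local intensity minima into chromatographic peaks.

    A candidate segment becomes a feature when (a) its apex exceeds the
    ``chrom_threshold`` intensity quantile of the whole EIC, (b) the
    apex-to-edge ratio is at least ``min_top_edge_ratio`` (edge = the larger
    of the two per-side minimum intensities within the segment), and (c) it
    spans at least ``min_points`` points. Area is the trapezoid over RT in
    minutes; the apex is the RT of the maximum point (first index on ties).
    """
    y = eic.intensity
    if len(y) == 0:
        return []
    minima = _local_minima(y)
    # The valley point goes with the left segment so features never share scans.
    starts = [0] + [m + 1 for m in minima]
    ends = minima + [len(y) - 1]
    quantile = float(np.quantile(y, chrom_threshold))
    features = []
    for start, end in zip(starts, ends):
        if end - start + 1 < min_points:
            continue
        seg = slice(start, end + 1)
        apex = start + int(np.argmax(y[seg]))
        height = float(y[apex])
        if height <= quantile:
            continue
        left_edge = float(np.min(y[start: apex + 1]))
        right_edge = float(np.min(y[apex: end + 1]))
        edge = max(left_edge, right_edge)
        if edge > 0 and height / edge < min_top_edge_ratio:
            continue
        # A valley point is the integration boundary of both neighbouring
        # peaks, so the right-hand segment integrates from the valley even
        # though the valley scan belongs to the left feature's span.
        i0 = start - 1 if start > 0 else 0
        area = float(np.trapezoid(y[i0: end + 1], eic.rt[i0: end + 1]))
        weights = y[seg]
        mz = (
            float(np.average(eic.mz[seg], weights=weights))
            if weights.sum() > 0
            else eic.mz_center
        )
        features.append(
            Feature(
                mz=mz,
                rt_apex=float(eic.rt[apex]),
                height=height,
                area=area,
                scan_first=int(eic.scan_idx[start]),
                scan_last=int(eic.scan_idx[end]),
                run_id=eic.run_id,
            )
        )
    return features


def extract_features(
    run: Run,
    noise_level: float = 100.0,
    mz_tol_da: float = 0.002,
    mz_tol_ppm: float = 20.0,
    min_group_size: int = 5,
    group_intensity_threshold: float = 200.0,
    smoothing_window: int = 7,
    smoothing_order: int = 2,
    chrom_threshold: float = 0.85,
    min_top_edge_ratio: float = 1.7,
    min_points: int = 5,
) -> list[Feature]:
    """Full per-run stack: noise floor, EIC building, smoothing, resolving."""
    filtered = Run(
        run.run_id,
        run.polarity,
        [detect_masses(s, noise_level) for s in run.scans],
        metadata=run.metadata,
    )
    eics = build_eics(
        filtered, mz_tol_da, mz_tol_ppm, min_group_size, group_intensity_threshold
    )
    features = []
    for eic in eics:
        smoothed = smooth_eic(eic, smoothing_window, smoothing_order)
        features.extend(
            resolve_features(smoothed, chrom_threshold, min_top_edge_ratio, min_points)
        )
    features.sort(key=lambda f: (f.mz, f.rt_apex))
    return features
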