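"""Prieto center-of-pressure indices from a single stabilometric trial.

A trial is the CoP trajectory recorded on a force platform during quiet
standing: two displacement series in millimetres, medio-lateral (ML) and
antero-posterior (AP), sampled at a fixed rate. After removing each axis
mean, the resultant distance series is RD[i] = sqrt(AP[i]^2 + ML[i]^2).

The registry comprises 40 indices in three groups:

* time-domain distance measures (mean/RMS distance, standard deviations,
  ranges, total excursion, mean velocity, the AP-ML cross-covariance,
  confidence ellipse/circle areas, sway area),
* hybrid measures (mean frequency: the rotational frequency of a point
  travelling the measured path at the measured mean distance),
* frequency-domain measures per direction (total power, 50%/95% power
  frequencies, centroidal frequency, frequency dispersion), derived from
  spectral moments mu_k = sum_f f^k G(f) df over a configurable band.

Conventions (documented because the literature varies): per-axis standard
deviations use the sample (N-1) denominator; the AP-ML cross-covariance and
the RD standard deviation use the population (1/N) convention on centered
series; the confidence-ellipse F statistic is fixed at 3.00 (its large-sample
value, within 0.3% of the exact F(0.05; 2, N-2) for trials of several
thousand samples); duration = N / fs with 0-based sample indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram, welch
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .registry import COP_INDICES

__all__ = [
    "StabilogramTrial",
    "DEFAULT_BAND",
    "center_trial",
    "time_domain_indices",
    "spectral_indices",
    "compute_all",
    "read_trial",
    "write_trial",
]

#: Default analysis band in Hz (Prieto's convention).
DEFAULT_BAND: tuple[float, float] = (0.15, 5.0)

#: 95th-percentile z value for the confidence-circle radius.
_Z95 = 1.645
#: Large-sample F(0.05; 2, inf) used in the 95% confidence ellipse area.
_F95 = 3.00


@dataclass(frozen=True)
class StabilogramTrial:
    """One stabilometric trial: raw ML/AP CoP displacement in mm."""

    subject_id: str
    trial_index: int
    fs: float
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        ml = np.asarray(self.ml, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if ml.ndim != 1 or ap.ndim != 1 or len(ml) != len(ap):
            raise ValueError("ml and ap must be 1-D series of equal length")
        if len(ml) < 2:
            raise ValueError("a trial needs at least 2 samples")
        if not (np.isfinite(ml).all() and np.isfinite(ap).all()):
            raise ValueError("trial contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.ml)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def center_trial(trial: StabilogramTrial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove axis means and form the resultant-distance series.

    Returns ``(ap, ml, rd)`` with AP and ML zero-mean and
    ``rd[i] = sqrt(ap[i]**2 + ml[i]**2)``.
    """
    ap = trial.ap - trial.ap.mean()
    ml = trial.ml - trial.ml.mean()
    rd = np.hypot(ap, ml)
    return ap, ml, rd


def _max_pairwise_distance(ml: np.ndarray, ap: np.ndarray) -> float:
    """Exact diameter of the planar sway path.

    Uses the convex hull (the diameter is attained at hull vertices) so the
    computation stays near O(N log N) for long trials; degenerate (collinear)
    clouds fall back to the extent along the principal direction, which is
    exact in that case.
    """
    pts = np.column_stack([ml, ap])
    if len(pts) <= 3:
        return float(pdist(pts).max()) if len(pts) >= 2 else 0.0
    try:
        hull = ConvexHull(pts)
        return float(pdist(pts[hull.vertices]).max())
    except QhullError:
        centered = pts - pts.mean(axis=0)
        if not centered.any():
            return 0.0
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        return float(proj.max() - proj.min())


def time_domain_indices(
    ap: np.ndarray, ml: np.ndarray, rd: np.ndarray, fs: float
) -> dict[str, float]:
    """Time-domain and hybrid Prieto indices from centered series.

    Degenerate flat trials (zero mean distance) leave the mean-frequency
    entries as NaN with a warning rather than raising.
    """
    n = len(rd)
    duration = n / fs

    mean_dist = float(rd.mean())
    mean_dist_ap = float(np.abs(ap).mean())
    mean_dist_ml = float(np.abs(ml).mean())

    rms_dist = float(np.sqrt(np.mean(rd**2)))
    rms_dist_ap = float(np.sqrt(np.mean(ap**2)))
    rms_dist_ml = float(np.sqrt(np.mean(ml**2)))

    # s_RD via the identity RDIST^2 = MDIST^2 + s_RD^2; axes use sample SD.
    std_rd = float(np.sqrt(max(rms_dist**2 - mean_dist**2, 0.0)))
    std_ap = float(ap.std(ddof=1))
    std_ml = float(ml.std(ddof=1))

    d_ap = np.diff(ap)
    d_ml = np.diff(ml)
    total_length = float(np.hypot(d_ap, d_ml).sum())
    total_length_ap = float(np.abs(d_ap).sum())
    total_length_ml = float(np.abs(d_ml).sum())

    mean_velocity = total_length / duration
    mean_velocity_ap = total_length_ap / duration
    mean_velocity_ml = total_length_ml / duration

    rng = _max_pairwise_distance(ml, ap)
    range_ap = float(ap.max() - ap.min())
    range_ml = float(ml.max() - ml.min())

    covariance_ml = float(np.mean(ap * ml))

    var_ap = std_ap**2
    var_ml = std_ml**2
    ellipse_area_95 = float(
        2.0 * np.pi * _F95 * np.sqrt(max(var_ap * var_ml - covariance_ml**2, 0.0))
    )
    circle_area_95 = float(np.pi * (mean_dist + _Z95 * std_rd) ** 2)
    sway_area = float(
        np.abs(ap[1:] * ml[:-1] - ap[:-1] * ml[1:]).sum() / (2.0 * duration)
    )

    if mean_dist > 0:
        mean_freq = mean_velocity / (2.0 * np.pi * mean_dist)
    else:
        warnings.warn("degenerate flat trial: mean distance is 0, "
                      "mean frequency undefined", stacklevel=2)
        mean_freq = np.nan
    mean_freq_ap = (
        mean_velocity_ap / (4.0 * mean_dist_ap) if mean_dist_ap > 0 else np.nan
    )
    mean_freq_ml = (
        mean_velocity_ml / (4.0 * mean_dist_ml) if mean_dist_ml > 0 else np.nan
    )
    if (mean_dist_ap == 0 or mean_dist_ml == 0) and mean_dist > 0:
        warnings.warn("degenerate axis: per-axis mean frequency undefined",
                      stacklevel=2)

    return {
        "mean_dist": mean_dist, "mean_dist_ap": mean_dist_ap,
        "mean_dist_ml": mean_dist_ml,
        "rms_dist": rms_dist, "rms_dist_ap": rms_dist_ap,
        "rms_dist_ml": rms_dist_ml,
        "std_rd": std_rd, "std_ap": std_ap, "std_ml": std_ml,
        "range": rng, "range_ap": range_ap, "range_ml": range_ml,
        "total_length": total_length, "total_length_ap": total_length_ap,
        "total_length_ml": total_length_ml,
        "mean_velocity": mean_velocity, "mean_velocity_ap": mean_velocity_ap,
        "mean_velocity_ml": mean_velocity_ml,
        "covariance_ml": covariance_ml,
        "ellipse_area_95": ellipse_area_95, "circle_area_95": circle_area_95,
        "sway_area": sway_area,
        "mean_freq": mean_freq, "mean_freq_ap": mean_freq_ap,
        "mean_freq_ml": mean_freq_ml,
    }


def _spectrum(series: np.ndarray, fs: float, estimator: str,
              nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    if estimator == "welch":
        return welch(series, fs=fs, window="hann",
                     nperseg=min(nperseg, len(series)), detrend=False)
    if estimator == "periodogram":
        return periodogram(series, fs=fs, window="boxcar", detrend=False)
    raise ValueError(f"unknown spectral estimator {estimator!r}")


def _direction_spectral(series: np.ndarray, fs: float,
                        band: tuple[float, float], estimator: str,
                        nperseg: int) -> dict[str, float]:
    f, g = _spectrum(series, fs, estimator, nperseg)
    df = f[1] - f[0]
    mask = (f >= band[0]) & (f <= band[1])
    fb, gb = f[mask], g[mask]
    mu0 = float(np.sum(gb) * df)
    if mu0 <= 0 or len(fb) == 0:
        warnings.warn("zero in-band power: spectral shape indices undefined",
                      stacklevel=3)
        return {"total_power": max(mu0, 0.0),
                **{k: np.nan for k in
                   ("power_freq_50", "power_freq_95",
                    "centroid_freq", "freq_dispersion")}}
    mu1 = float(np.sum(fb * gb) * df)
    mu2 = float(np.sum(fb**2 * gb) * df)
    cum = np.cumsum(gb) * df
    i50 = min(int(np.searchsorted(cum, 0.5 * mu0)), len(fb) - 1)
    i95 = min(int(np.searchsorted(cum, 0.95 * mu0)), len(fb) - 1)
    pf50 = float(fb[i50])
    pf95 = float(fb[i95])
    centroid = float(np.sqrt(mu2 / mu0))
    dispersion = float(np.sqrt(max(1.0 - mu1**2 / (mu0 * mu2), 0.0)))
    return {
        "total_power": mu0,
        "power_freq_50": pf50,
        "power_freq_95": pf95,
        "centroid_freq": centroid,
        "freq_dispersion": dispersion,
    }


def spectral_indices(
    ap: np.ndarray,
    ml: np.ndarray,
    rd: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    estimator: str = "welch",
    nperseg: int = 2048,
) -> dict[str, float]:
    """Frequency-domain indices for the RD, AP and ML directions.

    The spectral moments are restricted to ``band`` (Hz); the default
    estimator is a Hann-windowed averaged periodogram (Welch, 50% overlap),
    which stabilizes the moment estimates; ``estimator="periodogram"`` gives
    the raw periodogram for closed-form oracle checks.
    """
    if not (0 < band[0] < band[1] <= fs / 2):
        raise ValueError(f"band must lie within (0, fs/2], got {band}")
    out: dict[str, float] = {}
    for suffix, series in (("", rd), ("_ap", ap), ("_ml", ml)):
        vals = _direction_spectral(series, fs, band, estimator, nperseg)
        for key, v in vals.items():
            out[key + suffix] = v
    return out


def compute_all(
    trial: StabilogramTrial,
    band: tuple[float, float] = DEFAULT_BAND,
    estimator: str = "welch",
    nperseg: int = 2048,
) -> dict[str, float]:
    """All 40 CoP indices for one trial, keyed by registry name."""
    ap, ml, rd = center_trial(trial)
    vals = time_domain_indices(ap, ml, rd, trial.fs)
    vals.update(spectral_indices(ap, ml, rd, trial.fs, band=band,
                                 estimator=estimator, nperseg=nperseg))
    return {name: vals[name] for name in COP_INDICES}


# --- plain-text trial I/O ---------------------------------------------------

def write_trial(trial: StabilogramTrial, path) -> None:
    """Write a trial as two-column delimited text (ML_mm, AP_mm).

    The one-line header records the sampling rate so the file is
    self-describing.
    """
    header = f"fs_hz={trial.fs:g} columns=ml_mm,ap_mm"
    np.savetxt(path, np.column_stack([trial.ml, trial.ap]),
               fmt="%.6f", delimiter="\t", header=header)


def read_trial(path, subject_id: str = "", trial_index: int = 0) -> StabilogramTrial:
    """Read a trial written by :func:`write_trial`."""
    with open(path) as fh:
        first = fh.readline()
    if "fs_hz=" not in first:
        raise ValueError(f"{path}: missing fs_hz header line")
    fs = float(first.split("fs_hz=")[1].split()[0])
    data = np.loadtxt(path, delimiter="\t")
    return StabilogramTrial(subject_id=subject_id, trial_index=trial_index,
                            fs=fs, ml=data[:, 0], ap=data[:, 1])
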