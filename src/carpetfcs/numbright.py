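"""Number & brightness (N&B) moment analysis of line-scan carpets.

For each pixel column, the apparent number of molecules and apparent
molecular brightness follow from the first two temporal moments of the
photon counts k:

    N = <k>^2 / sigma^2        B = sigma^2 / <k>  (= <k> / N)

B distinguishes few bright from many dim emitters at equal mean
intensity; in the photon-counting convention used here, pure shot noise
gives B = 1 and true emitters add excess variance on top (B > 1).

Two segmentation schemes mirror how fast and slow fluctuations are
separated on a 30,000-line carpet: the *fast* scheme computes N and B
per segment of 300 raw lines (up to 100 segments), so rapid fluctuations
dominate the variance; the *slow* scheme first averages the carpet in
non-overlapping 100-line windows, suppressing fast dynamics, and then
computes N and B over the averaged series, exposing slow or immobile
bright structures (endosome-like aggregates).  Both knobs are
configurable since the scheme arithmetic admits more than one reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "NBSegmentationScheme",
    "nb_compute",
    "nb_aggregate",
    "joint_speed_partition",
    "brightness_vs_distance",
    "detect_rare_peaks",
]

NB_COLUMNS = ["segment_id", "column", "mean_k", "var_k", "N_apparent",
              "B_apparent", "scheme", "defined"]


@dataclass
class NBSegmentationScheme:
    """How a carpet is cut up before moment analysis.

    ``mode="fast"``: N&B per segment of ``block_lines`` raw lines.
    ``mode="slow"``: lines first averaged in non-overlapping windows of
    ``average_window`` lines, then N&B over the averaged series (one
    segment unless ``n_segments`` says otherwise).
    """

    mode: str = "fast"
    block_lines: int = 300
    average_window: int = 100
    n_segments: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "slow"):
            raise ValueError("mode must be 'fast' or 'slow'")
        if self.block_lines < 2 or self.average_window < 1:
            raise ValueError("block_lines must be >= 2 and average_window >= 1")


def _moments_to_nb(mean_k: np.ndarray, var_k: np.ndarray):
    defined = var_k > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(defined, mean_k**2 / var_k, np.nan)
        b = np.where(defined, var_k / mean_k, 0.0)
    return n, b, defined


def nb_compute(carpet, scheme: NBSegmentationScheme | None = None,
               channel: int = 0) -> pd.DataFrame:
    """Per-segment, per-column N and B under a named segmentation scheme.

    Returns a tidy frame with one row per (segment, column):
    ``segment_id, column, mean_k, var_k, N_apparent, B_apparent, scheme,
    defined``.  Zero-variance columns are flagged ``defined=False`` with
    N undefined (NaN) and B = 0 rather than dividing by zero.
    """
    scheme = scheme or NBSegmentationScheme()
    data = carpet.data[:, :, channel].astype(float)
    n_lines = data.shape[0]
    if scheme.mode == "slow":
        w = scheme.average_window
        n_win = n_lines // w
        if n_win < 2:
            raise ValueError(
                f"average_window {w} leaves {n_win} averaged lines; need >= 2"
            )
        data = data[: n_win * w].reshape(n_win, w, -1).mean(axis=1)
        block = n_win if scheme.n_segments in (None, 1) else n_win // scheme.n_segments
    else:
        block = scheme.block_lines
    n_segments = data.shape[0] // block
    if scheme.n_segments is not None:
        n_segments = min(n_segments, scheme.n_segments)
    if n_segments < 1:
        raise ValueError(
            f"scheme needs {block} lines per segment but carpet has {data.shape[0]}"
        )
    rows = []
    for s in range(n_segments):
        seg = data[s * block:(s + 1) * block]
        mean_k = seg.mean(axis=0)
        var_k = seg.var(axis=0, ddof=1)
        n, b, defined = _moments_to_nb(mean_k, var_k)
        for col in range(seg.shape[1]):
            rows.append((s, col, mean_k[col], var_k[col], n[col], b[col],
                         scheme.mode, bool(defined[col])))
    return pd.DataFrame(rows, columns=NB_COLUMNS)


def nb_aggregate(nb: pd.DataFrame) -> pd.DataFrame:
    """Across-segment mean ± SEM of N and B per column (defined rows only)."""
    d = nb[nb["defined"]]
    g = d.groupby("column")
    out = pd.DataFrame({
        "n_segments": g.size(),
        "mean_N": g["N_apparent"].mean(),
        "sem_N": g["N_apparent"].sem(ddof=1),
        "mean_B": g["B_apparent"].mean(),
        "sem_B": g["B_apparent"].sem(ddof=1),
        "mean_k": g["mean_k"].mean(),
    }).reset_index()
    out["sem_N"] = out["sem_N"].fillna(0.0)
    out["sem_B"] = out["sem_B"].fillna(0.0)
    return out


def joint_speed_partition(nb_fast: pd.DataFrame, nb_slow: pd.DataFrame,
                          fcs_results) -> pd.DataFrame:
    """Attach each column's N&B (from the matching scheme) to its speed class.

    Fast columns (by the diffusion fit) take their N and B from the fast
    scheme, slow columns from the slow scheme; invalid fits are dropped.
    Both N&B frames must cover the same columns as the fit results.
    """
    agg = {"fast": nb_aggregate(nb_fast).set_index("column"),
           "slow": nb_aggregate(nb_slow).set_index("column")}
    covered = {"fast": set(nb_fast["column"].unique()),
               "slow": set(nb_slow["column"].unique())}
    rows = []
    for r in fcs_results:
        if r.speed_class not in ("fast", "slow"):
            continue
        if r.column not in covered[r.speed_class]:
            raise ValueError(
                f"column {r.column} missing from {r.speed_class}-scheme N&B"
            )
        src = agg[r.speed_class]
        if r.column not in src.index:  # column defined in no segment
            continue
        a = src.loc[r.column]
        rows.append({
            "column": r.column,
            "speed_class": r.speed_class,
            "D_um2_s": r.D_um2_s,
            "N": a["mean_N"],
            "B": a["mean_B"],
            "sem_N": a["sem_N"],
            "sem_B": a["sem_B"],
        })
    return pd.DataFrame(rows, columns=["column", "speed_class", "D_um2_s", "N",
                                       "B", "sem_N", "sem_B"])


def brightness_vs_distance(nb: pd.DataFrame, zone_map, pixel_size_nm: float,
                           bin_width_um: float = 0.2) -> pd.DataFrame:
    """Mean B ± SEM binned by signed distance from the lamina.

    Negative distances are the cytoplasmic side.  Bin edges are aligned
    to multiples of ``bin_width_um`` so the lamina sits on an edge.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = nb[nb["defined"]]
    if d.empty:
        return pd.DataFrame(columns=["bin_left_um", "bin_center_um", "n",
                                     "mean_B", "sem_B"])
    cols = d["column"].to_numpy()
    dist = zone_map.signed_distance_um(pixel_size_nm, cols)
    idx = np.floor(dist / bin_width_um).astype(int)
    frame = pd.DataFrame({"bin": idx, "B": d["B_apparent"].to_numpy()})
    g = frame.groupby("bin")["B"]
    out = pd.DataFrame({
        "bin_left_um": g.size().index * bin_width_um,
        "bin_center_um": (g.size().index + 0.5) * bin_width_um,
        "n": g.size().to_numpy(),
        "mean_B": g.mean().to_numpy(),
        "sem_B": g.sem(ddof=1).fillna(0.0).to_numpy(),
    }).reset_index(drop=True)
    return out.sort_values("bin_left_um", ignore_index=True)


def detect_rare_peaks(series, min_prominence: float,
                      min_separation: int = 1) -> pd.DataFrame:
    """Prominence-based local maxima, for flagging rare bright transits.

    Returns position, height and prominence of every local maximum whose
    prominence exceeds ``min_prominence``, with maxima at least
    ``min_separation`` samples apart.  An empty result is a valid answer.
    """
    series = np.asarray(series, float)
    if series.ndim != 1:
        raise ValueError("peak detection expects a 1-D series")
    peaks, props = find_peaks(series, prominence=min_prominence,
                              distance=max(1, int(min_separation)))
    return pd.DataFrame({
        "position": peaks.astype(int),
        "height": series[peaks],
        "prominence": props["prominences"],
    })
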