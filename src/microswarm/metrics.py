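"""Per-track motion metrics and motility classification.

For a track with positions p_1 … p_n (µm) sampled at interval Δt:

* total path  L = Σ |p_{k+1} − p_k|
* net displacement  d = |p_n − p_1|
* confinement ratio  d / L  (0 when L = 0) — 0 means the cell returned to
  its starting point, 1 means straight-line motion
* mean speed  L / ((n − 1)·Δt), the total path over the elapsed time

Motility labels follow the observed behavioral cutoffs: zoospores with
mean speed below 10 µm/s are effectively non-motile (encysted or
deflagellated); vorticellae below 20 µm/s are sessile trophonts, faster
ones free-swimming telotrochs; bacteria carry no speed-based label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mean-speed cutoffs (µm/s) separating motility classes
ZOOSPORE_NONMOTILE_SPEED = 10.0
VORTICELLA_SESSILE_SPEED = 20.0

METRIC_COLUMNS = ["track_id", "species", "n_links", "mean_speed_ums",
                  "confinement_ratio", "net_um", "total_um", "duration_s",
                  "motility"]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    species: str
    n_links: int
    mean_speed: float
    confinement_ratio: float
    net_displacement: float
    total_path: float
    duration: float


def compute_metrics(positions: np.ndarray, dt: float,
                    track_id: int = 0, species: str = "unknown"
                    ) -> TrackMetrics:
    """Closed-form motion metrics for one ordered position array (µm)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        raise ValueError("track needs at least 2 spots for metrics")
    steps = np.diff(pos, axis=0)
    total = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = float(np.hypot(*(pos[-1] - pos[0])))
    ratio = net / total if total > 0 else 0.0
    n_links = len(pos) - 1
    return TrackMetrics(track_id=track_id, species=species, n_links=n_links,
                        mean_speed=total / (n_links * dt),
                        confinement_ratio=min(ratio, 1.0),
                        net_displacement=net, total_path=total,
                        duration=n_links * dt)


def classify_motility(mean_speed: float, species: str,
                      zoospore_cutoff: float = ZOOSPORE_NONMOTILE_SPEED,
                      vorticella_cutoff: float = VORTICELLA_SESSILE_SPEED
                      ) -> str:
    """Behavioral label from a track's mean speed.

    Strict inequality on the slow side: a vorticella at exactly the 20
    µm/s cutoff is a telotroch, a zoospore at exactly 10 µm/s is motile.
    """
    if mean_speed < 0:
        raise ValueError("mean_speed must be >= 0")
    if species == "zoospore":
        return "non_motile" if mean_speed < zoospore_cutoff else "motile"
    if species == "vorticella":
        return "sessile" if mean_speed < vorticella_cutoff else "telotroch"
    if species == "bacterium":
        return "unclassified"
    raise ValueError(f"unknown species {species!r}")


def compute_track_metrics(tracks: pd.DataFrame, dt: float,
                          min_length: int = 2) -> pd.DataFrame:
    """Metrics for every track of at least ``min_length`` spots.

    Singleton tracks (and any shorter than ``min_length``) carry no motion
    information and are excluded, with a log entry of how many were
    dropped.  Returns one row per retained track.
    """
    if len(tracks) == 0:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    rows = []
    n_short = 0
    for tid, df in tracks.groupby("track_id"):
        if len(df) < max(min_length, 2):
            n_short += 1
            continue
        df = df.sort_values("frame")
        species = df["species"].iloc[0]
        m = compute_metrics(df[["x_um", "y_um"]].to_numpy(), dt,
                            track_id=int(tid), species=species)
        rows.append([m.track_id, m.species, m.n_links, m.mean_speed,
                     m.confinement_ratio, m.net_displacement, m.total_path,
                     m.duration,
                     classify_motility(m.mean_speed, species)
                     if species in ("zoospore", "vorticella", "bacterium")
                     else "unclassified"])
    if n_short:
        logger.info("excluded %d tracks shorter than %d spots from metrics",
                    n_short, max(min_length, 2))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
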