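"""Nearest-neighbor linking of spots across consecutive frames.

Spots of one species are linked frame-to-frame by a greedy
ascending-distance assignment under a per-species maximal linking
distance: candidate pairs within ``d_max`` are sorted by distance (ties
broken by lower spot id) and accepted while both endpoints are free.  The
assignment is one-to-one and deterministic; chains of links form tracks.
There is no gap closing and no track splitting or merging — a spot that
jumps farther than ``d_max`` ends its track and starts a new one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "species", "frame", "spot_id", "x_um", "y_um"]


def link_frame_pair(xy_t: np.ndarray, xy_t1: np.ndarray,
                    d_max: float,
                    ids_t: np.ndarray | None = None,
                    ids_t1: np.ndarray | None = None
                    ) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-neighbor assignment between two frames.

    Returns index pairs ``(i, j)`` into the two coordinate arrays with
    pairwise distance ≤ ``d_max``.  Pairs are accepted in ascending
    distance order; exact ties are broken by the lower spot id (the row
    index unless explicit ids are given).
    """
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    xy_t = np.asarray(xy_t, dtype=float).reshape(-1, 2)
    xy_t1 = np.asarray(xy_t1, dtype=float).reshape(-1, 2)
    if len(xy_t) == 0 or len(xy_t1) == 0:
        return []
    ids_t = np.arange(len(xy_t)) if ids_t is None else np.asarray(ids_t)
    ids_t1 = np.arange(len(xy_t1)) if ids_t1 is None else np.asarray(ids_t1)
    dist = cdist(xy_t, xy_t1)
    ii, jj = np.nonzero(dist <= d_max)
    if len(ii) == 0:
        return []
    order = np.lexsort((ids_t1[jj], ids_t[ii], dist[ii, jj]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    links: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        links.append((i, j))
    return links


def build_tracks(spots: pd.DataFrame, d_max: float) -> pd.DataFrame:
    """Chain frame-to-frame links of one species' spots into tracks.

    Input needs columns ``frame, spot_id, x_um, y_um`` (``species``
    optional, propagated).  Every spot — including unlinked singletons —
    receives a ``track_id``; links only join strictly consecutive frames.
    Returns the long-form track table sorted by (track_id, frame).
    Duplicate spot ids are rejected.
    """
    required = {"frame", "spot_id", "x_um", "y_um"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns {sorted(missing)}")
    if spots["spot_id"].duplicated().any():
        raise ValueError("duplicate spot_ids in input")
    if len(spots) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    spots = spots.sort_values(["frame", "spot_id"]).reset_index(drop=True)
    species = (spots["species"].iloc[0] if "species" in spots.columns
               else "unknown")
    # successor[spot_id] = spot_id in the next frame
    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    by_frame = {int(f): df for f, df in spots.groupby("frame")}
    frames = sorted(by_frame)
    for f in frames:
        if f + 1 not in by_frame:
            continue
        a, b = by_frame[f], by_frame[f + 1]
        links = link_frame_pair(a[["x_um", "y_um"]].to_numpy(),
                                b[["x_um", "y_um"]].to_numpy(), d_max,
                                ids_t=a["spot_id"].to_numpy(),
                                ids_t1=b["spot_id"].to_numpy())
        for i, j in links:
            sid_a = int(a["spot_id"].iloc[i])
            sid_b = int(b["spot_id"].iloc[j])
            successor[sid_a] = sid_b
            has_pred.add(sid_b)
    # walk chains from their heads, in (frame, spot_id) order for
    # deterministic track ids
    track_of: dict[int, int] = {}
    tid = 0
    for f in frames:
        for sid in by_frame[f]["spot_id"]:
            sid = int(sid)
            if sid in has_pred:
                continue
            cur = sid
            track_of[cur] = tid
            while cur in successor:
                cur = successor[cur]
                track_of[cur] = tid
            tid += 1
    out = spots.copy()
    out["track_id"] = out["spot_id"].map(track_of)
    out["species"] = species
    out = out[["track_id", "species", "frame", "spot_id", "x_um", "y_um"]]
    out = out.sort_values(["track_id", "frame"]).reset_index(drop=True)
    # one-to-one-ness: each spot in exactly one track, frames consecutive
    assert out["spot_id"].is_unique
    n_tracks = out["track_id"].nunique()
    sizes = out.groupby("track_id").size()
    logger.info("built %d tracks (%d singletons, non-motile candidates) "
                "from %d spots", n_tracks, int((sizes == 1).sum()), len(out))
    return out


def track_all_species(labeled_spots: pd.DataFrame, rules) -> pd.DataFrame:
    """Run per-species tracking on a labeled spot table.

    ``rules`` is a list of :class:`~microswarm.partition.SpeciesRule`;
    unassigned spots are not tracked.  Track ids are unique across species.
    """
    tables = []
    offset = 0
    for rule in rules:
        sub = labeled_spots[labeled_spots["species"] == rule.species]
        if len(sub) == 0:
            continue
        tracks = build_tracks(sub, rule.max_linking_distance)
        tracks["track_id"] += offset
        offset = int(tracks["track_id"].max()) + 1
        tables.append(tracks)
    if not tables:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(tables, ignore_index=True)
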