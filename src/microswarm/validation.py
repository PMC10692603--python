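"""Ground-truth comparison utilities for simulated scenes.

These helpers score pipeline output against the simulator's ground truth:
spot-to-agent matching, species-label agreement, frame-to-frame link
recovery and ensemble speed recovery.  They are evaluation tools — the
pipeline itself never sees ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import link_frame_pair

#: motility labels that mark a track as actively swimming
MOTILE_LABELS = ("motile", "telotroch", "unclassified")


def match_spots_to_truth(spots: pd.DataFrame, truth: pd.DataFrame,
                         tolerance: float = 5.0,
                         species: str | None = None
                         ) -> pd.DataFrame:
    """One-to-one match detected spots to ground-truth agents per frame.

    Greedy nearest matching within ``tolerance`` µm (the same assignment
    rule as the tracker).  Returns a table with columns
    ``frame, agent_id, spot_id, species, species_detected``; agents or
    spots without a partner are absent.
    """
    if species is not None:
        truth = truth[truth["species"] == species]
        spots = spots[spots["species"] == species] \
            if "species" in spots.columns else spots
    rows = []
    spot_sp = "species" in spots.columns
    for f, tdf in truth.groupby("frame"):
        sdf = spots[spots["frame"] == f]
        if len(sdf) == 0:
            continue
        links = link_frame_pair(tdf[["x_um", "y_um"]].to_numpy(),
                                sdf[["x_um", "y_um"]].to_numpy(),
                                tolerance)
        for i, j in links:
            rows.append([int(f), int(tdf["agent_id"].iloc[i]),
                         int(sdf["spot_id"].iloc[j]),
                         tdf["species"].iloc[i],
                         sdf["species"].iloc[j] if spot_sp else None])
    return pd.DataFrame(rows, columns=["frame", "agent_id", "spot_id",
                                       "species", "species_detected"])


def species_agreement(spots_labeled: pd.DataFrame, truth: pd.DataFrame,
                      tolerance: float = 5.0) -> float:
    """Fraction of matched spots whose label equals the agent species."""
    matched = match_spots_to_truth(spots_labeled, truth, tolerance)
    if len(matched) == 0:
        raise ValueError("no spots matched to ground truth")
    return float((matched["species"] == matched["species_detected"]).mean())


def link_recovery(tracks: pd.DataFrame, truth: pd.DataFrame,
                  species: str, tolerance: float = 5.0,
                  among_detected: bool = False) -> float:
    """Fraction of ground-truth consecutive-frame links found in tracks.

    A ground-truth link (agent a, frame f → f+1) counts as recovered when
    both of the agent's matched spots exist and sit at consecutive frames
    of the same track.  With ``among_detected`` the denominator is
    restricted to links whose both endpoints were detected as separate
    spots — this scores the tracker alone, excluding detection losses from
    transiently merged blobs, which are a segmentation phenomenon.
    """
    truth = truth[truth["species"] == species]
    sub = tracks[tracks["species"] == species]
    matched = match_spots_to_truth(sub, truth, tolerance)
    spot_of = {(r.frame, r.agent_id): r.spot_id
               for r in matched.itertuples(index=False)}
    track_of = dict(zip(sub["spot_id"], sub["track_id"]))
    frames = sorted(truth["frame"].unique())
    n_links = 0
    n_recovered = 0
    for f in frames[:-1]:
        agents_now = truth.loc[truth["frame"] == f, "agent_id"]
        agents_next = set(truth.loc[truth["frame"] == f + 1, "agent_id"])
        for a in agents_now:
            if a not in agents_next:
                continue
            s0 = spot_of.get((f, a))
            s1 = spot_of.get((f + 1, a))
            if among_detected and (s0 is None or s1 is None):
                continue
            n_links += 1
            if s0 is None or s1 is None:
                continue
            t0, t1 = track_of.get(s0), track_of.get(s1)
            if t0 is not None and t0 == t1:
                n_recovered += 1
    if n_links == 0:
        raise ValueError(f"no ground-truth links for species {species!r}")
    return n_recovered / n_links


def ensemble_speed(metrics: pd.DataFrame, species: str,
                   min_links: int = 10) -> float:
    """Link-weighted ensemble mean speed of motile tracks (µm/s).

    Total path over total duration, pooled across tracks with at least
    ``min_links`` links and a motile motility label.  Weighting by links
    makes the estimate insensitive to track fragmentation.
    """
    sel = metrics[(metrics["species"] == species)
                  & (metrics["n_links"] >= min_links)
                  & (metrics["motility"].isin(MOTILE_LABELS))]
    if len(sel) == 0:
        raise ValueError(f"no motile tracks for species {species!r}")
    return float(sel["total_um"].sum() / sel["duration_s"].sum())


def configured_speed(truth: pd.DataFrame, species: str) -> float:
    """Mean configured speed of the species' swimming agents (µm/s)."""
    sub = truth[(truth["species"] == species)
                & (truth["mode"] == "swimming")]
    if len(sub) == 0:
        raise ValueError(f"no swimming agents for species {species!r}")
    return float(sub.groupby("agent_id")["speed_ums"].first().mean())
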