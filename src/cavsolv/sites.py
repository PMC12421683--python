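"""Hydration-site detection and per-site thermodynamics.

Hydration sites are 1 Å-radius spheres of high time-averaged water density.
Candidate centers are the observed water-oxygen positions themselves; a
greedy pass repeatedly accepts the candidate whose sphere holds the most
remaining observations, removes those observations, and stops when the best
sphere's occupancy per frame drops below ``min_occupancy_ratio`` times the
bulk expectation ``rho0 * (4/3) pi r^3``.  Accepted centers are kept at
least two radii apart, so site spheres are disjoint.

A site is classified as a donor (acceptor) when at least 60 % of its
occupant waters donate (accept) a hydrogen bond to the solute; "both" when
both fractions reach the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Trajectory
from .energetics import EnergyEvaluator, InteractionModel, WaterEnergies
from .hbonds import HBondCriteria, HBondEngine

SITE_RADIUS = 1.0


@dataclass
class HydrationSite:
    center: np.ndarray
    radius: float = SITE_RADIUS
    occupancy: float = 0.0
    n_obs: int = 0
    e_sw: float = 0.0
    e_ww: float = 0.0
    e_tot_ref: float = 0.0
    donor_fraction: float = 0.0
    acceptor_fraction: float = 0.0
    classification: str = "neither"
    mean_sw_hbonds: float = 0.0
    mean_ww_hbonds: float = 0.0
    mean_neighbors: float = 0.0


def _observations(trajectory: Trajectory, region, frame_range=None):
    """Water-oxygen observations inside the region as (frame ordinal, water
    ordinal, position) arrays."""
    oxy = trajectory.topology.solvent_oxygen_indices
    frames = trajectory.frames
    if frame_range is not None:
        frames = frames[frame_range[0] : frame_range[1]]
    pos, fi, wi = [], [], []
    for k, frame in enumerate(frames):
        p = frame.coordinates[oxy]
        mask = _region_mask(p, region)
        pos.append(p[mask])
        fi.append(np.full(int(mask.sum()), k))
        wi.append(np.flatnonzero(mask))
    return (
        np.concatenate(fi),
        np.concatenate(wi),
        np.vstack(pos) if pos else np.zeros((0, 3)),
        len(frames),
    )


def _region_mask(points: np.ndarray, region) -> np.ndarray:
    """Region is either a (lo, hi) bounding box pair or an object exposing
    ``contains(points)`` (e.g. a ligand-proximity subvolume spec)."""
    if hasattr(region, "contains"):
        return region.contains(points)
    lo, hi = np.asarray(region[0], float), np.asarray(region[1], float)
    return np.all((points >= lo) & (points <= hi), axis=1)


def find_sites(
    trajectory: Trajectory,
    region,
    min_occupancy_ratio: float = 2.0,
    rho0: float = 0.0334,
    radius: float = SITE_RADIUS,
    frame_range=None,
) -> list[HydrationSite]:
    """Greedy hydration-site detection over in-region oxygen observations."""
    fi, wi, pos, n_frames = _observations(trajectory, region, frame_range)
    if len(pos) == 0:
        return []
    bulk_expect = rho0 * (4.0 / 3.0) * np.pi * radius ** 3
    threshold = min_occupancy_ratio * bulk_expect * n_frames
    tree = cKDTree(pos)
    balls = tree.query_ball_point(pos, r=radius)
    alive = np.ones(len(pos), dtype=bool)
    allowed = np.ones(len(pos), dtype=bool)  # >= 2 r from accepted centers
    sites = []
    while True:
        counts = np.array(
            [np.sum(alive[b]) if allowed[i] else -1 for i, b in enumerate(balls)]
        )
        best = int(np.argmax(counts))  # argmax ties -> lowest index
        if counts[best] < threshold or counts[best] <= 0:
            break
        members = np.array([j for j in balls[best] if alive[j]], dtype=np.int64)
        sites.append(
            HydrationSite(
                center=pos[best].copy(),
                radius=radius,
                occupancy=len(members) / n_frames,
                n_obs=len(members),
            )
        )
        alive[members] = False
        allowed[tree.query_ball_point(pos[best], r=2.0 * radius)] = False
    return sites


def site_thermo(
    site: HydrationSite,
    trajectory: Trajectory,
    model: InteractionModel,
    criteria: HBondCriteria = HBondCriteria(),
    energies: Sequence[WaterEnergies] | None = None,
    frame_range=None,
) -> HydrationSite:
    """Average energetics, hydrogen-bond counts and donor/acceptor fractions
    over the waters occupying the site sphere."""
    top = trajectory.topology
    oxy = top.solvent_oxygen_indices
    frames = trajectory.frames
    if frame_range is not None:
        frames = frames[frame_range[0] : frame_range[1]]
    ev = EnergyEvaluator(top, model) if energies is None else None
    engine = HBondEngine(top, criteria, frames[0])
    sum_sw = sum_ww = sum_hb_sw = sum_hb_ww = 0.0
    n_donate = n_accept = n_occ = 0
    for k, frame in enumerate(frames):
        d = np.linalg.norm(frame.coordinates[oxy] - site.center, axis=1)
        occ = np.flatnonzero(d <= site.radius)
        if len(occ) == 0:
            continue
        we = energies[k] if energies is not None else ev.frame_energies(frame)
        hb_sw, hb_ww, donates, accepts = engine.per_water_counts(frame)
        sum_sw += float(np.sum(we.e_sw[occ]))
        sum_ww += float(np.sum(we.e_ww[occ]))
        sum_hb_sw += float(np.sum(hb_sw[occ]))
        sum_hb_ww += float(np.sum(hb_ww[occ]))
        n_donate += int(np.sum(donates[occ]))
        n_accept += int(np.sum(accepts[occ]))
        n_occ += len(occ)
    if n_occ == 0:
        raise ValueError("site has zero occupancy over the analysis window")
    site.e_sw = sum_sw / n_occ
    site.e_ww = sum_ww / n_occ
    site.e_tot_ref = site_total_energy(site.e_sw, site.e_ww, model.e_neat)
    site.mean_sw_hbonds = sum_hb_sw / n_occ
    site.mean_ww_hbonds = sum_hb_ww / n_occ
    site.donor_fraction = n_donate / n_occ
    site.acceptor_fraction = n_accept / n_occ
    site.occupancy = n_occ / len(frames)
    site.n_obs = n_occ
    site.classification = classify_site(site.donor_fraction, site.acceptor_fraction)
    return site


def site_total_energy(e_sw: float, e_ww: float, e_neat: float = 0.0) -> float:
    """Total per-site energy from its solute-water and water-water parts,
    referenced to ``e_neat`` (pass 0 when the parts are already referenced)."""
    return e_sw + e_ww - e_neat


def classify_site(
    donor_fraction: float, acceptor_fraction: float, threshold: float = 0.60
) -> str:
    """Donor/acceptor/both/neither by the 60 %-of-occupants rule."""
    for f in (donor_fraction, acceptor_fraction):
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
    d = donor_fraction >= threshold
    a = acceptor_fraction >= threshold
    if d and a:
        return "both"
    if d:
        return "donor"
    if a:
        return "acceptor"
    return "neither"


def sites_to_dataframe(sites: Sequence[HydrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": np.arange(len(sites)),
            "x": [s.center[0] for s in sites],
            "y": [s.center[1] for s in sites],
            "z": [s.center[2] for s in sites],
            "occupancy": [s.occupancy for s in sites],
            "e_sw": [s.e_sw for s in sites],
            "e_ww": [s.e_ww for s in sites],
            "e_tot_ref": [s.e_tot_ref for s in sites],
            "donor_fraction": [s.donor_fraction for s in sites],
            "acceptor_fraction": [s.acceptor_fraction for s in sites],
            "classification": [s.classification for s in sites],
            "mean_sw_hbonds": [s.mean_sw_hbonds for s in sites],
        }
    )


def write_sites_pdb(sites: Sequence[HydrationSite], path) -> None:
    """One pseudo-atom per site; occupancy in the occupancy column and the
    classification encoded in the B-factor (donor 1, acceptor 2, both 3,
    neither 0)."""
    code = {"neither": 0.0, "donor": 1.0, "acceptor": 2.0, "both": 3.0}
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            fh.write(
                "HETATM{serial:>5d}  O   HST A{res:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           O\n".format(
                    serial=i,
                    res=i,
                    x=s.center[0],
                    y=s.center[1],
                    z=s.center[2],
                    occ=min(s.occupancy, 9.99),
                    b=code[s.classification],
                )
            )
        fh.write("END\n")
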