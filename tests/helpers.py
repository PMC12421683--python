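"""Independent brute-force oracles used to cross-check the vectorised
implementation.  Everything here is written with plain Python loops and its
own periodic-image handling, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

COULOMB = 332.0636


def oracle_min_image_distance(a, b, box):
    """Minimum distance over the 27 periodic images of b."""
    best = math.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        img = (
            b[0] + sx * box[0] - a[0],
            b[1] + sy * box[1] - a[1],
            b[2] + sz * box[2] - a[2],
        )
        best = min(best, math.sqrt(img[0] ** 2 + img[1] ** 2 + img[2] ** 2))
    return best


def _mi(a, b, box):
    """Nearest-image displacement b-a by explicit image search."""
    best, bestd = None, math.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        v = (
            b[0] + sx * box[0] - a[0],
            b[1] + sy * box[1] - a[1],
            b[2] + sz * box[2] - a[2],
        )
        d = v[0] ** 2 + v[1] ** 2 + v[2] ** 2
        if d < bestd:
            best, bestd = v, d
    return best, math.sqrt(bestd)


def oracle_atom_pair_energy(ci, cj, qi, qj, si, sj, ei, ej, r):
    e = 0.0
    if qi * qj != 0.0:
        e += COULOMB * qi * qj / r
    eps = math.sqrt(ei * ej)
    if eps > 0.0:
        sig = 0.5 * (si + sj)
        sr6 = (sig / r) ** 6
        e += 4.0 * eps * (sr6 * sr6 - sr6)
    return e


def oracle_group_pair_energy(coords_a, coords_b, q_a, q_b, s_a, s_b, e_a, e_b, cutoff, box):
    """Plain per-atom-pair cutoff (the generic pair_energy rule)."""
    total = 0.0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            _, r = _mi(coords_a[i], coords_b[j], box)
            if r <= cutoff and (q_a[i] * q_b[j] != 0 or e_a[i] * e_b[j] > 0):
                total += oracle_atom_pair_energy(
                    coords_a[i], coords_b[j], q_a[i], q_b[j], s_a[i], s_b[j], e_a[i], e_b[j], r
                )
    return total


def _water_groups(top):
    """Solvent molecule -> atom index list, ordered by molecule id."""
    groups = {}
    for a in top.atoms:
        if a.role != "solute":
            groups.setdefault(a.molecule_id, []).append(a.index)
    return [groups[m] for m in sorted(groups)]


def oracle_water_energies(frame, top, model):
    """Per-water e_sw / e_ww with the package's stated conventions:
    oxygen-gated molecular cutoff against solute atoms; O-O gated molecule
    pairs for water-water; each pair split by ww_split."""
    coords, box = frame.coordinates, frame.box
    waters = _water_groups(top)
    oxygens = [
        [i for i in w if top.atoms[i].role == "solvent_oxygen"][0] for w in waters
    ]
    solute = [a.index for a in top.atoms if a.role == "solute"]
    q = [a.charge for a in top.atoms]
    s = [a.lj_sigma for a in top.atoms]
    e = [a.lj_epsilon for a in top.atoms]
    n = len(waters)
    e_sw = [0.0] * n
    e_ww = [0.0] * n
    for wi, w in enumerate(waters):
        for sa in solute:
            _, r_gate = _mi(coords[oxygens[wi]], coords[sa], box)
            if r_gate > model.cutoff:
                continue
            for ai in w:
                _, r = _mi(coords[ai], coords[sa], box)
                if q[ai] * q[sa] != 0 or e[ai] * e[sa] > 0:
                    e_sw[wi] += oracle_atom_pair_energy(
                        coords[ai], coords[sa], q[ai], q[sa], s[ai], s[sa], e[ai], e[sa], r
                    )
    for wi in range(n):
        for wj in range(wi + 1, n):
            _, roo = _mi(coords[oxygens[wi]], coords[oxygens[wj]], box)
            if roo > model.cutoff:
                continue
            pair = 0.0
            for ai in waters[wi]:
                for aj in waters[wj]:
                    _, r = _mi(coords[ai], coords[aj], box)
                    if q[ai] * q[aj] != 0 or e[ai] * e[aj] > 0:
                        pair += oracle_atom_pair_energy(
                            coords[ai], coords[aj], q[ai], q[aj], s[ai], s[aj], e[ai], e[aj], r
                        )
            e_ww[wi] += model.ww_split * pair
            e_ww[wj] += model.ww_split * pair
    return np.array(e_sw), np.array(e_ww)


def oracle_total_energy(frame, top, model):
    """Unique-pair total nonbonded energy under the same conventions."""
    e_sw, e_ww = oracle_water_energies(frame, top, model)
    # undo the per-partner split to recover the unique-pair water-water total
    return float(np.sum(e_sw) + np.sum(e_ww) / (2.0 * model.ww_split))


def oracle_hbonds(frame, top, criteria, attach_coords=None):
    """Exhaustive triple-loop H-bond detection.

    Returns a set of (donor_heavy, hydrogen, acceptor) index triples.
    """
    coords, box = frame.coordinates, frame.box
    attach = coords if attach_coords is None else attach_coords
    polar = set(criteria.polar_elements)
    donors = []  # (heavy, hydrogen)
    acceptors = []
    waters = _water_groups(top)
    for w in waters:
        o = [i for i in w if top.atoms[i].role == "solvent_oxygen"][0]
        acceptors.append(o)
        for i in w:
            if top.atoms[i].role == "solvent_hydrogen":
                donors.append((o, i))
    solute = [a.index for a in top.atoms if a.role == "solute"]
    solute_polar = [i for i in solute if top.atoms[i].element in polar]
    acceptors.extend(solute_polar)
    for h in solute:
        if top.atoms[h].element != "H":
            continue
        best, bestd = None, 1.25
        for p in solute_polar:
            if top.atoms[p].residue_id != top.atoms[h].residue_id:
                continue
            d = math.dist(attach[p], attach[h])
            if d < bestd:
                best, bestd = p, d
        if best is not None:
            donors.append((best, h))
    found = set()
    cos_max = math.cos(math.radians(criteria.angle_max))
    for dheavy, h in donors:
        for acc in acceptors:
            if acc == dheavy:
                continue
            da = top.atoms[dheavy]
            aa = top.atoms[acc]
            d_solv = da.role != "solute"
            a_solv = aa.role != "solute"
            if da.molecule_id == aa.molecule_id and (d_solv or a_solv):
                continue
            if (not d_solv) and (not a_solv) and da.residue_id == aa.residue_id:
                continue
            _, r = _mi(coords[dheavy], coords[acc], box)
            if not (1e-9 < r < criteria.heavy_distance_max):
                continue
            if criteria.angle_convention == "acceptor_donor_hydrogen":
                v1, _ = _mi(coords[dheavy], coords[acc], box)
                v2, _ = _mi(coords[dheavy], coords[h], box)
                dot = sum(a * b for a, b in zip(v1, v2))
                n1 = math.sqrt(sum(a * a for a in v1))
                n2 = math.sqrt(sum(a * a for a in v2))
                if n1 * n2 == 0 or dot / (n1 * n2) <= cos_max:
                    continue
            else:
                v1, _ = _mi(coords[h], coords[acc], box)
                v2, _ = _mi(coords[h], coords[dheavy], box)
                dot = sum(a * b for a, b in zip(v1, v2))
                n1 = math.sqrt(sum(a * a for a in v1))
                n2 = math.sqrt(sum(a * a for a in v2))
                if n1 * n2 == 0 or dot / (n1 * n2) >= math.cos(
                    math.radians(180.0 - criteria.angle_max)
                ):
                    continue
            found.add((dheavy, h, acc))
    return found


def oracle_neighbors(frame, top, group_atoms, cutoff):
    count = 0
    for a in top.atoms:
        if a.role != "solvent_oxygen":
            continue
        for g in group_atoms:
            _, r = _mi(frame.coordinates[a.index], frame.coordinates[g], frame.box)
            if r <= cutoff:
                count += 1
                break
    return count


def oracle_select_voxels(spec, ligand_coords, distance):
    """Brute-force scan of all voxel centers."""
    sel = []
    flat = 0
    for i in range(spec.shape[0]):
        for j in range(spec.shape[1]):
            for k in range(spec.shape[2]):
                c = (
                    spec.origin[0] + (i + 0.5) * spec.spacing,
                    spec.origin[1] + (j + 0.5) * spec.spacing,
                    spec.origin[2] + (k + 0.5) * spec.spacing,
                )
                for p in ligand_coords:
                    if math.dist(c, p) <= distance:
                        sel.append(flat)
                        break
                flat += 1
    return sel
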