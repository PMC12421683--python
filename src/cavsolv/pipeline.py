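"""End-to-end orchestration: energies -> grid -> H-bonds -> hydration sites
-> subvolumes -> rigid/flexible comparison, with all outputs on disk.

The run configuration is a TOML file (or an equivalent nested dict):

.. code-block:: toml

    [system]
    topology = "system.pdb"        # PDB with solute + waters
    params = "system_params.tsv"   # sidecar parameter table
    rigid = "rigid.xyz"            # frames (multi-model PDB or XYZ-with-box)
    flexible = "flexible.xyz"
    ligand = "ligand.pdb"          # aligned reference ligand (heavy atoms)

    [model]
    cutoff = 6.0
    e_neat = -10.97
    rho0 = 0.0334

    [grid]
    origin = [-9.0, -9.0, -9.0]
    shape = [36, 36, 36]
    spacing = 0.5

    [criteria]
    heavy_distance_max = 3.6
    angle_max = 30.0
    neighbor_cutoff = 3.6

    [subvolumes]
    distances = [3.0, 10.0]

    [hsa]
    min_occupancy_ratio = 2.0

    [blocks]
    n_blocks = 4

    [output]
    dir = "results"
"""

from __future__ import annotations

import json
import logging
from pathlib import Path


from .core import (
    ReferenceStructure,
    read_frames_pdb,
    read_frames_xyz,
    read_reference_pdb,
    read_topology,
    superpose,
)
from .energetics import InteractionModel
from .grid import GistGrid, GridSpec, accumulate, finalize, write_dx
from .hbonds import HBondCriteria, group_stats, read_groups_tsv
from .sites import find_sites, site_thermo, sites_to_dataframe, write_sites_pdb
from .subvolume import (
    SubvolumeSpec,
    block_average,
    compare,
    comparison_table,
    integrate,
    per_frame_subvolume_series,
    select_voxels,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapper

    return deco


def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


@_stage("input")
def _load_inputs(cfg: dict):
    sys_cfg = cfg.get("system", {})
    for key in ("topology", "params", "rigid", "flexible", "ligand"):
        if key not in sys_cfg:
            raise FileNotFoundError(f"missing input '{key}' in [system]")
        if not Path(sys_cfg[key]).exists():
            raise FileNotFoundError(f"input '{key}' not found: {sys_cfg[key]}")
    top = read_topology(sys_cfg["topology"], sys_cfg["params"])
    trajs = {}
    for label in ("rigid", "flexible"):
        p = Path(sys_cfg[label])
        if p.suffix == ".xyz":
            trajs[label] = read_frames_xyz(p, top)
        else:
            trajs[label] = read_frames_pdb(p, top)
    ligand = read_reference_pdb(sys_cfg["ligand"])
    return top, trajs, ligand


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the full analysis described by ``config`` (TOML path or dict).

    Writes DX grids, subvolume comparison tables, hydration-site tables/PDBs
    and a JSON run log; returns a summary dict with the comparison rows and
    resolved parameters.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir or cfg.get("output", {}).get("dir", "cavsolv_out"))
    out.mkdir(parents=True, exist_ok=True)

    top, trajs, ligand = _load_inputs(cfg)
    align = cfg.get("align", {})
    if align.get("enabled", False):
        # frames are assumed pre-aligned by default; when enabled, every
        # frame is superposed onto frame 0 of its own run over the selection
        sel = [int(i) for i in align["selection"]]
        for label, traj in trajs.items():
            ref = ReferenceStructure(
                traj.frames[0].coordinates[sel], [str(i) for i in sel]
            )
            traj.frames = [superpose(f, ref, sel) for f in traj.frames]
    mc = cfg.get("model", {})
    model = InteractionModel(
        cutoff=float(mc.get("cutoff", 10.0)),
        e_neat=float(mc.get("e_neat", -12.259)),
        rho0=float(mc.get("rho0", 0.0334)),
        ww_split=float(mc.get("ww_split", 0.5)),
    )
    gc = cfg.get("grid", {})
    spec = GridSpec(
        origin=tuple(gc.get("origin", (-9.0, -9.0, -9.0))),
        spacing=float(gc.get("spacing", 0.5)),
        shape=tuple(gc.get("shape", (36, 36, 36))),
    )
    cc = cfg.get("criteria", {})
    criteria = HBondCriteria(
        heavy_distance_max=float(cc.get("heavy_distance_max", 3.6)),
        angle_max=float(cc.get("angle_max", 30.0)),
        angle_convention=cc.get("angle_convention", "acceptor_donor_hydrogen"),
    )
    neighbor_cutoff = float(cc.get("neighbor_cutoff", 3.6))
    distances = [float(d) for d in cfg.get("subvolumes", {}).get("distances", (3.0,))]
    n_blocks = int(cfg.get("blocks", {}).get("n_blocks", 4))
    hsa_ratio = float(cfg.get("hsa", {}).get("min_occupancy_ratio", 2.0))

    grids: dict[str, GistGrid] = {}
    for label, traj in trajs.items():
        grids[label] = _run_grid(traj, model, spec, criteria)
        for name in ("g", "e_per_frame", "e_dens", "hb_sw", "hb_ww"):
            write_dx(grids[label], name, out / f"{label}_{name}.dx")

    rows = []
    block_info = {}
    for d in distances:
        sub = SubvolumeSpec(ligand_heavy_atoms=ligand, distance=d)
        vox = select_voxels(spec, sub)
        iq = {}
        stats = {}
        for label, traj in trajs.items():
            iq[label] = integrate(grids[label], vox, distance=d)
            series = per_frame_subvolume_series(traj, model, spec, vox, criteria)
            stats[label] = {
                k: block_average(series[k].to_numpy(), n_blocks)
                for k in ("e_tot", "n_water", "hb_sw")
            }
        rows.append(compare(iq["rigid"], iq["flexible"], stats["rigid"], stats["flexible"]))
        block_info[d] = {
            label: {k: {"mean": s.mean, "sem": s.sem} for k, s in stats[label].items()}
            for label in stats
        }
    table = comparison_table(rows)
    table.to_csv(out / "table1_totals.tsv", sep="\t", index=False)

    hsa_region = SubvolumeSpec(ligand_heavy_atoms=ligand, distance=max(distances))
    sites = {}
    for label, traj in trajs.items():
        found = find_sites(traj, hsa_region, min_occupancy_ratio=hsa_ratio, rho0=model.rho0)
        sites[label] = [site_thermo(s, traj, model, criteria) for s in found]
        sites_to_dataframe(sites[label]).to_csv(out / f"{label}_sites.tsv", sep="\t", index=False)
        write_sites_pdb(sites[label], out / f"{label}_sites.pdb")

    groups_path = cfg.get("system", {}).get("groups")
    if groups_path:
        for label, traj in trajs.items():
            groups = read_groups_tsv(groups_path, top, traj.frames[0])
            gs = group_stats(traj, groups, criteria, neighbor_cutoff)
            gs.to_dataframe().to_csv(out / f"{label}_group_stats.tsv", sep="\t", index=False)

    log = {
        "model": vars(model),
        "grid": {"origin": spec.origin, "spacing": spec.spacing, "shape": spec.shape},
        "criteria": {
            "heavy_distance_max": criteria.heavy_distance_max,
            "angle_max": criteria.angle_max,
            "angle_convention": criteria.angle_convention,
            "neighbor_cutoff": neighbor_cutoff,
        },
        "distances": distances,
        "n_blocks": n_blocks,
        "n_frames": {k: t.n_frames for k, t in trajs.items()},
        "blocks": block_info,
        "n_sites": {k: len(v) for k, v in sites.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return {"comparison": rows, "table": table, "sites": sites, "log": log}


@_stage("grid")
def _run_grid(traj, model, spec, criteria):
    return finalize(accumulate(traj, model, spec, criteria), model)
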