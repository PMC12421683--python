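"""Measure the neat-liquid reference energy of the synthetic water model.

Protocol (the run whose result is frozen in ``cavsolv.constants``):
64 waters at 0.0334 molecules/A^3 (cubic box), 300 K, 6 A truncation,
6000 equilibration sweeps, then 600 frames saved every 10 sweeps.
``e_neat`` is the mean potential energy per molecule over the saved frames;
``rho0`` is the (imposed) number density.

Run:  python scripts/calibrate_neat.py [--seed 2027]
"""

import argparse

import numpy as np

from cavsolv.synthetic import GeneratorConfig, default_model, gen_mc_water


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2027)
    ap.add_argument("--n-waters", type=int, default=64)
    ap.add_argument("--rho", type=float, default=0.0334)
    args = ap.parse_args()

    n = args.n_waters
    box = (n / args.rho) ** (1.0 / 3.0)
    cfg = GeneratorConfig(
        n_waters=n,
        box=(box, box, box),
        n_frames=600,
        seed=args.seed,
        mode="metropolis",
        sweeps_per_frame=10,
        n_equil_sweeps=6000,
    )
    res = gen_mc_water(cfg, model=default_model(), return_details=True)
    e = np.array(res.frame_energies) / n
    q = len(e) // 4
    quarters = [float(e[i * q : (i + 1) * q].mean()) for i in range(4)]
    print(f"box {box:.4f} A, acceptance {res.acceptance_rate:.3f}")
    print("per-molecule energy by quarter:", [round(v, 4) for v in quarters])
    print(f"e_neat = {e.mean():.4f} kcal/mol (sd of frame means {e.std(ddof=1):.4f})")
    print(f"rho0   = {n / box ** 3:.6f} molecules/A^3")


if __name__ == "__main__":
    main()
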