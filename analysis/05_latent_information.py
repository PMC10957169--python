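#!/usr/bin/env python
"""Information about the latent variable across the (eta, eps) plane.

Computes the Gaussian-MLE mutual information between population
activity and a quasi-static latent variable over the same grid as the
regime map.  Information rises with activity (lower eps, higher eta)
up to the point where the population saturates and the approximation
breaks down, so the highest valid information sits just above the
no-avalanche/high-activity boundary — while avalanches (and the
crackling relation) extend across a much wider band of eps.  Observing
avalanche criticality therefore does not by itself imply an
optimal-information network state.

Writes results/05_information_map.tsv.

    python analysis/05_latent_information.py [--seed 61]
"""

import argparse
from pathlib import Path

import numpy as np

import latent_avalanches as la
from latent_avalanches import draw_couplings

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=61)
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--T", type=int, default=1000, help="observation window (bins)")
args = parser.parse_args()

N = 128
cfg = la.SimulationConfig(
    n_neurons=N, n_fields=1, eta=1.0, epsilon=0.0, tau_F="quasistatic",
    n_steps=10, n_segments=1, seed=args.seed,
)
J = draw_couplings(cfg, np.random.default_rng(args.seed))

etas = np.arange(1.0, 10.5, 1.0)
epsilons = np.arange(0.0, 14.5, 1.0)
print(f"information surface on a {len(etas)}x{len(epsilons)} grid, T={args.T} ...")
surface = la.information_surface(J, etas, epsilons, T=args.T)

valid = surface[surface.valid]
best = valid.loc[valid.info_nats.idxmax()]
print(f"{len(valid)}/{len(surface)} grid points inside the valid region")
print(f"highest valid information: {best.info_nats:.2f} nats at "
      f"eta={best.eta:.0f}, eps={best.epsilon:.0f} "
      f"(regime: {la.classify_regime(best.eta, best.epsilon, J)})")

args.out.mkdir(parents=True, exist_ok=True)
surface.to_csv(args.out / "05_information_map.tsv", sep="\t", index=False)
print(f"table written to {args.out}/05_information_map.tsv")
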