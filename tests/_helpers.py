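"""Shared test utilities."""

import numpy as np

from dcsm.data_model import BinObservation, PairDataset, PersonTrajectory
from dcsm.dcsm_core import PairLayout


def dataset_from_vectors(spec, Y, sexes_per_pair, observed=None):
    """Wrap raw pair vectors (n_pairs, 2*k*n_bins) into a PairDataset.

    ``observed`` optionally maps flat positions to keep per pair (a
    missingness pattern); by default everything is observed.
    """
    layout = PairLayout(spec.n_traits, spec.grid.n_bins)
    pairs = []
    for pi, y in enumerate(np.atleast_2d(Y)):
        keep = set(range(layout.size)) if observed is None else set(observed[pi])
        twins = []
        for twin in range(2):
            traj = PersonTrajectory(
                person_id=f"p{pi}_{twin}", pair_id=f"pair{pi}",
                sex=sexes_per_pair[pi][twin],
            )
            for t in range(spec.grid.n_bins):
                values = {}
                for ti, trait in enumerate(spec.traits):
                    pos = layout.index(twin, ti, t)
                    if pos in keep:
                        values[trait] = float(y[pos])
                if values:
                    traj.observations[t] = BinObservation(
                        age=spec.grid.bin_start(t), values=values)
            twins.append(traj)
        pairs.append(tuple(twins))
    return PairDataset(grid=spec.grid, pairs=pairs, trait_labels=spec.traits)
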