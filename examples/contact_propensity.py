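"""Interaction propensity and RMSF on a scripted peptide-domain complex.

Builds a complex trajectory in which chosen peptide/domain residue pairs are
placed inside the 4 A contact cutoff in a scheduled fraction of frames, then
measures the propensity matrix and the peptide's per-residue fluctuation.
"""

import numpy as np

import pdzcoupling as pz
from pdzcoupling import synthetic_data as sd
from pdzcoupling.structure_io import Selection

peptide = "GSTFSLWQDIP"
pmap = pz.assign_pdz_positions(peptide)

# script the anchor region: P0 aspartate (residue 9) always bound, the P-2
# tryptophan (residue 7) bound in 60% of frames, P-5 never bound
schedule = {(9, 1): 1.0, (7, 2): 0.6, (4, 3): 0.0}
traj, truth = sd.gen_complex_trajectory(peptide, domain_size=4,
                                        contact_schedule=schedule,
                                        cutoff=4.0, n_frames=50, seed=8)

pm = pz.interaction_propensity(traj, Selection(chain_id="B"),
                               Selection(chain_id="A"), cutoff=4.0)
for (pi, dj), frac in sorted(schedule.items()):
    got = pm.values[pi - 1, dj - 1]
    print(f"peptide {peptide[pi - 1]}{pi} (P{pmap[pi]:+d}) vs domain residue "
          f"{dj}: scheduled {frac:.1f}, measured {got:.2f}")
# Measured propensities equal the scheduled frame fractions exactly: the
# statistic is a strict frame count of sub-cutoff side-chain contacts.

noisy = pz.Trajectory(traj.topology,
                      traj.frames + 0.3 * np.random.default_rng(8)
                      .standard_normal(traj.frames.shape))
prof = pz.rmsf(noisy, Selection(chain_id="B", atom_names=frozenset({"CA"})),
               fit=False)
print("peptide RMSF (A):",
      ", ".join(f"{l.split(':')[2]}{l.split(':')[1]}={v:.2f}"
                for l, v in zip(prof.labels, prof.values)))
# With 0.3 A isotropic jitter added, residues fluctuate near
# 0.3*sqrt(3) ~ 0.52 A — except the P-2 tryptophan, whose scripted
# binding/unbinding (60% bound) adds large real motion between its bound
# and unbound positions, exactly the propensity/RMSF coupling the analysis
# is designed to expose.
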