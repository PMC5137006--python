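"""Helix-transition statistics on synthetic PDB fixtures.

Generates seeded multi-chain PDB files with known per-transition means
and Gaussian (rho, theta) noise, then runs the full pipeline: four
nested filtering levels, per-transition histograms, means, 50%
confinement half-widths, and the isolated-pair-hypothesis (IPH) energy
table comparing heterogeneous transitions with their homogeneous
averages.
"""

import tempfile
from pathlib import Path

from turntilt import (
    FixtureSpec,
    TransitionStats,
    confinement,
    default_transform,
    extract_transitions,
    iph_exact_targets,
    iph_table,
    make_helix_pdb,
    predictability_fraction,
    read_structures,
    transition_means,
)

t = default_transform()
spec = FixtureSpec(targets=iph_exact_targets("ALG"),
                   samples_per_transition=150,
                   sigma_rho=0.1, sigma_theta=3.0, seed=8)

with tempfile.TemporaryDirectory() as tmp:
    paths, truth = make_helix_pdb(spec, Path(tmp), t)
    print(f"generated {len(paths)} PDB file(s), "
          f"{len(truth)} transitions with known ground truth")

    samples = extract_transitions(read_structures(paths), t)
    for lvl in range(4):
        print(f"  level {lvl}: {(samples['level'] >= lvl).sum()} transitions")

    stats = TransitionStats.from_samples(samples).compress_and_normalize()
    means = transition_means(stats, t)
    aa = means[(means.src == "A") & (means.dst == "A") & (means.level == 0)]
    print(f"A->A level-0 mean: phi = {aa['phi'].iloc[0]:.1f} deg, "
          f"psi = {aa['psi'].iloc[0]:.1f} deg, "
          f"rho = {aa['rho'].iloc[0]:.2f}, theta = {aa['theta'].iloc[0]:.1f}")

    conf = confinement(samples[samples.level >= 0])
    print("50% confinement half-widths (theta [deg], rho [Res/Turn]):")
    for row in conf.per_level.itertuples(index=False):
        print(f"  level {row.level}: ({row.d_theta:.1f}, {row.d_rho:.2f})"
              f"  from {row.n} samples")

    table = iph_table(means, level=1)
    frac = predictability_fraction(table, 1.0)
    print(f"IPH: {100 * frac:.0f}% of filled heterogeneous transitions are "
          "within 1 EU of their homogeneous average")
    print("(these fixtures are built IPH-exact, so only noise separates "
          "measured from predicted means)")
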