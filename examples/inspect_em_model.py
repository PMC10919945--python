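"""Fit the EM ensemble on one dataset and inspect what it learned.

The EM estimates, without any labels, how reliable each base-quality
stratum ("learner") is. Here the simulator plants known per-learner error
rates; the learned confusion-matrix diagonals should recover them.
"""

import tempfile

import numpy as np

from snvem.em import EMConfig, run_em
from snvem.pileup import LearnerSpec, build_pileups
from snvem.simulate import SimConfig, simulate

RATES = (0.05, 0.01, 0.001)  # planted substitution error per learner
BASEQ = (15, 25, 35)  # quality value that tags each stratum

with tempfile.TemporaryDirectory() as td:
    sim = simulate(
        SimConfig(
            seed=3,
            genome_length=30_000,
            coverage=20.0,
            error_rates=RATES,
            learner_baseq=BASEQ,
            learner_weights=(1 / 3, 1 / 3, 1 / 3),
        ),
        td,
    )
    pileups = build_pileups(sim.reads_sam, sim.reference_fasta)
    result = run_em(pileups, LearnerSpec(), EMConfig())

print(f"EM converged={result.converged} after {result.n_iters} iterations")
print("objective trace:", [round(x, 1) for x in result.objective_trace[:5]], "...")

spec = LearnerSpec()
for q, e in zip(BASEQ, RATES):
    j = spec.assign(q)
    # diagonal of the homozygous rows: P(emit x | genotype xx), i.e. the
    # learner's per-base accuracy; should match 1 - planted error rate
    diag = np.mean([result.model.theta[j, k, k] for k in range(4)])
    print(
        f"learner bin {j} (Q{q}): learned accuracy {diag:.4f}, "
        f"planted {1 - e:.4f}"
    )
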