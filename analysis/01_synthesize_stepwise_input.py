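#!/usr/bin/env python
"""Synthesise the stepwise population miR-9 input from per-cell locus activation.

Draws a 500-cell population in which pri-mir-9-4/-9-5 switch on near 30 hpf
and pri-mir-9-1 near 36.5 hpf, writes the population-mean input curve and the
per-cell co-expression summary, and reports where the sharp rise occurs.
"""

import numpy as np

from her6switch.config import load_reference_config
from her6switch.io import write_table
from her6switch.locus import coexpression_fractions, population_profile, simulate_locus_activation
from her6switch.seeds import component_seed

OUT = "results/01_synthetic_input"


def main() -> None:
    cfg = load_reference_config()
    seed = component_seed(cfg.seed, "locus-activation")
    pop = simulate_locus_activation(cfg.locus.activation_config(seed))
    profile = population_profile(pop, baseline=cfg.locus.baseline)

    write_table(profile.to_frame(pop.t_grid), f"{OUT}/population_input.tsv", seed=seed)
    times = np.arange(25.0, 48.5, 1.0)
    summary = coexpression_fractions(pop, times)
    write_table(summary.to_frame(), f"{OUT}/coexpression.tsv", seed=seed)

    m = np.asarray(profile(pop.t_grid))
    slope = np.gradient(m, pop.t_grid)
    t_rise = pop.t_grid[np.argmax(slope)]
    s37 = coexpression_fractions(pop, [30.0, 37.0, 48.0])
    print(f"population input: {m[0]:.2f} a.u. at 24 hpf -> {m[-1]:.2f} a.u. at 48 hpf")
    print(f"steepest rise at {t_rise:.1f} hpf (late pri-mir-9-1 onset 36.5 +/- 1 hpf)")
    print(
        "triple-positive fraction: "
        f"{s37.fraction_3[0]:.2f} (30 hpf) -> {s37.fraction_3[1]:.2f} (37 hpf) "
        f"-> {s37.fraction_3[2]:.2f} (48 hpf)"
    )
    print(f"tables written under {OUT}/")


if __name__ == "__main__":
    main()
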