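"""Small end-to-end pipeline: generate, simplify, simulate, fit, compare.

Runs two species at one removal intensity across landscape variants A, B
and C on a reduced grid and time horizon, then prints the per-cell
estimates of K and phi and the variant deltas.  The short-dispersing
beetle loses equilibrium abundance at each simplification step (its
overwintering margins are displaced from the fields); the ballooning
spider responds only through composition, not arrangement.
"""

import mosaicpop as mp

cfg = mp.PipelineConfig(
    extent_cells=(100, 100),
    n_patches=220,
    species=("beetle", "spider"),
    intensities=(0.95,),
    variants=("A", "B", "C"),
    total_years=62,          # 11 burn-in + 3 recovery windows
    burn_in_years=11,
    n_boot=100,
    seed=12,
)
result = mp.run_pipeline(cfg)

cols = ["species", "variant", "K", "phi", "converged"]
print(result.table[cols].round(2).to_string(index=False))
print("\nvariant deltas (value at later variant minus earlier):")
print(result.variant_deltas[["species", "transition", "dK", "dphi"]]
      .round(2).to_string(index=False))
print("\nNegative dK for beetle at A->B / B->C reflects the loss of "
      "corridor-adjacent overwintering habitat; the spider's B->C shift is "
      "small relative to its K (arrangement indifference).")
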