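"""Score discovery calls against the simulator's ground truth.

Precision is the fraction of calls matching a planted transcript at 50%
reciprocal overlap on the same strand (greedy one-to-one matching); recall is
the fraction of planted transcripts recovered.
"""

from ntrscout import AnnotationIndex, SimConfig, evaluate_calls, run_discovery, simulate

matched = n_calls = n_truth = 0
for seed in range(5):
    sim = simulate(SimConfig(seed=seed))
    result = run_discovery(sim.reads, AnnotationIndex(sim.truth.genes))
    ev = evaluate_calls(result.calls, sim.truth, min_reciprocal_overlap=0.5)
    print(f"seed {seed}: {len(result.calls)} calls, "
          f"precision={ev.precision:.2f} recall={ev.recall:.2f}")
    matched += len(ev.matched)
    n_calls += len(result.calls)
    n_truth += len(sim.truth.ntr_models)

print(f"\npooled over 5 replicates: precision={matched / n_calls:.3f} "
      f"recall={matched / n_truth:.3f} "
      f"({matched}/{n_calls} calls matched, {n_truth} planted transcripts)")
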