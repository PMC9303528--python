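"""Simulate gene-family evolution and score pipeline recovery.

Generates 300 families on the backbone (10% per-branch loss, duplications
planted at Euphyllophyta/Spermatophyta with probability 0.3, transcriptome
detection 0.7), runs the full inference chain, and prints how much of the
planted truth was recovered — and how recovery degrades as losses rise.
"""

from phylomode import SimulationConfig, simulate_histories
from phylomode.pipeline import analyze_simulation
from phylomode.simulate import recovery_report

config = SimulationConfig(seed=42, n_families=300, loss_prob=0.1)
result = simulate_histories(config)
report = recovery_report(result.histories, analyze_simulation(result))

print(f"families simulated        : {report['n_families']}")
print(f"origin exact recovery     : {report['origin_recovery']:.3f}")
print(f"duplication-node recall   : {report['dup_recall']:.3f}")
print(f"duplication-node precision: {report['dup_precision']:.3f}")
print(f"mode-label accuracy       : {report['mode_accuracy']:.3f}")
print("\nmode-label confusion (rows true, columns predicted):")
print(report["mode_confusion"].to_string())

print("\norigin recovery across loss probabilities:")
for lp in (0.0, 0.05, 0.1, 0.2):
    cfg = SimulationConfig(seed=42, n_families=300, loss_prob=lp)
    res = simulate_histories(cfg)
    rep = recovery_report(res.histories, analyze_simulation(res))
    print(f"  loss_prob={lp:0.2f}: {rep['origin_recovery']:.3f}")
print("Losses erode the presence pattern, so the inferred origin (the LCA "
      "of surviving evidence) drifts tipward of the planted gain.")
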