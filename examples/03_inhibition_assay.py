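"""Channel-blocker experiment: block and recovery calls.

Simulates the three-phase protocol (10 min activity, 20 min block with
sub-5-pA residual fluctuations, 10 min recovery), then quantifies it:
per-phase spike counts, robust fluctuation magnitudes, and the
block/recovery decisions.
"""
from oncoephys import (DetectionConfig, InhibitionProtocol, RecordingConfig,
                       analyze_inhibition, block_onset_time, detect_spikes,
                       pair_biphasic, simulate_inhibition_experiment)

prot = InhibitionProtocol()  # 600 s / 1200 s / 600 s, 5-pA residual cap
cfg = RecordingConfig(duration_s=prot.total_duration_s, seed=1)
rec, truth, phases = simulate_inhibition_experiment(cfg, prot)

det = DetectionConfig()
events = pair_biphasic(detect_spikes(rec, det), det)
report = analyze_inhibition(rec, events, phases)

for label in ("before", "during", "after"):
    print(f"{label:>7}: {report.spike_counts[label]:4d} spikes, "
          f"fluctuation {report.fluctuation_magnitudes_pa[label]:6.1f} pA")
print(f"block called:    {report.block_called} "
      f"(during-count <= 10% of before AND during-magnitude <= 5 pA)")
print(f"recovery called: {report.recovery_called} "
      f"(after-count within 50% of before)")

during = next(p for p in phases if p.label == "during")
onset = block_onset_time(rec, during)
print(f"first quiet 60-s window starts {onset - during.start_s:.0f} s "
      f"into the block phase")
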